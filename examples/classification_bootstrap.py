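"""Single- vs multi-domain classification and a bootstrap MCC comparison.

Segments a mixed synthetic dataset, scores the binary verdicts (multi =
positive class), then asks via bootstrap resampling whether the MCC of two
datasets differs beyond resampling noise.
"""

from rna3dseg import (accuracy, bootstrap_mcc_difference,
                      classify_decomposition, confusion_from_pairs,
                      generate_dataset, mcc, segment_trace)

pairs = []
for trace, truth in generate_dataset(24, class_mix=0.5,
                                     length_range=(120, 300), seed=13):
    decomposition, _ = segment_trace(trace)
    pairs.append((classify_decomposition(truth),
                  classify_decomposition(decomposition)))

counts = confusion_from_pairs(pairs)
print(f"confusion: TP={counts.tp} TN={counts.tn} FP={counts.fp} FN={counts.fn}")
print(f"accuracy : {accuracy(counts):.2f} %")
print(f"MCC      : {mcc(counts):.3f}")

# interleave so both halves keep the single/multi mix
half_a, half_b = pairs[::2], pairs[1::2]
observed, p = bootstrap_mcc_difference(half_a, half_b, n_boot=10000, seed=13)
print(f"\nbootstrap MCC difference between the two halves: {observed:+.3f}, "
      f"p = {p:.3f}")
print("(p is the fraction of 10,000 resampled differences exceeding the "
      "observed one; ~0.5 means no detectable difference)")
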