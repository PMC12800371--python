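"""Segment a synthetic two-domain chain and score it against its truth.

Builds a 310-nt chain of two compact globular domains joined by a 40-nt
linker, runs the full pipeline (Mean Shift on the C3' trace, then the
rule-based refinement), and prints the recovered decomposition next to the
ground truth with the three segmentation scores.
"""

from rna3dseg import (SyntheticSpec, generate_chain, score_pair,
                      segment_trace)

spec = SyntheticSpec(blocks=(("globular_domain", 120), ("linker", 40),
                             ("globular_domain", 150)), seed=7)
trace, truth = generate_chain(spec)

decomposition, labeling = segment_trace(trace)

print(f"chain length      : {len(trace)} nt")
print(f"bandwidth         : {labeling.bandwidth:.2f} Å "
      f"(quantile 0.2 of the nearest-neighbor distances)")
print(f"raw clusters      : {labeling.n_clusters} "
      f"(+{labeling.n_outliers} outlier points)")
print()
print("ground truth      :",
      "; ".join(f"{d.label} {d.start}-{d.end}" for d in truth.domains),
      "| linkers:", ", ".join(f"{a}-{b}" for a, b in truth.linkers))
print("computed          :",
      "; ".join(f"{d.label} {d.start}-{d.end}" for d in decomposition.domains),
      "| linkers:", ", ".join(f"{a}-{b}" for a, b in decomposition.linkers))
print()
report = score_pair(decomposition, truth)
print(f"NDO {report.ndo:.3f}  DBD {report.dbd:.3f}  CSD {report.csd:.3f}")
print("(1.0 = perfect agreement; boundaries a few residues off lower CSD "
      "and DBD first, while NDO tracks bulk residue overlap)")
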