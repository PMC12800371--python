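# rna3dseg

Density-based segmentation of RNA 3D structures into **3D domains** —
compact, spatially separate regions of a single chain of at least 30 nt —
and **linkers**, unfolded connecting segments of 10–100 nt.  The package is
aimed at structural bioinformaticians who need to split large RNA
structures (ribosomal RNAs, lncRNA models, riboswitches) into regions that
can plausibly fold or be studied on their own, and at method developers who
need quantitative scores for comparing alternative segmentations.

## Method

Each nucleotide is reduced to one backbone atom (C3′ by default; C4′ or C1′
as alternatives), giving a 3D trace *x₁ … x_L*.  The trace is clustered
with **Mean Shift**: every point is shifted iteratively to the
kernel-weighted centroid of its neighborhood

&nbsp;&nbsp;&nbsp;&nbsp;*x ← Σ K(‖x − xᵢ‖/h) xᵢ / Σ K(‖x − xᵢ‖/h)*

until it moves less than 0.001 Å.  The bandwidth *h* is the mean distance
to the ⌊q·n⌋-th nearest neighbor (default quantile *q* = 0.2, uniform
kernel — the tuned optimum); converged positions within one bandwidth merge
into modes, and points farther than *h* from every mode are labeled
**outliers**.  Because density clustering ignores chain connectivity, an
eight-rule post-clustering procedure then rewrites the per-residue label
sequence: outlier runs inside a cluster are absorbed, sub-linker runs are
split between their neighbors, terminal runs below 10 nt or at/above 100 nt
are absorbed, and labeled runs below 30 nt are merged into domain-sized
neighbors — iterated to a fixed point.  Surviving clusters become domains
(possibly discontinuous); surviving outlier runs become linkers.

Decompositions are compared with:

* **NDO** (normalized domain overlap): per domain, best-match overlap minus
  all other overlaps, summed over both decompositions and normalized by
  twice the true-domain residue count (≤ 1; negative under severe
  mis-segmentation);
* **DBD** (domain boundary distance): boundary-proximity score
  Σ max{T−|Bᵢ−Bⱼ|, 0} / (T·max{m,n}) with margin T = 20 nt; a linker
  separating two domains counts whole as the boundary;
* **CSD** (chain segment distance): per-domain 5′/3′-end distances,
  S = ½·max{2T − (d⁵′+d³′), 0}, best match summed over the larger domain
  set — a compromise between the overlap and boundary views;
* **IoU** per domain pair (agreement at ≥ 0.8), **Acc**/**MCC** for the
  single- vs multi-domain verdict, and a bootstrap test for MCC
  differences between datasets.

A synthetic-backbone generator (confined random-walk globular domains,
A-form-like double-helical domains, extended linkers, with per-residue
ground truth) makes every stage testable without downloading structures.

## Worked example

```sh
python examples/segment_synthetic_chain.py
```

```
chain length      : 310 nt
bandwidth         : 19.21 Å (quantile 0.2 of the nearest-neighbor distances)
raw clusters      : 3 (+29 outlier points)

ground truth      : D1 1-120; D2 161-310 | linkers: 121-160
computed          : D1 1-122; D2 148-310 | linkers: 123-147

NDO 0.972  DBD 1.000  CSD 0.950
```

The 310-nt chain holds two globular domains joined by a 40-nt linker.  Mean
Shift finds three raw clusters plus 29 outliers; refinement absorbs the
spurious cluster and trims the outliers into a single 25-nt linker.  The
recovered boundaries sit within a few residues of the truth: DBD is perfect
because the computed linker overlaps the true one, CSD loses 0.05 for the
13-residue total end displacement, and NDO reflects the 97% residue-level
agreement.

The same pipeline is available as a command-line tool:

```sh
rna3dseg synth --blocks domain:120,linker:40,domain:150 --seed 7 -o chain.pdb --truth truth.txt
rna3dseg segment chain.pdb -o predicted.txt
rna3dseg score predicted.txt truth.txt
```

Other examples: `score_decompositions.py` (how the metrics punish merging
vs boundary shifts), `tune_grid.py` (hyperparameter grid search),
`classification_bootstrap.py` (Acc/MCC and the bootstrap comparison).

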