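"""Sequence-aware refinement of raw cluster labels into domains and linkers.

Density clustering ignores chain connectivity, so its labels can be
scattered along the sequence.  This module converts them into a
biologically meaningful decomposition with eight rules applied to maximal
runs of equal label ("segments"):

outlier rules (applied first — expanding clusters is preferred to deleting
them):

  A  an outlier segment flanked on both sides by the same cluster is
     absorbed into it (no length condition);
  B  an interior outlier shorter than the minimum linker length between two
     different clusters is split half/half (left gets the ceiling);
  C  a terminal outlier shorter than the minimum linker length or at least
     the maximum linker length, next to a cluster of domain size, is
     absorbed into that cluster;
  D  a labeled segment below domain size flanked by two outlier segments of
     at least domain size dissolves into one outlier segment;

labeled-cluster rules:

  E  a labeled segment below domain size interior to one other cluster
     (same label on both flanks, each flank of domain size) is absorbed;
  F  a terminal labeled segment below domain size next to a cluster of
     domain size is absorbed into it;
  G  a labeled segment below domain size between two different clusters of
     domain size is split half/half;
  H  a labeled segment below domain size between a cluster of domain size
     and an outlier segment is absorbed into the cluster.

Each pass applies the leftmost applicable rule instance (rule priority
breaks ties at one position), re-merges segments and restarts the scan; the
outlier pass and the labeled pass alternate until a whole alternation
changes nothing.  Rules never create new cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import OUTLIER, Domain, DomainDecomposition


@dataclass(frozen=True)
class Thresholds:
    """Length thresholds (nt) defining domains and linkers.

    A domain needs at least ``min_domain`` residues; a linker is meaningful
    only between ``min_linker`` and ``max_linker`` residues.
    """

    min_domain: int = 30
    min_linker: int = 10
    max_linker: int = 100

    def __post_init__(self) -> None:
        if not self.min_linker < self.min_domain < self.max_linker:
            raise ValueError("need min_linker < min_domain < max_linker")


@dataclass(frozen=True)
class Segment:
    """Maximal run of one label: residues ``start..end`` (1-based inclusive)."""

    label: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_outlier(self) -> bool:
        return self.label == OUTLIER


def segments_from_labels(labels: Sequence[int]) -> list[Segment]:
    """Run-length encode a per-residue label sequence."""
    labels = list(labels)
    if not labels:
        raise ValueError("label sequence must be non-empty")
    segs: list[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append(Segment(int(labels[start]), start + 1, i))
            start = i
    return segs


def labels_from_segments(segments: Sequence[Segment]) -> np.ndarray:
    """Inverse of :func:`segments_from_labels`."""
    length = segments[-1].end
    out = np.empty(length, dtype=int)
    for s in segments:
        out[s.start - 1:s.end] = s.label
    return out


def _merge(segments: Sequence[Segment]) -> list[Segment]:
    """Re-merge adjacent segments that carry the same label."""
    merged: list[Segment] = []
    for s in segments:
        if merged and merged[-1].label == s.label:
            merged[-1] = Segment(s.label, merged[-1].start, s.end)
        else:
            merged.append(s)
    return merged


def _relabel(segs: list[Segment], i: int, label: int) -> list[Segment]:
    out = list(segs)
    out[i] = Segment(label, segs[i].start, segs[i].end)
    return out


def _split(segs: list[Segment], i: int, left_label: int, right_label: int) -> list[Segment]:
    s = segs[i]
    left_len = -(-s.length // 2)  # ceil: left neighbor receives the larger half
    out = list(segs[:i])
    out.append(Segment(left_label, s.start, s.start + left_len - 1))
    if left_len < s.length:
        out.append(Segment(right_label, s.start + left_len, s.end))
    out.extend(segs[i + 1:])
    return out


def _outlier_rule_at(segs: list[Segment], i: int, th: Thresholds) -> list[Segment] | None:
    s = segs[i]
    left = segs[i - 1] if i > 0 else None
    right = segs[i + 1] if i < len(segs) - 1 else None
    if s.is_outlier:
        if left is not None and right is not None:
            if left.label == right.label:                       # rule A
                return _relabel(segs, i, left.label)
            if s.length < th.min_linker:                        # rule B
                return _split(segs, i, left.label, right.label)
        elif (s.length < th.min_linker or s.length >= th.max_linker):  # rule C
            neighbor = left if left is not None else right
            if neighbor is not None and not neighbor.is_outlier \
                    and neighbor.length >= th.min_domain:
                return _relabel(segs, i, neighbor.label)
    else:
        if (left is not None and right is not None
                and left.is_outlier and right.is_outlier
                and s.length < th.min_domain
                and left.length >= th.min_domain
                and right.length >= th.min_domain):             # rule D
            return _relabel(segs, i, OUTLIER)
    return None


def _label_rule_at(segs: list[Segment], i: int, th: Thresholds) -> list[Segment] | None:
    s = segs[i]
    if s.is_outlier or s.length >= th.min_domain:
        return None
    left = segs[i - 1] if i > 0 else None
    right = segs[i + 1] if i < len(segs) - 1 else None
    if left is not None and right is not None:
        if (not left.is_outlier and not right.is_outlier
                and left.label == right.label
                and left.length >= th.min_domain
                and right.length >= th.min_domain):             # rule E
            return _relabel(segs, i, left.label)
        if (not left.is_outlier and not right.is_outlier
                and left.label != right.label
                and left.length >= th.min_domain
                and right.length >= th.min_domain):             # rule G
            return _split(segs, i, left.label, right.label)
        if left.is_outlier != right.is_outlier:                 # rule H
            labeled = right if left.is_outlier else left
            if labeled.length >= th.min_domain:
                return _relabel(segs, i, labeled.label)
    else:                                                       # rule F
        neighbor = left if left is not None else right
        if neighbor is not None and not neighbor.is_outlier \
                and neighbor.length >= th.min_domain:
            return _relabel(segs, i, neighbor.label)
    return None


def _run_pass(segs: list[Segment], th: Thresholds, rule_at) -> list[Segment]:
    segs = _merge(segs)
    while True:
        for i in range(len(segs)):
            new = rule_at(segs, i, th)
            if new is not None:
                segs = _merge(new)
                break
        else:
            return segs


def apply_outlier_rules(segs: Sequence[Segment],
                        th: Thresholds | None = None) -> list[Segment]:
    """Apply rules A-D (leftmost instance first, restart after each) to a fixed point."""
    return _run_pass(list(segs), th or Thresholds(), _outlier_rule_at)


def apply_label_rules(segs: Sequence[Segment],
                      th: Thresholds | None = None) -> list[Segment]:
    """Apply rules E-H (leftmost instance first, restart after each) to a fixed point."""
    return _run_pass(list(segs), th or Thresholds(), _label_rule_at)


MAX_PASSES = 1000


def refine_segments(segs: Sequence[Segment],
                    th: Thresholds | None = None) -> list[Segment]:
    """Alternate the outlier and labeled passes until nothing changes."""
    th = th or Thresholds()
    segs = _merge(list(segs))
    for _ in range(MAX_PASSES):
        before = segs
        segs = apply_outlier_rules(segs, th)
        segs = apply_label_rules(segs, th)
        if segs == before:
            return segs
    raise RuntimeError("post-clustering did not reach a fixed point "
                       f"within {MAX_PASSES} passes (rule cycling?)")


def decomposition_from_segments(segs: Sequence[Segment],
                                chain_length: int | None = None) -> DomainDecomposition:
    """Turn refined segments into a decomposition.

    Surviving outlier segments become linkers; segments sharing a cluster
    label form one (possibly discontinuous) domain.  Domains are named
    ``D1, D2, ...`` in 5'→3' order of first occurrence.
    """
    length = chain_length if chain_length is not None else segs[-1].end
    segs_by_label: dict[int, list[tuple[int, int]]] = {}
    linkers: list[tuple[int, int]] = []
    for s in segs:
        if s.is_outlier:
            linkers.append((s.start, s.end))
        else:
            segs_by_label.setdefault(s.label, []).append((s.start, s.end))
    domains = tuple(Domain(f"D{k}", tuple(sorted(v)))
                    for k, v in enumerate(segs_by_label.values(), start=1))
    return DomainDecomposition(length, domains, tuple(linkers))


def refine_decomposition(labels: Sequence[int],
                         th: Thresholds | None = None) -> DomainDecomposition:
    """Full refinement: raw per-residue cluster labels → domain decomposition.

    The output label set is always a subset of the input label set — the
    rules only expand or remove clusters, never create them.
    """
    segs = refine_segments(segments_from_labels(labels), th)
    return decomposition_from_segments(segs)
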