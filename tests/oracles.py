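"""Independent brute-force reference implementations for the tests.

Everything here works directly on per-residue label arrays and explicit
enumeration, sharing no code path with the package implementation, so the
two routes can check each other.
"""

from __future__ import annotations

import numpy as np


def runs(labels):
    """Maximal runs of equal values: list of (value, start, end), 1-based."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], start + 1, i))
            start = i
    return out


def regions(label_array):
    """(name, residue set) for every domain and every linker run.

    Domains (possibly discontinuous) come first, ordered by 5'-most
    residue; linker runs follow in sequence order.
    """
    doms: dict[str, set[int]] = {}
    linker_runs = []
    for value, a, b in runs(label_array):
        if value is None:
            linker_runs.append(set(range(a, b + 1)))
        else:
            doms.setdefault(value, set()).update(range(a, b + 1))
    ordered = sorted(doms.items(), key=lambda kv: min(kv[1]))
    out = [(name, res) for name, res in ordered]
    out += [(f"linker{i}", res) for i, res in enumerate(linker_runs)]
    return out, len(ordered)


def ndo_brute(computed_labels, truth_labels):
    """Eq.-level NDO: net overlap scores summed over both directions."""
    total = 0.0
    n_true = sum(1 for v in truth_labels if v is not None)

    def side(from_labels, other_labels):
        other_regions, n_dom = regions(other_labels)
        from_regions, n_from = regions(from_labels)
        s = 0.0
        for _, res in from_regions[:n_from]:
            overlaps = [len(res & other) for _, other in other_regions]
            dom_overlaps = overlaps[:n_dom]
            best = max(dom_overlaps) if dom_overlaps else 0
            s += best - (sum(overlaps) - best)
        return s

    total = side(computed_labels, truth_labels) + side(truth_labels, computed_labels)
    return total / (2.0 * n_true)


def boundaries_brute(label_array):
    """Boundary intervals: point at the 3'-end of the upstream domain, or
    the whole linker when one separates two different domains."""
    r = runs(label_array)
    out = []
    for i in range(len(r) - 1):
        lab, a, b = r[i]
        if lab is None:
            continue
        nlab, na, nb = r[i + 1]
        if nlab is not None:
            if nlab != lab:
                out.append((b, b))
        elif i + 2 < len(r):
            lab2 = r[i + 2][0]
            if lab2 is not None and lab2 != lab:
                out.append((na, nb))
    return out


def dbd_brute(computed_labels, truth_labels, T=20):
    bi = boundaries_brute(computed_labels)
    bj = boundaries_brute(truth_labels)
    m, n = len(bi), len(bj)
    if m == 0 and n == 0:
        return 1.0
    if m == 0 or n == 0:
        return 0.0

    def dist(x, y):
        return max(x[0] - y[1], y[0] - x[1], 0)

    total = 0
    for b in bi:
        total += max(T - min(dist(b, t) for t in bj), 0)
    return total / (T * max(m, n))


def _domain_end_options(label_array):
    """Per domain (5'→3'): candidate 5' and 3' positions, including
    extension across adjacent interior linkers."""
    r = runs(label_array)
    doms: dict[str, set[int]] = {}
    for value, a, b in r:
        if value is not None:
            doms.setdefault(value, set()).update(range(a, b + 1))
    interior_linkers = [(a, b) for i, (v, a, b) in enumerate(r)
                        if v is None and 0 < i < len(r) - 1]
    out = []
    for name, res in sorted(doms.items(), key=lambda kv: min(kv[1])):
        lo, hi = min(res), max(res)
        five, three = [lo], [hi]
        for a, b in interior_linkers:
            if b == lo - 1:
                five.append(a)
            if a == hi + 1:
                three.append(b)
        out.append((five, three))
    return out


def csd_brute(computed_labels, truth_labels, T=20):
    ec = _domain_end_options(computed_labels)
    et = _domain_end_options(truth_labels)
    m, n = len(ec), len(et)

    def s(i, j):
        d5 = min(abs(x - y) for x in ec[i][0] for y in et[j][0])
        d3 = min(abs(x - y) for x in ec[i][1] for y in et[j][1])
        return 0.5 * max(2 * T - (d5 + d3), 0)

    if m >= n:
        return sum(max(s(i, j) for j in range(n)) for i in range(m)) / (T * m)
    return sum(max(s(i, j) for i in range(m)) for j in range(n)) / (T * n)


def iou_brute(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


# -- rule applicability (for the fixed-point property) ---------------------

def applicable_rules(segments, min_domain=30, min_linker=10, max_linker=100):
    """Names of rules A-H still applicable anywhere in a segment list.

    ``segments`` is a list of (label, start, end) with label -1 = outlier.
    """
    found = []
    n = len(segments)
    for i, (lab, a, b) in enumerate(segments):
        length = b - a + 1
        left = segments[i - 1] if i > 0 else None
        right = segments[i + 1] if i < n - 1 else None
        llen = left[2] - left[1] + 1 if left else 0
        rlen = right[2] - right[1] + 1 if right else 0
        if lab == -1:
            if left and right and left[0] == right[0]:
                found.append("A")
            if left and right and left[0] != right[0] and length < min_linker:
                found.append("B")
            if (left is None) != (right is None) and \
                    (length < min_linker or length >= max_linker):
                nb = left if left is not None else right
                nblen = nb[2] - nb[1] + 1
                if nb[0] != -1 and nblen >= min_domain:
                    found.append("C")
        else:
            if left and right and left[0] == -1 and right[0] == -1 \
                    and length < min_domain and llen >= min_domain and rlen >= min_domain:
                found.append("D")
            if length < min_domain:
                if left and right and left[0] not in (-1,) and right[0] not in (-1,):
                    if left[0] == right[0] and llen >= min_domain and rlen >= min_domain:
                        found.append("E")
                    if left[0] != right[0] and llen >= min_domain and rlen >= min_domain:
                        found.append("G")
                if (left is None) != (right is None):
                    nb = left if left is not None else right
                    nblen = nb[2] - nb[1] + 1
                    if nb[0] != -1 and nblen >= min_domain:
                        found.append("F")
                if left and right and (left[0] == -1) != (right[0] == -1):
                    nb = right if left[0] == -1 else left
                    nblen = nb[2] - nb[1] + 1
                    if nb[0] != -1 and nblen >= min_domain:
                        found.append("H")
    return found


# -- random decompositions --------------------------------------------------

def random_label_array(rng, length, max_domains=3, min_seg=3):
    """Random per-residue domain/linker array (None = linker) with maximal
    runs of at least ``min_seg`` residues; labels may recur, producing
    discontinuous domains.  May contain zero domains; callers filter."""
    labels = list("ABC"[:max_domains])
    arr: list = []
    prev: object = object()
    while len(arr) < length:
        seg = int(rng.integers(min_seg, min_seg + max(2, length // 3)))
        seg = min(seg, length - len(arr))
        if length - len(arr) - seg < min_seg:
            seg = length - len(arr)  # avoid a trailing run below min_seg
        options = [lab for lab in labels + [None] if lab != prev]
        pick = options[int(rng.integers(0, len(options)))]
        arr.extend([pick] * seg)
        prev = pick
    return arr
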