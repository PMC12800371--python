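"""Segmentation-quality and classification metrics.

Three segmentation scores compare a computed decomposition against a
reference on the same chain:

* **NDO** (normalized domain overlap) — residue-overlap score that rewards
  each domain's best match and subtracts every other overlap, penalizing
  over-segmentation.  At most 1; negative values indicate severe mis- or
  over-segmentation.
* **DBD** (domain boundary distance) — boundary-proximity score with a
  linear decay over a margin of T residues, normalized by T times the
  larger boundary count.  When a linker separates two domains, the whole
  linker is the boundary.
* **CSD** (chain segment distance) — per-domain 5'/3'-end distances under a
  2T budget, normalized over the larger domain set; a compromise between
  the overlap view of NDO and the boundary view of DBD.

Classification metrics (Acc, MCC) treat "multi-domain" as the positive
class, and a bootstrap test compares MCC values between datasets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Domain, DomainDecomposition

#: Minimum intersection-over-union for two domain annotations to agree.
IOU_AGREEMENT = 0.8


@dataclass(frozen=True)
class ScoreConfig:
    """Margin T (nt) of the boundary/end distance decay (default 20)."""

    T: int = 20

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; multi-domain is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ScoreReport:
    """NDO/DBD/CSD for one (computed, reference) pair."""

    ndo: float
    dbd: float
    csd: float


def _check_same_chain(a: DomainDecomposition, b: DomainDecomposition) -> None:
    if a.chain_length != b.chain_length:
        raise ValueError(f"chain lengths differ: {a.chain_length} vs {b.chain_length}")


# -- NDO -------------------------------------------------------------------

def _region_arrays(d: DomainDecomposition) -> tuple[np.ndarray, list[frozenset[int]]]:
    """Per-residue region id and the residue set of each region.

    Regions are the domains (in 5'→3' order, ids ``0..k-1``) followed by the
    linkers (ids ``k..``); every residue belongs to exactly one region.
    """
    region = np.empty(d.chain_length, dtype=int)
    sets: list[frozenset[int]] = []
    for idx, dom in enumerate(d.domains):
        for a, b in dom.segments:
            region[a - 1:b] = idx
        sets.append(dom.residues())
    k = len(d.domains)
    for j, (a, b) in enumerate(d.linkers):
        region[a - 1:b] = k + j
        sets.append(frozenset(range(a, b + 1)))
    return region, sets


def _ndo_side(from_: DomainDecomposition, other: DomainDecomposition) -> float:
    """Sum of net overlap scores S_i of the domains of ``from_`` against
    the regions (domains and linkers) of ``other``."""
    _, other_sets = _region_arrays(other)
    n_other_domains = len(other.domains)
    total = 0.0
    for dom in from_.domains:
        res = dom.residues()
        overlaps = [len(res & s) for s in other_sets]
        if n_other_domains:
            # j*: the other-side domain with the largest overlap
            # (ties: earliest in sequence, i.e. lowest domain index)
            j_star = int(np.argmax(overlaps[:n_other_domains]))
            best = overlaps[j_star]
        else:
            j_star, best = None, 0
        rest = sum(overlaps) - best
        total += best - rest
    return total


def ndo(computed: DomainDecomposition, truth: DomainDecomposition) -> float:
    """Normalized domain overlap.  Not symmetric: the normalizer counts the
    residues of the *true* domains."""
    _check_same_chain(computed, truth)
    if not truth.domains:
        raise ValueError("NDO is undefined for a reference with zero domains")
    n_true = sum(dom.size for dom in truth.domains)
    total = _ndo_side(computed, truth) + _ndo_side(truth, computed)
    return total / (2.0 * n_true)


# -- DBD -------------------------------------------------------------------

def boundary_set(d: DomainDecomposition) -> list[tuple[int, int]]:
    """Domain boundaries of a decomposition, as closed intervals.

    Walking the chain 5'→3': a junction between two *different* domains is a
    point boundary at the 3'-end residue of the upstream domain (an
    interval of length 1); when one linker separates two different domains,
    the whole linker is the boundary.  Terminal linkers and linkers between
    two segments of the same (discontinuous) domain contribute nothing.
    """
    labels = d.label_array()
    runs: list[tuple[str | None, int, int]] = []
    start = 0
    for i in range(1, d.chain_length + 1):
        if i == d.chain_length or labels[i] != labels[start]:
            runs.append((labels[start], start + 1, i))
            start = i
    out: list[tuple[int, int]] = []
    for idx in range(len(runs) - 1):
        lab, a, b = runs[idx]
        nxt_lab, na, nb = runs[idx + 1]
        if lab is None:
            continue
        if nxt_lab is not None:
            if nxt_lab != lab:
                out.append((b, b))
        elif idx + 2 < len(runs):
            after_lab, _, _ = runs[idx + 2]
            if after_lab is not None and after_lab != lab:
                out.append((na, nb))
    return out


def _interval_distance(x: tuple[int, int], y: tuple[int, int]) -> int:
    """Gap between two closed intervals (0 when they touch or overlap)."""
    return max(x[0] - y[1], y[0] - x[1], 0)


def dbd(computed: DomainDecomposition, truth: DomainDecomposition,
        cfg: ScoreConfig | None = None) -> float:
    """Domain boundary distance in [0, 1].

    Each computed boundary contributes ``max(T - d, 0)`` against its
    closest true boundary; the total is normalized by ``T * max(m, n)``,
    which keeps the score in [0, 1] on any input.  (Because domains are at
    least 30 nt long, true boundaries sit farther apart than T and at most
    one can be within the margin anyway.)  With no boundaries on either
    side the score is 1.0; with boundaries on exactly one side it is 0.0.
    """
    cfg = cfg or ScoreConfig()
    _check_same_chain(computed, truth)
    bi = boundary_set(computed)
    bj = boundary_set(truth)
    m, n = len(bi), len(bj)
    if m == 0 and n == 0:
        return 1.0
    if m == 0 or n == 0:
        return 0.0
    total = 0.0
    for b in bi:
        total += max(cfg.T - min(_interval_distance(b, t) for t in bj), 0)
    return total / (cfg.T * max(m, n))


# -- CSD -------------------------------------------------------------------

def _end_options(d: DomainDecomposition) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """For each domain (5'→3' order): candidate 5'-end and 3'-end positions.

    A domain end adjacent to an *interior* linker (one with domain residues
    on both sides) may alternatively be measured from the far end of that
    linker; the choice is made per end, whichever lowers the distance sum.
    """
    labels = d.label_array()
    runs: list[tuple[str | None, int, int]] = []
    start = 0
    for i in range(1, d.chain_length + 1):
        if i == d.chain_length or labels[i] != labels[start]:
            runs.append((labels[start], start + 1, i))
            start = i
    linker_runs = {}
    for idx, (lab, a, b) in enumerate(runs):
        if lab is None:
            interior = 0 < idx < len(runs) - 1
            linker_runs[(a, b)] = interior
    out = []
    for dom in d.domains:
        five = [dom.start]
        three = [dom.end]
        for (a, b), interior in linker_runs.items():
            if interior and b == dom.start - 1:
                five.append(a)
            if interior and a == dom.end + 1:
                three.append(b)
        out.append((tuple(five), tuple(three)))
    return out


def csd(computed: DomainDecomposition, truth: DomainDecomposition,
        cfg: ScoreConfig | None = None) -> float:
    """Chain segment distance in [0, 1].

    For each domain pair, ``S = 0.5 * max(2T - (d5 + d3), 0)`` where ``d5``
    and ``d3`` are the distances (nt) between the 5'-most and 3'-most
    residues; the score sums each larger-set domain's best S and normalizes
    by T times the larger domain count.
    """
    cfg = cfg or ScoreConfig()
    _check_same_chain(computed, truth)
    if not computed.domains or not truth.domains:
        raise ValueError("CSD is undefined when either side has zero domains")
    ends_c = _end_options(computed)
    ends_t = _end_options(truth)
    m, n = len(ends_c), len(ends_t)

    def score(ci: int, tj: int) -> float:
        (c5, c3), (t5, t3) = ends_c[ci], ends_t[tj]
        d5 = min(abs(x - y) for x in c5 for y in t5)
        d3 = min(abs(x - y) for x in c3 for y in t3)
        return 0.5 * max(2 * cfg.T - (d5 + d3), 0)

    if m >= n:
        total = sum(max(score(i, j) for j in range(n)) for i in range(m))
        return total / (cfg.T * m)
    total = sum(max(score(i, j) for i in range(m)) for j in range(n))
    return total / (cfg.T * n)


def score_pair(computed: DomainDecomposition, truth: DomainDecomposition,
               cfg: ScoreConfig | None = None) -> ScoreReport:
    """All three segmentation scores for one (computed, reference) pair."""
    return ScoreReport(ndo=ndo(computed, truth),
                       dbd=dbd(computed, truth, cfg),
                       csd=csd(computed, truth, cfg))


# -- IoU -------------------------------------------------------------------

def iou(a: Iterable[int], b: Iterable[int]) -> float:
    """Intersection-over-union of two residue sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("IoU is undefined for empty sets")
    return len(sa & sb) / len(sa | sb)


def best_match_iou(query: Domain | Iterable[int],
                   decomposition: DomainDecomposition) -> float:
    """IoU of a query domain against its best partner in a decomposition.

    The partner is the domain sharing the largest intersection with the
    query (ties: earliest in sequence); returns 0.0 when no domain
    intersects the query at all.
    """
    res = query.residues() if isinstance(query, Domain) else frozenset(query)
    if not res:
        raise ValueError("query domain is empty")
    if not decomposition.domains:
        return 0.0
    overlaps = [len(res & dom.residues()) for dom in decomposition.domains]
    j_star = int(np.argmax(overlaps))
    if overlaps[j_star] == 0:
        return 0.0
    return iou(res, decomposition.domains[j_star].residues())


# -- classification --------------------------------------------------------

def classify_decomposition(d: DomainDecomposition) -> str:
    """``"multi"`` iff the decomposition has at least two domains.

    A zero-domain (all-linker) output counts as single: no segmentation was
    found.
    """
    return "multi" if len(d.domains) >= 2 else "single"


def accuracy(c: ConfusionCounts) -> float:
    """Accuracy as a percentage."""
    if c.total == 0:
        raise ValueError("accuracy is undefined for empty counts")
    return 100.0 * (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)


def confusion_from_pairs(pairs: Sequence[tuple[str, str]]) -> ConfusionCounts:
    """Confusion counts from (true class, predicted class) pairs, classes
    being ``"single"``/``"multi"``."""
    tp = sum(1 for t, p in pairs if t == "multi" and p == "multi")
    tn = sum(1 for t, p in pairs if t == "single" and p == "single")
    fp = sum(1 for t, p in pairs if t == "single" and p == "multi")
    fn = sum(1 for t, p in pairs if t == "multi" and p == "single")
    if tp + tn + fp + fn != len(pairs):
        raise ValueError('classes must be "single" or "multi"')
    return ConfusionCounts(tp, tn, fp, fn)


def _mcc_vectorized(tp, tn, fp, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out = np.zeros_like(denom, dtype=float)
    nz = denom > 0
    out[nz] = (tp[nz] * tn[nz] - fp[nz] * fn[nz]) / np.sqrt(denom[nz])
    return out


def bootstrap_mcc_difference(set_a: Sequence[tuple[str, str]],
                             set_b: Sequence[tuple[str, str]],
                             n_boot: int = 10000,
                             seed: int = 0) -> tuple[float, float]:
    """Bootstrap test of the MCC difference between two labeled datasets.

    Each replicate resamples each dataset with replacement to its own
    original size and recomputes both MCCs (zero-denominator resamples use
    the MCC = 0 convention).  Returns ``(observed difference, p)`` where p
    is the fraction of replicate differences greater than the observed one.
    Deterministic given ``seed``.
    """
    if not set_a or not set_b:
        raise ValueError("both datasets must be non-empty")
    observed = mcc(confusion_from_pairs(set_a)) - mcc(confusion_from_pairs(set_b))
    rng = np.random.default_rng(seed)

    def resampled_mcc(pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        true = np.array([t == "multi" for t, _ in pairs])
        pred = np.array([p == "multi" for _, p in pairs])
        idx = rng.integers(0, len(pairs), size=(n_boot, len(pairs)))
        t, p = true[idx], pred[idx]
        tp = np.sum(t & p, axis=1)
        tn = np.sum(~t & ~p, axis=1)
        fp = np.sum(~t & p, axis=1)
        fn = np.sum(t & ~p, axis=1)
        return _mcc_vectorized(tp, tn, fp, fn)

    diffs = resampled_mcc(set_a) - resampled_mcc(set_b)
    p_value = float(np.mean(diffs > observed))
    return observed, p_value


# -- hyperparameter tuning harness -----------------------------------------

def tune_hyperparameters(dataset: Sequence[tuple["ChainTrace", DomainDecomposition]],
                         quantiles: Sequence[float],
                         kernels: Sequence[str],
                         cfg: ScoreConfig | None = None,
                         thresholds=None,
                         segment_fn: Callable | None = None,
                         ) -> tuple[pd.DataFrame, dict[str, tuple[str, float]]]:
    """Grid-evaluate the full pipeline (cluster → refine → score).

    Only multi-domain references are used — with wide bandwidths Mean Shift
    trivially produces single clusters, which would bias the tuning toward
    single-domain annotations.  Returns the per-cell mean-score table and,
    per metric, the argmax ``(kernel, quantile)`` cell.
    """
    from .pipeline import segment_trace  # deferred: avoid import cycle

    if not quantiles or not kernels:
        raise ValueError("the hyperparameter grid must be non-empty")
    cfg = cfg or ScoreConfig()
    segment_fn = segment_fn or segment_trace
    multi = [(trace, truth) for trace, truth in dataset if len(truth.domains) >= 2]
    if not multi:
        raise ValueError("tuning needs at least one multi-domain reference")
    rows = []
    for kernel, quantile in itertools.product(kernels, quantiles):
        from .meanshift import MeanShiftConfig
        config = MeanShiftConfig(bandwidth_quantile=quantile, kernel=kernel)
        reports = []
        for trace, truth in multi:
            computed, _ = segment_fn(trace, config=config, thresholds=thresholds)
            reports.append(score_pair(computed, truth, cfg))
        rows.append({
            "kernel": kernel,
            "quantile": quantile,
            "mean_ndo": float(np.mean([r.ndo for r in reports])),
            "mean_dbd": float(np.mean([r.dbd for r in reports])),
            "mean_csd": float(np.mean([r.csd for r in reports])),
            "n_chains": len(multi),
        })
    table = pd.DataFrame(rows)
    best = {}
    for metric in ("ndo", "dbd", "csd"):
        row = table.loc[table[f"mean_{metric}"].idxmax()]
        best[metric] = (str(row["kernel"]), float(row["quantile"]))
    return table, best
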