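"""Ground-truthed synthetic RNA-like backbones.

The generator emulates the geometry the segmentation pipeline targets:
chains of compact globular domains (confined random walks), optional
double-helix-like elongated domains (two antiparallel strands on a
cylinder), and extended linkers, with per-residue ground-truth labels.
Defaults follow conventional RNA backbone geometry: consecutive C3'-C3'
spacing ~5.9 Å, A-form-like helices (~9 Å radius, ~2.8 Å rise per base
pair, 11 bp per turn).  Domain compactness scales as r = 2.7·L^(1/3) Å,
giving realistic densities for folded RNA.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .core import ChainTrace, DomainDecomposition
from .postcluster import Thresholds

_KINDS = ("globular_domain", "helical_domain", "linker")

#: A-form-like helix geometry (Å, radians).
HELIX_RADIUS = 9.0
HELIX_RISE = 2.8
HELIX_TWIST = 2.0 * np.pi / 11.0

#: Soft self-avoidance: resample steps closer than this to recent residues.
MIN_SELF_DISTANCE = 3.0
_SELF_AVOID_TRIES = 30
_SELF_AVOID_WINDOW = 12


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic chain.

    blocks : ordered ``(kind, length)`` pairs; kinds are
        ``globular_domain``, ``helical_domain``, ``linker``.  Domain blocks
        must be >= 30 nt, linker blocks 10-100 nt.
    step_length : consecutive-residue spacing in domains (Å).
    domain_radius_scale : sphere radius per nt^(1/3) for globular domains.
    linker_rise : Å advanced per linker residue.
    jitter : std of Gaussian positional noise (Å).
    """

    blocks: tuple[tuple[str, int], ...]
    step_length: float = 5.9
    domain_radius_scale: float = 2.7
    linker_rise: float = 5.0
    jitter: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        blocks = tuple((str(k), int(n)) for k, n in self.blocks)
        if not blocks:
            raise ValueError("at least one block is required")
        th = Thresholds()
        for kind, length in blocks:
            if kind not in _KINDS:
                raise ValueError(f"unknown block kind {kind!r}")
            if kind.endswith("domain") and length < th.min_domain:
                raise ValueError(f"domain blocks need >= {th.min_domain} nt, got {length}")
            if kind == "linker" and not th.min_linker <= length <= th.max_linker:
                raise ValueError(f"linker blocks must be {th.min_linker}-{th.max_linker} nt, "
                                 f"got {length}")
        if sum(n for _, n in blocks) < th.min_domain:
            raise ValueError("total length must be >= 30 nt")
        object.__setattr__(self, "blocks", blocks)

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.blocks)


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _basis_perp(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return e1, e2


def _globular_radius(scale: float, length: int) -> float:
    return scale * length ** (1.0 / 3.0)


def _globular_walk(rng: np.random.Generator, length: int, center: np.ndarray,
                   start: np.ndarray, step: float, radius: float) -> np.ndarray:
    """Fixed-step random walk confined to a sphere, reflecting at the
    boundary, with soft self-avoidance."""
    pts = np.empty((length, 3))
    pts[0] = start
    for i in range(1, length):
        nxt = None
        for _ in range(_SELF_AVOID_TRIES):
            cand = pts[i - 1] + step * _random_unit(rng)
            v = cand - center
            r = np.linalg.norm(v)
            if r > radius:
                cand = center + v / r * max(2 * radius - r, 0.1 * radius)
            recent = pts[max(0, i - _SELF_AVOID_WINDOW):i - 1]
            if recent.size == 0 or np.linalg.norm(recent - cand, axis=1).min() >= MIN_SELF_DISTANCE:
                nxt = cand
                break
            nxt = cand  # accepted anyway if tries run out
        pts[i] = nxt
    return pts


def _helix(length: int, origin: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Two antiparallel strands wound on a cylinder, 5'→3' up then back."""
    e1, e2 = _basis_perp(axis)
    n1 = -(-length // 2)  # ceil
    n2 = length - n1
    pts = np.empty((length, 3))
    for t in range(n1):
        phi = t * HELIX_TWIST
        pts[t] = origin + axis * (HELIX_RISE * t) + HELIX_RADIUS * (
            np.cos(phi) * e1 + np.sin(phi) * e2)
    for k in range(n2):
        t = n2 - 1 - k  # descend the axis
        phi = t * HELIX_TWIST + np.pi
        pts[n1 + k] = origin + axis * (HELIX_RISE * t) + HELIX_RADIUS * (
            np.cos(phi) * e1 + np.sin(phi) * e2)
    return pts


def _helix_extent(length: int) -> float:
    """Effective half-extent of a helical domain, for spacing purposes."""
    n1 = -(-length // 2)
    return 0.5 * HELIX_RISE * (n1 - 1) + HELIX_RADIUS


def generate_chain(spec: SyntheticSpec) -> tuple[ChainTrace, DomainDecomposition]:
    """Generate one chain and its ground-truth decomposition.

    Consecutive domains are guaranteed centroid separations larger than
    twice the larger domain radius: linkers point away from the previous
    domain's centroid and are stretched (uniformly per residue) when their
    nominal span would be too short.
    """
    rng = np.random.default_rng(spec.seed)
    coords: list[np.ndarray] = []
    labels: list[str | None] = []
    cursor = np.zeros(3)
    direction = _random_unit(rng)
    prev_center: np.ndarray | None = None
    prev_radius = 0.0
    centers: list[np.ndarray] = []
    n_domains = 0

    for kind, length in spec.blocks:
        if kind == "linker":
            if prev_center is not None:
                direction = _unit(cursor - prev_center)
                if np.dot(direction, cursor - prev_center) < 1e-9:
                    direction = _random_unit(rng)
            rise = spec.linker_rise
            # stretch if the next domain could otherwise sit too close
            upcoming = _next_domain_radius(spec, kind, length, labels)
            if prev_center is not None and upcoming is not None:
                needed = 2.0 * max(prev_radius, upcoming) + 1.0
                nominal = float(np.linalg.norm(cursor - prev_center)) + rise * length + upcoming
                if nominal < needed:
                    rise = (needed - upcoming - float(np.linalg.norm(cursor - prev_center))) / length
            base = cursor if coords else cursor - rise * direction
            for i in range(1, length + 1):
                coords.append(base + rise * i * direction)
            labels.extend([None] * length)
            cursor = coords[-1]
            continue

        n_domains += 1
        label = f"D{n_domains}"
        if coords and prev_center is not None:
            away = cursor - prev_center
            if np.linalg.norm(away) > 1e-9:
                direction = _unit(away)
        if kind == "globular_domain":
            radius = _globular_radius(spec.domain_radius_scale, length)
            if coords:
                start = cursor + spec.step_length * direction
                center = cursor + direction * radius
            else:
                start = cursor
                center = cursor + direction * radius
            pts = _globular_walk(rng, length, center, start, spec.step_length, radius)
            centroid = center
            extent = radius
        else:
            origin = cursor + spec.step_length * direction if coords else cursor
            pts = _helix(length, origin, direction)
            n1 = -(-length // 2)
            centroid = origin + direction * (0.5 * HELIX_RISE * (n1 - 1))
            extent = _helix_extent(length)
        coords.extend(pts)
        labels.extend([label] * length)
        cursor = coords[-1]
        prev_center, prev_radius = centroid, extent
        centers.append(centroid)

    arr = np.array(coords)
    if spec.jitter > 0:
        arr = arr + rng.normal(0.0, spec.jitter, size=arr.shape)
    trace = ChainTrace("A", "C3'",
                       tuple(str(i) for i in range(1, spec.total_length + 1)), arr)
    truth = DomainDecomposition.from_label_array(labels)
    return trace, truth


def _next_domain_radius(spec: SyntheticSpec, kind: str, length: int,
                        labels_so_far: list) -> float | None:
    """Radius of the domain block following the current linker, if any."""
    consumed = len(labels_so_far) + length
    running = 0
    for k, n in spec.blocks:
        running += n
        if running <= consumed:
            continue
        if k == "globular_domain":
            return _globular_radius(spec.domain_radius_scale, n)
        if k == "helical_domain":
            return _helix_extent(n)
        return None  # two consecutive linkers: no constraint to enforce
    return None


def generate_dataset(n: int, class_mix: float = 0.5,
                     length_range: tuple[int, int] = (100, 400),
                     seed: int = 0,
                     helical_fraction: float = 0.0,
                     ) -> list[tuple[ChainTrace, DomainDecomposition]]:
    """Reproducible collection of single- and multi-domain chains.

    ``class_mix`` is the fraction of multi-domain chains (two globular or
    helical domains joined by a 30-60 nt linker); the rest are
    single-domain, a third of which carry a terminal linker.  Per-chain
    seeds are derived from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= class_mix <= 1.0:
        raise ValueError("class_mix must be in [0, 1]")
    n_multi = round(n * class_mix)
    lo, hi = length_range
    if lo < 70:
        raise ValueError("length_range must allow a 30-nt domain plus linkers (>= 70)")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n)
    out = []
    for i in range(n):
        rng = np.random.default_rng(child_seeds[i])
        total = int(rng.integers(lo, hi + 1))
        kind = ("helical_domain" if rng.random() < helical_fraction
                else "globular_domain")
        if i < n_multi:
            total = max(total, 120)  # room for two domains and a linker
            linker = int(rng.integers(30, min(60, total - 60) + 1))
            d1 = int(rng.integers(30, total - linker - 30 + 1))
            d2 = total - linker - d1
            blocks = ((kind, d1), ("linker", linker), (kind, d2))
        else:
            if rng.random() < 1 / 3 and total >= 60:
                tail = int(rng.integers(10, min(60, total - 30) + 1))
                blocks = ((kind, total - tail), ("linker", tail))
            else:
                blocks = ((kind, total),)
        spec = SyntheticSpec(blocks=blocks, seed=int(child_seeds[i]))
        out.append(generate_chain(spec))
    return out


_RESIDUE_NAMES = ("A", "C", "G", "U")


def export_fixture(trace: ChainTrace, path: str | Path) -> None:
    """Write a trace as a PDB file, one ATOM record per residue.

    Residue names cycle A, C, G, U; author numbering is preserved.
    Re-importing through :mod:`rna3dseg.structure_io` reproduces the
    coordinates to the 0.001 Å precision of the PDB format.
    """
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chain = gemmi.Chain(trace.chain_id)
    for i, (num, xyz) in enumerate(zip(trace.author_numbers, trace.coords)):
        res = gemmi.Residue()
        res.name = _RESIDUE_NAMES[i % 4]
        num_str = str(num)
        icode = ""
        while num_str and not (num_str[-1].isdigit() or num_str[-1] == "-"):
            icode = num_str[-1] + icode
            num_str = num_str[:-1]
        res.seqid = gemmi.SeqId(int(num_str), icode[0] if icode else " ")
        atom = gemmi.Atom()
        atom.name = trace.atom_name
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
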