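"""Core value types shared by every pipeline stage.

The whole pipeline operates on *observed-residue* indices: residues are
numbered 1..L consecutively over the residues that actually carry the chosen
backbone atom.  Author numbering (PDB residue numbers plus insertion codes)
is carried along as opaque text for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel cluster label for points not assigned to any cluster.
OUTLIER: int = -1

#: Backbone atoms usable as single-atom representations of a nucleotide.
ALLOWED_ATOMS = ("C3'", "C4'", "C1'")

#: Reserved label marking linker records in annotation files.
LINKER_LABEL = "linker"


class StructureParseError(ValueError):
    """A coordinate file could not be parsed."""


class AnnotationError(ValueError):
    """A domain-decomposition annotation file is malformed or inconsistent."""


@dataclass(frozen=True)
class ChainTrace:
    """Ordered single-atom coordinate trace of one RNA chain.

    ``coords[i]`` is the position (Å) of observed residue ``i + 1``;
    ``author_numbers[i]`` is the source-file residue number (plus any
    insertion code) of that residue, kept as opaque text.
    """

    chain_id: str
    atom_name: str
    author_numbers: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.atom_name not in ALLOWED_ATOMS:
            raise ValueError(f"atom_name must be one of {ALLOWED_ATOMS}, got {self.atom_name!r}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (L, 3) array")
        if coords.shape[0] < 1:
            raise ValueError("a trace must contain at least one residue")
        if not np.all(np.isfinite(coords)):
            raise ValueError("all coordinates must be finite")
        if len(self.author_numbers) != coords.shape[0]:
            raise ValueError("author_numbers and coords must have equal length")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "author_numbers", tuple(self.author_numbers))

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class Domain:
    """One (possibly discontinuous) domain: a labeled union of segments.

    Segments are 1-based inclusive ``(start, end)`` pairs, sorted and
    non-adjacent (maximal).
    """

    label: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        if not segs:
            raise ValueError("a domain needs at least one segment")
        for a, b in segs:
            if a < 1 or b < a:
                raise ValueError(f"invalid segment {a}-{b}")
        segs = tuple(sorted(segs))
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 <= b1 + 1:
                raise ValueError(f"segments of domain {self.label!r} overlap or touch: "
                                 f"{a1}-{b1}, {a2}-{b2}")
        object.__setattr__(self, "segments", segs)

    @property
    def start(self) -> int:
        """5'-most residue index."""
        return self.segments[0][0]

    @property
    def end(self) -> int:
        """3'-most residue index."""
        return self.segments[-1][1]

    @property
    def size(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    def residues(self) -> frozenset[int]:
        return frozenset(i for a, b in self.segments for i in range(a, b + 1))


@dataclass(frozen=True)
class DomainDecomposition:
    """Final segmentation of a chain into domains and linkers.

    Domains and linkers are pairwise disjoint and jointly cover
    ``1..chain_length``; domain labels are unique.  Domains are stored in
    5'→3' order of their 5'-most residue, linkers in sequence order.
    """

    chain_length: int
    domains: tuple[Domain, ...]
    linkers: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        domains = tuple(sorted(self.domains, key=lambda d: d.start))
        labels = [d.label for d in domains]
        if len(set(labels)) != len(labels):
            raise ValueError("domain labels must be unique")
        linkers = tuple(sorted((int(a), int(b)) for a, b in self.linkers))
        covered = np.zeros(self.chain_length, dtype=bool)
        for d in domains:
            for a, b in d.segments:
                self._claim(covered, a, b, f"domain {d.label!r}")
        for a, b in linkers:
            if a < 1 or b < a:
                raise ValueError(f"invalid linker segment {a}-{b}")
            self._claim(covered, a, b, "linker")
        if not covered.all():
            first = int(np.flatnonzero(~covered)[0]) + 1
            raise ValueError(f"residue {first} is covered by neither domain nor linker")
        object.__setattr__(self, "domains", domains)
        object.__setattr__(self, "linkers", linkers)

    def _claim(self, covered: np.ndarray, a: int, b: int, what: str) -> None:
        if b > self.chain_length:
            raise ValueError(f"{what} segment {a}-{b} exceeds chain length {self.chain_length}")
        window = covered[a - 1:b]
        if window.any():
            raise ValueError(f"{what} segment {a}-{b} overlaps another record")
        window[:] = True

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_label_array(cls, labels: Sequence[str | None],
                         chain_length: int | None = None) -> "DomainDecomposition":
        """Build from a per-residue array of domain labels (``None`` = linker)."""
        labels = list(labels)
        L = chain_length if chain_length is not None else len(labels)
        if len(labels) != L:
            raise ValueError("label array length must equal chain_length")
        segs_by_label: dict[str | None, list[tuple[int, int]]] = {}
        start = 0
        for i in range(1, L + 1):
            if i == L or labels[i] != labels[start]:
                segs_by_label.setdefault(labels[start], []).append((start + 1, i))
                start = i
        linkers = tuple(segs_by_label.pop(None, ()))
        domains = tuple(Domain(lab, tuple(segs)) for lab, segs in segs_by_label.items())
        return cls(L, domains, linkers)

    def label_array(self) -> list[str | None]:
        """Per-residue domain label, ``None`` on linker residues."""
        out: list[str | None] = [None] * self.chain_length
        for d in self.domains:
            for a, b in d.segments:
                for i in range(a - 1, b):
                    out[i] = d.label
        return out

    def relabeled(self, mapping: dict[str, str]) -> "DomainDecomposition":
        """Return a copy with domain labels renamed through ``mapping``."""
        return DomainDecomposition(
            self.chain_length,
            tuple(Domain(mapping.get(d.label, d.label), d.segments) for d in self.domains),
            self.linkers,
        )


def format_ranges(segments: Iterable[tuple[int, int]]) -> str:
    """Render segments as the comma-joined ``start-end`` annotation syntax."""
    return ",".join(f"{a}-{b}" for a, b in segments)
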