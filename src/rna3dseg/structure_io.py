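"""Reading structures and annotation files; writing decompositions.

Coordinate files are parsed with :mod:`gemmi` (PDB and mmCIF).  Only the
first model of multi-model files is used, and for alternate-location atoms
the highest-occupancy copy is kept (ties go to the first one encountered).

Annotation files are plain text, one record per line::

    # comment
    D1 1-50,120-180
    linker 51-119

``label<whitespace>start-end[,start-end...]`` with 1-based inclusive ranges;
the reserved label ``linker`` marks linkers; residues not listed in any
record default to linkers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .core import (ALLOWED_ATOMS, LINKER_LABEL, AnnotationError, ChainTrace,
                   Domain, DomainDecomposition, StructureParseError,
                   format_ranges)

logger = logging.getLogger(__name__)

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def parse_structure(path: str | Path, format: str = "auto") -> gemmi.Structure:
    """Read a coordinate file and return a structure handle.

    Parameters
    ----------
    path : file path to a PDB or mmCIF file.
    format : ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from contents).
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMATS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureParseError(f"{path}: no models found")
    if len(structure) > 1:
        logger.warning("%s: %d models found, keeping model 1 only", path, len(structure))
        for i in range(len(structure) - 1, 0, -1):
            del structure[i]
    structure.setup_entities()
    return structure


def chain_ids(structure: gemmi.Structure) -> list[str]:
    """Names of the chains in the (first) model."""
    return [chain.name for chain in structure[0]]


def extract_trace(structure: gemmi.Structure, chain_id: str,
                  atom_name: str = "C3'") -> ChainTrace:
    """Extract the single-atom trace of one chain, ordered 5'→3'.

    One point per residue possessing ``atom_name``; residues lacking the
    atom are skipped with a logged warning.  For alternate locations the
    highest-occupancy atom is kept.
    """
    if atom_name not in ALLOWED_ATOMS:
        raise ValueError(f"atom_name must be one of {ALLOWED_ATOMS}, got {atom_name!r}")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise KeyError(f"chain {chain_id!r} not found; available: {chain_ids(structure)}")
    coords: list[tuple[float, float, float]] = []
    numbers: list[str] = []
    for residue in chain:
        best = None
        for atom in residue:
            if atom.name != atom_name:
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        icode = residue.seqid.icode.strip()
        author = f"{residue.seqid.num}{icode}"
        if best is None:
            if residue.is_water() or not any(True for _ in residue):
                continue
            logger.warning("chain %s residue %s (%s) lacks atom %s; skipped",
                           chain_id, author, residue.name, atom_name)
            continue
        coords.append((best.pos.x, best.pos.y, best.pos.z))
        numbers.append(author)
    if not coords:
        raise ValueError(f"chain {chain_id!r} has no residue with atom {atom_name!r}")
    return ChainTrace(chain_id, atom_name, tuple(numbers), np.array(coords, dtype=float))


def first_rna_chain(structure: gemmi.Structure, atom_name: str = "C3'") -> str:
    """Name of the first chain containing at least one residue with ``atom_name``."""
    for chain in structure[0]:
        for residue in chain:
            if any(atom.name == atom_name for atom in residue):
                return chain.name
    raise ValueError(f"no chain contains atom {atom_name!r}")


# -- annotation files ------------------------------------------------------

def _parse_ranges(text: str, lineno: int) -> list[tuple[int, int]]:
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        lo, sep, hi = part.partition("-")
        try:
            a = int(lo)
            b = int(hi) if sep else a
        except ValueError:
            raise AnnotationError(f"line {lineno}: cannot parse range {part!r}") from None
        if b < a or a < 1:
            raise AnnotationError(f"line {lineno}: invalid range {part!r}")
        out.append((a, b))
    if not out:
        raise AnnotationError(f"line {lineno}: record has no ranges")
    return out


def read_decomposition(path: str | Path, chain_length: int) -> DomainDecomposition:
    """Read an annotation file into a :class:`DomainDecomposition`.

    Residues not listed in any record are linkers by default.  Repeated
    labels accumulate segments into one (discontinuous) domain.
    """
    segs_by_label: dict[str, list[tuple[int, int]]] = {}
    linker_segs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split(None, 1)
            if len(fields) != 2:
                raise AnnotationError(f"line {lineno}: expected 'label ranges', got {raw!r}")
            label, ranges = fields
            segs = _parse_ranges(ranges, lineno)
            for a, b in segs:
                if b > chain_length:
                    raise AnnotationError(
                        f"line {lineno}: segment {a}-{b} outside 1..{chain_length}")
            if label.lower() == LINKER_LABEL:
                linker_segs.extend(segs)
            else:
                segs_by_label.setdefault(label, []).extend(segs)
    covered = np.zeros(chain_length, dtype=bool)
    for label, segs in segs_by_label.items():
        for a, b in segs:
            if covered[a - 1:b].any():
                raise AnnotationError(f"segment {a}-{b} of {label!r} overlaps another record")
            covered[a - 1:b] = True
    for a, b in linker_segs:
        if covered[a - 1:b].any():
            raise AnnotationError(f"linker segment {a}-{b} overlaps another record")
        covered[a - 1:b] = True
    # fill unlisted residues as linkers
    implicit = _runs(~covered)
    all_linkers = _merge_adjacent(sorted(linker_segs + implicit))
    domains = tuple(Domain(lab, tuple(sorted(segs))) for lab, segs in segs_by_label.items())
    return DomainDecomposition(chain_length, domains, tuple(all_linkers))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """1-based inclusive runs of True in a boolean array."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        out.append((int(idx[s]) + 1, int(idx[e]) + 1))
    return out


def _merge_adjacent(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in segs:
        if merged and a == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def write_decomposition(decomposition: DomainDecomposition, path: str | Path,
                        style: str = "ranges",
                        author_numbers: Sequence[str] | None = None) -> None:
    """Write a decomposition to ``path``.

    ``ranges`` style emits one line per domain/linker (round-trips exactly
    through :func:`read_decomposition`); ``per_residue`` emits a TSV of
    ``seq_index, author_number, label``.
    """
    if style not in ("ranges", "per_residue"):
        raise ValueError(f"unknown style {style!r}")
    import contextlib
    ctx = (contextlib.nullcontext(path) if hasattr(path, "write")
           else open(path, "w"))
    with ctx as fh:
        if style == "ranges":
            for d in decomposition.domains:
                fh.write(f"{d.label}\t{format_ranges(d.segments)}\n")
            for a, b in decomposition.linkers:
                fh.write(f"{LINKER_LABEL}\t{a}-{b}\n")
        else:
            labels = decomposition.label_array()
            if author_numbers is None:
                author_numbers = [str(i) for i in range(1, decomposition.chain_length + 1)]
            if len(author_numbers) != decomposition.chain_length:
                raise ValueError("author_numbers length must equal chain_length")
            fh.write("seq_index\tauthor_number\tlabel\n")
            for i, (num, lab) in enumerate(zip(author_numbers, labels), start=1):
                fh.write(f"{i}\t{num}\t{lab if lab is not None else LINKER_LABEL}\n")
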