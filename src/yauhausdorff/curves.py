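"""Graphical (2D curve) encodings of DNA and protein sequences.

A sequence of length ``l`` is drawn as a planar curve with ``l + 1`` points:
the walk starts at the origin and advances by one unit in x per residue,
while the y step carries the residue identity.  The DNA steps are fixed::

    T -> (1,  2/3)    A -> (1,  1/3)    C -> (1, -1/3)    G -> (1, -2/3)

so a DNA curve encodes its sequence exactly (the y increments are distinct,
hence the map is invertible).  Protein curves use per-amino-acid y steps in
``[-1, 1]`` derived from a hydrophobicity scale: amino acids with positive
scale values are spread uniformly over ``(0, 1]`` in ascending scale order,
the non-positive ones uniformly over ``[-1, 0)`` in descending scale order.
The default scale is the Fauchere-Pliska octanol/water partition scale; any
20-value scale (or a fully explicit step table) may be substituted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .errors import InputError

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Fauchere & Pliska (1983) octanol/water side-chain hydrophobicity (pi values).
FAUCHERE_PLISKA: Mapping[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}


@dataclass(frozen=True)
class SequenceRecord:
    """A validated sequence: an identifier and its residue string."""

    id: str
    residues: str


@dataclass(frozen=True)
class AlphabetMapping:
    """Residue -> (dx, dy) step table; dx is always exactly 1."""

    kind: str  # "dna" or "protein"
    steps: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.kind not in ("dna", "protein"):
            raise InputError(f"unknown alphabet kind {self.kind!r}")
        expected = set(DNA_ALPHABET) if self.kind == "dna" else set(AMINO_ACIDS)
        if set(self.steps) != expected:
            raise InputError(
                f"{self.kind} mapping must have exactly the keys "
                f"{''.join(sorted(expected))}, got {''.join(sorted(self.steps))}"
            )
        for res, (dx, dy) in self.steps.items():
            if dx != 1:
                raise InputError(f"step for {res!r} has dx={dx}, expected exactly 1")
            if self.kind == "protein" and not -1.0 <= dy <= 1.0:
                raise InputError(f"protein step for {res!r} has dy={dy} outside [-1, 1]")

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.steps)


@dataclass(frozen=True)
class SequenceCurve:
    """A labeled curve: ``points`` has shape (l+1, 2), starts at the origin."""

    label: str
    points: np.ndarray = field(repr=False)


def default_dna_mapping() -> AlphabetMapping:
    """The fixed four-vector DNA step table."""
    return AlphabetMapping(
        kind="dna",
        steps={
            "T": (1.0, 2.0 / 3.0),
            "A": (1.0, 1.0 / 3.0),
            "C": (1.0, -1.0 / 3.0),
            "G": (1.0, -2.0 / 3.0),
        },
    )


def protein_mapping_from_scale(scale: Mapping[str, float]) -> AlphabetMapping:
    """Build the 20-entry protein step table from a hydrophobicity scale.

    Positive-scale amino acids get ``dy = rank / P`` (ascending scale ->
    ascending dy, so the most hydrophobic maps to +1); the ``Q`` non-positive
    ones get ``dy = -rank / Q`` in descending scale order (the least
    hydrophilic maps to the smallest magnitude, the most hydrophilic to -1).

    Raises on anything but 20 distinct values: with ties the ranking is
    undefined and silently breaking them would change every downstream
    distance.
    """
    if len(scale) != 20:
        raise InputError(f"hydrophobicity scale must have 20 keys, got {len(scale)}")
    return AlphabetMapping(kind="protein", steps=_rank_uniform_steps(scale))


def _rank_uniform_steps(scale: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    """Rank-uniform y-step construction, agnostic of alphabet size."""
    values = list(scale.values())
    if len(set(values)) != len(values):
        raise InputError("hydrophobicity scale has tied values; ranking is undefined")
    positives = sorted((v, aa) for aa, v in scale.items() if v > 0)
    nonpos = sorted(((v, aa) for aa, v in scale.items() if v <= 0), reverse=True)
    steps: dict[str, tuple[float, float]] = {}
    for rank, (_, aa) in enumerate(positives, start=1):
        steps[aa] = (1.0, rank / len(positives))
    for rank, (_, aa) in enumerate(nonpos, start=1):
        steps[aa] = (1.0, -rank / len(nonpos))
    return steps


def default_protein_mapping() -> AlphabetMapping:
    """Protein step table from the Fauchere-Pliska scale."""
    return protein_mapping_from_scale(FAUCHERE_PLISKA)


def read_fasta(
    path: str | Path,
    alphabet: str,
    on_ambiguous: str = "error",
) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are uppercased; for DNA, ``U`` is transliterated to ``T`` before
    validation.  Symbols outside the alphabet (ambiguity codes such as ``N``,
    ``R``, protein ``X``) are handled per ``on_ambiguous``: ``"error"`` aborts
    naming the symbol and its 1-based position, ``"skip"`` drops them (logged)
    — skipping alters the curve, so erroring is the default.
    """
    if alphabet not in ("dna", "protein"):
        raise InputError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    if on_ambiguous not in ("error", "skip"):
        raise InputError(f"on_ambiguous must be 'error' or 'skip', got {on_ambiguous!r}")
    allowed = set(DNA_ALPHABET) if alphabet == "dna" else set(AMINO_ACIDS)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "dna":
            seq = seq.replace("U", "T")
        bad = [(i, c) for i, c in enumerate(seq) if c not in allowed]
        if bad:
            if on_ambiguous == "error":
                i, c = bad[0]
                raise InputError(
                    f"record {rec.id!r}: symbol {c!r} at position {i + 1} is not a "
                    f"{alphabet} residue (use on_ambiguous='skip' to drop it)"
                )
            logger.info(
                "record %r: dropping %d symbol(s) outside the %s alphabet",
                rec.id, len(bad), alphabet,
            )
            drop = {i for i, _ in bad}
            seq = "".join(c for i, c in enumerate(seq) if i not in drop)
        if not seq:
            raise InputError(f"record {rec.id!r} has no residues after validation")
        records.append(SequenceRecord(id=rec.id, residues=seq))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def encode(record: SequenceRecord, mapping: AlphabetMapping) -> SequenceCurve:
    """Encode a sequence as its graphical curve (cumulative sum of steps)."""
    steps = mapping.steps
    for i, c in enumerate(record.residues):
        if c not in steps:
            raise InputError(
                f"record {record.id!r}: residue {c!r} at position {i + 1} "
                f"is not in the {mapping.kind} step table"
            )
    dy = np.fromiter((steps[c][1] for c in record.residues), dtype=float)
    n = len(record.residues)
    points = np.empty((n + 1, 2), dtype=float)
    points[:, 0] = np.arange(n + 1, dtype=float)
    points[0, 1] = 0.0
    np.cumsum(dy, out=points[1:, 1])
    return SequenceCurve(label=record.id, points=points)


def encode_all(records: Iterable[SequenceRecord], mapping: AlphabetMapping) -> list[SequenceCurve]:
    return [encode(r, mapping) for r in records]


def write_curve_tsv(curve: SequenceCurve, path: str | Path, mapping: AlphabetMapping) -> None:
    """Write a curve as ``x<TAB>y`` plus a JSON sidecar (``<path>.json``)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("x\ty\n")
        for x, y in curve.points:
            fh.write(f"{x:.12g}\t{y:.12g}\n")
    sidecar = {
        "label": curve.label,
        "alphabet": mapping.kind,
        "mapping": {res: list(step) for res, step in sorted(mapping.steps.items())},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_curve_tsv(path: str | Path) -> SequenceCurve:
    """Read a curve written by :func:`write_curve_tsv`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    sidecar_path = Path(str(path) + ".json")
    label = path.stem
    if sidecar_path.exists():
        label = json.loads(sidecar_path.read_text())["label"]
    return SequenceCurve(label=label, points=data)
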