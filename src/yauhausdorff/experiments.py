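"""Synthetic sequences and the stability / deletion / runtime experiments.

Everything here is generated in-process from explicit seeds, so the whole
pipeline can be exercised without any external data: uniform random DNA or
protein sequences, composition-biased sequence families with small
within-family divergence, multiplicative y-perturbations of curves, series
of contiguous deletion mutants, and a wall-clock/call-count profile of the
distance computation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .clustering import to_newick, topology_equal, upgma
from .curves import (
    AlphabetMapping,
    AMINO_ACIDS,
    DNA_ALPHABET,
    SequenceCurve,
    SequenceRecord,
    default_dna_mapping,
    encode,
)
from .distmat import DistanceMatrix
from .errors import InputError
from .yau import PreparedPointSet, YauOptions, pairwise_matrix, yau_hausdorff

__all__ = [
    "PerturbationSpec",
    "MutationSeries",
    "StabilityReport",
    "random_sequence",
    "point_substitutions",
    "make_families",
    "perturb_curve",
    "stability_experiment",
    "deletion_scan",
    "runtime_profile",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Random y-coordinate perturbation of a curve.

    ``mode="relative"`` (default) multiplies each y by ``1 + u`` with u
    uniform in [-fraction, +fraction]; ``mode="additive"`` adds u directly.
    """

    fraction: float = 0.10
    seed: int = 0
    mode: str = "relative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise InputError(f"perturbation fraction must be in [0, 1], got {self.fraction}")
        if self.mode not in ("relative", "additive"):
            raise InputError(f"perturbation mode must be 'relative' or 'additive', got {self.mode!r}")


@dataclass(frozen=True)
class MutationSeries:
    """A base sequence and its deletion mutants (length, start, record)."""

    base: SequenceRecord
    mutants: tuple[tuple[int, int, SequenceRecord], ...]
    seed: int


@dataclass
class StabilityReport:
    """Baseline tree plus per-repeat topology comparison and matrix drift."""

    baseline_matrix: DistanceMatrix
    baseline_newick: str
    repeats: list[dict] = field(default_factory=list)

    @property
    def all_topologies_unchanged(self) -> bool:
        return all(r["topology_unchanged"] for r in self.repeats)

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_newick": self.baseline_newick,
                "labels": self.baseline_matrix.labels,
                "repeats": self.repeats,
            },
            indent=2,
        )


def random_sequence(
    alphabet: str,
    length: int,
    seed: int,
    *,
    label: str | None = None,
    weights: np.ndarray | None = None,
) -> SequenceRecord:
    """An i.i.d. random sequence; ``weights`` optionally biases the composition."""
    if length < 1:
        raise InputError("sequence length must be >= 1")
    if alphabet == "dna":
        symbols = DNA_ALPHABET
    elif alphabet == "protein":
        symbols = AMINO_ACIDS
    else:
        raise InputError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(symbols),) or np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be nonnegative, one per symbol")
        p = w / w.sum()
    idx = rng.choice(len(symbols), size=length, p=p)
    seq = "".join(symbols[i] for i in idx)
    return SequenceRecord(id=label or f"rand_{alphabet}_{seed}", residues=seq)


def point_substitutions(record: SequenceRecord, n_subs: int, seed: int, *, label: str | None = None) -> SequenceRecord:
    """Substitute ``n_subs`` distinct positions with a different residue each."""
    if n_subs > len(record.residues):
        raise InputError("more substitutions than positions")
    symbols = DNA_ALPHABET if set(record.residues) <= set(DNA_ALPHABET) else AMINO_ACIDS
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(record.residues), size=n_subs, replace=False)
    seq = list(record.residues)
    for pos in positions:
        choices = [c for c in symbols if c != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return SequenceRecord(id=label or f"{record.id}_mut{seed}", residues="".join(seq))


def make_families(
    n_families: int,
    per_family: int,
    length: int,
    seed: int,
    *,
    alphabet: str = "dna",
    n_substitutions: int = 1,
    length_step: int = 15,
) -> list[SequenceRecord]:
    """Well-separated synthetic families: founders of staggered length, light mutation.

    The Yau-Hausdorff distance is invariant under rotation and translation,
    so two same-length random walks are often surprisingly alignable;
    robust between-family separation needs founders that differ in *shape
    extent*, which here means length (family ``f`` has length
    ``length + length_step * f * (f + 1) / 2``, so successive gaps grow and
    no two inter-family distances nearly tie) on top of independent random
    content — much like real gene families, which differ by indels as well
    as substitutions.  Within a family, members are the founder plus
    ``n_substitutions`` point substitutions, a perturbation far smaller
    than the founder-to-founder divergence.
    """
    if n_families < 2 or per_family < 1:
        raise InputError("need >= 2 families with >= 1 member each")
    if length_step < 0:
        raise InputError("length_step must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for f in range(n_families):
        founder = random_sequence(
            alphabet, length + length_step * (f * (f + 1) // 2), int(rng.integers(2**31)),
            label=f"fam{f}_0",
        )
        records.append(founder)
        for m in range(1, per_family):
            records.append(
                point_substitutions(
                    founder, n_substitutions, int(rng.integers(2**31)),
                    label=f"fam{f}_{m}",
                )
            )
    return records


def perturb_curve(curve: SequenceCurve, spec: PerturbationSpec) -> np.ndarray:
    """Perturbed copy of the curve's points; x is untouched, y jittered per point."""
    pts = np.array(curve.points, dtype=float)
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(-spec.fraction, spec.fraction, size=pts.shape[0])
    if spec.mode == "relative":
        pts[:, 1] *= 1.0 + u
    else:
        pts[:, 1] += u
    return pts


def stability_experiment(
    records: list[SequenceRecord],
    spec: PerturbationSpec,
    options: YauOptions,
    repeats: int,
    *,
    mapping: AlphabetMapping | None = None,
) -> StabilityReport:
    """Perturb all curves, rebuild the UPGMA tree, compare topology to baseline.

    Each repeat ``r`` perturbs every curve with seed ``spec.seed + r`` (one
    stream per repeat, recorded in the report) and reports whether the tree
    topology survived plus the largest absolute change of any matrix entry.
    """
    if len(records) < 3:
        raise InputError("stability experiment needs at least 3 sequences")
    mapping = mapping or default_dna_mapping()
    curves = [encode(r, mapping) for r in records]
    baseline_matrix = pairwise_matrix(curves, options)
    baseline_tree = upgma(baseline_matrix)
    report = StabilityReport(
        baseline_matrix=baseline_matrix,
        baseline_newick=to_newick(baseline_tree),
    )
    for r in range(repeats):
        rep_seed = spec.seed + r
        rep_spec = PerturbationSpec(fraction=spec.fraction, seed=rep_seed, mode=spec.mode)
        perturbed = [
            SequenceCurve(label=c.label, points=perturb_curve(c, rep_spec))
            for c in curves
        ]
        matrix = pairwise_matrix(perturbed, options)
        tree = upgma(matrix)
        report.repeats.append(
            {
                "seed": rep_seed,
                "topology_unchanged": topology_equal(baseline_tree, tree),
                "max_matrix_change": float(
                    np.max(np.abs(matrix.values - baseline_matrix.values))
                ),
            }
        )
    return report


def deletion_scan(
    base: SequenceRecord,
    n_mutants: int,
    max_deletion: int,
    seed: int,
    options: YauOptions,
    *,
    mapping: AlphabetMapping | None = None,
) -> list[tuple[int, float]]:
    """Distance from a base sequence to contiguous-deletion mutants of growing size.

    Deletion lengths run from 1 to ``max_deletion`` spread evenly over
    ``n_mutants`` (with ``n_mutants == max_deletion`` every length occurs
    exactly once); each deletion starts at a seeded random position.
    Returns ``(deletion_length, yau_hausdorff_distance)`` pairs in
    increasing length order.
    """
    if n_mutants < 1:
        raise InputError("n_mutants must be >= 1")
    if max_deletion < 1 or max_deletion >= len(base.residues):
        raise InputError("max_deletion must be in [1, len(base) - 1]")
    mapping = mapping or default_dna_mapping()
    lengths = np.rint(np.linspace(1, max_deletion, n_mutants)).astype(int)
    rng = np.random.default_rng(seed)
    prepared_base = PreparedPointSet(encode(base, mapping), options)
    out: list[tuple[int, float]] = []
    for dlen in lengths:
        start = int(rng.integers(0, len(base.residues) - dlen + 1))
        mutant = SequenceRecord(
            id=f"{base.id}_del{dlen}",
            residues=base.residues[:start] + base.residues[start + dlen:],
        )
        d = yau_hausdorff(prepared_base, encode(mutant, mapping), options)
        out.append((int(dlen), float(d)))
    return out


def build_mutation_series(
    base: SequenceRecord, n_mutants: int, max_deletion: int, seed: int
) -> MutationSeries:
    """The deletion mutants themselves (no distances), for export/inspection."""
    if max_deletion < 1 or max_deletion >= len(base.residues):
        raise InputError("max_deletion must be in [1, len(base) - 1]")
    lengths = np.rint(np.linspace(1, max_deletion, n_mutants)).astype(int)
    rng = np.random.default_rng(seed)
    mutants = []
    for dlen in lengths:
        start = int(rng.integers(0, len(base.residues) - dlen + 1))
        rec = SequenceRecord(
            id=f"{base.id}_del{dlen}",
            residues=base.residues[:start] + base.residues[start + dlen:],
        )
        mutants.append((int(dlen), start, rec))
    return MutationSeries(base=base, mutants=tuple(mutants), seed=seed)


def runtime_profile(
    lengths: list[int],
    options: YauOptions,
    seed: int,
) -> list[dict]:
    """Time the distance on random same-length DNA pairs; report H1 call counts.

    Purely observational (no pass/fail): the table makes the growth of the
    rotation-set product and the effectiveness of pruning visible.
    """
    if sorted(lengths) != list(lengths):
        raise InputError("lengths must be sorted ascending")
    mapping = default_dna_mapping()
    rows = []
    for i, length in enumerate(lengths):
        rec_a = random_sequence("dna", length, seed + 2 * i, label=f"a{length}")
        rec_b = random_sequence("dna", length, seed + 2 * i + 1, label=f"b{length}")
        stats: dict = {}
        t0 = time.perf_counter()
        d = yau_hausdorff(encode(rec_a, mapping), encode(rec_b, mapping), options, stats=stats)
        elapsed = time.perf_counter() - t0
        rows.append(
            {
                "m_plus_n": 2 * (length + 1),
                "seconds": elapsed,
                "distance": d,
                "h1_calls": stats.get("h1_calls", 0),
                "h_evals": stats.get("h_evals", 0),
            }
        )
    return rows
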