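"""Labeled symmetric distance matrices and their on-disk dialects.

Two plain-text formats are supported, matching what the pipeline writes and
what the clustering stage reads back:

* relaxed PHYLIP square: a count line, then one row per taxon as
  ``label d1 d2 ... dn`` (whitespace-separated; labels of any length);
* labeled TSV: a header row of labels (leading empty cell), then
  ``label<TAB>d1<TAB>...`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with a zero diagonal and unique labels."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InputError("distance matrix labels are not unique")
        if self.values.shape != (n, n):
            raise InputError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise InputError("distance matrix contains negative entries")
        if not np.allclose(self.values, self.values.T, rtol=0.0, atol=1e-9):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise InputError("distance matrix diagonal is not zero")
        # canonicalise tiny float asymmetries away
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    # ---- writers ---------------------------------------------------------

    def to_phylip(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"{len(self)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + " ".join(f"{v:.12g}" for v in row) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")

    # ---- readers ---------------------------------------------------------

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines:
            raise InputError(f"empty distance matrix file {path}")
        try:
            n = int(lines[0].split()[0])
        except ValueError as exc:
            raise InputError(f"{path}: first line must be the taxon count") from exc
        if len(lines) - 1 != n:
            raise InputError(f"{path}: expected {n} rows, found {len(lines) - 1}")
        labels, rows = [], []
        for ln in lines[1:]:
            parts = ln.split()
            if len(parts) != n + 1:
                raise InputError(f"{path}: malformed row {ln!r}")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels=labels, values=np.array(rows))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines:
            raise InputError(f"empty distance matrix file {path}")
        header = lines[0].split("\t")
        labels = header[1:]
        rows = []
        row_labels = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            row_labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if row_labels != labels:
            raise InputError(f"{path}: row labels do not match header labels")
        return cls(labels=labels, values=np.array(rows))

    @classmethod
    def read(cls, path: str | Path) -> "DistanceMatrix":
        """Sniff the dialect: a first line that is a bare integer means PHYLIP."""
        first = Path(path).read_text().splitlines()[0] if Path(path).read_text() else ""
        if first.strip().isdigit():
            return cls.from_phylip(path)
        return cls.from_tsv(path)
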