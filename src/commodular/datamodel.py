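"""Community count matrices and per-sample metadata.

The analysis operates on a samples x taxa matrix of non-negative integer
counts (individuals per 30-plant sample) together with sample metadata
locating each sample in the study design: which farm, which year, and which
biweekly sampling occasion within the season (an integer index 1..T, not a
calendar date).

Files are plain comma-delimited text: the counts table has a ``sample_id``
first column and one column per taxon; the metadata table has columns
``sample_id, farm, year, time_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "SampleMeta",
    "ValidationError",
    "read_dataset",
    "write_dataset",
]

SAMPLE_ID_COL = "sample_id"
META_COLS = (SAMPLE_ID_COL, "farm", "year", "time_index")


class ValidationError(ValueError):
    """Raised when a dataset violates the count-matrix or metadata contract."""


@dataclass
class CommunityMatrix:
    """Non-negative integer counts, samples x taxa, with identifiers."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        c = self.counts
        if c.ndim != 2:
            raise ValidationError(f"counts must be 2-dimensional, got ndim={c.ndim}")
        if c.shape[0] != len(self.sample_ids):
            raise ValidationError(
                f"counts has {c.shape[0]} rows but {len(self.sample_ids)} sample ids"
            )
        if c.shape[1] != len(self.taxon_ids):
            raise ValidationError(
                f"counts has {c.shape[1]} columns but {len(self.taxon_ids)} taxon ids"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if not np.issubdtype(c.dtype, np.number):
            raise ValidationError("counts must be numeric")
        bad = ~np.isfinite(c.astype(float)) | (c < 0) | (np.mod(c, 1) != 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                "counts must be non-negative integers; offending cell "
                f"sample={self.sample_ids[i]!r}, taxon={self.taxon_ids[j]!r}, "
                f"value={c[i, j]!r}"
            )
        self.counts = c.astype(np.int64)

    def zero_taxa(self) -> list[str]:
        """Taxa whose column is all zeros (retained, but unusable for model fits)."""
        return [t for t, tot in zip(self.taxon_ids, self.counts.sum(axis=0)) if tot == 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name=SAMPLE_ID_COL),
                            columns=self.taxon_ids)

    def with_counts(self, counts: np.ndarray) -> "CommunityMatrix":
        """A copy of this matrix holding ``counts`` under the same identifiers."""
        return CommunityMatrix(counts=np.asarray(counts), sample_ids=list(self.sample_ids),
                               taxon_ids=list(self.taxon_ids))


@dataclass
class SampleMeta:
    """Design metadata for the samples: farm, year, biweekly occasion index.

    Stored as a DataFrame keyed by sample_id; (farm, year, time_index)
    combinations must be unique so every sample occupies one design cell.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in META_COLS if c not in t.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        t = t.loc[:, list(META_COLS)].copy()
        t[SAMPLE_ID_COL] = t[SAMPLE_ID_COL].astype(str)
        t["farm"] = t["farm"].astype(str)
        t["year"] = t["year"].astype(str)
        try:
            t["time_index"] = t["time_index"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"time_index must be integer: {exc}") from None
        if (t["time_index"] < 1).any():
            raise ValidationError("time_index must be >= 1")
        if t[SAMPLE_ID_COL].duplicated().any():
            dup = t.loc[t[SAMPLE_ID_COL].duplicated(), SAMPLE_ID_COL].iloc[0]
            raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
        if t.duplicated(subset=["farm", "year", "time_index"]).any():
            row = t[t.duplicated(subset=["farm", "year", "time_index"])].iloc[0]
            raise ValidationError(
                "duplicate (farm, year, time_index) combination: "
                f"({row['farm']}, {row['year']}, {row['time_index']})"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table[SAMPLE_ID_COL].tolist()

    def aligned_to(self, sample_ids: list[str]) -> pd.DataFrame:
        """Metadata rows reordered to match ``sample_ids``; error on any missing id."""
        t = self.table.set_index(SAMPLE_ID_COL)
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing[:5]}")
        return t.loc[sample_ids].reset_index()


def _check_pair(cm: CommunityMatrix, meta: SampleMeta) -> None:
    meta.aligned_to(cm.sample_ids)


def read_dataset(counts_path: str | Path, meta_path: str | Path) -> tuple[CommunityMatrix, SampleMeta]:
    """Read and validate a counts CSV + metadata CSV pair.

    The metadata is reordered to match the counts table's sample order.
    """
    counts_path, meta_path = Path(counts_path), Path(meta_path)
    for p in (counts_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"dataset file not found: {p}")
    ctab = pd.read_csv(counts_path)
    if ctab.shape[1] < 2:
        raise ValidationError(f"{counts_path}: counts table needs a sample-id column plus taxa")
    sample_ids = ctab.iloc[:, 0].astype(str).tolist()
    taxon_ids = [str(c) for c in ctab.columns[1:]]
    cm = CommunityMatrix(counts=ctab.iloc[:, 1:].to_numpy(), sample_ids=sample_ids,
                         taxon_ids=taxon_ids)
    meta = SampleMeta(pd.read_csv(meta_path))
    aligned = meta.aligned_to(cm.sample_ids)
    return cm, SampleMeta(aligned)


def write_dataset(cm: CommunityMatrix, meta: SampleMeta, counts_path: str | Path,
                  meta_path: str | Path) -> tuple[Path, Path]:
    """Write a validated dataset pair as CSV; lossless for integer counts."""
    if cm.n_taxa < 2:
        raise ValidationError(
            "matrix must have >= 2 taxa (correlation analysis is undefined otherwise)"
        )
    _check_pair(cm, meta)
    counts_path, meta_path = Path(counts_path), Path(meta_path)
    cm.to_frame().to_csv(counts_path)
    meta.aligned_to(cm.sample_ids).to_csv(meta_path, index=False)
    return counts_path, meta_path
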