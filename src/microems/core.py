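"""Core in-memory containers shared across the pipeline.

The analysis passes three kinds of objects between stages: sample-by-OTU
count tables, binary site-by-species incidence matrices (the substrate of
the metacommunity-structure statistics), and labelled pairwise distance
matrices. Each container validates its defining invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio


class ValidationError(ValueError):
    """An input violated a structural invariant (ids, shape, sign)."""


@dataclass
class AbundanceTable:
    """Samples x OTUs non-negative integer counts with optional taxonomy.

    ``counts`` is a pandas DataFrame indexed by sample id with OTU-id
    columns. ``taxonomy`` maps OTU id -> lineage string for any subset of
    OTUs.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate OTU ids: {dups[:5]}")
        arr = c.to_numpy()
        if arr.size and (arr < 0).any():
            bad = c.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative count in sample {bad!r}")
        # store as integer; fractional counts are a parse error upstream
        self.counts = c.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def equals(self, other: "AbundanceTable") -> bool:
        return self.counts.equals(other.counts) and self.taxonomy == other.taxonomy


@dataclass
class IncidenceMatrix:
    """Binary sites x species matrix with explicit row/column orderings."""

    values: np.ndarray
    site_ids: list[str]
    species_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2:
            raise ValidationError("incidence matrix must be 2-D")
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("incidence entries must be 0/1")
        if v.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValidationError(
                f"shape {v.shape} inconsistent with "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValidationError("duplicate species ids")
        self.values = v
        self.site_ids = list(self.site_ids)
        self.species_ids = list(self.species_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def drop_empty(self, warn: bool = False) -> "IncidenceMatrix":
        """Remove all-zero rows and columns (required before ordination)."""
        rows = self.values.sum(axis=1) > 0
        cols = self.values.sum(axis=0) > 0
        if rows.all() and cols.all():
            return self
        return IncidenceMatrix(
            self.values[np.ix_(rows, cols)],
            [s for s, k in zip(self.site_ids, rows) if k],
            [s for s, k in zip(self.species_ids, cols) if k],
        )

    def reorder(self, row_order: np.ndarray, col_order: np.ndarray) -> "IncidenceMatrix":
        return IncidenceMatrix(
            self.values[np.ix_(row_order, col_order)],
            [self.site_ids[i] for i in row_order],
            [self.species_ids[j] for j in col_order],
        )


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise dissimilarities with a kind label."""

    data: np.ndarray
    ids: list[str]
    kind: str = "generic"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if d.size and d.min() < -1e-12:
            raise ValidationError("negative distances")
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
        self.data = d
        self.ids = list(self.ids)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.data, ids=self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def filter(self, ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"ids not in distance matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(self.data[np.ix_(idx, idx)], list(ids), self.kind)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def read_tsv(cls, path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], kind)
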