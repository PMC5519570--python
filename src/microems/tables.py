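"""OTU-table I/O, preprocessing and alpha-level summaries.

Implements the preprocessing applied to the study's OTU table — a relative
abundance filter (OTUs under a fixed fraction of the grand total are treated
as likely sequencing artefacts and removed), rarefaction to a common read
depth, and the core-microbiome prevalence screen — plus per-sample richness,
Shannon diversity, and the animal-water shared-OTU proportion.

On-disk formats: TSV with OTUs as rows and samples as columns (the layout
QIIME-era tables use), and a dense BIOM-style v1.0 JSON document. Output
files carry a provenance comment line; the readers skip '#' lines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AbundanceTable, IncidenceMatrix, ValidationError
from .version import provenance_line

logger = logging.getLogger(__name__)

TAXONOMY_COLUMN = "taxonomy"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(path, format: str = "tsv") -> AbundanceTable:
    """Read an OTU table from TSV (rows=OTUs, cols=samples) or BIOM JSON."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom_json(path)
    raise ValueError(f"unknown table format: {format!r}")


def write_table(table: AbundanceTable, path, format: str = "tsv", **meta) -> None:
    if format == "tsv":
        _write_tsv(table, path, **meta)
    elif format == "biom":
        _write_biom_json(table, path, **meta)
    else:
        raise ValueError(f"unknown table format: {format!r}")


def _read_tsv(path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    taxonomy: dict[str, str] = {}
    if TAXONOMY_COLUMN in df.columns:
        taxonomy = {
            otu: str(v)
            for otu, v in df[TAXONOMY_COLUMN].items()
            if not pd.isna(v)
        }
        df = df.drop(columns=[TAXONOMY_COLUMN])
    arr = df.to_numpy()
    if np.isnan(arr.astype(float)).any():
        bad = df.index[np.isnan(arr.astype(float)).any(axis=1)][0]
        raise ValidationError(f"missing/ragged values in OTU row {bad!r}")
    if not np.allclose(arr.astype(float) % 1, 0):
        raise ValidationError("non-integer counts in table")
    # file layout is OTUs x samples; in memory we keep samples x OTUs
    return AbundanceTable(df.T.astype(np.int64), taxonomy)


def _write_tsv(table: AbundanceTable, path, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(**meta))
        out = table.counts.T.copy()
        out.index.name = "OTU_ID"
        if table.taxonomy:
            out[TAXONOMY_COLUMN] = [
                table.taxonomy.get(o, "") for o in out.index
            ]
        out.to_csv(fh, sep="\t")


def _read_biom_json(path) -> AbundanceTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ValidationError("only dense BIOM-style JSON supported")
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    data = np.asarray(doc["data"], dtype=float)
    n_otu, n_samp = doc["shape"]
    if data.shape != (n_otu, n_samp):
        raise ValidationError(
            f"BIOM data shape {data.shape} != declared shape {(n_otu, n_samp)}"
        )
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax is not None:
            taxonomy[str(r["id"])] = (
                "; ".join(tax) if isinstance(tax, (list, tuple)) else str(tax)
            )
    df = pd.DataFrame(data.T, index=sample_ids, columns=otu_ids)
    return AbundanceTable(df, taxonomy)


def _write_biom_json(table: AbundanceTable, path, **meta) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "generated_by": provenance_line(**meta).lstrip("# ").strip(),
        "type": "OTU table",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [len(table.otu_ids), len(table.sample_ids)],
        "rows": [
            {
                "id": o,
                "metadata": (
                    {"taxonomy": table.taxonomy[o]} if o in table.taxonomy else None
                ),
            }
            for o in table.otu_ids
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.T.to_numpy().astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


REQUIRED_METADATA_COLUMNS = [
    "sample_id",
    "population",
    "deme",
    "sample_type",
    "latitude",
    "longitude",
    "elevation",
    "forest_cover",
]


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    bad = set(md["sample_type"]) - {"animal", "water"}
    if bad:
        raise ValidationError(f"unknown sample_type values: {sorted(bad)}")
    return md.set_index("sample_id", drop=False)


def write_metadata(md: pd.DataFrame, path, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(**meta))
        md.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_rare_otus(table: AbundanceTable, min_fraction: float = 0.00005) -> AbundanceTable:
    """Drop OTUs whose total count falls below min_fraction of the grand total.

    The threshold is computed on the *input* table (grand total before any
    removal). ``min_fraction=0.00005`` is the 0.005 % error-screen used on
    the study's table.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    totals = table.counts.sum(axis=0)
    threshold = min_fraction * float(totals.sum())
    keep = totals >= threshold
    if not keep.any():
        warnings.warn("abundance filter removed every OTU", stacklevel=2)
    kept = table.counts.loc[:, keep]
    taxonomy = {o: t for o, t in table.taxonomy.items() if o in set(kept.columns)}
    return AbundanceTable(kept, taxonomy)


def rarefy(table: AbundanceTable, depth: int = 8800, seed: int | None = None) -> AbundanceTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (with a logged
    warning), not padded. Uses the multivariate hypergeometric distribution,
    which is exactly sampling-without-replacement from the expanded read
    multiset.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    kept_ids = []
    dropped = []
    for sid, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            rows.append(row.to_numpy())
        else:
            rows.append(rng.multivariate_hypergeometric(row.to_numpy(), depth))
        kept_ids.append(sid)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(kept_ids), len(table.otu_ids)),
        index=kept_ids,
        columns=table.otu_ids,
    )
    return AbundanceTable(counts, dict(table.taxonomy))


def core_microbiome(table: AbundanceTable, prevalence: float = 0.80) -> list[str]:
    """OTUs present (count>0) in at least ``prevalence`` of samples.

    Comparison is >= on the exact fraction (41/51 ~ 0.804 is in at 0.80;
    40/51 ~ 0.784 is out). Result is sorted by mean relative abundance,
    descending, ties by OTU id.
    """
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    n = len(table.sample_ids)
    if n == 0:
        return []
    present = (table.counts > 0).sum(axis=0) / n
    core = present[present >= prevalence].index
    row_sums = table.counts.sum(axis=1).replace(0, 1)
    rel = table.counts.div(row_sums, axis=0)
    mean_rel = rel[core].mean(axis=0)
    order = sorted(core, key=lambda o: (-mean_rel[o], o))
    return [str(o) for o in order]


# ---------------------------------------------------------------------------
# Alpha summaries
# ---------------------------------------------------------------------------

@dataclass
class AlphaSummary:
    sample_id: str
    richness: int
    shannon: float
    shared_proportion: float | None  # animal samples only; None if no water


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shared_proportion(
    animal_counts: np.ndarray,
    water_counts: np.ndarray,
    denominator: str = "animal",
) -> float | None:
    """Proportion of an animal sample's OTUs also present in its river water.

    ``denominator='animal'`` (default): |animal & water| / |animal|.
    ``denominator='union'``: |animal & water| / |animal | water|.
    Returns None (undefined) for an animal sample with no OTUs.
    """
    a = np.asarray(animal_counts) > 0
    w = np.asarray(water_counts) > 0
    if a.sum() == 0:
        return None
    inter = int((a & w).sum())
    if denominator == "animal":
        return inter / int(a.sum())
    if denominator == "union":
        union = int((a | w).sum())
        return inter / union if union else None
    raise ValueError(f"unknown denominator convention {denominator!r}")


def alpha_summaries(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    shannon_base: float | None = None,
    shared_denominator: str = "animal",
) -> pd.DataFrame:
    """Per-sample richness, Shannon H, and (animals) water-shared proportion.

    Warns if row sums are unequal (the table should be rarefied first). The
    shared proportion uses the water sample(s) of the animal's population;
    with several water samples their OTU sets are pooled.
    """
    sums = table.counts.sum(axis=1)
    if len(set(sums)) > 1:
        warnings.warn(
            "alpha_summaries: unequal sample depths; rarefy first", stacklevel=2
        )
    md = metadata.loc[[s for s in table.sample_ids if s in metadata.index]]
    water_by_pop: dict[str, np.ndarray] = {}
    for pop, group in md[md["sample_type"] == "water"].groupby("population"):
        ids = [s for s in group["sample_id"] if s in table.counts.index]
        if ids:
            water_by_pop[pop] = table.counts.loc[ids].sum(axis=0).to_numpy()
    records = []
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        rich = int((row > 0).sum())
        h = shannon(row, base=shannon_base)
        shared = None
        if sid in md.index and md.at[sid, "sample_type"] == "animal":
            pop = md.at[sid, "population"]
            if pop in water_by_pop:
                shared = shared_proportion(
                    row, water_by_pop[pop], denominator=shared_denominator
                )
        records.append(
            {
                "sample_id": sid,
                "richness": rich,
                "shannon": h,
                "shared_proportion": shared,
            }
        )
    return pd.DataFrame(records).set_index("sample_id", drop=False)


def to_incidence(
    table: AbundanceTable,
    metadata: pd.DataFrame | None = None,
    include_sample_types: tuple[str, ...] = ("animal",),
) -> IncidenceMatrix:
    """Binarize the table into a sites x species incidence matrix.

    Restricted to the requested sample types when metadata is given (the
    metacommunity analysis uses skin samples only); OTUs absent from every
    retained sample are dropped.
    """
    counts = table.counts
    if metadata is not None:
        keep = [
            s
            for s in counts.index
            if s in metadata.index
            and metadata.at[s, "sample_type"] in include_sample_types
        ]
        counts = counts.loc[keep]
    occupied = counts.sum(axis=0) > 0
    counts = counts.loc[:, occupied]
    return IncidenceMatrix(
        (counts.to_numpy() > 0).astype(np.int8),
        [str(s) for s in counts.index],
        [str(o) for o in counts.columns],
    )
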