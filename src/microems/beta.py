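"""Between-sample community structure.

Jaccard and (un)weighted UniFrac distances, principal coordinates, and the
permutation tests the study runs on them: ANOSIM and PERMANOVA (Adonis) for
group differences, and Mantel correlations of community dissimilarity
against population genetic distance (Fst) and geographic distance.

The distance and test computations are delegated to scikit-bio behind this
module's surface; permutation p-values use the (count + 1) / (n + 1)
estimator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import beta_diversity
from skbio.stats import distance as skdist
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core import AbundanceTable, DistanceMatrix, ValidationError

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def jaccard_matrix(table: AbundanceTable) -> DistanceMatrix:
    """1 - |A∩B| / |A∪B| over OTU presence sets (counts binarized)."""
    v = table.counts.to_numpy() > 0
    empty = ~v.any(axis=1)
    if empty.sum() >= 2:
        warnings.warn(
            "two or more empty samples: their pairwise Jaccard distance is 0",
            stacklevel=2,
        )
    d = squareform(pdist(v, metric="jaccard"))
    return DistanceMatrix(d, table.sample_ids, kind="jaccard")


def _check_tree_coverage(table: AbundanceTable, tree: skbio.TreeNode) -> None:
    leaves = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in leaves]
    if missing:
        raise ValidationError(
            f"{len(missing)} OTU(s) missing from tree, e.g. {missing[:5]}"
        )


def unifrac_matrix(
    table: AbundanceTable,
    tree: skbio.TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """Phylogenetic distance between samples.

    Unweighted: unique branch length between the two samples' leaf sets
    divided by the branch length their union spans. Weighted: branch
    lengths weighted by the difference in read proportions descending from
    each branch, normalized into [0, 1] by default.
    """
    _check_tree_coverage(table, tree)
    counts = table.counts.to_numpy()
    if weighted:
        dm = beta_diversity(
            "weighted_unifrac",
            counts,
            ids=table.sample_ids,
            tree=tree,
            taxa=table.otu_ids,
            normalized=normalized,
        )
        kind = "weighted_unifrac"
    else:
        dm = beta_diversity(
            "unweighted_unifrac",
            counts,
            ids=table.sample_ids,
            tree=tree,
            taxa=table.otu_ids,
        )
        kind = "unweighted_unifrac"
    return DistanceMatrix(dm.data, table.sample_ids, kind=kind)


def geographic_distances(metadata: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between sample coordinates."""
    missing = metadata.index[
        metadata[["latitude", "longitude"]].isna().any(axis=1)
    ].tolist()
    if missing:
        raise ValidationError(f"samples without coordinates: {missing[:5]}")
    lat = np.radians(metadata["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [str(s) for s in metadata.index], kind="geographic")


def expand_fst_to_samples(
    fst: DistanceMatrix, metadata: pd.DataFrame, sample_ids: list[str] | None = None
) -> DistanceMatrix:
    """Sample-level matrix with d(i, j) = Fst(pop_i, pop_j), 0 within."""
    if sample_ids is None:
        sample_ids = [
            str(s)
            for s in metadata.index
            if metadata.at[s, "sample_type"] == "animal"
        ]
    pos = {p: k for k, p in enumerate(fst.ids)}
    pops = []
    for s in sample_ids:
        p = metadata.at[s, "population"]
        if p not in pos:
            raise ValidationError(f"population {p!r} (sample {s}) not in Fst matrix")
        pops.append(pos[p])
    idx = np.asarray(pops)
    d = fst.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, sample_ids, kind="fst")


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame       # samples x retained positive axes
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix, keep_negative: bool = False) -> PCoAResult:
    """Principal coordinates via Gower double-centering.

    Axes with negative eigenvalues are reported but dropped from the
    coordinates by default.
    """
    if len(dm.ids) < 3:
        raise ValidationError("PCoA needs >= 3 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm.to_skbio(), method="eigh", warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    coords = res.samples
    coords.index = dm.ids
    neg = eig[eig < -1e-12]
    if not keep_negative:
        keep = np.flatnonzero(eig > 1e-12)
        coords = coords.iloc[:, keep]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=res.proportion_explained.to_numpy(),
        negative_eigenvalues=neg,
    )


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    method: str
    statistic: float            # ANOSIM R or PERMANOVA pseudo-F
    r_squared: float | None     # PERMANOVA only
    n_permutations: int
    p: float


@dataclass
class MantelResult:
    r: float | None
    n_permutations: int
    p: float | None


def _check_groups(dm: DistanceMatrix, groups) -> pd.Series:
    g = pd.Series(list(groups), index=dm.ids)
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValidationError("need >= 2 groups")
    small = sizes[sizes < 2]
    if len(small):
        raise ValidationError(f"groups with a single member: {list(small.index)}")
    return g


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """ANOSIM R with a label-permutation p-value."""
    g = _check_groups(dm, groups)
    res = skdist.anosim(
        dm.to_skbio(), g.to_numpy(), permutations=n_permutations, seed=seed
    )
    return GroupTestResult(
        "anosim",
        float(res["test statistic"]),
        None,
        n_permutations,
        float(res["p-value"]),
    )


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """One-factor PERMANOVA (Adonis): pseudo-F, R², permutation p."""
    g = _check_groups(dm, groups)
    res = skdist.permanova(
        dm.to_skbio(), g.to_numpy(), permutations=n_permutations, seed=seed
    )
    f = float(res["test statistic"])
    n = len(dm.ids)
    k = g.nunique()
    # R^2 = SSB/SST follows from F = (SSB/(k-1)) / (SSW/(n-k));
    # zero within-group scatter gives F = inf, R^2 = 1
    r2 = 1.0 if not np.isfinite(f) else f * (k - 1) / (f * (k - 1) + (n - k))
    return GroupTestResult("permanova", f, float(r2), n_permutations, float(res["p-value"]))


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_permutations: int = 10000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices over matching ids."""
    if set(dm_a.ids) != set(dm_b.ids):
        raise ValidationError("distance matrices have different id sets")
    if len(dm_a.ids) < 4:
        raise ValidationError("Mantel needs >= 4 entities")
    b = dm_b.filter(dm_a.ids)
    if np.allclose(dm_a.condensed().std(), 0) or np.allclose(b.condensed().std(), 0):
        warnings.warn("zero-variance distance matrix: Mantel r undefined", stacklevel=2)
        return MantelResult(None, n_permutations, None)
    r, p, _ = skdist.mantel(
        dm_a.to_skbio(),
        b.to_skbio(),
        method="pearson",
        permutations=n_permutations,
        alternative=alternative,
        seed=seed,
    )
    return MantelResult(float(r), n_permutations, float(p))
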