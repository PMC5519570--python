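"""Elements of Metacommunity Structure (EMS).

The EMS framework asks whether the species-by-site incidence pattern of a
metacommunity is consistent with species responding to a single latent
environmental gradient, and if so, how ranges are arranged along it. The
procedure is:

1. *Ordinate* the incidence matrix by reciprocal averaging (correspondence
   analysis): rows and columns are reordered by their first non-trivial CA
   axis scores so that sites with similar species composition, and species
   with similar occupancy, become adjacent.
2. *Coherence*: count embedded absences (gaps strictly inside a species'
   range along the ordination; by default the same count over site rows is
   added). Fewer absences than expected under the null means ranges are
   coherent intervals on the gradient; significantly more indicates a
   checkerboard.
3. *Turnover*: after filling each range (setting embedded absences to
   presences), count species replacements, summed over species pairs as
   (#sites with i only) x (#sites with j only). More replacements than the
   null indicates Gleasonian/Clementsian turnover, fewer indicates
   nestedness.
4. *Boundary clumping*: Morisita's index of dispersion of range boundaries
   across sites. I_M > 1 means boundaries clump (Clementsian compartments),
   I_M < 1 means they are hyperdispersed (evenly spaced), I_M ~ 1 means
   boundaries fall at random (Gleasonian).

Null distributions come from the fixed-proportional ("r1") model: each
random matrix preserves every site's observed richness while species are
drawn, without replacement within a site, with probability proportional to
their observed marginal totals. Empty species columns are allowed (not
resampled); nulls are re-ordinated before counting by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core import IncidenceMatrix, ValidationError

logger = logging.getLogger(__name__)


class OrdinationError(ValueError):
    """The incidence matrix has no usable non-trivial ordination axis."""


# ---------------------------------------------------------------------------
# Ordination (reciprocal averaging / correspondence analysis)
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """First correspondence-analysis axis and the matrix reordered by it.

    ``site_scores`` / ``species_scores`` are standard coordinates in the
    *input* row/column order; ``row_order`` / ``col_order`` are the argsorts
    applied to produce ``ordered``.
    """

    site_scores: np.ndarray
    species_scores: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray
    ordered: IncidenceMatrix
    eigenvalue: float

    def scores_by_site(self) -> pd.Series:
        """Site scores indexed by site id (ordination order)."""
        return pd.Series(
            self.site_scores[self.row_order], index=self.ordered.site_ids
        )


def ordinate(matrix: IncidenceMatrix) -> OrdinationResult:
    """Rank sites and species by the first non-trivial CA axis.

    Computed by singular decomposition of the chi-square standardized
    matrix (mathematically equivalent to iterated reciprocal averaging,
    but deterministic). Sign convention: the axis is oriented so the first
    input row's score is non-negative (first row with a nonzero score if
    the first is zero); ties in the ordering are broken by original index.
    """
    X = matrix.values.astype(float)
    T, S = X.shape
    if T < 2 or S < 2:
        raise OrdinationError(f"matrix too small to ordinate: {T}x{S}")
    rs = X.sum(axis=1)
    cs = X.sum(axis=0)
    if (rs == 0).any():
        raise OrdinationError("empty site rows present; drop them before ordination")
    if (cs == 0).any():
        raise OrdinationError("empty species columns present; drop them before ordination")
    n = X.sum()
    P = X / n
    r = rs / n
    c = cs / n
    expected = np.outer(r, c)
    M = (P - expected) / np.sqrt(expected)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s[0] < 1e-10:
        raise OrdinationError(
            "matrix has no non-trivial correspondence axis "
            "(rank-deficient, e.g. all rows proportional)"
        )
    u = U[:, 0] / np.sqrt(r)
    v = Vt[0, :] / np.sqrt(c)
    # orient: first input row with a score distinguishable from zero is positive
    sign = 0.0
    for val in u:
        if abs(val) > 1e-12:
            sign = 1.0 if val > 0 else -1.0
            break
    if sign < 0:
        u = -u
        v = -v
    row_order = np.lexsort((np.arange(T), u))
    col_order = np.lexsort((np.arange(S), v))
    return OrdinationResult(
        site_scores=u,
        species_scores=v,
        row_order=row_order,
        col_order=col_order,
        ordered=matrix.reorder(row_order, col_order),
        eigenvalue=float(s[0] ** 2),
    )


# ---------------------------------------------------------------------------
# Counting primitives
# ---------------------------------------------------------------------------

def _column_spans(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(first, last, n_ones) per column; columns with no 1 get first=-1."""
    T = values.shape[0]
    any_col = values.any(axis=0)
    first = np.where(any_col, values.argmax(axis=0), -1)
    last = np.where(any_col, T - 1 - values[::-1].argmax(axis=0), -1)
    return first, last, values.sum(axis=0)


def embedded_absences(values: np.ndarray, margins: str = "both") -> int:
    """Zeros lying strictly inside the 1-span of each column (and row).

    ``margins='both'`` (default) adds the same count over rows;
    ``margins='columns'`` counts columns only.
    """
    def one_margin(v: np.ndarray) -> int:
        first, last, ones = _column_spans(v)
        occ = ones > 0
        return int(((last - first + 1) - ones)[occ].sum())

    total = one_margin(values)
    if margins == "both":
        total += one_margin(values.T)
    elif margins != "columns":
        raise ValueError(f"unknown margins convention {margins!r}")
    return total


def fill_ranges(values: np.ndarray) -> np.ndarray:
    """Set every embedded absence within each column's span to 1."""
    T, S = values.shape
    first, last, _ = _column_spans(values)
    idx = np.arange(T)[:, None]
    filled = ((idx >= first[None, :]) & (idx <= last[None, :])).astype(np.int8)
    filled[:, first < 0] = 0
    return filled


def replacements(values: np.ndarray) -> int:
    """Species replacements on the range-filled matrix.

    Sum over unordered species pairs (i, j) of
    (#sites with i but not j) x (#sites with j but not i).
    """
    filled = fill_ranges(values)
    S = filled.shape[1]
    if S < 2:
        warnings.warn("replacements undefined for a single species", stacklevel=2)
        return 0
    F = filled.astype(np.float32)
    C = F.T @ F  # co-occurrence counts
    n = np.diag(C).copy()
    only_i = n[:, None] - C
    R = only_i * only_i.T
    return int(round((R.sum(dtype=np.float64) - np.diag(R).sum(dtype=np.float64)) / 2.0))


def boundary_counts(values: np.ndarray) -> np.ndarray:
    """Per-site tallies of species range boundaries on the ordered matrix.

    Each species with any occurrence contributes two boundaries: the first
    and last site of its (filled) range — both at the same site for a
    single-site range.
    """
    T = values.shape[0]
    first, last, _ = _column_spans(values)
    occ = first >= 0
    counts = np.bincount(first[occ], minlength=T) + np.bincount(last[occ], minlength=T)
    return counts


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullModelSpec:
    """Fixed-proportional ('r1') null-model settings.

    Defaults follow the study: 99 permutations, empty rows/columns allowed
    in null matrices, nulls re-ordinated before counting.
    """

    model: str = "r1"
    n_permutations: int = 99
    allow_empty: bool = True
    reordinate_nulls: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model != "r1":
            raise ValueError(f"unsupported null model {self.model!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def r1_null(matrix: IncidenceMatrix, spec: NullModelSpec) -> Iterator[np.ndarray]:
    """Yield r1 null matrices (as 0/1 arrays) for ``spec.n_permutations``.

    Row sums are conserved exactly; within each row, species are drawn
    without replacement with probability proportional to the observed
    column totals (Efraimidis–Spirakis exponential-key sampling, identical
    in distribution to sequential weighted draws).
    """
    values = matrix.values
    T, S = values.shape
    richness = values.sum(axis=1)
    if (richness > S).any():
        raise ValidationError("row richness exceeds species count")
    w = values.sum(axis=0).astype(float)
    positive = w > 0
    if (richness > positive.sum()).any():
        raise ValidationError(
            "row richness exceeds the number of species with positive marginals"
        )
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_permutations):
        # key = Exp(1)/w per cell; the k smallest keys in a row are a
        # weighted sample without replacement of size k
        e = rng.exponential(size=(T, S))
        with np.errstate(divide="ignore"):
            keys = e / w  # zero-marginal species get key = inf: never drawn
        order = np.argsort(keys, axis=1)
        null = np.zeros((T, S), dtype=np.int8)
        for i in range(T):
            null[i, order[i, : richness[i]]] = 1
        yield null


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class NullStat:
    """Observed statistic against its permutation null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    z: float | None
    p: float | None            # two-tailed normal approximation on z
    p_empirical: float | None  # two-tailed rank-based (count+1)/(n+1)
    n_permutations: int
    degenerate: bool = False


def _null_stat(observed: float, nulls: np.ndarray) -> NullStat:
    nulls = np.asarray(nulls, dtype=float)
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
    n = len(nulls)
    if sd == 0:
        warnings.warn("degenerate null distribution (sd = 0)", stacklevel=3)
        return NullStat(observed, mean, sd, None, None, None, n, degenerate=True)
    z = (observed - mean) / sd
    p = float(2 * stats.norm.sf(abs(z)))
    ge = int((nulls >= observed).sum())
    le = int((nulls <= observed).sum())
    p_emp = min(1.0, 2 * (min(ge, le) + 1) / (n + 1))
    return NullStat(observed, mean, sd, float(z), p, p_emp, n)


def _null_counts(
    matrix: IncidenceMatrix,
    spec: NullModelSpec,
    margins: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Absences and replacements for each null matrix (shared null stream)."""
    absences = np.empty(spec.n_permutations)
    repl = np.empty(spec.n_permutations)
    for k, null in enumerate(r1_null(matrix, spec)):
        # empty columns (permitted by allow_empty) carry no range: drop
        # them so they cannot inject spurious gaps into site rows
        occupied = null.any(axis=0)
        null = null[:, occupied]
        if spec.reordinate_nulls and null.shape[1] >= 2:
            try:
                ords = ordinate(
                    IncidenceMatrix(
                        null,
                        [f"r{i}" for i in range(null.shape[0])],
                        [f"c{j}" for j in range(null.shape[1])],
                    )
                )
                null = ords.ordered.values
            except OrdinationError:
                logger.debug("null %d degenerate; counted unordinated", k)
        absences[k] = embedded_absences(null, margins=margins)
        repl[k] = replacements(null)
    return absences, repl


def coherence(
    ordered: IncidenceMatrix,
    null: NullModelSpec,
    margins: str = "both",
) -> NullStat:
    """Embedded-absence count vs the r1 null (observed < null => coherent)."""
    obs = embedded_absences(ordered.values, margins=margins)
    null_abs, _ = _null_counts(ordered, null, margins)
    return _null_stat(obs, null_abs)


def turnover(
    ordered: IncidenceMatrix,
    null: NullModelSpec,
    margins: str = "both",
) -> NullStat:
    """Replacement count on the range-filled matrix vs the r1 null."""
    obs = replacements(ordered.values)
    _, null_rep = _null_counts(ordered, null, margins)
    return _null_stat(obs, null_rep)


@dataclass
class ClumpingResult:
    """Morisita's index of range-boundary dispersion with its chi-square test."""

    morisita: float
    chi2: float
    df: int
    p: float          # two-sided
    p_clumped: float  # upper tail (I_M > 1)
    p_even: float     # lower tail (I_M < 1)
    n_boundaries: int


def morisita_index(counts: np.ndarray) -> float:
    """Morisita's index of dispersion over per-site boundary tallies.

    I_M = T * sum n_i (n_i - 1) / (N (N - 1)); N must be >= 2.
    """
    counts = np.asarray(counts)
    T = len(counts)
    N = int(counts.sum())
    if N < 2:
        raise ValidationError("Morisita's index undefined for < 2 boundaries")
    return T * float((counts * (counts - 1)).sum()) / (N * (N - 1))


def boundary_clumping(ordered: IncidenceMatrix, df_convention: str = "sites") -> ClumpingResult:
    """Morisita's index over per-site boundary tallies.

    I_M = T * sum n_i (n_i - 1) / (N (N - 1)) over T sites with n_i
    boundaries at site i and N total boundaries. Departure from 1 is tested
    with the Morisita dispersion chi-square, chi2 = I_M (N - 1) + T - N,
    with df = T - 1 by default (``df_convention='sites'``;
    ``'species'`` uses #species ranges - 1 instead).
    """
    counts = boundary_counts(ordered.values)
    T = len(counts)
    N = int(counts.sum())
    im = morisita_index(counts)
    n_species = int(ordered.values.any(axis=0).sum())
    if df_convention == "sites":
        df = T - 1
    elif df_convention == "species":
        df = max(n_species - 1, 1)
    else:
        raise ValueError(f"unknown df convention {df_convention!r}")
    chi2 = im * (N - 1) + T - N
    p_clumped = float(stats.chi2.sf(chi2, df))
    p_even = float(stats.chi2.cdf(chi2, df))
    p = min(1.0, 2 * min(p_clumped, p_even))
    return ClumpingResult(im, float(chi2), df, p, p_clumped, p_even, N)


def clumping_null_test(
    ordered: IncidenceMatrix,
    null: NullModelSpec,
) -> NullStat:
    """Morisita's index against the random-range-placement null.

    The null hypothesis of boundary clumping is Gleason's model: species
    ranges placed independently and uniformly along the gradient. Each null
    matrix keeps the observed (filled) range lengths, draws uniform range
    starts, and is pushed through the same ordination-and-counting pipeline
    as the data, so ordination artefacts (e.g. score compression at the
    gradient ends) affect observed and null identically.
    """
    T = ordered.shape[0]
    first, last, _ = _column_spans(ordered.values)
    lengths = (last - first + 1)[first >= 0]
    if len(lengths) == 0:
        raise ValidationError("no occupied species ranges")
    obs = boundary_clumping(ordered).morisita
    rng = np.random.default_rng(null.seed)
    ims = np.empty(null.n_permutations)
    S = len(lengths)
    idx = np.arange(T)[:, None]
    for k in range(null.n_permutations):
        starts = (rng.random(S) * (T - lengths + 1)).astype(int)
        v = ((idx >= starts[None, :]) & (idx < (starts + lengths)[None, :])).astype(np.int8)
        m = IncidenceMatrix(
            v, [f"r{i}" for i in range(T)], [f"c{j}" for j in range(S)]
        )
        try:
            v = ordinate(m).ordered.values
        except OrdinationError:
            pass
        ims[k] = boundary_clumping(
            IncidenceMatrix(v, m.site_ids, m.species_ids)
        ).morisita
    return _null_stat(obs, ims)


# ---------------------------------------------------------------------------
# Classification and reporting
# ---------------------------------------------------------------------------

STRUCTURES = (
    "clementsian",
    "gleasonian",
    "nested",
    "evenly_spaced",
    "checkerboard",
    "random",
)


def classify(
    coherence_stat: NullStat,
    turnover_stat: NullStat,
    clumping: ClumpingResult,
    quasi: bool = False,
    alpha: float = 0.05,
    clumping_null: NullStat | None = None,
    p_kind: str = "empirical",
) -> str:
    """Decision tree over the three EMS statistics.

    Significantly more absences than null -> checkerboard; non-significant
    coherence -> random; positive coherence branches on turnover sign
    (negative -> nested) and boundary clumping (I_M significantly > 1 ->
    Clementsian, significantly < 1 -> evenly spaced, otherwise Gleasonian).
    Clumping significance comes from the random-range-placement Monte Carlo
    test when ``clumping_null`` is given (preferred: it is calibrated for
    ordination artefacts), otherwise from the chi-square test. With
    ``quasi``, a non-significant turnover under positive coherence yields
    the "quasi-" variant of the sign-based label.

    ``p_kind`` selects the p-value the tree thresholds: the rank-based
    ``"empirical"`` p (default; exactly calibrated under exchangeability of
    the permutation null) or the ``"normal"`` z-approximation.
    """
    if p_kind not in ("empirical", "normal"):
        raise ValueError(f"unknown p_kind {p_kind!r}")

    def pval(stat: NullStat) -> float:
        return stat.p_empirical if p_kind == "empirical" else stat.p

    if coherence_stat.degenerate or turnover_stat.degenerate:
        return "indeterminate"
    if pval(coherence_stat) >= alpha:
        return "random"
    if coherence_stat.observed > coherence_stat.null_mean:
        return "checkerboard"
    # positive coherence
    if clumping_null is not None and not clumping_null.degenerate:
        clumped = (
            clumping.morisita > 1
            and clumping_null.z > 0
            and pval(clumping_null) < alpha
        )
        even = (
            clumping.morisita < 1
            and clumping_null.z < 0
            and pval(clumping_null) < alpha
        )
    else:
        clumped = clumping.morisita > 1 and clumping.p < alpha
        even = clumping.morisita < 1 and clumping.p < alpha
    positive_turnover = turnover_stat.observed >= turnover_stat.null_mean
    if positive_turnover:
        if clumped:
            base = "clementsian"
        elif even:
            base = "evenly_spaced"
        else:
            base = "gleasonian"
    else:
        base = "nested"
    if quasi and pval(turnover_stat) >= alpha:
        return "quasi-" + base
    return base


@dataclass
class EMSReport:
    """Full EMS analysis of one incidence matrix."""

    ordination: OrdinationResult
    coherence: NullStat
    turnover: NullStat
    clumping: ClumpingResult
    clumping_null: NullStat | None
    classification: str

    def to_dict(self) -> dict:
        def ns(x: NullStat) -> dict:
            return {
                "observed": x.observed,
                "null_mean": x.null_mean,
                "null_sd": x.null_sd,
                "z": x.z,
                "p": x.p,
                "p_empirical": x.p_empirical,
                "n_permutations": x.n_permutations,
            }

        return {
            "eigenvalue": self.ordination.eigenvalue,
            "coherence": ns(self.coherence),
            "turnover": ns(self.turnover),
            "boundary_clumping": {
                "morisita": self.clumping.morisita,
                "chi2": self.clumping.chi2,
                "df": self.clumping.df,
                "p": self.clumping.p,
                "null_mean": (
                    self.clumping_null.null_mean if self.clumping_null else None
                ),
                "null_sd": (
                    self.clumping_null.null_sd if self.clumping_null else None
                ),
                "p_montecarlo": (
                    self.clumping_null.p if self.clumping_null else None
                ),
            },
            "classification": self.classification,
        }


def ems_report(
    matrix: IncidenceMatrix,
    null: NullModelSpec | None = None,
    margins: str = "both",
    df_convention: str = "sites",
    quasi: bool = False,
    alpha: float = 0.05,
    p_kind: str = "empirical",
) -> EMSReport:
    """Ordinate and compute all three EMS statistics with one null stream."""
    null = null or NullModelSpec()
    matrix = matrix.drop_empty()
    ords = ordinate(matrix)
    obs_abs = embedded_absences(ords.ordered.values, margins=margins)
    obs_rep = replacements(ords.ordered.values)
    null_abs, null_rep = _null_counts(ords.ordered, null, margins)
    coh = _null_stat(obs_abs, null_abs)
    turn = _null_stat(obs_rep, null_rep)
    clump = boundary_clumping(ords.ordered, df_convention=df_convention)
    clump_null_spec = NullModelSpec(
        n_permutations=null.n_permutations,
        allow_empty=null.allow_empty,
        reordinate_nulls=null.reordinate_nulls,
        seed=None if null.seed is None else null.seed + 1,
    )
    clump_null = clumping_null_test(ords.ordered, clump_null_spec)
    label = classify(
        coh,
        turn,
        clump,
        quasi=quasi,
        alpha=alpha,
        clumping_null=clump_null,
        p_kind=p_kind,
    )
    return EMSReport(ords, coh, turn, clump, clump_null, label)


# ---------------------------------------------------------------------------
# Compartments and covariates
# ---------------------------------------------------------------------------

@dataclass
class CompartmentSplit:
    boundary_row_index: int
    children: tuple[IncidenceMatrix, IncidenceMatrix]
    reports: tuple[EMSReport | None, EMSReport | None]
    separation: float


def propose_boundary(ordered: IncidenceMatrix) -> tuple[int, float]:
    """Boundary maximizing between- minus within-group mean Jaccard distance.

    Candidate splits run over every interior position of the ordered rows;
    ties go to the smallest index.
    """
    v = ordered.values.astype(bool)
    T = v.shape[0]
    if T < 2:
        raise ValidationError("cannot split fewer than 2 sites")
    D = squareform(pdist(v, metric="jaccard"))
    best_b, best_score = 1, -np.inf
    labels = np.zeros(T, dtype=bool)
    iu = np.triu_indices(T, k=1)
    for b in range(1, T):
        labels[:] = False
        labels[b:] = True
        between = labels[iu[0]] != labels[iu[1]]
        d = D[iu]
        within = d[~between]
        score = d[between].mean() - (within.mean() if within.size else 0.0)
        if score > best_score + 1e-15:
            best_b, best_score = b, score
    return best_b, float(best_score)


def split_compartments(
    ordination: OrdinationResult,
    boundary_row_index: int | str = "auto",
    null: NullModelSpec | None = None,
    min_rows: int = 4,
    **ems_kwargs,
) -> CompartmentSplit:
    """Split the ordered matrix at a row boundary and re-analyze each child.

    ``boundary_row_index='auto'`` proposes the split maximizing the
    between-vs-within Jaccard separation of ordered rows. Children with
    fewer than ``min_rows`` sites are not analyzed (report is None).
    """
    ordered = ordination.ordered
    T = ordered.shape[0]
    if boundary_row_index == "auto":
        b, sep = propose_boundary(ordered)
    else:
        b = int(boundary_row_index)
        if not 0 < b < T:
            raise ValidationError(f"boundary {b} not strictly inside [1, {T - 1}]")
        sep = float("nan")
    children = []
    reports: list[EMSReport | None] = []
    for rows in (slice(0, b), slice(b, T)):
        child = IncidenceMatrix(
            ordered.values[rows],
            ordered.site_ids[rows],
            list(ordered.species_ids),
        ).drop_empty()
        children.append(child)
        if child.shape[0] < min_rows:
            warnings.warn(
                f"compartment with {child.shape[0]} site(s) < {min_rows}: "
                "analysis refused",
                stacklevel=2,
            )
            reports.append(None)
        else:
            reports.append(ems_report(child, null=null, **ems_kwargs))
    return CompartmentSplit(b, (children[0], children[1]), (reports[0], reports[1]), sep)


def score_covariate_correlation(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    covariate: str,
) -> dict[str, float | None]:
    """Pearson correlation of site ordination scores with a metadata column."""
    sites = ordination.ordered.site_ids
    scores_by_id = dict(zip(sites, ordination.site_scores[ordination.row_order]))
    ids = [s for s in sites if s in metadata.index]
    if len(ids) < 3:
        raise ValidationError("need >= 3 samples with metadata for correlation")
    x = np.array([scores_by_id[s] for s in ids], dtype=float)
    y = metadata.loc[ids, covariate].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        warnings.warn(f"zero-variance covariate {covariate!r}", stacklevel=2)
        return {"r": None, "p": None, "n": len(ids)}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(ids)}
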