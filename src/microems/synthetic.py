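"""Synthetic metacommunity datasets with known ground-truth structure.

Every downstream stage (preprocessing, EMS, beta diversity) is exercised on
data generated here: binary incidence matrices built to have one of the six
canonical metacommunity structures along a 1-D latent gradient, an abundance
overlay reproducing the skewed rank-abundance profile of host-associated
16S data (one dominant OTU family around 46.5 % mean relative abundance and
a long rare tail), a random coalescent phylogeny over the OTUs, a sample
metadata table emulating the study design (8 river populations in 2 genetic
demes, 43 animal plus 8 water samples), and a population-level Fst matrix
with higher divergence between demes than within.

Sites are generated already sorted along the gradient and shuffled at the
dataset level; the true ordering and per-sample compartment labels are kept
in the ``truth`` payload so ordination/classification recovery is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .core import AbundanceTable, DistanceMatrix, IncidenceMatrix, ValidationError
from . import tables as tables_mod

STRUCTURES = (
    "clementsian",
    "gleasonian",
    "nested",
    "evenly_spaced",
    "checkerboard",
    "random",
)


@dataclass
class MetacommunityScenario:
    """Ground-truth recipe for one incidence matrix.

    ``gradient_positions`` are latent per-site positions (default: evenly
    spaced on [0, 1]); ``boundary_noise`` is the probability that each cell
    is flipped after the structure is built; ``compartment_sizes`` optionally
    fixes the Clementsian site-block sizes (default: near-equal blocks).
    """

    structure_label: str
    n_sites: int
    n_species: int
    n_compartments: int = 1
    boundary_noise: float = 0.0
    gradient_positions: np.ndarray | None = None
    compartment_sizes: list[int] | None = None
    random_fill: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.structure_label not in STRUCTURES:
            raise ValidationError(f"unknown structure {self.structure_label!r}")
        if self.n_sites < 4:
            raise ValidationError("n_sites must be >= 4")
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if not 0 <= self.boundary_noise < 0.5:
            raise ValidationError("boundary_noise must be in [0, 0.5)")
        if self.n_compartments < 1:
            raise ValidationError("n_compartments must be >= 1")
        if self.n_compartments > self.n_sites / 2:
            raise ValidationError(
                f"{self.n_compartments} compartments over {self.n_sites} sites "
                "would be degenerate (need >= 2 sites per compartment)"
            )
        if self.gradient_positions is None:
            self.gradient_positions = np.linspace(0.0, 1.0, self.n_sites)
        else:
            self.gradient_positions = np.asarray(self.gradient_positions, dtype=float)
            if len(self.gradient_positions) != self.n_sites:
                raise ValidationError("gradient_positions length != n_sites")

    def site_compartments(self) -> np.ndarray:
        """Per-site compartment index (gradient order)."""
        if self.compartment_sizes is not None:
            sizes = list(self.compartment_sizes)
            if sum(sizes) != self.n_sites or len(sizes) != self.n_compartments:
                raise ValidationError("compartment_sizes inconsistent with scenario")
        else:
            base = self.n_sites // self.n_compartments
            extra = self.n_sites % self.n_compartments
            sizes = [base + (1 if k < extra else 0) for k in range(self.n_compartments)]
        return np.repeat(np.arange(self.n_compartments), sizes)


def _balanced_flat_patterns(
    n_patterns: int, n_sites: int, rng: np.random.Generator, n_iter: int = 120000
) -> np.ndarray:
    """Balanced +-1 site patterns with flattened site co-occurrence.

    Starting from random balanced sign patterns, greedy pair swaps minimize
    the off-diagonal energy of the site-by-site Gram matrix. The resulting
    exclusion patterns are mutually decorrelated across sites, so the
    checkerboard is not reducible to a latent gradient: no single site
    ordering can compact the species ranges.
    """
    P = np.ones((n_patterns, n_sites), dtype=np.int32)
    for p in range(n_patterns):
        P[p, rng.permutation(n_sites)[: n_sites // 2]] = -1
    Q = P.T @ P
    np.fill_diagonal(Q, 0)
    for _ in range(n_iter):
        p = int(rng.integers(n_patterns))
        plus = np.flatnonzero(P[p] == 1)
        minus = np.flatnonzero(P[p] == -1)
        i = int(plus[rng.integers(len(plus))])
        j = int(minus[rng.integers(len(minus))])
        new_qi = Q[i] - 2 * P[p, i] * P[p]
        new_qj = Q[j] - 2 * P[p, j] * P[p]
        # both cells flip, so the (i, j) product is unchanged
        new_qi[j] = Q[i, j]
        new_qj[i] = Q[i, j]
        new_qi[i] = 0
        new_qj[j] = 0
        delta = (
            (new_qi.astype(np.int64) ** 2).sum()
            + (new_qj.astype(np.int64) ** 2).sum()
            - (Q[i].astype(np.int64) ** 2).sum()
            - (Q[j].astype(np.int64) ** 2).sum()
        )
        if delta < 0:
            P[p, i] *= -1
            P[p, j] *= -1
            Q[i] = new_qi
            Q[:, i] = new_qi
            Q[j] = new_qj
            Q[:, j] = new_qj
    return P


def generate_incidence(scenario: MetacommunityScenario) -> IncidenceMatrix:
    """Build the canonical structure, then flip cells with boundary_noise.

    Sites come out sorted along the latent gradient. Constructions:
    clementsian — species span exactly their compartment's site block
    (coincident boundaries, no inter-compartment overlap); gleasonian —
    contiguous ranges with independently uniform endpoints; nested —
    species occupy all sites up to a species-specific gradient threshold;
    evenly spaced — equal-length contiguous ranges with maximally staggered
    starts; checkerboard — mutually exclusive complementary pairs whose
    balanced site sets are decorrelated across sites, so the exclusion gaps
    survive any reordering; random — independent Bernoulli occupancy at
    ``random_fill``.
    """
    T, S = scenario.n_sites, scenario.n_species
    rng = np.random.default_rng(scenario.seed)
    v = np.zeros((T, S), dtype=np.int8)
    label = scenario.structure_label

    if label == "clementsian":
        comp_of_site = scenario.site_compartments()
        comp_of_species = np.arange(S) % scenario.n_compartments
        for s in range(S):
            v[comp_of_site == comp_of_species[s], s] = 1
    elif label == "gleasonian":
        ends = np.sort(rng.integers(0, T, size=(S, 2)), axis=1)
        for s in range(S):
            v[ends[s, 0]: ends[s, 1] + 1, s] = 1
    elif label == "nested":
        # species-specific thresholds stratified evenly over the gradient
        # (every species holds >= 1 site); stratification keeps the richness
        # profile stable across replicates
        ks = 1 + (np.arange(S) * T) // S
        rng.shuffle(ks)
        for s in range(S):
            v[: ks[s], s] = 1
    elif label == "evenly_spaced":
        L = max(1, T // 2)
        starts = np.round(np.linspace(0, T - L, S)).astype(int)
        for s in range(S):
            v[starts[s]: starts[s] + L, s] = 1
    elif label == "checkerboard":
        n_pairs = S // 2
        patterns = _balanced_flat_patterns(n_pairs + (S % 2), T, rng)
        for k in range(n_pairs):
            a = (patterns[k] == 1).astype(np.int8)
            v[:, 2 * k] = a
            v[:, 2 * k + 1] = 1 - a
        if S % 2:
            v[:, -1] = (patterns[-1] == 1).astype(np.int8)
    elif label == "random":
        # "no structure given margins": a Bernoulli template at the target
        # fill sets the per-site richness and per-species marginals, and the
        # returned matrix is one fixed-proportional draw at those margins —
        # the same process the EMS significance tests use as their null
        # hypothesis, so this is the calibration case for the classifier
        template = (rng.random((T, S)) < scenario.random_fill).astype(np.int8)
        richness = template.sum(axis=1)
        w = template.sum(axis=0).astype(float)
        e = rng.exponential(size=(T, S))
        with np.errstate(divide="ignore"):
            keys = e / w  # zero-marginal species never drawn
        order = np.argsort(keys, axis=1)
        v = np.zeros((T, S), dtype=np.int8)
        for i in range(T):
            v[i, order[i, : richness[i]]] = 1

    if scenario.boundary_noise > 0:
        flips = rng.random((T, S)) < scenario.boundary_noise
        v = np.where(flips, 1 - v, v).astype(np.int8)

    return IncidenceMatrix(
        v,
        [f"site{i:03d}" for i in range(T)],
        [f"sp{j:04d}" for j in range(S)],
    )


# ---------------------------------------------------------------------------
# Abundance overlay
# ---------------------------------------------------------------------------

@dataclass
class AbundanceModel:
    """Rank-abundance and read-depth parameters for the count overlay.

    Species weights are iid lognormal(mu, sigma); the most prevalent
    species is re-weighted so its expected within-sample relative abundance
    equals ``dominant_fraction``. Per-sample depth is gamma-Poisson
    (negative binomial) with mean ``depth_mean`` and shape
    ``depth_dispersion``.
    """

    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    dominant_fraction: float = 0.465
    depth_mean: float = 20000.0
    depth_dispersion: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.dominant_fraction < 1:
            raise ValidationError("dominant_fraction must be in (0, 1)")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")


def overlay_abundance(incidence: IncidenceMatrix, model: AbundanceModel) -> AbundanceTable:
    """Allocate reads to present species by weighted multinomial sampling.

    Absent species never receive reads; an all-zero incidence row yields an
    all-zero abundance row.
    """
    rng = np.random.default_rng(model.seed)
    T, S = incidence.shape
    v = incidence.values.astype(bool)
    # abundance-occupancy coupling restricted to the ubiquitous tier: species
    # present in >= 80 % of sites take the largest lognormal weights (ordered
    # by prevalence, ties by column index); all other species receive the
    # remaining weights in random order, so structured-but-narrow species are
    # not systematically starved of reads
    draws = np.sort(rng.lognormal(model.lognormal_mu, model.lognormal_sigma, size=S))[::-1]
    prevalence = v.sum(axis=0)
    ubiquitous = np.flatnonzero(prevalence >= 0.8 * T)
    ubiquitous = ubiquitous[np.lexsort((ubiquitous, -prevalence[ubiquitous]))]
    rest = np.setdiff1d(np.arange(S), ubiquitous)
    rank = np.concatenate([ubiquitous, rng.permutation(rest)]).astype(int)
    weights = np.empty(S)
    weights[rank] = draws
    top_candidates = np.lexsort((np.arange(S), -prevalence))
    top = int(top_candidates[0])  # most prevalent species; ties -> first index
    if len(ubiquitous) == 0:
        # no ubiquitous tier: give the top-prevalence species the top weight
        weights[top], weights[rank[0]] = weights[rank[0]], weights[top]
    # calibrate the dominant species' weight against the mean total weight
    # of the other species co-occurring with it
    others = weights.copy()
    others[top] = 0.0
    with_top = v[:, top]
    co_weight = (v[with_top] * others).sum(axis=1) if with_top.any() else np.array([others.sum()])
    mbar = float(co_weight.mean())
    d = model.dominant_fraction
    weights[top] = d / (1.0 - d) * mbar if mbar > 0 else 1.0

    lam = rng.gamma(model.depth_dispersion, model.depth_mean / model.depth_dispersion, size=T)
    depths = rng.poisson(lam)
    counts = np.zeros((T, S), dtype=np.int64)
    for i in range(T):
        present = v[i]
        if not present.any():
            continue
        depth = max(int(depths[i]), 1)
        p = weights * present
        counts[i] = rng.multinomial(depth, p / p.sum())
    return AbundanceTable(
        pd.DataFrame(counts, index=incidence.site_ids, columns=incidence.species_ids)
    )


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def generate_tree_newick(otu_ids: list[str], seed: int | None = None) -> str:
    """Random sequential coalescence over the OTUs; Exp(1) branch lengths.

    Output is a deterministic Newick string (byte-identical under a fixed
    seed).
    """
    ids = list(otu_ids)
    if len(ids) < 2:
        raise ValidationError("need >= 2 OTU ids for a tree")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate OTU ids")
    rng = np.random.default_rng(seed)
    clusters = list(ids)
    while len(clusters) > 1:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        li, lj = rng.exponential(1.0, size=2)
        a, b = clusters[i], clusters[j]
        merged = f"({a}:{li:.6f},{b}:{lj:.6f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters[0] + ";"


def generate_tree(otu_ids: list[str], seed: int | None = None) -> skbio.TreeNode:
    """Rooted binary random tree whose leaf set equals ``otu_ids``."""
    return skbio.TreeNode.read([generate_tree_newick(otu_ids, seed)])


# ---------------------------------------------------------------------------
# Metadata, Fst, water samples
# ---------------------------------------------------------------------------

DEFAULT_SAMPLES_PER_POPULATION = (5, 5, 7, 5, 3, 5, 8, 5)  # 43 animals
DEFAULT_COVARIATE_GRADIENTS = {
    # population-level means drift along the latent gradient; endpoints
    # bracket the two compartments' reported environmental means
    "latitude": (38.1, 35.5),
    "elevation": (390.0, 600.0),
    "forest_cover": (63.0, 75.0),
}


def generate_metadata(
    n_populations: int = 8,
    samples_per_population: tuple[int, ...] | int = DEFAULT_SAMPLES_PER_POPULATION,
    covariate_gradients: dict[str, tuple[float, float]] | None = None,
    water_per_population: int = 1,
    seed: int | None = None,
    n_deme1_populations: int | None = None,
) -> pd.DataFrame:
    """Sample metadata emulating the study design.

    Populations are ordered along the latent gradient and split into two
    demes (default 3 + 5 when there are 8 populations, mirroring the two
    river drainages). Covariate values are drawn around population-level
    means that drift linearly along the gradient; pseudo-coordinates place
    populations along a longitude transect with per-sample jitter.
    """
    if n_populations < 2:
        raise ValidationError("need >= 2 populations")
    if isinstance(samples_per_population, int):
        spp = [samples_per_population] * n_populations
    else:
        spp = list(samples_per_population)
        if len(spp) != n_populations:
            raise ValidationError("samples_per_population length != n_populations")
    grads = covariate_gradients or DEFAULT_COVARIATE_GRADIENTS
    if n_deme1_populations is None:
        n_deme1_populations = 3 if n_populations == 8 else n_populations // 2
    rng = np.random.default_rng(seed)
    pops = [f"pop{k + 1}" for k in range(n_populations)]
    pos = np.linspace(0.0, 1.0, n_populations)
    rows = []
    for k, pop in enumerate(pops):
        deme = "deme1" if k < n_deme1_populations else "deme2"
        means = {name: a + (b - a) * pos[k] for name, (a, b) in grads.items()}
        lon0 = -86.0 + 3.0 * pos[k]
        members = [("animal", i) for i in range(spp[k])]
        members += [("water", i) for i in range(water_per_population)]
        for stype, i in members:
            tag = "A" if stype == "animal" else "W"
            rows.append(
                {
                    "sample_id": f"{pop}_{tag}{i + 1}",
                    "population": pop,
                    "deme": deme,
                    "sample_type": stype,
                    "latitude": means.get("latitude", 36.0) + rng.normal(0, 0.05),
                    "longitude": lon0 + rng.normal(0, 0.02),
                    "elevation": means.get("elevation", 500.0) + rng.normal(0, 15.0),
                    "forest_cover": float(
                        np.clip(means.get("forest_cover", 70.0) + rng.normal(0, 2.0), 0, 100)
                    ),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def generate_fst(
    population_compartments: dict[str, int] | pd.Series,
    within_divergence: float = 0.05,
    between_divergence: float = 0.25,
    noise: float = 0.0,
    seed: int | None = None,
) -> DistanceMatrix:
    """Population Fst matrix with higher divergence between compartments."""
    if not 0 <= within_divergence <= between_divergence:
        raise ValidationError("need between_divergence >= within_divergence >= 0")
    comp = dict(population_compartments)
    pops = list(comp)
    n = len(pops)
    rng = np.random.default_rng(seed)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = within_divergence if comp[pops[i]] == comp[pops[j]] else between_divergence
            val = np.clip(base + rng.normal(0, noise), 0.0, 1.0)
            d[i, j] = d[j, i] = val
    return DistanceMatrix(d, pops, kind="fst")


def inject_water_overlap(
    animal_table: AbundanceTable,
    population: str,
    target_shared_proportion: float,
    seed: int | None = None,
    n_water_exclusive: int = 40,
    depth: int = 20000,
    lognormal_sigma: float = 1.5,
) -> AbundanceTable:
    """Append one river-water sample sharing a target OTU fraction.

    Every OTU present in the population's animal samples enters the water
    sample independently with probability ``target_shared_proportion``, so
    each animal's expected shared proportion (animal-richness denominator)
    equals the target. ``n_water_exclusive`` fresh water-only OTUs are
    added on top.
    """
    if not 0 <= target_shared_proportion <= 1:
        raise ValidationError("target_shared_proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = animal_table.counts
    pool = counts.columns[(counts > 0).any(axis=0)]
    n_shared = int(round(target_shared_proportion * len(pool)))
    shared = list(pool[rng.permutation(len(pool))[:n_shared]])
    # hyphenated ids: unquoted underscores are mangled to spaces by Newick readers
    exclusive = [f"wOTU-{population}-{k:03d}" for k in range(n_water_exclusive)]
    water_otus = shared + exclusive
    water_id = f"{population}_W1"
    out = counts.copy()
    for o in exclusive:
        out[o] = 0
    row = pd.Series(0, index=out.columns, dtype=np.int64)
    if water_otus:
        w = rng.lognormal(0.0, lognormal_sigma, size=len(water_otus))
        reads = rng.multinomial(depth, w / w.sum())
        row.loc[water_otus] = reads
        # presence must be certain for every selected OTU
        row.loc[water_otus] = np.maximum(row.loc[water_otus].to_numpy(), 1)
    out.loc[water_id] = row
    return AbundanceTable(out, dict(animal_table.taxonomy))


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Synthetic study: abundance + tree + metadata + Fst + ground truth."""

    abundance: AbundanceTable
    newick: str
    metadata: pd.DataFrame
    fst: DistanceMatrix
    truth: dict = field(default_factory=dict)

    @property
    def tree(self) -> skbio.TreeNode:
        return skbio.TreeNode.read([self.newick])

    def validate(self) -> None:
        md_ids = set(self.metadata["sample_id"])
        missing = [s for s in self.abundance.sample_ids if s not in md_ids]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")
        leaves = {n.name for n in self.tree.tips()}
        missing_otus = [o for o in self.abundance.otu_ids if o not in leaves]
        if missing_otus:
            raise ValidationError(f"OTUs missing from tree: {missing_otus[:5]}")
        pops = set(self.metadata["population"])
        if set(self.fst.ids) != pops:
            raise ValidationError("Fst populations != metadata populations")


def simulate_dataset(
    scenario: MetacommunityScenario | None = None,
    abundance_model: AbundanceModel | None = None,
    n_core_species: int = 9,
    bridge_fraction: float = 0.05,
    shared_by_deme: dict[str, float] | None = None,
    metadata_kwargs: dict | None = None,
    fst_kwargs: dict | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate the emulated study end to end.

    Defaults mirror the study design: 8 populations in 2 demes, 43 animal
    and 8 water samples, a 2-compartment Clementsian structure whose site
    blocks coincide with the demes, ~1,800 structured OTUs plus
    ``n_core_species`` core OTUs present on every animal, water overlap
    targets of 0.29 (deme 1) and 0.16 (deme 2), and an Fst matrix with
    higher between-deme divergence.
    """
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    md_kwargs = dict(metadata_kwargs or {})
    md_kwargs.setdefault("seed", child())
    metadata = generate_metadata(**md_kwargs)
    animals = metadata[metadata["sample_type"] == "animal"]
    # gradient order: populations in index order, animals within population
    animal_ids = list(animals["sample_id"])
    n_sites = len(animal_ids)
    deme_of_pop = dict(
        metadata.drop_duplicates("population")[["population", "deme"]].values
    )
    # two gradient compartments per deme: the deme boundary is the major
    # compartment split, with finer population groupings inside each deme
    comp_sizes: list[int] = []
    for deme in dict.fromkeys(deme_of_pop.values()):
        n = int((animals["deme"] == deme).sum())
        comp_sizes += [n // 2, n - n // 2]
    if scenario is None:
        scenario = MetacommunityScenario(
            "clementsian",
            n_sites=n_sites,
            n_species=1800,
            n_compartments=len(comp_sizes),
            compartment_sizes=comp_sizes,
            boundary_noise=0.01,
            seed=child(),
        )
    if scenario.n_sites != n_sites:
        raise ValidationError(
            f"scenario has {scenario.n_sites} sites but metadata has {n_sites} animals"
        )
    incidence = generate_incidence(scenario)
    v = incidence.values
    # core OTUs present on every animal (they take the dominant weights)
    core_ids = [f"core{k:02d}" for k in range(n_core_species)]
    # broad-ranged generalist OTUs whose contiguous ranges straddle
    # compartment edges: they carry the between-compartment gradient order
    # that strictly disjoint compartments cannot encode
    bridge_rng = np.random.default_rng(child())
    n_bridge = max(0, int(round(bridge_fraction * scenario.n_species)))
    bridge_ids = [f"bridge{k:03d}" for k in range(n_bridge)]
    bridge = np.zeros((n_sites, n_bridge), dtype=np.int8)
    L = max(2, n_sites // 2)
    for k in range(n_bridge):
        start = int(bridge_rng.integers(0, n_sites - L + 1))
        bridge[start: start + L, k] = 1
    v = np.hstack(
        [np.ones((n_sites, n_core_species), dtype=np.int8), bridge, v]
    )
    species_ids = core_ids + bridge_ids + incidence.species_ids
    # shuffle sites; truth keeps the gradient order
    order = rng.permutation(n_sites)
    site_comp = scenario.site_compartments()
    shuffled_ids = [animal_ids[i] for i in order]
    inc = IncidenceMatrix(v[order], shuffled_ids, species_ids)

    model = abundance_model or AbundanceModel(seed=child())
    if model.seed is None:
        model.seed = child()
    animal_abund = overlay_abundance(inc, model)

    shared = shared_by_deme or {"deme1": 0.29, "deme2": 0.16}
    combined = animal_abund.counts
    water_rows = []
    for pop in metadata["population"].unique():
        pop_animals = [
            s for s in animal_ids if metadata.at[s, "population"] == pop
        ]
        sub = AbundanceTable(animal_abund.counts.loc[pop_animals])
        target = shared.get(deme_of_pop[pop], 0.2)
        with_water = inject_water_overlap(
            sub, pop, target, seed=child(),
            depth=int(model.depth_mean),
        )
        water_rows.append(with_water.counts.iloc[[-1]])
    all_cols = list(combined.columns)
    for wr in water_rows:
        all_cols += [c for c in wr.columns if c not in set(all_cols)]
    combined = combined.reindex(columns=all_cols, fill_value=0)
    water = pd.concat(
        [wr.reindex(columns=all_cols, fill_value=0) for wr in water_rows]
    )
    # the dominant core taxa are aquatic: every water sample carries them at
    # an abundance that survives rarefaction (~0.5 % of reads each)
    core_floor = max(1, int(model.depth_mean) // 200)
    water[core_ids] = np.maximum(water[core_ids].to_numpy(), core_floor)
    abundance = AbundanceTable(pd.concat([combined, water]))

    newick = generate_tree_newick(list(abundance.otu_ids), seed=child())
    compartment_names = list(dict.fromkeys(deme_of_pop.values()))
    pop_comp = {
        p: compartment_names.index(d) for p, d in deme_of_pop.items()
    }
    fst = generate_fst(pop_comp, seed=child(), **(fst_kwargs or {}))

    truth = {
        "scenario": {
            "structure_label": scenario.structure_label,
            "n_sites": scenario.n_sites,
            "n_species": scenario.n_species,
            "n_compartments": scenario.n_compartments,
            "boundary_noise": scenario.boundary_noise,
            "seed": scenario.seed,
        },
        "gradient_order": animal_ids,
        "site_compartment": {
            sid: int(site_comp[k]) for k, sid in enumerate(animal_ids)
        },
        "population_compartment": pop_comp,
        "core_otus": core_ids,
        "master_seed": seed,
    }
    ds = SimulatedDataset(abundance, newick, metadata, fst, truth)
    ds.validate()
    return ds


def write_dataset(ds: SimulatedDataset, outdir, seed: int | None = None) -> dict[str, str]:
    """Write table (TSV + BIOM JSON), tree, metadata, Fst and truth labels."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table_tsv": out / "otu_table.tsv",
        "table_biom": out / "otu_table.biom.json",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "fst": out / "fst.tsv",
        "truth": out / "truth.json",
    }
    tables_mod.write_table(ds.abundance, paths["table_tsv"], "tsv", seed=seed)
    tables_mod.write_table(ds.abundance, paths["table_biom"], "biom", seed=seed)
    paths["tree"].write_text(ds.newick + "\n")
    tables_mod.write_metadata(ds.metadata, paths["metadata"], seed=seed)
    ds.fst.write_tsv(paths["fst"])
    paths["truth"].write_text(json.dumps(ds.truth, indent=1))
    return {k: str(v) for k, v in paths.items()}
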