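"""End-to-end orchestration: preprocess -> alpha -> EMS -> compartments -> beta.

``run`` executes the full analysis from input files (OTU table, Newick
tree, metadata TSV, optional population Fst TSV) with the study's default
parameters: 0.005 % abundance filter, rarefaction to 8,800 reads, 80 % core
prevalence, r1 null with 99 permutations, Mantel with 10,000 permutations.
``demo`` first simulates the emulated study design (8 populations, 2 demes,
43 animal + 8 water samples) and then runs the same analysis on it.

One master seed drives everything; per-stage child seeds are derived
deterministically so identical config + seed gives an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
import yaml

from . import beta as beta_mod
from . import synthetic, tables
from .core import DistanceMatrix, ValidationError
from .ems import NullModelSpec, ems_report, score_covariate_correlation, split_compartments
from .version import __version__

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis inputs and parameters; defaults match the study."""

    table_path: str | None = None
    table_format: str = "tsv"
    tree_path: str | None = None
    metadata_path: str | None = None
    fst_path: str | None = None
    output_dir: str = "microems_out"

    filter_min_fraction: float = 0.00005   # 0.005 % of the grand total
    rarefaction_depth: int = 8800
    core_prevalence: float = 0.80
    shared_denominator: str = "animal"

    null_model: str = "r1"
    null_permutations: int = 99
    null_allow_empty: bool = True
    null_reordinate: bool = True
    ems_margins: str = "both"
    ems_alpha: float = 0.05
    split_compartments: bool = True

    unifrac_weighted: bool = True
    unifrac_unweighted: bool = True
    group_test_permutations: int = 999
    mantel_permutations: int = 10000

    seed: int = 0

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("output_dir")  # where results land is not part of the analysis
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _child_seeds(master: int, names: list[str]) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the master seed."""
    out = {}
    for name in names:
        h = hashlib.sha256(f"{master}:{name}".encode()).digest()
        out[name] = int.from_bytes(h[:4], "big") % (2**31 - 1)
    return out


@dataclass
class RunReport:
    config: PipelineConfig
    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "config": asdict(self.config),
            **self.sections,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _validate_inputs(table, tree, metadata) -> None:
    md_ids = set(metadata.index)
    missing_md = [s for s in table.sample_ids if s not in md_ids]
    problems = []
    if missing_md:
        problems.append(f"{len(missing_md)} sample(s) missing metadata: {missing_md[:5]}")
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        missing_otus = [o for o in table.otu_ids if o not in leaves]
        if missing_otus:
            problems.append(
                f"{len(missing_otus)} OTU(s) missing from tree: {missing_otus[:5]}"
            )
    if problems:
        raise ValidationError("input reconciliation failed: " + "; ".join(problems))


def run(config: PipelineConfig) -> RunReport:
    """Execute every stage in fixed order; optional stages skip with a warning."""
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(
        config.seed, ["rarefy", "ems", "ems_c1", "ems_c2", "beta", "mantel"]
    )

    if config.table_path is None:
        raise ValidationError("no OTU table configured")
    table = tables.read_table(config.table_path, config.table_format)
    metadata = tables.read_metadata(config.metadata_path)
    tree = None
    want_unifrac = config.unifrac_weighted or config.unifrac_unweighted
    if config.tree_path:
        tree = skbio.TreeNode.read(config.tree_path)
    elif want_unifrac:
        raise ValidationError("UniFrac requested but no tree path configured")
    _validate_inputs(table, tree, metadata)

    report = RunReport(config)
    report.provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    # --- preprocessing -----------------------------------------------------
    filtered = tables.filter_rare_otus(table, config.filter_min_fraction)
    rarefied = tables.rarefy(filtered, config.rarefaction_depth, seed=seeds["rarefy"])
    report.sections["preprocessing"] = {
        "input_samples": len(table.sample_ids),
        "input_otus": len(table.otu_ids),
        "otus_after_filter": len(filtered.otu_ids),
        "samples_after_rarefaction": len(rarefied.sample_ids),
        "rarefaction_depth": config.rarefaction_depth,
    }
    tables.write_table(rarefied, out / "table_preprocessed.tsv", seed=config.seed)

    # --- alpha -------------------------------------------------------------
    core = tables.core_microbiome(rarefied, config.core_prevalence)
    alpha = tables.alpha_summaries(
        rarefied, metadata, shared_denominator=config.shared_denominator
    )
    alpha.to_csv(out / "alpha_summaries.tsv", sep="\t", index=False)
    animal_alpha = alpha[
        [s in metadata.index and metadata.at[s, "sample_type"] == "animal"
         for s in alpha.index]
    ]
    report.sections["alpha"] = {
        "core_otus": core,
        "n_core": len(core),
        "mean_richness_animals": float(animal_alpha["richness"].mean()),
        "mean_shannon_animals": float(animal_alpha["shannon"].mean()),
        "mean_shared_proportion": (
            float(animal_alpha["shared_proportion"].dropna().mean())
            if animal_alpha["shared_proportion"].notna().any()
            else None
        ),
    }

    # --- EMS ---------------------------------------------------------------
    incidence = tables.to_incidence(rarefied, metadata, ("animal",))
    null = NullModelSpec(
        model=config.null_model,
        n_permutations=config.null_permutations,
        allow_empty=config.null_allow_empty,
        reordinate_nulls=config.null_reordinate,
        seed=seeds["ems"],
    )
    ems = ems_report(
        incidence, null, margins=config.ems_margins, alpha=config.ems_alpha
    )
    section = ems.to_dict()
    section["covariate_correlations"] = {
        cov: score_covariate_correlation(ems.ordination, metadata, cov)
        for cov in ("forest_cover", "elevation", "latitude")
    }
    # ordered incidence with covariate side bars, as plot data
    ordered = ems.ordination.ordered
    plot = pd.DataFrame(
        ordered.values, index=ordered.site_ids, columns=ordered.species_ids
    )
    for cov in ("latitude", "elevation", "forest_cover"):
        plot.insert(0, f"_{cov}", metadata.loc[plot.index, cov].to_numpy())
    plot.to_csv(out / "ordered_incidence.tsv", sep="\t", index_label="sample_id")

    if config.split_compartments:
        split = split_compartments(
            ems.ordination,
            "auto",
            null=NullModelSpec(
                model=config.null_model,
                n_permutations=config.null_permutations,
                allow_empty=config.null_allow_empty,
                reordinate_nulls=config.null_reordinate,
                seed=seeds["ems_c1"],
            ),
            margins=config.ems_margins,
            alpha=config.ems_alpha,
        )
        section["compartments"] = {
            "boundary_row_index": split.boundary_row_index,
            "separation": split.separation,
            "children": [
                {
                    "n_sites": child.shape[0],
                    "n_species": child.shape[1],
                    "sites": child.site_ids,
                    "report": rep.to_dict() if rep is not None else None,
                }
                for child, rep in zip(split.children, split.reports)
            ],
        }
    report.sections["ems"] = section

    # --- beta --------------------------------------------------------------
    animals = [
        s for s in rarefied.sample_ids
        if metadata.at[s, "sample_type"] == "animal"
    ]
    animal_table = tables.AbundanceTable(
        rarefied.counts.loc[animals], dict(rarefied.taxonomy)
    )
    groups_pop = metadata.loc[animals, "population"]
    groups_deme = metadata.loc[animals, "deme"]
    beta_section: dict = {}
    dms: dict[str, DistanceMatrix] = {}
    dms["jaccard"] = beta_mod.jaccard_matrix(animal_table)
    if config.unifrac_unweighted:
        dms["unweighted_unifrac"] = beta_mod.unifrac_matrix(
            animal_table, tree, weighted=False
        )
    if config.unifrac_weighted:
        dms["weighted_unifrac"] = beta_mod.unifrac_matrix(
            animal_table, tree, weighted=True
        )
    rng = np.random.default_rng(seeds["beta"])
    for name, dm in dms.items():
        dm.write_tsv(out / f"distance_{name}.tsv")
        entry: dict = {}
        if name != "jaccard":
            for label, grouping in (("population", groups_pop), ("deme", groups_deme)):
                ad = beta_mod.permanova(
                    dm, grouping, config.group_test_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                )
                an = beta_mod.anosim(
                    dm, grouping, config.group_test_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                )
                entry[label] = {
                    "adonis_r2": ad.r_squared,
                    "adonis_pseudo_f": ad.statistic,
                    "adonis_p": ad.p,
                    "anosim_r": an.statistic,
                    "anosim_p": an.p,
                }
            pc = beta_mod.pcoa(dm)
            pcoa_df = pc.coordinates.copy()
            pcoa_df.to_csv(out / f"pcoa_{name}.tsv", sep="\t", index_label="sample_id")
            entry["pcoa_prop_explained_1_2"] = [
                float(x) for x in pc.proportion_explained[:2]
            ]
        beta_section[name] = entry

    # Mantel: Fst vs UniFrac; geographic vs 1-Jaccard
    mantel_rng = np.random.default_rng(seeds["mantel"])
    if config.fst_path:
        fst = DistanceMatrix.read_tsv(config.fst_path, kind="fst")
        fst_samples = beta_mod.expand_fst_to_samples(fst, metadata, animals)
        for name in ("unweighted_unifrac", "weighted_unifrac"):
            if name in dms:
                mr = beta_mod.mantel(
                    dms[name], fst_samples, config.mantel_permutations,
                    seed=int(mantel_rng.integers(2**31 - 1)),
                )
                beta_section[f"mantel_fst_{name}"] = {"r": mr.r, "p": mr.p}
    else:
        logger.warning("no Fst matrix supplied; skipping Fst Mantel tests")
    geo = beta_mod.geographic_distances(metadata.loc[animals])
    mr = beta_mod.mantel(
        dms["jaccard"], geo, config.mantel_permutations,
        seed=int(mantel_rng.integers(2**31 - 1)),
    )
    beta_section["mantel_geographic_jaccard"] = {"r": mr.r, "p": mr.p}
    report.sections["beta"] = beta_section

    report.provenance["runtime_s"] = round(time.time() - t_start, 2)
    report.write(out / "report.json")
    _write_text_report(report, out / "report.txt")
    return report


def _write_text_report(report: RunReport, path) -> None:
    lines = [
        f"microems v{__version__} run report",
        f"config hash: {report.provenance['config_hash']}  seed: {report.provenance['seed']}",
        "",
    ]
    pre = report.sections.get("preprocessing", {})
    lines.append(
        f"preprocessing: {pre.get('input_otus')} OTUs -> "
        f"{pre.get('otus_after_filter')} after abundance filter; "
        f"{pre.get('samples_after_rarefaction')} samples at depth "
        f"{pre.get('rarefaction_depth')}"
    )
    ems = report.sections.get("ems", {})
    if ems:
        coh, turn, bc = ems["coherence"], ems["turnover"], ems["boundary_clumping"]
        lines += [
            "",
            "metacommunity structure (EMS):",
            f"  coherence: absences {coh['observed']:.0f} "
            f"(null {coh['null_mean']:.1f} +- {coh['null_sd']:.1f}, p {coh['p']:.3g})",
            f"  turnover: replacements {turn['observed']:.0f} "
            f"(null {turn['null_mean']:.1f} +- {turn['null_sd']:.1f}, p {turn['p']:.3g})",
            f"  boundary clumping: Morisita {bc['morisita']:.2f} (p {bc['p']:.3g})",
            f"  classification: {ems['classification']}",
        ]
    beta_s = report.sections.get("beta", {})
    for name, entry in beta_s.items():
        if isinstance(entry, dict) and "population" in entry:
            pop = entry["population"]
            lines.append(
                f"  {name} by population: Adonis R2 {pop['adonis_r2']:.2f} "
                f"(p {pop['adonis_p']:.3g}); ANOSIM R {pop['anosim_r']:.2f} "
                f"(p {pop['anosim_p']:.3g})"
            )
        if name.startswith("mantel"):
            r = entry.get("r")
            lines.append(
                f"  {name}: r {r if r is None else round(r, 3)} p {entry.get('p')}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def demo(output_dir, seed: int = 0) -> RunReport:
    """Simulate the emulated study and run the full pipeline on it."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = synthetic.simulate_dataset(seed=seed)
    paths = synthetic.write_dataset(ds, out / "data", seed=seed)
    config = PipelineConfig(
        table_path=paths["table_tsv"],
        tree_path=paths["tree"],
        metadata_path=paths["metadata"],
        fst_path=paths["fst"],
        output_dir=str(out / "analysis"),
        seed=seed,
    )
    report = run(config)
    report.sections["truth"] = {
        "structure_label": ds.truth["scenario"]["structure_label"],
        "n_compartments": ds.truth["scenario"]["n_compartments"],
    }
    report.write(out / "analysis" / "report.json")
    return report
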