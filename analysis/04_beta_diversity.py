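#!/usr/bin/env python
"""Compositional and phylogenetic beta diversity of the animal samples.

Builds unweighted/weighted UniFrac and Jaccard distance matrices, tests
group differences by deme and population with PERMANOVA (Adonis) and
ANOSIM, embeds communities with PCoA, and runs Mantel tests of community
dissimilarity against population genetic distance (Fst) and geographic
distance (10,000 permutations).
"""

import json
from pathlib import Path

import skbio

from microems import beta, tables
from microems.core import AbundanceTable, DistanceMatrix

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    table = tables.read_table(DATA / "otu_table_preprocessed.tsv")
    metadata = tables.read_metadata(DATA / "metadata.tsv")
    tree = skbio.TreeNode.read(str(DATA / "tree.nwk"))
    fst = DistanceMatrix.read_tsv(DATA / "fst.tsv", kind="fst")

    animals = [
        s for s in table.sample_ids if metadata.at[s, "sample_type"] == "animal"
    ]
    at = AbundanceTable(table.counts.loc[animals], dict(table.taxonomy))
    out: dict = {}
    dms = {
        "unweighted_unifrac": beta.unifrac_matrix(at, tree, weighted=False),
        "weighted_unifrac": beta.unifrac_matrix(at, tree, weighted=True),
        "jaccard": beta.jaccard_matrix(at),
    }
    for name in ("unweighted_unifrac", "weighted_unifrac"):
        dm = dms[name]
        entry = {}
        for factor in ("deme", "population"):
            groups = metadata.loc[animals, factor]
            ad = beta.permanova(dm, groups, 999, seed=SEED)
            an = beta.anosim(dm, groups, 999, seed=SEED)
            entry[factor] = {
                "adonis_r2": round(ad.r_squared, 3),
                "adonis_p": ad.p,
                "anosim_r": round(an.statistic, 3),
                "anosim_p": an.p,
            }
            print(
                f"{name} by {factor}: Adonis R2 {ad.r_squared:.2f} "
                f"(p {ad.p:.3g}); ANOSIM R {an.statistic:.2f} (p {an.p:.3g})"
            )
        pc = beta.pcoa(dm)
        pc.coordinates.iloc[:, :4].to_csv(
            TABLES / f"pcoa_{name}.tsv", sep="\t", index_label="sample_id"
        )
        entry["pcoa_prop_explained_1_2"] = [
            round(float(x), 3) for x in pc.proportion_explained[:2]
        ]
        out[name] = entry

    fst_samples = beta.expand_fst_to_samples(fst, metadata, animals)
    for name in ("unweighted_unifrac", "weighted_unifrac"):
        mr = beta.mantel(dms[name], fst_samples, 10000, seed=SEED)
        out[f"mantel_fst_{name}"] = {"r": round(mr.r, 3), "p": mr.p}
        print(f"Mantel Fst vs {name}: r {mr.r:.2f} (p {mr.p:.3g})")
    geo = beta.geographic_distances(metadata.loc[animals])
    mr = beta.mantel(dms["jaccard"], geo, 10000, seed=SEED)
    out["mantel_geographic_jaccard"] = {"r": round(mr.r, 3), "p": mr.p}
    print(f"Mantel geographic distance vs 1-Jaccard: r {mr.r:.2f} (p {mr.p:.3g})")

    TABLES.mkdir(parents=True, exist_ok=True)
    (TABLES / "beta_tests.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
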