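"""Generate the seeded synthetic inputs for the whole analysis.

Writes a 30-tissue expression panel with 10 planted brain-specific genes,
a fluid-detectable proteome subset, a 110-sample normal/LGG/GBM cohort
with 20 planted marker-like genes (8 negative / 8 positive planted
methylation-expression coupling), and a four-stratum two-marker
methylation cohort — all under results/data, plus the ground-truth labels.
"""

import json

import pandas as pd

from common import COHORT, DATA, FLUID, PANEL, SEED, TWO_MARKER
from omniscreen import io as oio
from omniscreen import synthetic as syn


def main():
    DATA.mkdir(parents=True, exist_ok=True)

    panel, panel_truth, site_map = syn.simulate_tissue_panel(**PANEL, seed=SEED)
    oio.write_expression_matrix(panel, DATA / "panel_expression.tsv")
    pd.DataFrame({"site_id": list(site_map), "tissue": list(site_map.values())}) \
        .to_csv(DATA / "site_map.tsv", sep="\t", index=False, lineterminator="\n")

    fluid = syn.simulate_fluid_proteome(panel.gene_ids, FLUID["n_detectable"],
                                        seed=SEED + 1)
    oio.write_fluid_proteome(fluid, DATA / "fluid_proteome.tsv")

    bundle = syn.simulate_glioma_cohort(**COHORT, seed=SEED + 2)
    oio.write_expression_matrix(bundle.expression, DATA / "cohort_expression.tsv")
    oio.write_methylation_matrix(bundle.methylation, DATA / "cohort_beta.tsv",
                                 DATA / "probe_annotation.tsv")
    oio.write_clinical_table(bundle.clinical, DATA / "cohort_clinical.tsv")
    oio.write_cnv_table(bundle.cnv, DATA / "cohort_cnv.tsv")

    tm_meth, tm_clin = syn.simulate_two_marker_cohort(**TWO_MARKER, seed=SEED + 3)
    oio.write_methylation_matrix(tm_meth, DATA / "tmz_beta.tsv",
                                 DATA / "tmz_probe_annotation.tsv")
    oio.write_clinical_table(tm_clin, DATA / "tmz_clinical.tsv")

    (DATA / "truth.json").write_text(json.dumps({
        "panel_specific_genes": panel_truth.specific_genes,
        "marker_like_genes": bundle.truth.marker_like_genes,
        "correlation_sign": bundle.truth.correlation_sign,
        "planted_probe": bundle.truth.planted_probe,
        "group_hazards": bundle.truth.group_hazards,
    }, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    print(f"panel: {len(panel.gene_ids)} genes x {len(panel.sample_ids)} sites "
          f"({PANEL['n_specific']} planted brain-specific)")
    print(f"fluid proteome: {len(fluid.gene_ids)} detectable genes")
    print(f"cohort: {len(bundle.clinical.sample_ids)} samples, "
          f"{len(bundle.expression.gene_ids)} genes "
          f"({COHORT['n_marker_like']} planted marker-like)")
    print(f"TMZ two-marker cohort: {len(tm_clin.sample_ids)} samples in 4 strata")
    print(f"inputs written to {DATA}")


if __name__ == "__main__":
    main()
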