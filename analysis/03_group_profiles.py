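"""Diagnosis-group expression and promoter-methylation profiles of the
lead candidate gene.

Pairwise rank-sum comparisons (with ns/*/**/*** coding) of the profiled
gene's expression across normal/LGG/GBM and across GBM anatomic regions,
and of its planted promoter probe's beta values across diagnoses.
Writes results/comparisons.tsv.
"""

import dataclasses
import json

import pandas as pd

from common import DATA, RESULTS
from omniscreen import group_stats as gs
from omniscreen import io as oio


def main():
    expr = oio.read_expression_matrix(DATA / "cohort_expression.tsv")
    meth = oio.read_methylation_matrix(DATA / "cohort_beta.tsv",
                                       DATA / "probe_annotation.tsv")
    clin = oio.read_clinical_table(DATA / "cohort_clinical.tsv")
    truth = json.loads((DATA / "truth.json").read_text())

    cand = pd.read_csv(RESULTS / "candidates.tsv", sep="\t")
    in_cohort = [g for g in cand["gene_id"] if g in set(expr.gene_ids)]
    gene = in_cohort[0] if in_cohort else truth["marker_like_genes"][0]
    probe = truth["planted_probe"].get(gene, f"{gene}.p1")

    rows = []
    for layer, values in (("expression", expr.values.loc[gene]),
                          ("methylation", meth.beta.loc[probe])):
        for by in ("diagnosis", "anatomic_region"):
            for r in gs.compare_across_labels(values.to_dict(), clin, by):
                rows.append({"gene": gene, "layer": layer, "by": by,
                             **dataclasses.asdict(r)})
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "comparisons.tsv", sep="\t", index=False,
               float_format="%.6g", lineterminator="\n")

    print(f"profiled gene: {gene} (promoter probe {probe})")
    for _, r in out[out["by"] == "diagnosis"].iterrows():
        print(f"  {r.layer:12s} {r.group_a:>6s} vs {r.group_b:<6s} "
              f"p={r.p_value:.2e} [{r.code}]  ({r.direction})")
    n_sig = (out["code"] != "ns").sum()
    print(f"{n_sig}/{len(out)} comparisons significant; table in results/comparisons.tsv")


if __name__ == "__main__":
    main()
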