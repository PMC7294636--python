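"""Four-criterion marker-like gene screen, correlation partition and
enrichment.

Screens every cohort gene for the marker-like pattern (promoter
hypermethylation in glioma vs normal; higher methylation and expression in
LGG vs GBM; lower expression in glioma vs normal), partitions passing
genes by the sign of their tumor-sample methylation-expression Spearman
correlation, and tests the passing set for over-representation of the
planted marker-like gene set against seeded random sets.  Writes
results/marker_audit.tsv, marker_partition.tsv and marker_enrichment.tsv.
"""

import dataclasses
import json

import numpy as np
import pandas as pd

from common import DATA, RESULTS, SEED, THRESHOLDS
from omniscreen import io as oio
from omniscreen import marker_screen as ms
from omniscreen import synthetic as syn


def main():
    bundle = syn.CohortBundle(
        expression=oio.read_expression_matrix(DATA / "cohort_expression.tsv"),
        methylation=oio.read_methylation_matrix(DATA / "cohort_beta.tsv",
                                                DATA / "probe_annotation.tsv"),
        cnv=oio.read_cnv_table(DATA / "cohort_cnv.tsv"),
        clinical=oio.read_clinical_table(DATA / "cohort_clinical.tsv"),
        truth=None,
    )
    truth = json.loads((DATA / "truth.json").read_text())
    planted = set(truth["marker_like_genes"])
    alpha = THRESHOLDS["alpha"]

    records = ms.screen_marker_like(bundle, alpha=alpha)
    audit = ms.audit_table(records)
    audit.to_csv(RESULTS / "marker_audit.tsv", sep="\t", float_format="%.6g",
                 lineterminator="\n")
    passes = [r.gene_id for r in records if r.passes_all]
    tp = len(set(passes) & planted)
    print(f"{len(passes)} of {len(records)} genes pass all four criteria "
          f"(recall {tp}/{len(planted)} planted, "
          f"{len(passes) - tp} false positives)")

    partition = ms.partition_by_correlation(records, bundle, alpha=alpha)
    pd.DataFrame([dataclasses.asdict(p) for p in partition]).to_csv(
        RESULTS / "marker_partition.tsv", sep="\t", index=False,
        float_format="%.6g", lineterminator="\n")
    counts = pd.Series([p.group for p in partition]).value_counts()
    print("correlation partition:",
          ", ".join(f"{k}={v}" for k, v in counts.items()))

    rng = np.random.default_rng(SEED + 4)
    universe = bundle.expression.gene_ids
    sets = {"planted_marker_like": sorted(planted)}
    for i in range(4):
        sets[f"random_set_{i}"] = sorted(
            rng.choice(universe, size=int(rng.integers(10, 30)), replace=False))
    enr = ms.enrich(passes, oio.GeneSetCollection(sets=sets), universe=universe)
    pd.DataFrame([dataclasses.asdict(e) for e in enr]).to_csv(
        RESULTS / "marker_enrichment.tsv", sep="\t", index=False,
        float_format="%.6g", lineterminator="\n")
    top = enr[0]
    print(f"top enriched set: {top.set_name} "
          f"(overlap {top.overlap}/{top.set_size}, adj. p={top.adjusted_p:.2e})")


if __name__ == "__main__":
    main()
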