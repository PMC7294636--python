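"""Four-criterion marker-like gene discovery, correlation partition and
gene-set enrichment.

A gene is "marker-like" when it mirrors the reference marker's joint
expression/methylation pattern across diagnosis groups:

1. higher methylation of at least one promoter CpG probe in glioma
   (LGG and GBM pooled) than in normal samples;
2. higher promoter methylation in LGG than in GBM;
3. higher expression in LGG than in GBM;
4. lower expression in glioma (pooled) than in normal samples.

"Higher"/"lower" is operationalized as a one-sided rank-sum test in the
stated direction at p < alpha (default 0.05).  Criteria 1 and 2 scan all
annotated promoter probes and pass if any probe passes; the probe with the
smallest criterion-1 p-value ("best probe") anchors the downstream
methylation-expression correlation.  Genes passing all four criteria are
partitioned by the sign of the Spearman correlation between expression and
best-probe beta across tumor samples: negative / positive when p < alpha
with that sign, else uncorrelated — the explicit third category for genes
in neither signed group.

Enrichment of a gene group against user-supplied gene sets is a one-sided
hypergeometric over-representation test with Benjamini-Hochberg adjustment
across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from omniscreen.group_stats import wilcoxon_compare
from omniscreen.io import GeneSetCollection
from omniscreen.synthetic import CohortBundle

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class CriterionOutcome:
    passed: bool
    p_value: float | None = None
    probe_id: str | None = None
    reason: str | None = None


@dataclass
class MarkerLikeRecord:
    gene_id: str
    crit1_promoter_meth_up_in_glioma: CriterionOutcome
    crit2_meth_higher_lgg_vs_gbm: CriterionOutcome
    crit3_expr_higher_lgg_vs_gbm: CriterionOutcome
    crit4_expr_lower_in_glioma: CriterionOutcome
    passes_all: bool = field(init=False)

    def __post_init__(self):
        self.passes_all = all(c.passed for c in self.criteria())

    def criteria(self):
        return (self.crit1_promoter_meth_up_in_glioma,
                self.crit2_meth_higher_lgg_vs_gbm,
                self.crit3_expr_higher_lgg_vs_gbm,
                self.crit4_expr_lower_in_glioma)


@dataclass(frozen=True)
class CorrelationPartition:
    gene_id: str
    rho: float | None
    p_value: float | None
    group: str  # negative | positive | uncorrelated
    probe_id: str | None = None
    n: int = 0
    reason: str | None = None


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float


def _one_sided_meth_test(beta_row: pd.Series, high_samples, low_samples):
    """One-sided rank-sum on a probe's beta values, alternative: high > low.
    Missing betas drop per group."""
    x = beta_row.reindex(high_samples).to_numpy(dtype=float)
    y = beta_row.reindex(low_samples).to_numpy(dtype=float)
    if np.isnan(x).all() or np.isnan(y).all():
        return None
    res = wilcoxon_compare(x, y, alternative="a_greater")
    return res.p_value


def evaluate_criteria(gene_id: str, bundle: CohortBundle,
                      alpha: float = DEFAULT_ALPHA) -> MarkerLikeRecord:
    """Evaluate the four marker-like criteria for one gene.

    Criteria 1 and 2 require at least one annotated promoter probe; without
    one they fail with reason ``no_promoter_probe``.  With ``alpha=1.0``
    every test passes on p, leaving only the directional content of the
    one-sided p-values themselves.
    """
    clin = bundle.clinical
    normal = clin.samples_with(diagnosis="normal")
    lgg = clin.samples_with(diagnosis="LGG")
    gbm = clin.samples_with(diagnosis="GBM")
    glioma = lgg + gbm

    promoter_probes = bundle.methylation.probes_for_gene(gene_id, promoter_only=True)
    if not promoter_probes:
        c1 = CriterionOutcome(False, reason="no_promoter_probe")
        c2 = CriterionOutcome(False, reason="no_promoter_probe")
    else:
        beta = bundle.methylation.beta
        c1 = _best_probe_outcome(
            {p: _one_sided_meth_test(beta.loc[p], glioma, normal)
             for p in promoter_probes}, alpha)
        c2 = _best_probe_outcome(
            {p: _one_sided_meth_test(beta.loc[p], lgg, gbm)
             for p in promoter_probes}, alpha)

    expr = bundle.expression.values.loc[gene_id]
    r3 = wilcoxon_compare(expr.reindex(lgg), expr.reindex(gbm), alternative="a_greater")
    r4 = wilcoxon_compare(expr.reindex(glioma), expr.reindex(normal), alternative="a_less")
    c3 = CriterionOutcome(r3.p_value < alpha, p_value=r3.p_value)
    c4 = CriterionOutcome(r4.p_value < alpha, p_value=r4.p_value)
    return MarkerLikeRecord(gene_id, c1, c2, c3, c4)


def _best_probe_outcome(p_by_probe: dict, alpha: float) -> CriterionOutcome:
    valid = {p: pv for p, pv in p_by_probe.items() if pv is not None}
    if not valid:
        return CriterionOutcome(False, reason="no_informative_probe")
    best = min(valid, key=valid.get)
    return CriterionOutcome(valid[best] < alpha, p_value=valid[best], probe_id=best)


def screen_marker_like(bundle: CohortBundle,
                       alpha: float = DEFAULT_ALPHA) -> list[MarkerLikeRecord]:
    """Run :func:`evaluate_criteria` over every gene in the bundle.

    Returns the full audit list (one record per gene) with passing genes
    first, then by gene id; non-passing genes retain their per-criterion
    p-values or failure reasons.
    """
    records = [evaluate_criteria(g, bundle, alpha=alpha)
               for g in bundle.expression.gene_ids]
    records.sort(key=lambda r: (not r.passes_all, r.gene_id))
    n_pass = sum(r.passes_all for r in records)
    logger.info("marker screen: %d of %d genes pass all four criteria",
                n_pass, len(records))
    return records


def audit_table(records: list[MarkerLikeRecord]) -> pd.DataFrame:
    """Flat audit table: one row per screened gene with the four criterion
    flags, p-values and failure reasons."""
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "passes_all": r.passes_all}
        for name, c in zip(("crit1", "crit2", "crit3", "crit4"), r.criteria()):
            row[f"{name}_pass"] = c.passed
            row[f"{name}_p"] = c.p_value
            if name in ("crit1", "crit2"):
                row[f"{name}_probe"] = c.probe_id
            row[f"{name}_reason"] = c.reason
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def partition_by_correlation(records: list[MarkerLikeRecord], bundle: CohortBundle,
                             alpha: float = DEFAULT_ALPHA) -> list[CorrelationPartition]:
    """Partition marker-like genes by the sign of the Spearman correlation
    between expression and best-promoter-probe beta across tumor samples.

    Only genes with ``passes_all`` are partitioned.  Pairs with a missing
    beta are excluded; fewer than 3 pairs (or a constant margin) yields
    ``uncorrelated`` with a reason.
    """
    tumors = bundle.clinical.samples_with(diagnosis=("LGG", "GBM"))
    out = []
    for r in records:
        if not r.passes_all:
            continue
        probe = r.crit1_promoter_meth_up_in_glioma.probe_id
        beta = bundle.methylation.beta.loc[probe].reindex(tumors).to_numpy(dtype=float)
        expr = bundle.expression.values.loc[r.gene_id].reindex(tumors).to_numpy(dtype=float)
        ok = ~np.isnan(beta) & ~np.isnan(expr)
        if ok.sum() < 3:
            out.append(CorrelationPartition(r.gene_id, None, None, "uncorrelated",
                                            probe_id=probe, n=int(ok.sum()),
                                            reason="fewer_than_3_pairs"))
            continue
        rho, p = stats.spearmanr(expr[ok], beta[ok])
        if np.isnan(rho):
            out.append(CorrelationPartition(r.gene_id, None, None, "uncorrelated",
                                            probe_id=probe, n=int(ok.sum()),
                                            reason="constant_values"))
            continue
        if p < alpha and rho < 0:
            group = "negative"
        elif p < alpha and rho > 0:
            group = "positive"
        else:
            group = "uncorrelated"
        out.append(CorrelationPartition(r.gene_id, float(rho), float(p), group,
                                        probe_id=probe, n=int(ok.sum())))
    counts = pd.Series([o.group for o in out]).value_counts().to_dict()
    logger.info("correlation partition: %s", counts)
    return out


def enrich(gene_group, collection: GeneSetCollection,
           universe=None) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation of ``gene_group`` in
    each gene set, BH-adjusted across sets and sorted by adjusted p.

    The universe defaults to the collection's own universe; set members
    outside the universe are ignored, but a query gene outside the universe
    is an error.
    """
    query = list(dict.fromkeys(gene_group))
    if universe is None:
        universe = collection.universe
    if universe is None:
        raise ValueError("a universe is required (argument or collection.universe)")
    uni = set(universe)
    offenders = [g for g in query if g not in uni]
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders}")
    n_uni, n_query = len(uni), len(query)
    qset = set(query)
    names, pvals, rows = [], [], []
    for name, members in collection.sets.items():
        in_uni = [m for m in members if m in uni]
        k = len(qset.intersection(in_uni))
        # P(X >= k) for X ~ Hypergeom(N=n_uni, K=len(in_uni), n=n_query)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(in_uni), n_query))
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, k, len(in_uni)))
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    out = [EnrichmentRecord(set_name=name, overlap=k, set_size=sz,
                            query_size=n_query, universe_size=n_uni,
                            p_value=p, adjusted_p=float(ap))
           for (name, k, sz), p, ap in zip(rows, pvals, adjusted)]
    out.sort(key=lambda r: (r.adjusted_p, r.p_value, r.set_name))
    return out
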