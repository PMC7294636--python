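"""Cross-omics association profiling for a single marker gene.

Spearman rank correlations (average ranks on ties) between a gene's
expression and (a) its copy-number value, overall and within CNV-status
strata, and (b) promoter CpG beta values probe by probe.  Stratified and
pooled analyses apply the same pair-exclusion rule: a sample contributes
iff both members of the pair are present and non-missing.

The CNV axis is the numeric segment mean when available; otherwise the
ordinal coding loss=-1, neutral=0, gain=+1 keeps the operation total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from omniscreen.io import CnvTable, ExpressionMatrix, MethylationMatrix, ClinicalTable

_ORDINAL_STATUS = {"loss": -1.0, "neutral": 0.0, "gain": 1.0}
MIN_PAIRS = 3


@dataclass(frozen=True)
class AssociationResult:
    gene_id: str
    partner: str  # "cnv" or a probe id
    stratum: str  # loss | gain | all | none
    rho: float | None
    p_value: float | None
    n: int
    reason: str | None = None


def _spearman(x: np.ndarray, y: np.ndarray, gene: str, partner: str,
              stratum: str) -> AssociationResult:
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < MIN_PAIRS:
        return AssociationResult(gene, partner, stratum, None, None, n,
                                 reason="fewer_than_3_pairs")
    rho, p = stats.spearmanr(x[ok], y[ok])
    if np.isnan(rho):
        return AssociationResult(gene, partner, stratum, None, None, n,
                                 reason="constant_values")
    return AssociationResult(gene, partner, stratum, float(rho), float(p), n)


def expr_cnv_association(gene_id: str, expression: ExpressionMatrix, cnv: CnvTable,
                         strata=("loss", "gain", "all")) -> list[AssociationResult]:
    """Spearman correlation between a gene's expression and its CNV value,
    within each requested status stratum plus optionally pooled ("all")."""
    allowed = {"loss", "gain", "neutral", "all"}
    bad = set(strata) - allowed
    if bad:
        raise ValueError(f"unknown strata: {sorted(bad)}")
    records = cnv.for_gene(gene_id)
    if records.empty:
        raise ValueError(f"no CNV records for gene {gene_id!r}")
    expr = expression.values.loc[gene_id]
    common = records.index.intersection(expr.index)
    records = records.loc[common]
    if "value" in records.columns and records["value"].notna().any():
        cnv_axis = records["value"].astype(float)
    else:
        cnv_axis = records["status"].map(_ORDINAL_STATUS).astype(float)
    out = []
    for stratum in strata:
        mask = (pd.Series(True, index=records.index) if stratum == "all"
                else records["status"] == stratum)
        out.append(_spearman(
            expr.reindex(records.index[mask]).to_numpy(dtype=float),
            cnv_axis[mask].to_numpy(dtype=float),
            gene_id, "cnv", stratum,
        ))
    return out


def expr_meth_association(gene_id: str, expression: ExpressionMatrix,
                          methylation: MethylationMatrix, probe_ids=None,
                          clinical: ClinicalTable | None = None,
                          tumor_only: bool = False) -> list[AssociationResult]:
    """Spearman correlation between a gene's expression and each listed
    promoter probe's beta values on paired samples.

    ``probe_ids`` defaults to the gene's annotated promoter probes; every
    requested probe must be annotated to the gene.  With ``tumor_only`` a
    clinical table is required and only LGG/GBM samples contribute.
    """
    annotated = set(methylation.probes_for_gene(gene_id))
    if probe_ids is None:
        probe_ids = methylation.probes_for_gene(gene_id, promoter_only=True)
    for p in probe_ids:
        if p not in annotated:
            raise ValueError(f"probe {p!r} is not annotated to gene {gene_id!r}")
    expr = expression.values.loc[gene_id]
    samples = methylation.beta.columns.intersection(expr.index)
    if tumor_only:
        if clinical is None:
            raise ValueError("tumor_only requires a clinical table")
        tumors = clinical.samples_with(diagnosis=("LGG", "GBM"))
        samples = samples.intersection(tumors)
    out = []
    for probe in probe_ids:
        out.append(_spearman(
            expr.reindex(samples).to_numpy(dtype=float),
            methylation.beta.loc[probe].reindex(samples).to_numpy(dtype=float),
            gene_id, probe, "none",
        ))
    return out
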