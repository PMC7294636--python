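"""Brain-specific, fluid-detectable candidate prioritization.

The screen proceeds in four steps: (1) average expression over sampling
sites belonging to the same tissue; (2) drop genes whose maximal tissue
mean falls below a detectability floor (default 10 TPM, strictly-smaller
removal); (3) score each remaining gene with the tissue-specificity index

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

over n >= 2 tissues, where x_i is the gene's mean expression in tissue i —
tau is 0 for a uniformly expressed housekeeping gene and 1 for a gene
expressed in exactly one tissue; (4) keep genes whose maximal tissue is the
target tissue and whose tau strictly exceeds a cutoff (default 0.9), rank
by tau and truncate to the top n (default 100).  Candidates are finally
intersected with a fluid-detectable proteome and ordered by fluorescence
intensity, high to low.

tau is computed on the linear expression scale with no log transform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from omniscreen.io import ExpressionMatrix, FluidProteomeTable

logger = logging.getLogger(__name__)


def aggregate_sites(expr: ExpressionMatrix, site_to_tissue: dict[str, str]) -> pd.DataFrame:
    """Average expression over sampling sites from the same tissue.

    Parameters
    ----------
    expr
        Gene x site expression matrix (columns are individual sampling sites).
    site_to_tissue
        Mapping of every site (sample) id to its tissue label.

    Returns
    -------
    Gene x tissue DataFrame of per-tissue arithmetic means.  Tissue column
    order follows first appearance in the input site order.
    """
    unmapped = [s for s in expr.sample_ids if s not in site_to_tissue]
    if unmapped:
        raise ValueError(f"sites with no tissue mapping: {unmapped}")
    tissues = pd.Index([site_to_tissue[s] for s in expr.sample_ids], name="tissue")
    # groupby(sort=False) keeps first-appearance tissue order
    profile = expr.values.T.groupby(tissues, sort=False).mean().T
    logger.info("aggregated %d sites into %d tissues", len(expr.sample_ids),
                profile.shape[1])
    return profile


def filter_detectable(profiles: pd.DataFrame, min_max_tpm: float = 10.0) -> pd.DataFrame:
    """Remove genes whose maximal tissue mean is strictly smaller than
    ``min_max_tpm`` (a gene at exactly the threshold is retained)."""
    if min_max_tpm < 0:
        raise ValueError("min_max_tpm must be >= 0")
    keep = profiles.max(axis=1) >= min_max_tpm
    n_removed = int((~keep).sum())
    logger.info("detectability filter at %g: removed %d of %d genes",
                min_max_tpm, n_removed, len(profiles))
    return profiles.loc[keep]


def compute_tau(profiles: pd.DataFrame) -> pd.DataFrame:
    """Tissue-specificity index tau per gene.

    Each row of ``profiles`` is a gene's tissue-mean vector.  Requires at
    least two tissues, and every gene must have a positive maximum (an
    all-zero profile leaves the normalized expression undefined).

    Returns a DataFrame indexed by gene with columns ``tau`` (in [0, 1]),
    ``argmax_tissue`` (ties broken by first tissue in column order) and
    ``max_expression``.
    """
    n = profiles.shape[1]
    if n < 2:
        raise ValueError("tau requires at least 2 tissues")
    x = profiles.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression in tissue profile")
    xmax = x.max(axis=1)
    if (xmax <= 0).any():
        bad = profiles.index[xmax <= 0].tolist()
        raise ValueError(f"all-zero profile(s), tau undefined: {bad}")
    xhat = x / xmax[:, None]
    tau = (1.0 - xhat).sum(axis=1) / (n - 1)
    argmax = profiles.columns[np.argmax(x, axis=1)]  # first max on ties
    return pd.DataFrame(
        {"tau": tau, "argmax_tissue": argmax, "max_expression": xmax},
        index=profiles.index,
    )


def select_tissue_specific(scores: pd.DataFrame, target_tissue: str,
                           tau_min: float = 0.9, top_n: int = 100) -> pd.DataFrame:
    """Genes maximally expressed in ``target_tissue`` with tau strictly
    greater than ``tau_min``, sorted by tau descending and truncated to
    ``top_n``.  Ties in tau break by max_expression descending, then gene id.
    """
    if not 0 <= tau_min <= 1:
        raise ValueError("tau_min must be in [0, 1]")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    hits = scores[(scores["argmax_tissue"] == target_tissue) & (scores["tau"] > tau_min)]
    hits = hits.assign(_gene=hits.index)
    hits = hits.sort_values(
        by=["tau", "max_expression", "_gene"], ascending=[False, False, True]
    ).drop(columns="_gene")
    logger.info("%d gene(s) specific to %r at tau > %g; keeping top %d",
                len(hits), target_tissue, tau_min, top_n)
    return hits.head(top_n)


def rank_fluid_candidates(specific_genes, fluid: FluidProteomeTable) -> pd.DataFrame:
    """Intersect a tissue-specific gene list with the fluid-detectable
    proteome; rank by fluorescence intensity from high to low.

    Returns a DataFrame with columns ``gene_id`` and ``fluorescence``; ties
    in intensity break by gene id for a deterministic order.
    """
    specific = list(specific_genes)
    inter = [g for g in specific if g in fluid.table.index]
    if not inter:
        logger.warning("no overlap between specific genes and the fluid proteome")
        return pd.DataFrame(columns=["gene_id", "fluorescence"])
    out = pd.DataFrame(
        {"gene_id": inter,
         "fluorescence": fluid.table.loc[inter, "fluorescence"].to_numpy()}
    ).sort_values(by=["fluorescence", "gene_id"], ascending=[False, True],
                  ignore_index=True)
    logger.info("%d of %d specific genes detectable in fluid", len(out), len(specific))
    return out
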