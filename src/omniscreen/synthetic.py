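"""Seeded synthetic cohorts with ground truth for every pipeline stage.

The generators emulate the *statistical structure* the analysis assumes —
ordering of group means, correlation signs, hazard ratios — not the
marginal distributions of any real cohort:

* a multi-tissue expression panel with planted tissue-specific genes
  (``simulate_tissue_panel``);
* a tumor/normal glioma cohort with planted "marker-like" genes whose
  promoter methylation rises from normal to glioma and from GBM to LGG
  while expression falls from normal to LGG to GBM, with a planted sign of
  the within-tumor methylation-expression correlation
  (``simulate_glioma_cohort``);
* a fluid-detectable proteome subset (``simulate_fluid_proteome``);
* exponential survival draws and a four-stratum two-marker methylation
  cohort (``simulate_survival``, ``simulate_two_marker_cohort``);
* a copy-number/expression construction exhibiting a Simpson-type reversal
  between within-stratum and pooled correlations (``simulate_simpson_cnv``).

Noise models: expression uses log-normal multiplicative noise around group
means (values stay positive); beta values are drawn from a Beta
distribution with group-specific mean m and common precision nu
(shape parameters m*nu, (1-m)*nu), keeping values in [0, 1].  The
methylation-expression coupling is a Gaussian copula: the latent normals
behind a gene's expression and its planted promoter probe share a
correlation whose sign is the gene's truth label.  All draws flow from a
single ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from omniscreen.io import (
    ClinicalTable,
    CnvTable,
    ExpressionMatrix,
    FluidProteomeTable,
    MethylationMatrix,
)

# -- default generator conditions -------------------------------------------

DEFAULT_EFFECTS = {
    # expression: log2 fold changes applied multiplicatively to group means
    "expr_normal_mean": 100.0,      # TPM, marker-like genes in normal tissue
    "expr_null_mean": 50.0,         # TPM, null genes everywhere
    "expr_log2fc_lgg_vs_normal": -1.5,
    "expr_log2fc_gbm_vs_lgg": -0.75,
    "expr_sigma": 0.5,              # sd of log-scale noise
    # methylation: planted promoter-probe beta means per group
    "beta_normal": 0.20,
    "beta_gbm": 0.45,
    "beta_lgg": 0.52,
    "beta_null": 0.30,              # unplanted probes, all groups
    "beta_precision": 50.0,         # Beta-distribution precision nu
    # latent-normal correlation magnitude for planted coupling signs
    "coupling_rho": 0.75,
}

DEFAULT_HAZARDS = {"LGG": 0.02, "GBM": 0.08}  # events per month

CNV_STATUS_PROBS = {"loss": 0.2, "neutral": 0.6, "gain": 0.2}
CNV_VALUE_PARAMS = {"loss": (-0.5, 0.1), "neutral": (0.0, 0.05), "gain": (0.5, 0.1)}


@dataclass
class TissuePanelTruth:
    specific_genes: dict[str, str]  # gene_id -> tissue
    background_genes: list[str]


@dataclass
class CohortTruth:
    marker_like_genes: list[str]
    correlation_sign: dict[str, str]  # gene_id -> negative | positive | none
    group_hazards: dict[str, float]
    planted_effect_sizes: dict[str, dict]
    planted_probe: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortBundle:
    expression: ExpressionMatrix
    methylation: MethylationMatrix
    cnv: CnvTable
    clinical: ClinicalTable
    truth: CohortTruth


# -- tissue panel -----------------------------------------------------------

def planted_tissue_mean(base_mean: float, specificity_fold: float) -> float:
    """Mean expression of a planted gene in its target tissue (before noise)."""
    return specificity_fold * base_mean


def simulate_tissue_panel(n_genes: int, n_tissues: int, n_specific: int,
                          target_tissue: str = "brain",
                          base_mean: float = 20.0, noise_sigma: float = 0.5,
                          specificity_fold: float = 50.0,
                          sites_per_tissue: int = 1,
                          seed: int = 0) -> tuple[ExpressionMatrix, TissuePanelTruth]:
    """Multi-tissue expression panel with ``n_specific`` genes planted as
    specific to ``target_tissue``.

    Background genes draw i.i.d. log-normal expression with mean
    ``base_mean`` in every tissue site; planted genes have mean
    ``specificity_fold * base_mean`` in the target tissue and ``base_mean``
    elsewhere.  Tissues contribute ``sites_per_tissue`` sampling sites each
    (site ids ``<tissue>.s<k>``), so site-to-tissue aggregation is
    exercised whenever ``sites_per_tissue > 1``.
    """
    if n_specific >= n_genes:
        raise ValueError("n_specific must be < n_genes")
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    if specificity_fold <= 1:
        raise ValueError("specificity_fold must be > 1")
    if base_mean <= 0 or noise_sigma < 0:
        raise ValueError("degenerate base distribution parameters")
    rng = np.random.default_rng(seed)

    tissues = [target_tissue] + [f"tissue{i:02d}" for i in range(1, n_tissues)]
    sites = [f"{t}.s{k}" for t in tissues for k in range(sites_per_tissue)]
    site_tissue = {s: s.rsplit(".s", 1)[0] for s in sites}
    genes = [f"g{i:04d}" for i in range(n_genes)]
    specific = genes[:n_specific]

    mean = np.full((n_genes, len(sites)), base_mean)
    target_cols = [i for i, s in enumerate(sites) if site_tissue[s] == target_tissue]
    mean[:n_specific, target_cols] = planted_tissue_mean(base_mean, specificity_fold)
    # log-normal noise with E[value] = mean
    noise = rng.normal(0.0, noise_sigma, size=mean.shape) if noise_sigma > 0 else 0.0
    values = mean * np.exp(noise - noise_sigma**2 / 2)

    expr = ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=sites),
                            unit="TPM")
    truth = TissuePanelTruth(
        specific_genes={g: target_tissue for g in specific},
        background_genes=genes[n_specific:],
    )
    return expr, truth, site_tissue


# -- glioma cohort ----------------------------------------------------------

def _beta_shapes(mean: float, precision: float) -> tuple[float, float]:
    return mean * precision, (1.0 - mean) * precision


def _validate_effects(eff: dict) -> None:
    """The planted shifts must satisfy all four marker-screen criteria."""
    problems = []
    if not eff["expr_log2fc_lgg_vs_normal"] < 0:
        problems.append("expression must be lower in LGG than normal")
    if not eff["expr_log2fc_gbm_vs_lgg"] < 0:
        problems.append("expression must be lower in GBM than LGG")
    if not eff["beta_lgg"] > eff["beta_gbm"]:
        problems.append("promoter beta must be higher in LGG than GBM")
    if not min(eff["beta_lgg"], eff["beta_gbm"]) > eff["beta_normal"]:
        problems.append("promoter beta must be higher in glioma than normal")
    for key in ("beta_normal", "beta_gbm", "beta_lgg", "beta_null"):
        if not 0 < eff[key] < 1:
            problems.append(f"{key} outside (0,1)")
    if problems:
        raise ValueError("inconsistent effect sizes: " + "; ".join(problems))


def _beta_from_latent(z: np.ndarray, mean, precision) -> np.ndarray:
    """Quantile-transform standard-normal latents to Beta(mean, precision).

    With infinite precision (noise-free mode) the value is the mean itself.
    """
    if not np.isfinite(precision):
        return np.broadcast_to(np.asarray(mean, dtype=float), z.shape).copy()
    a, b = _beta_shapes(np.asarray(mean, dtype=float), precision)
    return stats.beta.ppf(stats.norm.cdf(z), a, b)


def simulate_glioma_cohort(n_normal: int = 30, n_lgg: int = 40, n_gbm: int = 40,
                           n_genes: int = 200, n_marker_like: int = 20,
                           n_negative_corr: int = 8, n_positive_corr: int = 8,
                           effect_sizes: dict | None = None,
                           hazards_by_stratum: dict | None = None,
                           censor_rate: float = 0.2, t_max: float = 60.0,
                           seed: int = 0) -> CohortBundle:
    """Tumor/normal glioma cohort with planted marker-like genes.

    The first ``n_marker_like`` genes receive the planted shifts: expression
    ordered normal > LGG > GBM and promoter beta (on the gene's first
    promoter probe) ordered LGG > GBM > normal.  Of these, the first
    ``n_negative_corr`` carry a negative within-tumor methylation-expression
    coupling, the next ``n_positive_corr`` a positive one, the rest none.
    Every gene gets two promoter probes and one non-promoter probe; only the
    first promoter probe carries planted shifts and coupling, exercising the
    at-least-one-promoter-probe rule.  Remaining genes are null: identical
    distributions in every group.

    Survival: LGG/GBM samples draw exponential event times with the
    per-diagnosis hazards; with probability ``censor_rate`` a subject gets
    an independent uniform(0, t_max) administrative censoring time.  Normal
    samples carry no survival data.
    """
    eff = dict(DEFAULT_EFFECTS, **(effect_sizes or {}))
    hazards = dict(hazards_by_stratum or DEFAULT_HAZARDS)
    if n_negative_corr + n_positive_corr > n_marker_like:
        raise ValueError("n_negative_corr + n_positive_corr must be <= n_marker_like")
    if n_marker_like > n_genes:
        raise ValueError("n_marker_like must be <= n_genes")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0,1)")
    if any(h <= 0 for h in hazards.values()):
        raise ValueError("hazards must be positive")
    _validate_effects(eff)
    rng = np.random.default_rng(seed)

    genes = [f"g{i:04d}" for i in range(n_genes)]
    markers = genes[:n_marker_like]
    sign = {}
    for i, g in enumerate(markers):
        sign[g] = ("negative" if i < n_negative_corr
                   else "positive" if i < n_negative_corr + n_positive_corr
                   else "none")
    for g in genes[n_marker_like:]:
        sign[g] = "none"

    samples = ([f"N{i:03d}" for i in range(n_normal)]
               + [f"L{i:03d}" for i in range(n_lgg)]
               + [f"G{i:03d}" for i in range(n_gbm)])
    diagnosis = np.array(["normal"] * n_normal + ["LGG"] * n_lgg + ["GBM"] * n_gbm)
    n_samples = len(samples)
    is_tumor = diagnosis != "normal"

    # group means per gene x sample
    expr_mean = np.full((n_genes, n_samples), eff["expr_null_mean"])
    beta_mean_planted = np.full((n_genes, n_samples), eff["beta_null"])
    lgg_mult = 2.0 ** eff["expr_log2fc_lgg_vs_normal"]
    gbm_mult = lgg_mult * 2.0 ** eff["expr_log2fc_gbm_vs_lgg"]
    for mult, bmean, mask in (
        (1.0, eff["beta_normal"], diagnosis == "normal"),
        (lgg_mult, eff["beta_lgg"], diagnosis == "LGG"),
        (gbm_mult, eff["beta_gbm"], diagnosis == "GBM"),
    ):
        expr_mean[:n_marker_like, mask] = eff["expr_normal_mean"] * mult
        beta_mean_planted[:n_marker_like, mask] = bmean

    # coupled latent normals per gene x sample (coupling in tumor samples only)
    rho = np.zeros((n_genes, 1))
    rho[:n_marker_like, 0] = [
        {"negative": -eff["coupling_rho"], "positive": eff["coupling_rho"],
         "none": 0.0}[sign[g]] for g in markers
    ]
    z_expr = rng.standard_normal((n_genes, n_samples))
    z_ind = rng.standard_normal((n_genes, n_samples))
    z_beta = np.where(is_tumor[None, :],
                      rho * z_expr + np.sqrt(1.0 - rho**2) * z_ind,
                      z_ind)

    sigma = eff["expr_sigma"]
    expr_values = expr_mean * np.exp(sigma * z_expr - sigma**2 / 2)
    expression = ExpressionMatrix(
        values=pd.DataFrame(expr_values, index=genes, columns=samples), unit="TPM")

    # probes: <gene>.p1 (planted promoter), <gene>.p2 (promoter), <gene>.np (body)
    nu = eff["beta_precision"]
    beta_p1 = _beta_from_latent(z_beta, beta_mean_planted, nu)
    beta_p2 = _beta_from_latent(rng.standard_normal((n_genes, n_samples)),
                                eff["beta_null"], nu)
    beta_np = _beta_from_latent(rng.standard_normal((n_genes, n_samples)),
                                eff["beta_null"], nu)
    probe_ids, rows, ann_rows = [], [], []
    for j, g in enumerate(genes):
        for suffix, mat, promoter in (("p1", beta_p1, True), ("p2", beta_p2, True),
                                      ("np", beta_np, False)):
            probe_ids.append(f"{g}.{suffix}")
            rows.append(mat[j])
            ann_rows.append({"gene_id": g, "is_promoter": promoter})
    methylation = MethylationMatrix(
        beta=pd.DataFrame(np.vstack(rows), index=probe_ids, columns=samples),
        probe_annotation=pd.DataFrame(ann_rows, index=pd.Index(probe_ids, name="probe_id")),
    )

    # CNV: tumor samples draw status per gene; normals are neutral
    statuses = np.array(list(CNV_STATUS_PROBS))
    probs = np.array([CNV_STATUS_PROBS[s] for s in statuses])
    cnv_records = []
    status_idx = rng.choice(len(statuses), size=(n_genes, n_samples), p=probs)
    for j, g in enumerate(genes):
        for k, s in enumerate(samples):
            st = statuses[status_idx[j, k]] if is_tumor[k] else "neutral"
            mu, sd = CNV_VALUE_PARAMS[st]
            cnv_records.append((s, g, st, mu + sd * rng.standard_normal()))
    cnv = CnvTable(table=pd.DataFrame(cnv_records,
                                      columns=["sample_id", "gene_id", "status", "value"]))

    # clinical with exponential survival for tumor samples
    os_months = np.full(n_samples, np.nan)
    os_event = np.full(n_samples, np.nan)
    for dx, hz in hazards.items():
        mask = diagnosis == dx
        n = int(mask.sum())
        if n == 0:
            continue
        t, e = _draw_survival(rng, n, hz, censor_rate, t_max)
        os_months[mask] = t
        os_event[mask] = e
    grade = np.where(diagnosis == "GBM", "IV",
                     np.where(diagnosis == "LGG",
                              rng.choice(["II", "III"], size=n_samples), None))
    clinical = ClinicalTable(table=pd.DataFrame({
        "diagnosis": diagnosis,
        "grade": pd.Series(grade, index=samples).where(diagnosis != "normal"),
        "idh_status": rng.choice(["mut", "WT"], size=n_samples),
        "anatomic_region": pd.Series(
            rng.choice(["LE", "IT", "CT", "PAN", "MVP"], size=n_samples),
            index=samples).where(diagnosis == "GBM"),
        "recurrence": pd.Series(np.where(diagnosis == "normal", None, "primary"),
                                index=samples),
        "os_months": os_months,
        "os_event": os_event,
        "treatment": pd.Series(np.where(diagnosis == "GBM", "TMZ", None), index=samples),
    }, index=pd.Index(samples, name="sample_id")))

    truth = CohortTruth(
        marker_like_genes=list(markers),
        correlation_sign=sign,
        group_hazards=hazards,
        planted_effect_sizes={g: {
            "expr_log2fc_lgg_vs_normal": eff["expr_log2fc_lgg_vs_normal"],
            "expr_log2fc_gbm_vs_lgg": eff["expr_log2fc_gbm_vs_lgg"],
            "beta_shift_glioma_vs_normal": (eff["beta_lgg"] + eff["beta_gbm"]) / 2
                                            - eff["beta_normal"],
            "beta_shift_lgg_vs_gbm": eff["beta_lgg"] - eff["beta_gbm"],
        } for g in markers},
        planted_probe={g: f"{g}.p1" for g in markers},
    )
    return CohortBundle(expression=expression, methylation=methylation,
                        cnv=cnv, clinical=clinical, truth=truth)


# -- fluid proteome ---------------------------------------------------------

def simulate_fluid_proteome(gene_pool, n_detectable: int,
                            intensity_mu: float = 1.0, intensity_sigma: float = 1.0,
                            seed: int = 0) -> FluidProteomeTable:
    """Sample ``n_detectable`` genes from the pool and assign log-normal
    fluorescence intensities (all positive by construction)."""
    pool = list(gene_pool)
    if n_detectable > len(pool):
        raise ValueError("n_detectable exceeds the gene pool size")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_detectable, replace=False)
    intensities = rng.lognormal(intensity_mu, intensity_sigma, size=n_detectable)
    return FluidProteomeTable(table=pd.DataFrame(
        {"fluorescence": intensities}, index=pd.Index(chosen, name="gene_id")))


# -- survival draws ---------------------------------------------------------

def _draw_survival(rng, n, hazard, censor_rate, t_max):
    event_t = rng.exponential(1.0 / hazard, size=n)
    censored = rng.random(n) < censor_rate
    censor_t = np.where(censored, rng.uniform(0.0, t_max, size=n), np.inf)
    t = np.minimum(event_t, censor_t)
    e = (event_t <= censor_t).astype(int)
    return t, e


def simulate_survival(n: int, hazard: float, censor_rate: float = 0.0,
                      t_max: float = 60.0, seed: int = 0):
    """Exponential event times (median ln2/hazard) with independent
    uniform(0, t_max) administrative censoring applied to a ``censor_rate``
    fraction of subjects.  Returns (times, events)."""
    if hazard <= 0:
        raise ValueError("hazard must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    return _draw_survival(rng, n, hazard, censor_rate, t_max)


def simulate_two_marker_cohort(n_per_stratum: int = 60,
                               hazards=(0.12, 0.08, 0.05, 0.03),
                               marker_a: str = "markerA", marker_b: str = "markerB",
                               beta_unmeth: float = 0.15, beta_meth: float = 0.60,
                               beta_precision: float = 50.0,
                               censor_rate: float = 0.1, t_max: float = 60.0,
                               seed: int = 0) -> tuple[MethylationMatrix, ClinicalTable]:
    """Four-stratum GBM-like cohort defined by two markers' methylation.

    Strata follow the fixed order (A unmeth + B unmeth, A unmeth + B meth,
    A meth + B unmeth, A meth + B meth) with one exponential hazard each —
    the default hazards decrease across strata so survival improves from
    the double-unmethylated to the double-methylated group.  Beta values
    are drawn Beta-distributed around 0.15 (unmethylated) or 0.60
    (methylated), both clear of the 0.3 call cutoff.
    """
    if len(hazards) != 4:
        raise ValueError("exactly four stratum hazards required")
    rng = np.random.default_rng(seed)
    patterns = [(0, 0), (0, 1), (1, 0), (1, 1)]
    sample_ids, beta_a, beta_b, os_t, os_e = [], [], [], [], []
    for si, ((ma, mb), hz) in enumerate(zip(patterns, hazards)):
        t, e = _draw_survival(rng, n_per_stratum, hz, censor_rate, t_max)
        for k in range(n_per_stratum):
            sample_ids.append(f"S{si}{k:03d}")
        for meth_flag, store in ((ma, beta_a), (mb, beta_b)):
            mean = beta_meth if meth_flag else beta_unmeth
            store.extend(_beta_from_latent(rng.standard_normal(n_per_stratum),
                                           mean, beta_precision))
        os_t.extend(t)
        os_e.extend(e)
    probes = [f"{marker_a}.p1", f"{marker_b}.p1"]
    meth = MethylationMatrix(
        beta=pd.DataFrame([beta_a, beta_b], index=probes, columns=sample_ids),
        probe_annotation=pd.DataFrame(
            {"gene_id": [marker_a, marker_b], "is_promoter": [True, True]},
            index=pd.Index(probes, name="probe_id")),
    )
    clinical = ClinicalTable(table=pd.DataFrame({
        "diagnosis": "GBM",
        "os_months": os_t,
        "os_event": os_e,
        "treatment": "TMZ",
    }, index=pd.Index(sample_ids, name="sample_id")))
    return meth, clinical


# -- Simpson-type CNV construction ------------------------------------------

def simulate_simpson_cnv(gene_id: str = "g0000", n_per_stratum: int = 100,
                         within_slope: float = 1.0, noise_sd: float = 0.15,
                         confound_shift: float = 2.0,
                         seed: int = 0) -> tuple[pd.Series, CnvTable]:
    """One gene's expression and CNV values where loss and gain strata each
    show a positive expression-CNV coupling, but a stratum-level confound
    (e.g. promoter methylation silencing concentrated in the gain stratum)
    reverses or cancels the pooled correlation.

    Returns (expression values per sample, CnvTable) for the gene.
    """
    rng = np.random.default_rng(seed)
    records, expr = [], {}
    for stratum, mu, shift in (("loss", -0.5, confound_shift), ("gain", 0.5, 0.0)):
        vals = rng.normal(mu, 0.1, size=n_per_stratum)
        log_expr = shift + within_slope * (vals - mu) + rng.normal(0, noise_sd,
                                                                   n_per_stratum)
        for k in range(n_per_stratum):
            sid = f"{stratum[0].upper()}{k:03d}"
            records.append((sid, gene_id, stratum, vals[k]))
            expr[sid] = float(np.exp(log_expr[k]))
    cnv = CnvTable(table=pd.DataFrame(records,
                                      columns=["sample_id", "gene_id", "status", "value"]))
    return pd.Series(expr, name=gene_id), cnv
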