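"""Shared configuration for the numbered analysis scripts.

Every script reads its inputs from ``scratch/data`` (written by
``01_simulate_cohorts.py``; regenerate at will, the seed below fixes the
whole analysis) and writes its result tables under ``results/``.
"""

from pathlib import Path

SEED = 11

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

# study conditions: cohort and panel sizes used throughout the analysis
PANEL = dict(n_genes=300, n_tissues=30, n_specific=10, sites_per_tissue=2,
             specificity_fold=50.0)
FLUID = dict(n_detectable=60)
COHORT = dict(n_normal=30, n_lgg=40, n_gbm=40, n_genes=200, n_marker_like=20,
              n_negative_corr=8, n_positive_corr=8)
TWO_MARKER = dict(n_per_stratum=60, hazards=(0.12, 0.08, 0.05, 0.03))

THRESHOLDS = dict(min_max_tpm=10.0, tau_min=0.9, top_n=100, beta_cutoff=0.3,
                  alpha=0.05, t_eval_months=20.0)
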