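"""End-to-end orchestration from a single YAML config.

A run either simulates its inputs (seeded) or loads them from files, then
executes every stage in order: tissue-specificity candidate screen, fluid
intersection, diagnosis-group expression/methylation comparisons for the
profiled gene, survival stratification (expression split within the cohort
and the four-stratum two-marker methylation signature), the four-criterion
marker-like screen with correlation partition and enrichment, and
expression-CNV/methylation association profiling.  Each stage writes a TSV
under the output directory with fixed float formatting, and the run ends
with a machine-readable manifest (package version, seed, thresholds,
sha256 of every written file) sufficient to reproduce the run: identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import omniscreen
from omniscreen import io as oio
from omniscreen import screen as cs
from omniscreen import group_stats as gs
from omniscreen import survival as sv
from omniscreen import marker_screen as ms
from omniscreen import assoc as asc
from omniscreen import synthetic as syn

logger = logging.getLogger(__name__)

_FMT = "%.12g"


class ConfigError(ValueError):
    pass


DEFAULT_THRESHOLDS = {
    "min_max_tpm": 10.0,
    "tau_min": 0.9,
    "top_n": 100,
    "beta_cutoff": 0.3,
    "alpha": 0.05,
    "survival_scheme": "median",
    "t_eval_months": 20.0,
}

DEFAULT_SIMULATE = {
    "tissue_panel": {"n_genes": 300, "n_tissues": 30, "n_specific": 10,
                     "sites_per_tissue": 2, "specificity_fold": 50.0},
    "fluid": {"n_detectable": 60},
    "cohort": {"n_normal": 30, "n_lgg": 40, "n_gbm": 40, "n_genes": 200,
               "n_marker_like": 20, "n_negative_corr": 8, "n_positive_corr": 8},
    "two_marker": {"n_per_stratum": 60, "hazards": [0.12, 0.08, 0.05, 0.03]},
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    target_tissue: str = "brain"
    thresholds: dict = dataclasses.field(default_factory=dict)
    simulate: dict | None = None
    inputs: dict | None = None

    def __post_init__(self):
        self.thresholds = dict(DEFAULT_THRESHOLDS, **(self.thresholds or {}))
        t = self.thresholds
        checks = [
            (0 <= t["tau_min"] <= 1, "tau_min must be in [0,1]"),
            (0 <= t["beta_cutoff"] <= 1, "beta_cutoff must be in [0,1]"),
            (0 < t["alpha"] <= 1, "alpha must be in (0,1]"),
            (t["min_max_tpm"] >= 0, "min_max_tpm must be >= 0"),
            (int(t["top_n"]) >= 1, "top_n must be >= 1"),
            (t["t_eval_months"] >= 0, "t_eval_months must be >= 0"),
            (t["survival_scheme"] in ("median", "tertile"),
             "survival_scheme must be median or tertile"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config must provide either 'simulate' or 'inputs'")
        if self.simulate is not None and self.seed is None:
            raise ConfigError("seed is mandatory when simulating")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw or "output_dir" not in raw:
            raise ConfigError("config requires 'seed' and 'output_dir'")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index=False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=_FMT, na_rep="NA", lineterminator="\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest = {
        "package": "omniscreen",
        "version": omniscreen.__version__,
        "seed": config.seed,
        "thresholds": thr,
        "target_tissue": config.target_tissue,
        "stages": {},
        "files": {},
    }

    # deterministic per-stage seeds drawn in fixed order
    seed_rng = np.random.default_rng(config.seed)
    stage_seed = {name: int(seed_rng.integers(2**31))
                  for name in ("panel", "fluid", "cohort", "two_marker", "gene_sets")}

    # ---- inputs: simulate or load ----------------------------------------
    if config.simulate is not None:
        sim = {k: dict(DEFAULT_SIMULATE[k], **(config.simulate.get(k) or {}))
               for k in DEFAULT_SIMULATE}
        panel, panel_truth, site_map = syn.simulate_tissue_panel(
            **sim["tissue_panel"], target_tissue=config.target_tissue,
            seed=stage_seed["panel"])
        fluid = syn.simulate_fluid_proteome(panel.gene_ids,
                                            sim["fluid"]["n_detectable"],
                                            seed=stage_seed["fluid"])
        bundle = syn.simulate_glioma_cohort(**sim["cohort"], seed=stage_seed["cohort"])
        tm_meth, tm_clin = syn.simulate_two_marker_cohort(
            n_per_stratum=sim["two_marker"]["n_per_stratum"],
            hazards=tuple(sim["two_marker"]["hazards"]), seed=stage_seed["two_marker"])
        manifest["stages"]["simulate"] = {
            "panel_genes": len(panel.gene_ids),
            "panel_sites": len(panel.sample_ids),
            "fluid_proteins": len(fluid.gene_ids),
            "cohort_samples": len(bundle.clinical.sample_ids),
            "cohort_genes": len(bundle.expression.gene_ids),
        }
    else:
        inp = config.inputs
        panel = oio.read_expression_matrix(inp["expression_panel"])
        site_df = pd.read_csv(inp["site_map"], sep="\t")
        site_map = dict(zip(site_df["site_id"].astype(str), site_df["tissue"].astype(str)))
        fluid = oio.read_fluid_proteome(inp["fluid_proteome"])
        bundle = syn.CohortBundle(
            expression=oio.read_expression_matrix(inp["cohort_expression"]),
            methylation=oio.read_methylation_matrix(inp["cohort_methylation"],
                                                    inp["probe_annotation"]),
            cnv=oio.read_cnv_table(inp["cohort_cnv"]),
            clinical=oio.read_clinical_table(inp["cohort_clinical"]),
            truth=None,
        )
        tm_meth, tm_clin = bundle.methylation, bundle.clinical
        panel_truth = None

    # ---- candidate screen -------------------------------------------------
    profiles = cs.aggregate_sites(panel, site_map)
    profiles = cs.filter_detectable(profiles, thr["min_max_tpm"])
    scores = cs.compute_tau(profiles)
    specific = cs.select_tissue_specific(scores, config.target_tissue,
                                         tau_min=thr["tau_min"],
                                         top_n=int(thr["top_n"]))
    ranking = cs.rank_fluid_candidates(specific.index, fluid)
    cand = ranking.merge(
        specific[["tau", "argmax_tissue", "max_expression"]],
        left_on="gene_id", right_index=True)
    cand.insert(0, "rank", np.arange(1, len(cand) + 1))
    _write(cand[["rank", "gene_id", "tau", "argmax_tissue", "max_expression",
                 "fluorescence"]], out / "candidates.tsv")
    manifest["stages"]["candidate_screen"] = {
        "genes_after_detectability": len(profiles),
        "tissue_specific": len(specific),
        "fluid_detectable": len(cand),
    }

    # profiled gene: top fluid candidate present in the cohort, else the
    # first cohort gene
    cohort_genes = set(bundle.expression.gene_ids)
    profiled = next((g for g in cand["gene_id"] if g in cohort_genes),
                    bundle.expression.gene_ids[0])
    manifest["stages"]["profiled_gene"] = profiled

    # ---- diagnosis-group comparisons --------------------------------------
    expr_vals = bundle.expression.values.loc[profiled].to_dict()
    comp = gs.compare_across_labels(expr_vals, bundle.clinical, "diagnosis")
    comp_df = pd.DataFrame([dataclasses.asdict(c) for c in comp])
    _write(comp_df, out / "comparisons.tsv")
    manifest["stages"]["group_comparisons"] = {"pairs": len(comp)}

    # ---- survival ----------------------------------------------------------
    clin = bundle.clinical.table
    glioma = clin.index[(clin["diagnosis"] != "normal") & clin["os_months"].notna()]
    rows = []
    if len(glioma) >= 4:
        split = sv.split_by_expression(
            bundle.expression.values.loc[profiled, glioma],
            scheme=thr["survival_scheme"])
        lr = sv.logrank_test(clin.loc[glioma, "os_months"],
                             clin.loc[glioma, "os_event"], split.loc[glioma])
        for label in sorted(split.unique()):
            sub = glioma[split.loc[glioma] == label]
            curve = sv.km_curve(clin.loc[sub, "os_months"], clin.loc[sub, "os_event"])
            rows.append({
                "analysis": f"expression_{thr['survival_scheme']}", "stratum": label,
                "n": len(sub), "events": int(clin.loc[sub, "os_event"].sum()),
                f"S_{thr['t_eval_months']:g}m": sv.survival_at(curve, thr["t_eval_months"]),
                "chi_square": lr.chi_square, "df": lr.df, "p_value": lr.p_value,
            })

    tm_genes = sorted({g for g in tm_meth.probe_annotation["gene_id"]})[:2]
    probe_a = tm_meth.probes_for_gene(tm_genes[0], promoter_only=True)[0]
    probe_b = tm_meth.probes_for_gene(tm_genes[1], promoter_only=True)[0]
    calls_a = sv.call_methylation_series(tm_meth.beta.loc[probe_a],
                                         marker=tm_genes[0], cutoff=thr["beta_cutoff"])
    calls_b = sv.call_methylation_series(tm_meth.beta.loc[probe_b],
                                         marker=tm_genes[1], cutoff=thr["beta_cutoff"])
    strata = sv.joint_strata(calls_a, calls_b, name_a=tm_genes[0], name_b=tm_genes[1])
    tm_tab = tm_clin.table.loc[strata.index]
    with_os = tm_tab.index[tm_tab["os_months"].notna()]
    lr4 = sv.logrank_test(tm_tab.loc[with_os, "os_months"],
                          tm_tab.loc[with_os, "os_event"], strata.loc[with_os])
    for label in sv.stratum_labels(tm_genes[0], tm_genes[1]):
        sub = with_os[strata.loc[with_os] == label]
        if len(sub) == 0:
            continue
        curve = sv.km_curve(tm_tab.loc[sub, "os_months"], tm_tab.loc[sub, "os_event"])
        rows.append({
            "analysis": "joint_methylation", "stratum": label,
            "n": len(sub), "events": int(tm_tab.loc[sub, "os_event"].sum()),
            f"S_{thr['t_eval_months']:g}m": sv.survival_at(curve, thr["t_eval_months"]),
            "chi_square": lr4.chi_square, "df": lr4.df, "p_value": lr4.p_value,
        })
    _write(pd.DataFrame(rows), out / "survival_strata.tsv")
    manifest["stages"]["survival"] = {"strata_rows": len(rows)}

    # ---- marker-like screen ------------------------------------------------
    records = ms.screen_marker_like(bundle, alpha=thr["alpha"])
    audit = ms.audit_table(records)
    _write(audit, out / "marker_audit.tsv", index=True, index_label="gene_id")
    passes = [r.gene_id for r in records if r.passes_all]
    _write(pd.DataFrame({"gene_id": passes}), out / "marker_passes.tsv")
    partition = ms.partition_by_correlation(records, bundle, alpha=thr["alpha"])
    part_df = pd.DataFrame([dataclasses.asdict(p) for p in partition])
    _write(part_df, out / "marker_partition.tsv")

    universe = bundle.expression.gene_ids
    collection = _reference_gene_sets(bundle, universe, stage_seed["gene_sets"])
    enr = ms.enrich(passes, collection, universe=universe) if passes else []
    _write(pd.DataFrame([dataclasses.asdict(e) for e in enr]), out / "enrichment.tsv")
    manifest["stages"]["marker_screen"] = {
        "screened": len(records),
        "passing": len(passes),
        "partition": {g: sum(p.group == g for p in partition)
                      for g in ("negative", "positive", "uncorrelated")},
    }

    # ---- associations ------------------------------------------------------
    assoc_rows = []
    try:
        assoc_rows += asc.expr_cnv_association(profiled, bundle.expression, bundle.cnv)
    except ValueError as exc:
        logger.warning("CNV association skipped for %s: %s", profiled, exc)
    assoc_rows += asc.expr_meth_association(profiled, bundle.expression,
                                            bundle.methylation,
                                            clinical=bundle.clinical, tumor_only=True)
    _write(pd.DataFrame([dataclasses.asdict(a) for a in assoc_rows]),
           out / "associations.tsv")
    manifest["stages"]["associations"] = {"rows": len(assoc_rows)}

    # ---- manifest ----------------------------------------------------------
    for f in sorted(out.glob("*.tsv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest


def _reference_gene_sets(bundle, universe, seed) -> oio.GeneSetCollection:
    """Gene sets for the enrichment stage of a simulated run: the planted
    marker-like set (when truth is available) plus seeded random sets."""
    rng = np.random.default_rng(seed)
    sets = {}
    if bundle.truth is not None:
        sets["planted_marker_like"] = list(bundle.truth.marker_like_genes)
    for i in range(4):
        size = int(rng.integers(10, 30))
        sets[f"random_set_{i}"] = list(rng.choice(universe, size=size, replace=False))
    return oio.GeneSetCollection(sets=sets, universe=list(universe))
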