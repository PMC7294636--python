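from math import comb

import numpy as np
import pandas as pd
import pytest

from omniscreen import marker_screen as ms
from omniscreen import synthetic as syn
from omniscreen.io import GeneSetCollection


def hypergeom_tail(k, n_universe, set_size, query_size):
    """Independent upper-tail oracle: direct summation of the
    hypergeometric pmf via binomial coefficients."""
    total = 0
    for i in range(k, min(set_size, query_size) + 1):
        total += comb(set_size, i) * comb(n_universe - set_size, query_size - i)
    return total / comb(n_universe, query_size)


class TestEvaluateCriteria:
    def test_planted_gene_passes_all_four_in_noise_free_cohort(self, noise_free_bundle):
        b = noise_free_bundle
        rec = ms.evaluate_criteria(b.truth.marker_like_genes[0], b)
        assert rec.passes_all
        for c in rec.criteria():
            assert c.passed and c.p_value < 0.05
        # the planted promoter probe is the best probe for criteria 1 and 2
        assert rec.crit1_promoter_meth_up_in_glioma.probe_id == \
            b.truth.planted_probe[b.truth.marker_like_genes[0]]

    def test_null_gene_fails_everything_in_noise_free_cohort(self, noise_free_bundle):
        b = noise_free_bundle
        null_gene = b.expression.gene_ids[-1]
        rec = ms.evaluate_criteria(null_gene, b)
        assert not rec.passes_all
        assert not any(c.passed for c in rec.criteria())

    def test_passes_all_is_the_conjunction(self, glioma_bundle):
        recs = ms.screen_marker_like(glioma_bundle)
        for r in recs:
            assert r.passes_all == all(c.passed for c in r.criteria())
        # at least one gene passing 3 of 4 but not all exists among nulls
        # rarely; assert the invariant held over the full audit instead
        assert len(recs) == len(glioma_bundle.expression.gene_ids)

    def test_gene_without_promoter_probe_fails_with_reason(self, glioma_bundle):
        b = glioma_bundle
        gene = b.expression.gene_ids[0]
        stripped = syn.CohortBundle(
            expression=b.expression,
            methylation=syn.MethylationMatrix(
                beta=b.methylation.beta.loc[[f"{gene}.np"]],
                probe_annotation=b.methylation.probe_annotation.loc[[f"{gene}.np"]]),
            cnv=b.cnv, clinical=b.clinical, truth=b.truth)
        rec = ms.evaluate_criteria(gene, stripped)
        assert not rec.passes_all
        assert rec.crit1_promoter_meth_up_in_glioma.reason == "no_promoter_probe"
        assert rec.crit2_meth_higher_lgg_vs_gbm.reason == "no_promoter_probe"


class TestScreenMarkerLike:
    def test_audit_lists_every_gene_exactly_once(self, glioma_bundle):
        recs = ms.screen_marker_like(glioma_bundle)
        table = ms.audit_table(recs)
        assert sorted(table.index) == sorted(glioma_bundle.expression.gene_ids)
        # every gene carries either a p-value or a reason per criterion
        for col in ("crit1", "crit2", "crit3", "crit4"):
            has_info = table[f"{col}_p"].notna() | table[f"{col}_reason"].notna()
            assert has_info.all()

    def test_recall_and_false_positive_rate_on_default_cohort(self):
        tp = fp = n_marker = n_null = 0
        for seed in range(5):
            b = syn.simulate_glioma_cohort(seed=100 + seed)
            planted = set(b.truth.marker_like_genes)
            passes = {r.gene_id for r in ms.screen_marker_like(b) if r.passes_all}
            tp += len(passes & planted)
            fp += len(passes - planted)
            n_marker += len(planted)
            n_null += len(b.expression.gene_ids) - len(planted)
        assert tp / n_marker >= 0.9
        assert fp / n_null <= 0.05

    def test_alpha_one_reduces_to_directional_content(self, noise_free_bundle):
        recs = ms.screen_marker_like(noise_free_bundle, alpha=1.0)
        # with alpha=1 every computed p passes, so any gene with promoter
        # probes and non-degenerate p-values passes all criteria
        by_gene = {r.gene_id: r for r in recs}
        for g in noise_free_bundle.truth.marker_like_genes:
            assert by_gene[g].passes_all


class TestPartitionByCorrelation:
    def _record(self, bundle, gene):
        return ms.evaluate_criteria(gene, bundle)

    def test_monotone_pairs_recover_signs(self, glioma_bundle):
        recs = [r for r in ms.screen_marker_like(glioma_bundle) if r.passes_all]
        parts = ms.partition_by_correlation(recs, glioma_bundle)
        by_gene = {p.gene_id: p for p in parts}
        truth = glioma_bundle.truth.correlation_sign
        planted = [g for g in glioma_bundle.truth.marker_like_genes
                   if truth[g] in ("negative", "positive") and g in by_gene]
        correct = sum(by_gene[g].group == truth[g] for g in planted)
        assert correct / len(planted) >= 0.9
        for p in parts:
            if p.group == "negative":
                assert p.rho < 0 and p.p_value < 0.05
            elif p.group == "positive":
                assert p.rho > 0 and p.p_value < 0.05

    def test_partition_covers_exactly_the_passing_genes(self, glioma_bundle):
        recs = ms.screen_marker_like(glioma_bundle)
        parts = ms.partition_by_correlation(recs, glioma_bundle)
        passing = {r.gene_id for r in recs if r.passes_all}
        assert {p.gene_id for p in parts} == passing
        groups = pd.Series({p.gene_id: p.group for p in parts})
        assert set(groups.unique()) <= {"negative", "positive", "uncorrelated"}

    def test_perfectly_monotone_pairs(self):
        """Deterministically coupled beta/expression gives rho = +-1."""
        b = syn.simulate_glioma_cohort(n_genes=10, n_marker_like=2,
                                       n_negative_corr=1, n_positive_corr=1, seed=4)
        tumors = b.clinical.samples_with(diagnosis=("LGG", "GBM"))
        gene = b.truth.marker_like_genes[0]
        probe = b.truth.planted_probe[gene]
        # overwrite with exact monotone coupling
        expr = b.expression.values.loc[gene, tumors].to_numpy()
        b.methylation.beta.loc[probe, tumors] = (
            pd.Series(expr).rank().to_numpy() / (len(tumors) + 1))
        recs = [r for r in ms.screen_marker_like(b) if r.gene_id == gene]
        parts = ms.partition_by_correlation(recs, b)
        if parts and parts[0].rho is not None:
            assert parts[0].rho == pytest.approx(1.0)


class TestEnrichment:
    def test_degenerate_universe_gives_p_one(self):
        coll = GeneSetCollection(sets={"s": ["a", "b", "c"]})
        out = ms.enrich(["a", "b", "c"], coll, universe=["a", "b", "c"])
        assert out[0].p_value == pytest.approx(1.0)

    def test_tail_probability_matches_direct_pmf_summation(self):
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(100)]
        members = list(rng.choice(universe, size=10, replace=False))
        coll = GeneSetCollection(sets={"s": members})
        query = members[:5] + [g for g in universe if g not in members][:5]
        out = ms.enrich(query, coll, universe=universe)
        assert out[0].overlap == 5
        assert out[0].p_value == pytest.approx(hypergeom_tail(5, 100, 10, 10),
                                               rel=1e-12)

    def test_zero_overlap_never_enriched(self):
        universe = [f"g{i}" for i in range(50)]
        coll = GeneSetCollection(sets={"s": universe[:10]})
        out = ms.enrich(universe[40:], coll, universe=universe)
        assert out[0].overlap == 0
        assert out[0].p_value == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        coll = GeneSetCollection(sets={"s": ["a"]})
        with pytest.raises(ValueError, match="zzz"):
            ms.enrich(["zzz"], coll, universe=["a", "b"])

    def test_bh_adjustment_preserves_p_ordering(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(80)]
        sets = {f"s{j}": list(rng.choice(universe, size=12, replace=False))
                for j in range(6)}
        coll = GeneSetCollection(sets=sets)
        out = ms.enrich(list(rng.choice(universe, size=15, replace=False)),
                        coll, universe=universe)
        by_p = sorted(out, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        for r in out:
            assert r.adjusted_p >= r.p_value - 1e-12
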