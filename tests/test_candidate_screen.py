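import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omniscreen import screen as cs
from omniscreen import synthetic as syn


def brute_force_tau(profile: np.ndarray) -> float:
    """Independent evaluation of the specificity index: normalize by the
    maximum, then average the complements over n-1 tissues."""
    xmax = max(profile)
    total = 0.0
    for x in profile:
        total += 1.0 - x / xmax
    return total / (len(profile) - 1)


class TestAggregateSites:
    def test_two_sites_average(self):
        expr = syn.ExpressionMatrix(values=pd.DataFrame(
            {"brain.s0": [10.0], "brain.s1": [20.0]}, index=["g"]))
        prof = cs.aggregate_sites(expr, {"brain.s0": "brain", "brain.s1": "brain"})
        assert prof.loc["g", "brain"] == 15.0

    def test_one_site_per_tissue_is_identity(self):
        expr = syn.ExpressionMatrix(values=pd.DataFrame(
            {"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["g1", "g2"]))
        prof = cs.aggregate_sites(expr, {"a": "A", "b": "B"})
        assert np.array_equal(prof.to_numpy(), expr.values.to_numpy())

    def test_matches_brute_force_per_tissue_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, size=(5, 6))
        sites = [f"s{i}" for i in range(6)]
        site_map = {s: f"T{i // 2}" for i, s in enumerate(sites)}
        expr = syn.ExpressionMatrix(values=pd.DataFrame(
            vals, index=[f"g{i}" for i in range(5)], columns=sites))
        prof = cs.aggregate_sites(expr, site_map)
        for ti in range(3):
            expected = vals[:, 2 * ti:2 * ti + 2].mean(axis=1)
            assert np.allclose(prof[f"T{ti}"], expected)

    def test_unmapped_site_is_an_error_listing_ids(self):
        expr = syn.ExpressionMatrix(values=pd.DataFrame({"a": [1.0], "b": [2.0]},
                                                        index=["g"]))
        with pytest.raises(ValueError, match="b"):
            cs.aggregate_sites(expr, {"a": "A"})


class TestFilterDetectable:
    @pytest.mark.parametrize("max_val,kept", [(9.9, False), (10.0, True), (10.1, True)])
    def test_strictly_smaller_removal_semantics(self, max_val, kept):
        prof = pd.DataFrame({"t1": [max_val], "t2": [1.0]}, index=["g"])
        out = cs.filter_detectable(prof, 10.0)
        assert ("g" in out.index) is kept

    def test_zero_threshold_is_identity(self):
        prof = pd.DataFrame({"t1": [0.1, 5.0], "t2": [0.0, 2.0]}, index=["a", "b"])
        assert cs.filter_detectable(prof, 0.0).equals(prof)


class TestComputeTau:
    def test_housekeeping_profile_scores_zero(self):
        prof = pd.DataFrame([[50.0] * 30], index=["hk"],
                            columns=[f"t{i}" for i in range(30)])
        assert cs.compute_tau(prof).loc["hk", "tau"] == 0.0

    def test_single_tissue_profile_scores_one(self):
        prof = pd.DataFrame([[100.0] + [0.0] * 29], index=["sp"],
                            columns=[f"t{i}" for i in range(30)])
        res = cs.compute_tau(prof)
        assert res.loc["sp", "tau"] == 1.0
        assert res.loc["sp", "argmax_tissue"] == "t0"
        assert res.loc["sp", "max_expression"] == 100.0

    def test_hand_computed_gradient_profile(self, tiny_profiles):
        # (10, 5, 0): (0 + 0.5 + 1) / 2 = 0.75
        res = cs.compute_tau(tiny_profiles)
        assert res.loc["gradient", "tau"] == pytest.approx(0.75, abs=1e-15)

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(123)
        n_genes, n_tissues = 1000, 30
        vals = rng.uniform(0.0, 200.0, size=(n_genes, n_tissues))
        vals[rng.random(size=vals.shape) < 0.2] = 0.0
        vals[:, 0] += 0.1  # guarantee a positive maximum
        prof = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"t{i}" for i in range(n_tissues)])
        res = cs.compute_tau(prof)
        for i in range(n_genes):
            assert abs(res["tau"].iloc[i] - brute_force_tau(vals[i])) < 1e-12

    def test_all_zero_profile_rejected(self):
        prof = pd.DataFrame({"t1": [0.0], "t2": [0.0]}, index=["g"])
        with pytest.raises(ValueError, match="all-zero"):
            cs.compute_tau(prof)

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2, max_size=40)
           .filter(lambda v: max(v) > 0),
           st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_tau_invariant_under_positive_rescaling(self, profile, scale):
        prof = pd.DataFrame([profile, [scale * x for x in profile]],
                            index=["raw", "scaled"],
                            columns=[f"t{i}" for i in range(len(profile))])
        res = cs.compute_tau(prof)
        assert res.loc["raw", "tau"] == pytest.approx(res.loc["scaled", "tau"],
                                                      abs=1e-9)

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=3, max_size=20)
           .filter(lambda v: max(v) > 1.0))
    @settings(max_examples=200, deadline=None)
    def test_tau_monotone_when_mass_moves_to_max_tissue(self, profile):
        """Lowering a non-max tissue (moving mass toward the max) never
        decreases tau."""
        arr = np.array(profile)
        i_max = int(arr.argmax())
        i_other = (i_max + 1) % len(arr)
        reduced = arr.copy()
        reduced[i_other] = reduced[i_other] / 2.0
        prof = pd.DataFrame([arr, reduced], index=["base", "shifted"],
                            columns=[f"t{i}" for i in range(len(arr))])
        res = cs.compute_tau(prof)
        assert res.loc["shifted", "tau"] >= res.loc["base", "tau"] - 1e-12


class TestSelectTissueSpecific:
    def _scores(self):
        return pd.DataFrame({
            "tau": [0.95, 0.92, 0.91, 0.9, 0.99],
            "argmax_tissue": ["brain", "brain", "brain", "brain", "liver"],
            "max_expression": [10.0, 20.0, 30.0, 40.0, 50.0],
        }, index=["a", "b", "c", "d", "e"])

    def test_top_n_truncation_by_tau(self):
        out = cs.select_tissue_specific(self._scores(), "brain", 0.9, top_n=2)
        assert list(out.index) == ["a", "b"]

    def test_tau_exactly_at_cutoff_excluded(self):
        out = cs.select_tissue_specific(self._scores(), "brain", 0.9, top_n=10)
        assert "d" not in out.index  # tau == 0.9 fails the strict comparison
        assert "e" not in out.index  # wrong argmax tissue

    def test_planted_genes_all_recovered(self, tissue_panel):
        expr, truth, site_map = tissue_panel
        prof = cs.filter_detectable(cs.aggregate_sites(expr, site_map), 10.0)
        scores = cs.compute_tau(prof)
        out = cs.select_tissue_specific(scores, "brain", 0.9, 100)
        assert set(truth.specific_genes).issubset(set(out.index))


class TestRankFluidCandidates:
    def test_intersection_sorted_by_intensity(self):
        fluid = syn.FluidProteomeTable(table=pd.DataFrame(
            {"fluorescence": [10.0, 30.0, 5.0]}, index=["B", "C", "D"]))
        out = cs.rank_fluid_candidates(["A", "B", "C"], fluid)
        assert list(out["gene_id"]) == ["C", "B"]

    def test_empty_intersection_gives_empty_ranking(self):
        fluid = syn.FluidProteomeTable(table=pd.DataFrame(
            {"fluorescence": [1.0]}, index=["Z"]))
        out = cs.rank_fluid_candidates(["A"], fluid)
        assert out.empty

    def test_planted_panel_fluid_overlap(self, tissue_panel):
        expr, truth, site_map = tissue_panel
        planted = list(truth.specific_genes)
        fluid = syn.simulate_fluid_proteome(planted[:3] + truth.background_genes[:40],
                                            20, seed=9)
        out = cs.rank_fluid_candidates(planted, fluid)
        expected = [g for g in planted[:3] if g in fluid.table.index]
        assert set(out["gene_id"]) == set(expected)
        assert list(out["fluorescence"]) == sorted(out["fluorescence"], reverse=True)
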