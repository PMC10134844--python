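"""Diversity indices, RAD normalization, Zipf fit, CLR distances, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import killwinner as kw
from killwinner.errors import InsufficientDataError, InvalidParameterError
from killwinner.synthetic import TREATMENT_P, TREATMENT_PV


class TestRarefy:
    def test_full_depth_identity(self):
        c = np.array([10, 20, 30])
        assert np.array_equal(kw.rarefy(c, 60, seed=0), c)

    def test_sum_and_richness(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 500, 50)
        out = kw.rarefy(c, 3188, seed=1)
        assert out.sum() == 3188
        assert (out > 0).sum() <= (c > 0).sum()
        assert np.all(out <= c)

    def test_hypergeometric_expectation(self):
        # 2-taxon community (9000, 1000), depth 1000: E[taxon 1] = 900
        rng = np.random.default_rng(2)
        draws = np.array([kw.rarefy([9000, 1000], 1000, rng)[0] for _ in range(10_000)])
        var = 1000 * 0.9 * 0.1 * (10_000 - 1000) / (10_000 - 1)  # hypergeometric variance
        se = np.sqrt(var / 10_000)
        assert abs(draws.mean() - 900) < 3 * se

    def test_depth_exceeding_total(self):
        with pytest.raises(InsufficientDataError):
            kw.rarefy([5, 5], 11, seed=0)


class TestNormalizedRad:
    def test_no_subsampling_is_sorted_proportions(self):
        c = np.array([50, 30, 0, 20])
        rad = kw.normalized_rad(c, target_richness=3, n_norm=500, seed=0)
        assert np.allclose(rad, [0.5, 0.3, 0.2])

    def test_even_community_gives_uniform(self):
        rad = kw.normalized_rad(np.full(12, 100), target_richness=5, n_norm=200, seed=0)
        assert np.allclose(rad, 0.2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_non_increasing_and_simplex(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(1, 1000, 20)
        rad = kw.normalized_rad(c, target_richness=8, n_norm=50, seed=seed)
        assert np.all(np.diff(rad) <= 1e-12)
        assert rad.sum() == pytest.approx(1.0, abs=1e-9)

    def test_target_exceeding_richness(self):
        with pytest.raises(InsufficientDataError):
            kw.normalized_rad([5, 5], target_richness=3)


class TestZipfAndEvenness:
    def test_exact_power_laws(self):
        ranks = np.arange(1, 51, dtype=float)
        one_over_r = (1 / ranks) / (1 / ranks).sum()
        decay, gamma = kw.fit_zipf(one_over_r)
        assert decay == pytest.approx(1.0, abs=1e-10)
        assert gamma == pytest.approx(-1.0, abs=1e-10)
        half = ranks**-0.5 / (ranks**-0.5).sum()
        assert kw.fit_zipf(half)[0] == pytest.approx(0.5, abs=1e-10)

    def test_flat_rad_zero_decay(self):
        assert kw.fit_zipf(np.full(20, 0.05))[0] == pytest.approx(0.0, abs=1e-12)

    def test_scale_and_relabel_invariance(self):
        rng = np.random.default_rng(1)
        c = np.sort(rng.random(30))[::-1]
        assert kw.fit_zipf(c / c.sum())[0] == pytest.approx(kw.fit_zipf(3 * c)[0], abs=1e-10)

    def test_pielou_evenness(self):
        assert kw.evenness(np.full(7, 1 / 7)) == pytest.approx(1.0)
        assert kw.evenness([0.5, 0.5]) == pytest.approx(1.0)
        h = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert kw.evenness([0.9, 0.1]) == pytest.approx(h / np.log(2))
        assert kw.evenness([0.9, 0.1]) == pytest.approx(0.4690, abs=1e-4)
        assert kw.evenness([0.7, 0.2, 0.1]) < 1.0
        with pytest.raises(InsufficientDataError):
            kw.evenness([1.0])


class TestClr:
    def test_identity_and_symmetry(self):
        x = np.array([8, 1, 1])
        y = np.array([1, 8, 1])
        assert kw.clr_euclidean(x, x) == 0.0
        assert kw.clr_euclidean(x, y) == pytest.approx(kw.clr_euclidean(y, x))

    def test_scale_invariance_without_pseudocount(self):
        x = np.array([8.0, 4.0, 2.0, 6.0])
        assert kw.clr_euclidean(x, 3 * x, pseudocount=0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scikit_bio_oracle(self):
        # independent CLR implementation as the reference
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.integers(1, 500, 12).astype(float)
            y = rng.integers(1, 500, 12).astype(float)
            expected = np.linalg.norm(skbio_clr(x / x.sum()) - skbio_clr(y / y.sum()))
            assert kw.clr_euclidean(x, y, pseudocount=0) == pytest.approx(expected, abs=1e-10)

    def test_hand_computed_example(self):
        x, y = np.array([8.0, 1.0, 1.0]), np.array([1.0, 8.0, 1.0])
        lx, ly = np.log(x), np.log(y)
        expected = float(np.linalg.norm((lx - lx.mean()) - (ly - ly.mean())))
        assert kw.clr_euclidean(x, y, pseudocount=0) == pytest.approx(expected, abs=1e-12)


class TestDiversityPipeline:
    def test_records_layout(self, noisy_dataset):
        div = kw.diversity_table(noisy_dataset.counts, noisy_dataset.metadata,
                                 n_norm=100, seed=0)
        assert len(div) == 16
        assert div["evenness"].between(0, 1).all()
        assert (div["rad_decay"] >= 0).all()
        assert (div["richness"] >= 1).all()

    def test_lmm_single_experiment_reduces_to_ols(self, noisy_dataset):
        div = kw.diversity_table(noisy_dataset.counts, noisy_dataset.metadata,
                                 n_norm=100, seed=0)
        res = kw.diversity_vs_dilution(div, TREATMENT_PV, "evenness")
        sub = div[div["treatment"] == TREATMENT_PV]
        from conftest import brute_force_ols

        slope, intercept = brute_force_ols(sub["dilution_factor"], sub["evenness"])
        assert res.fixed_slope == pytest.approx(slope, abs=1e-6)
        assert res.fixed_intercept == pytest.approx(intercept, abs=1e-6)

    def test_richness_slope_recovery(self):
        # diversity LMM recovers a known linear richness-vs-d slope
        rng = np.random.default_rng(17)
        slopes = []
        for _ in range(50):
            rows = []
            for e in range(6):
                b = rng.normal(0, 1.0)
                for d in (0.25, 0.5, 0.75, 1.0):
                    for _rep in range(2):
                        rows.append(dict(experiment=f"e{e}", treatment=TREATMENT_PV,
                                         dilution_factor=d,
                                         richness=100 + b + 20 * d + rng.normal(0, 2)))
            div = pd.DataFrame(rows)
            slopes.append(kw.diversity_vs_dilution(div, TREATMENT_PV, "richness").fixed_slope)
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 20) < 2 * mc_se + 0.05

    def test_constant_index_flat_slope(self):
        rows = [dict(experiment="e1", treatment=TREATMENT_P, dilution_factor=d,
                     evenness=0.8) for d in (0.25, 0.5, 0.75, 1.0) for _ in range(2)]
        res = kw.diversity_vs_dilution(pd.DataFrame(rows), TREATMENT_P, "evenness")
        assert res.fixed_slope == pytest.approx(0.0, abs=1e-12)


class TestCompositionMaintenance:
    def test_identical_compositions_near_zero_slope(self, noisy_dataset):
        counts = noisy_dataset.counts.copy()
        meta = noisy_dataset.metadata
        t0 = meta[meta["treatment"] == "source"]["sample_id"].iloc[0]
        for s in meta[meta["timepoint"] == "T12"]["sample_id"]:
            counts[s] = counts[t0]  # T12 identical to T0
        comp = kw.composition_maintenance(counts, meta, n_sub=30, seed=3)
        reg = comp["regressions"]
        # distances reduce to the paired-rarefaction sampling floor; no d trend
        assert (comp["distances"]["distance"] < 1.0).all()
        assert (reg["slope_p"] > 0.01).all()

    def test_ancova_interaction_reported(self, noisy_dataset):
        comp = kw.composition_maintenance(noisy_dataset.counts, noisy_dataset.metadata,
                                          n_sub=20, seed=4)
        assert len(comp["ancova"]) == 1
        assert 0 <= comp["ancova"][0].interaction_p <= 1

    def test_distances_decrease_with_dilution_under_strong_tradeoff(self):
        # more top-down control remaining (higher d) preserves the T0 community;
        # the trend shows under the protists+viruses-diluted treatment, where
        # the whole mortality gradient scales with d
        tr = kw.draw_traits(40, alpha_P=0.0, beta_P=0.4, alpha_V=0.0, beta_V=0.8,
                            noise_sd=0.005, seed=11)
        ds = kw.simulate_experiment(kw.ExperimentDesign(seed=11), tr)
        comp = kw.composition_maintenance(ds.counts, ds.metadata, n_sub=30, seed=5)
        reg = comp["regressions"].set_index("treatment")
        assert reg.loc[TREATMENT_PV, "slope"] < 0
        assert reg.loc[TREATMENT_PV, "slope_p"] < 0.05
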