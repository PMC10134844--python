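"""Rate estimation: absolute abundances, PNGR, PNGR-TCDF fits, trait recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import killwinner as kw
from killwinner.errors import DegenerateDesignError, InsufficientDataError
from killwinner.rates import ols_line
from killwinner.synthetic import TREATMENT_P, TREATMENT_PV

from conftest import brute_force_ols


class TestAbsoluteAbundance:
    def test_duplicate_mean_arithmetic(self):
        # taxon at 50% relative abundance, duplicate densities 1.0e6 and 2.0e6
        counts = pd.DataFrame(
            {"t0": [5, 5], "s1": [50, 50], "s2": [30, 70]},
            index=pd.Index(["A", "B"], name="taxon_id"),
        )
        metadata = pd.DataFrame([
            dict(sample_id="t0", experiment="e", treatment="source",
                 dilution_factor=np.nan, replicate=np.nan, timepoint="T0"),
            dict(sample_id="s1", experiment="e", treatment=TREATMENT_P,
                 dilution_factor=0.5, replicate=1, timepoint="T12"),
            dict(sample_id="s2", experiment="e", treatment=TREATMENT_P,
                 dilution_factor=0.5, replicate=2, timepoint="T12"),
        ])
        densities = pd.DataFrame([
            dict(bottle_id="b1", experiment="e", treatment=TREATMENT_P,
                 dilution_factor=0.5, replicate=1, timepoint="T0", cells_per_ml=5e5),
            dict(bottle_id="b1", experiment="e", treatment=TREATMENT_P,
                 dilution_factor=0.5, replicate=1, timepoint="T12", cells_per_ml=1.0e6),
            dict(bottle_id="b2", experiment="e", treatment=TREATMENT_P,
                 dilution_factor=0.5, replicate=2, timepoint="T0", cells_per_ml=5e5),
            dict(bottle_id="b2", experiment="e", treatment=TREATMENT_P,
                 dilution_factor=0.5, replicate=2, timepoint="T12", cells_per_ml=2.0e6),
        ])
        ab = kw.estimate_absolute_abundance(counts, densities, metadata)
        n12 = ab[(ab["taxon_id"] == "A") & (ab["timepoint"] == "T12")
                 & (ab["replicate"] == 1)]["N"].iloc[0]
        assert n12 == pytest.approx(0.5 * 1.5e6)  # duplicate-mean density

    def test_zero_read_series_filter(self, noisy_dataset):
        counts = noisy_dataset.counts.copy()
        taxon = counts.index[0]
        # zero out one T12 sample under the protists treatment for this taxon
        t12_p = noisy_dataset.metadata[
            (noisy_dataset.metadata["treatment"] == TREATMENT_P)
            & (noisy_dataset.metadata["timepoint"] == "T12")
        ]["sample_id"].iloc[0]
        counts.loc[taxon, t12_p] = 0
        ab = kw.estimate_absolute_abundance(counts, noisy_dataset.densities,
                                            noisy_dataset.metadata)
        pngr = kw.pngr_table(ab)
        gone = pngr[(pngr["taxon_id"] == taxon) & (pngr["treatment"] == TREATMENT_P)]
        kept = pngr[(pngr["taxon_id"] == taxon) & (pngr["treatment"] == TREATMENT_PV)]
        assert gone.empty  # whole protists series dropped
        assert not kept.empty  # other treatment's series untouched
        assert np.isfinite(pngr["R"]).all()

    def test_missing_replicate_still_fits(self, noisy_dataset):
        # drop one T12 composition sample (the failed-PCR situation)
        meta = noisy_dataset.metadata
        victim = meta[(meta["treatment"] == TREATMENT_P)
                      & (meta["dilution_factor"] == 0.25)
                      & (meta["replicate"] == 1)]["sample_id"].iloc[0]
        counts = noisy_dataset.counts.drop(columns=[victim])
        meta = meta[meta["sample_id"] != victim]
        res = kw.estimate_rates(counts, noisy_dataset.densities, meta)
        n_p = res["pngr"][res["pngr"]["treatment"] == TREATMENT_P].groupby("taxon_id").size()
        assert n_p.max() == 7  # 8 bottles minus the failed one
        assert not res["fits"].empty


class TestComputePngr:
    def test_identity_and_analytic_values(self):
        assert kw.compute_pngr(1e5, 1e5) == pytest.approx(0.0)
        assert kw.compute_pngr(1e5, 1e5 * np.e**1.2, 12.0) == pytest.approx(0.1)
        assert kw.compute_pngr(1e5, 1e5 / np.e, 12.0) == pytest.approx(-1 / 12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n0=st.floats(1e2, 1e8), n12=st.floats(1e2, 1e8), c=st.floats(0.01, 100))
    def test_per_capita_invariance(self, n0, n12, c):
        # scaling both timepoints by a constant leaves R unchanged
        assert kw.compute_pngr(c * n0, c * n12) == pytest.approx(kw.compute_pngr(n0, n12))

    def test_nonpositive_rejected(self):
        with pytest.raises(InsufficientDataError):
            kw.compute_pngr(0.0, 1e5)


class TestPngrTcdfFit:
    def test_perfect_line(self):
        rec = pd.DataFrame({"dilution_factor": [0.25, 0.5, 0.75, 1.0],
                            "R": [0.4, 0.3, 0.2, 0.1]})
        fit = kw.fit_pngr_tcdf(rec)
        assert fit.slope == pytest.approx(-0.4)
        assert fit.intercept == pytest.approx(0.5)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_series_nonsignificant(self):
        rec = pd.DataFrame({"dilution_factor": [0.25, 0.5, 0.75, 1.0], "R": [0.2] * 4})
        fit = kw.fit_pngr_tcdf(rec)
        assert fit.slope == 0.0
        assert fit.slope_p == 1.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = np.repeat([0.25, 0.5, 0.75, 1.0], 2)
            y = rng.normal(size=8)
            fit = ols_line(x, y)
            slope, intercept = brute_force_ols(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_degenerate_designs(self):
        with pytest.raises(InsufficientDataError):
            kw.fit_pngr_tcdf(pd.DataFrame({"dilution_factor": [0.25, 0.5], "R": [0, 1]}))
        with pytest.raises(DegenerateDesignError):
            ols_line([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])


class TestTraitRecovery:
    def test_noiseless_end_to_end_recovery(self, noiseless_rates, tradeoff_traits):
        tr = noiseless_rates["traits"].set_index("taxon_id")
        truth = tradeoff_traits.set_index("taxon_id")
        assert len(tr) == len(truth)  # nothing filtered in exact mode
        assert np.allclose(tr["competitiveness"], truth["g"], atol=1e-8)
        assert np.allclose(tr["resistance_P"], -truth["m_P"], atol=1e-8)
        assert np.allclose(tr["resistance_PV"], -(truth["m_P"] + truth["m_V"]), atol=1e-8)
        assert np.allclose(tr["resistance_V"], -truth["m_V"], atol=1e-8)

    def test_closed_form_single_taxon(self):
        tr = pd.DataFrame({"taxon_id": ["A", "B"], "g": [0.12, 0.10],
                           "m_P": [0.03, 0.02], "m_V": [0.05, 0.01], "p0": [0.5, 0.5]})
        ds = kw.simulate_experiment(
            kw.ExperimentDesign(exact_proportions=True, density_cv=0.0, seed=0), tr)
        est = kw.estimate_rates(ds)["traits"].set_index("taxon_id").loc["A"]
        assert est["competitiveness"] == pytest.approx(0.12, abs=1e-8)
        assert est["resistance_P"] == pytest.approx(-0.03, abs=1e-8)
        assert est["resistance_PV"] == pytest.approx(-0.08, abs=1e-8)
        assert est["resistance_V"] == pytest.approx(-0.05, abs=1e-8)

    def test_zero_viral_mortality_gives_zero_resistance_v(self):
        tr = pd.DataFrame({"taxon_id": ["A", "B"], "g": [0.12, 0.10],
                           "m_P": [0.03, 0.02], "m_V": [0.0, 0.0], "p0": [0.4, 0.6]})
        ds = kw.simulate_experiment(
            kw.ExperimentDesign(exact_proportions=True, density_cv=0.0, seed=0), tr)
        est = kw.estimate_rates(ds)["traits"]
        assert np.allclose(est["resistance_V"], 0.0, atol=1e-8)

    def test_partial_data_contract(self, noisy_rates):
        fits = noisy_rates["fits"]
        only_pv = fits[fits["treatment"] == TREATMENT_PV].iloc[[0]]
        traits = kw.estimate_traits(only_pv)
        row = traits.iloc[0]
        assert np.isfinite(row["competitiveness"]) and np.isfinite(row["resistance_PV"])
        assert np.isnan(row["resistance_P"]) and np.isnan(row["resistance_V"])

    def test_subtraction_order_flag(self, noiseless_rates):
        flipped = kw.estimate_traits(noiseless_rates["fits"],
                                     subtraction_order="p_minus_pv")
        default = noiseless_rates["traits"]
        assert np.allclose(flipped["resistance_V"], -default["resistance_V"])


class TestCommunityQc:
    def test_noiseless_slopes_negative_and_pv_above_p(self, noiseless_rates):
        qc = noiseless_rates["community_qc"]
        assert (qc["slope"] < 0).all()
        assert qc["pv_line_above_p"].all()

    def test_no_mortality_flat_lines(self):
        tr = kw.draw_traits(10, alpha_P=0.0, beta_P=0.0, alpha_V=0.0, beta_V=0.0,
                            noise_sd=0.0, seed=3)
        ds = kw.simulate_experiment(
            kw.ExperimentDesign(exact_proportions=True, density_cv=0.0, seed=3), tr)
        qc = kw.community_pngr_qc(ds.densities)
        assert np.allclose(qc["slope"], 0.0, atol=1e-10)
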