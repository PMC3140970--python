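"""Synthetic cell populations, RFI counting noise and threshold recovery."""

import numpy as np
import pandas as pd
import pytest

import filonet as fn
from filonet.filopodia import PopulationModel, fraction_forming
from filonet.population import truncated_fraction_forming


class TestSampling:
    def test_sample_mean_within_clt_bound(self):
        n, mu, sigma = 100_000, 100.0, 10.0
        x = fn.sample_population(mu, sigma, n, seed=11)
        assert abs(x.mean() - mu) <= 3.0 * sigma / np.sqrt(n)

    def test_zero_width_limit_is_deterministic_mean(self):
        x = fn.sample_population(50.0, 0.0, 100, seed=0)
        assert np.all(x == 50.0)

    def test_same_seed_reproduces_vector(self):
        a = fn.sample_population(100.0, 25.0, 1000, seed=42)
        b = fn.sample_population(100.0, 25.0, 1000, seed=42)
        assert np.array_equal(a, b)

    def test_truncation_keeps_concentrations_non_negative(self):
        x = fn.sample_population(5.0, 20.0, 10_000, seed=3)
        assert x.min() >= 0.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            fn.sample_population(1.0, 1.0, 0, seed=0)


class TestTailAgreement:
    @pytest.mark.parametrize(
        "mu,sigma,fi_crit",
        [
            (100.0, 25.0, 100.0),
            (120.0, 25.0, 100.0),
            (80.0, 25.0, 100.0),
            (100.0, 10.0, 110.0),
            (150.0, 40.0, 100.0),
        ],
    )
    def test_monte_carlo_matches_truncated_tail(self, mu, sigma, fi_crit):
        pop = PopulationModel(mu=mu, sigma=sigma, fi_crit=fi_crit)
        n = 40_000
        x = fn.sample_population(mu, sigma, n, seed=int(mu + sigma + fi_crit))
        p_hat = float(np.mean(x > fi_crit))
        p = truncated_fraction_forming(pop)
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(p_hat - p) <= 3.0 * se

    def test_truncation_correction_is_negligible_at_default_width(self):
        # the analytic layer integrates an untruncated Gaussian; at the
        # default sigma = mu/4 the mass below zero is ~Phi(-4)
        pop = fn.default_population(100.0)
        assert abs(
            truncated_fraction_forming(pop) - fraction_forming(pop)
        ) < 1e-3


@pytest.fixture(scope="module")
def fii_table():
    return pd.DataFrame(
        {
            "context": ["hela"] * 6,
            "genotype": ["WT", "a", "b", "c", "d", "e"],
            "fii": [1.0, 0.2, 0.6, 0.9, 1.2, 1.6],
        }
    )


class TestRFIExperiment:
    def test_wild_type_rfi_is_near_one(self, fii_table):
        pop = fn.default_population(100.0)
        out = fn.simulate_rfi_experiment(fii_table, pop, n_cells=20_000, seed=5)
        wt = out[out.genotype == "WT"].iloc[0]
        assert wt.rfi_obs == 1.0  # self-normalized
        assert abs(wt.observed_fraction - 0.5) < 0.02

    def test_large_population_converges_to_analytic_rfi(self, fii_table):
        pop = fn.default_population(100.0)
        n = 200_000
        out = fn.simulate_rfi_experiment(fii_table, pop, n_cells=n, seed=17)
        frac_wt = float(out[out.genotype == "WT"].observed_fraction.iloc[0])
        se_wt = np.sqrt(frac_wt * (1 - frac_wt) / n)
        for _, row in out.iterrows():
            pred = fn.predict_rfi(
                float(fii_table[fii_table.genotype == row.genotype].fii.iloc[0]), pop
            ).predicted_rfi
            p = row.observed_fraction
            se_g = np.sqrt(max(p * (1 - p), 1e-12) / n)
            # binomial noise enters through numerator and WT denominator
            se_ratio = row.rfi_obs * np.sqrt(
                (se_g / max(p, 1e-9)) ** 2 + (se_wt / frac_wt) ** 2
            )
            # 3 SE plus the small truncation offset of the sampler
            assert abs(row.rfi_obs - pred) <= 3.0 * se_ratio + 2e-3

    def test_zero_fii_genotype_sits_at_the_tail_floor(self):
        pop = fn.default_population(100.0)
        table = pd.DataFrame(
            {"context": ["c", "c"], "genotype": ["WT", "null"], "fii": [1.0, 0.0]}
        )
        out = fn.simulate_rfi_experiment(table, pop, n_cells=50_000, seed=23)
        frac = float(out[out.genotype == "null"].observed_fraction.iloc[0])
        assert frac <= 3e-4  # ~Phi(-4) with counting noise

    def test_determinism_per_seed(self, fii_table):
        pop = fn.default_population(100.0)
        a = fn.simulate_rfi_experiment(fii_table, pop, n_cells=1000, seed=9)
        b = fn.simulate_rfi_experiment(fii_table, pop, n_cells=1000, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_wt_row_rejected(self):
        pop = fn.default_population(100.0)
        table = pd.DataFrame(
            {"context": ["c"], "genotype": ["mut"], "fii": [0.5]}
        )
        with pytest.raises(ValueError, match="WT"):
            fn.simulate_rfi_experiment(table, pop, n_cells=100, seed=0)


class TestThresholdRecovery:
    @staticmethod
    def _experiments(fi_crit, sigma, fiis, n_cells, seed):
        mu_wt = 100.0
        pop = PopulationModel(mu=mu_wt, sigma=sigma, fi_crit=fi_crit)
        table = pd.DataFrame(
            {
                "context": ["c"] * len(fiis),
                "genotype": ["WT"] + [f"g{i}" for i in range(1, len(fiis))],
                "fii": fiis,
            }
        )
        return fn.simulate_rfi_experiment(table, pop, n_cells=n_cells, seed=seed)

    def test_recovery_within_ten_percent_at_1e4_cells(self):
        fiis = [1.0, 0.2, 0.6, 0.9, 1.2, 1.6]
        out = self._experiments(100.0, 25.0, fiis, n_cells=10_000, seed=31)
        fit = fn.recover_threshold(out)
        assert fit.fi_crit == pytest.approx(100.0, rel=0.10)
        assert fit.sigma == pytest.approx(25.0, rel=0.10)

    def test_noise_free_fractions_recovered_exactly(self):
        mus = np.array([20.0, 60.0, 90.0, 100.0, 120.0, 160.0])
        fracs = [
            fraction_forming(PopulationModel(m, 25.0, 100.0)) for m in mus
        ]
        table = pd.DataFrame({"mu": mus, "observed_fraction": fracs})
        fit = fn.recover_threshold(table)
        assert fit.fi_crit == pytest.approx(100.0, rel=1e-6)
        assert fit.sigma == pytest.approx(25.0, rel=1e-6)

    def test_two_point_design_is_under_determined(self):
        table = pd.DataFrame({"mu": [50.0, 150.0], "observed_fraction": [0.1, 0.9]})
        with pytest.raises(ValueError, match="under-determined"):
            fn.recover_threshold(table)

    def test_recovery_error_shrinks_with_population_size(self):
        fiis = [1.0, 0.2, 0.6, 0.9, 1.2, 1.6]
        errors = []
        for n_cells in (1_000, 100_000):
            errs = []
            for seed in (1, 2, 3, 4, 5):
                out = self._experiments(100.0, 25.0, fiis, n_cells, seed)
                fit = fn.recover_threshold(out)
                errs.append(abs(fit.fi_crit - 100.0))
            errors.append(np.mean(errs))
        assert errors[-1] < errors[0]
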