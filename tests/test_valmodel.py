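"""Logistic validation model: closed forms, parameter recovery, Wald
identities, separation diagnostics and backward elimination."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from transnp import SeparationError, backward_eliminate, logistic_fit
from transnp.valmodel import assemble_predictors, simulate_validation_outcomes


def _sim_table(rng, n=2000, beta0=-0.4, beta1=0.8):
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame({"x": x, "y": y})


class TestLogisticFit:
    def test_intercept_only_closed_form(self, rng):
        y = np.array([1] * 30 + [0] * 70)
        table = pd.DataFrame({"y": y})
        fit = logistic_fit(table, "y", [])
        assert fit.coefficients["constant"] == pytest.approx(np.log(30 / 70), abs=1e-8)
        assert fit.model_df == 0

    def test_parameter_recovery_within_three_se(self, rng):
        table = _sim_table(rng)
        fit = logistic_fit(table, "y", ["x"])
        assert abs(fit.coefficients["x"] - 0.8) < 3 * fit.std_errors["x"]
        assert abs(fit.coefficients["constant"] + 0.4) < 3 * fit.std_errors["constant"]
        assert fit.converged

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm

        table = _sim_table(rng, n=500)
        fit = logistic_fit(table, "y", ["x"])
        x = sm.add_constant(table[["x"]].to_numpy())
        ref = sm.Logit(table.y.to_numpy(), x).fit(disp=0)
        assert fit.coefficients["constant"] == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.std_errors["x"] == pytest.approx(ref.bse[1], rel=1e-4)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_wald_identity_and_pvalue(self, rng):
        table = _sim_table(rng, n=800)
        fit = logistic_fit(table, "y", ["x"])
        w = (fit.coefficients["x"] / fit.std_errors["x"]) ** 2
        assert fit.wald["x"] == pytest.approx(w)
        assert fit.p_values["x"] == pytest.approx(float(chi2.sf(w, 1)))

    def test_complete_separation_raises(self):
        x = np.linspace(-2, 2, 40)
        table = pd.DataFrame({"x": x, "y": (x > 0).astype(int)})
        with pytest.raises(SeparationError):
            logistic_fit(table, "y", ["x"])

    def test_row_order_invariance(self, rng):
        table = _sim_table(rng, n=400)
        f1 = logistic_fit(table, "y", ["x"])
        f2 = logistic_fit(table.sample(frac=1.0, random_state=1), "y", ["x"])
        assert f1.coefficients["x"] == pytest.approx(f2.coefficients["x"], abs=1e-9)

    def test_affine_rescaling_transforms_coefficients(self, rng):
        table = _sim_table(rng, n=600)
        f1 = logistic_fit(table, "y", ["x"])
        table2 = table.assign(x=table.x * 10 + 5)
        f2 = logistic_fit(table2, "y", ["x"])
        assert f2.coefficients["x"] * 10 == pytest.approx(f1.coefficients["x"],
                                                          rel=1e-6)

    def test_null_model_chi2_distribution(self, rng):
        # under the null the LR statistic is chi-square(1); K-S at alpha=0.01
        stats = []
        for _ in range(300):
            x = rng.normal(size=150)
            y = (rng.uniform(size=150) < 0.4).astype(int)
            fit = logistic_fit(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
            stats.append(fit.model_chi2)
        _, p = kstest(stats, chi2(df=1).cdf)
        assert p > 0.01


class TestBackwardElimination:
    def test_pure_noise_reduces_to_intercept_only(self, rng):
        n = 600
        table = pd.DataFrame({f"z{i}": rng.normal(size=n) for i in range(4)})
        table["y"] = (rng.uniform(size=n) < 0.5).astype(int)
        fit, trace = backward_eliminate(table, "y", [f"z{i}" for i in range(4)])
        assert fit.terms == []
        assert len(trace) == 4

    def test_signal_retained_among_noise(self, rng):
        n = 2000
        x = rng.normal(size=n)
        table = pd.DataFrame({"x": x,
                              "z1": rng.normal(size=n), "z2": rng.normal(size=n)})
        p = 1 / (1 + np.exp(-1.0 * x))
        table["y"] = (rng.uniform(size=n) < p).astype(int)
        fit, _ = backward_eliminate(table, "y", ["x", "z1", "z2"])
        assert "x" in fit.terms
        assert fit.p_values["x"] < 0.05

    def test_trace_replays_to_same_model(self, rng):
        table = _sim_table(rng, n=500)
        table["z"] = rng.normal(size=500)
        fit, trace = backward_eliminate(table, "y", ["x", "z"])
        terms = ["x", "z"]
        for step in trace:
            terms = [t for t in terms if t != step["removed"]]
        refit = logistic_fit(table, "y", terms)
        assert refit.coefficients.equals(fit.coefficients)

    def test_deterministic(self, rng):
        table = _sim_table(rng, n=300)
        table["z"] = rng.normal(size=300)
        f1, t1 = backward_eliminate(table, "y", ["x", "z"])
        f2, t2 = backward_eliminate(table, "y", ["x", "z"])
        assert t1 == t2 and f1.terms == f2.terms


class TestAssemblePredictors:
    def _snp_table(self):
        return pd.DataFrame({
            "contig_id": ["c1", "c2", "c3"], "position": [100, 150, 200],
            "individuals_covering": [8, 6, 7], "depth": [20, 10, 15],
            "minor_count": [5, 2, 3], "individuals_with_minor": [4, 2, 3],
            "ads": [0.9, 0.5, 0.8],
            "boundary": ["single_exon", "no_match", "boundary"],
            "supporting_species": [3, 0, 1], "nsq": [0, 2, 5],
        })

    def test_outcome_coding_and_polymorphism_nullity(self):
        outcomes = pd.DataFrame({"contig_id": ["c1", "c2", "c3"],
                                 "position": [100, 150, 200],
                                 "conversion": [1, 0, 1],
                                 "polymorphism": [1, 0, 0]})
        table = assemble_predictors(self._snp_table(), outcomes)
        assert table.loc[table.contig_id == "c2", "polymorphism"].isna().all()
        assert table.loc[table.contig_id == "c1", "polymorphism"].iloc[0] == 1.0
        assert table.loc[table.contig_id == "c3", "polymorphism"].iloc[0] == 0.0

    def test_predictor_columns_match_recomputation(self):
        outcomes = pd.DataFrame({"contig_id": ["c1", "c2", "c3"],
                                 "position": [100, 150, 200],
                                 "conversion": [1, 1, 1]})
        snp = self._snp_table()
        table = assemble_predictors(snp, outcomes)
        assert np.allclose(table.minor_freq, snp.minor_count / snp.depth)
        assert table.boundary_single.tolist() == [1.0, 0.0, 0.0]
        assert table.boundary_intron.tolist() == [0.0, 0.0, 1.0]
        assert not table.missing_predictor.any()

    def test_end_to_end_with_simulated_outcomes(self, rng):
        snp = pd.concat([self._snp_table()] * 200, ignore_index=True)
        snp["ads"] = rng.uniform(0, 1, len(snp))
        snp["nsq"] = rng.integers(0, 8, len(snp))
        snp["position"] = np.arange(len(snp))
        snp["contig_id"] = [f"c{i}" for i in range(len(snp))]
        outcomes = pd.DataFrame({"contig_id": snp.contig_id,
                                 "position": snp.position, "conversion": 1})
        table = assemble_predictors(snp, outcomes)
        table = simulate_validation_outcomes(table, seed=4)
        fit = logistic_fit(table, "conversion", ["ads"])
        assert fit.coefficients["ads"] > 0   # planted positive effect
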