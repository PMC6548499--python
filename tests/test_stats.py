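import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.special
import scipy.stats

from opseq.stats import (
    ModelSpec,
    fit_count_model,
    one_sample_t,
    paired_t,
    pearson_r,
    sqrt_prop,
)


class TestSqrtProp:
    def test_fixed_points_and_example(self):
        assert list(sqrt_prop([0.0, 1.0, 0.25])) == [0.0, 1.0, 0.5]

    def test_monotone(self):
        x = np.linspace(0, 1, 50)
        assert np.all(np.diff(sqrt_prop(x)) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sqrt_prop([1.5])


class TestTTests:
    def test_paired_t_hand_computation(self):
        """Differences (1,1,2): mean 4/3, SE 1/3 -> t = 4, df = 2."""
        res = paired_t([1, 2, 3], [2, 3, 5])
        assert res.t == pytest.approx(4.0, abs=1e-10)
        assert res.df == 2
        assert res.p == pytest.approx(2 * scipy.stats.t.sf(4.0, 2), abs=1e-12)

    def test_paired_t_zero_for_identical_samples(self):
        assert paired_t([1.0, 2.0, 4.0], [1.0, 2.0, 4.0]).t == 0.0

    def test_paired_t_shift_invariance(self):
        x = np.array([0.3, 1.2, 5.0, 2.2])
        y = np.array([1.0, 0.7, 6.1, 2.0])
        a = paired_t(x, y)
        b = paired_t(x + 17.0, y + 17.0)
        assert a.t == pytest.approx(b.t, abs=1e-12)

    def test_one_sample_hand_computation(self):
        """x = (2,4,6): mean 4, SE 2/sqrt(3) -> t = 2*sqrt(3) = 3.4641."""
        res = one_sample_t([2.0, 4.0, 6.0], 0.0)
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert res.df == 2

    def test_one_sample_symmetric_zero(self):
        assert one_sample_t([-1.0, 1.0], 0.0).t == 0.0

    def test_paired_equals_one_sample_on_differences(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        y = np.array([2.0, 3.0, 5.0, 8.5])
        assert paired_t(x, y).t == pytest.approx(one_sample_t(y - x, 0.0).t, abs=1e-12)

    def test_type_one_error_near_nominal(self):
        """Null gaussian simulations reject at ~alpha = .05."""
        rng = np.random.default_rng(123)
        n_reps, n = 2000, 10
        rejections = sum(
            one_sample_t(rng.normal(size=n), 0.0).p < 0.05 for _ in range(n_reps)
        )
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 0.02


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_hand_computation(self):
        """x=(1,2,3), y=(2,1,4): sum dx*dy = 2, sum dx^2 = 2, sum dy^2 = 14/3,
        so r = 2 / sqrt(28/3)."""
        res = pearson_r([1.0, 2.0, 3.0], [2.0, 1.0, 4.0])
        assert res.r == pytest.approx(2.0 / np.sqrt(28.0 / 3.0), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _gh_poisson_mle(df, n_nodes=40):
    """Independent oracle: exact (adaptive-free) Gauss-Hermite ML fit of a
    Poisson log-link model with a single by-subject random intercept and one
    binary predictor."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # hermegauss integrates against exp(-x^2/2): E_phi[f] = sum w f / sqrt(2 pi)
    w = weights / np.sqrt(2 * np.pi)
    groups = [g for _, g in df.groupby("subject_id")]

    def nll(params):
        b0, b1, log_sd = params
        sd = np.exp(log_sd)
        total = 0.0
        for g in groups:
            eta = b0 + b1 * g["x"].to_numpy() # (n_j,)
            y = g["y"].to_numpy()
            lam = np.exp(eta[:, None] + sd * nodes[None, :])
            ll = (y[:, None] * np.log(lam) - lam).sum(axis=0)
            ll -= scipy.special.gammaln(y + 1).sum()
            total += scipy.special.logsumexp(ll + np.log(w))
        return -total

    res = scipy.optimize.minimize(nll, [1.0, 0.5, np.log(0.3)], method="Nelder-Mead",
                                  options={"xatol": 1e-6, "fatol": 1e-9,
                                           "maxiter": 2000})
    return res.x


class TestCountModel:
    def test_degenerate_poisson_closed_form(self):
        """Saturated binary predictor, no random effects: intercept log 3,
        slope log(8/3)."""
        data = pd.DataFrame(
            {"subject_id": ["a", "b", "a", "b"], "grp": ["A", "A", "B", "B"],
             "y": [2, 4, 8, 8]}
        )
        fit = fit_count_model(ModelSpec("y", "poisson_log", fixed=("grp",)), data)
        assert fit.converged
        assert fit.coefficients["Intercept"].b == pytest.approx(np.log(3.0), abs=1e-8)
        assert fit.coefficients["grp[B]"].b == pytest.approx(np.log(8 / 3), abs=1e-8)

    def test_glm_oracle_equivalence_without_random_effects(self):
        rng = np.random.default_rng(7)
        n = 60
        df = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)],
             "grp": rng.choice(["A", "B"], n),
             "period": rng.choice(["pre", "CS"], n)}
        )
        lam = 5 * np.where(df["grp"] == "B", 2.0, 1.0)
        df["y"] = rng.poisson(lam)
        fit = fit_count_model(
            ModelSpec("y", "poisson_log", fixed=("grp", "period")), df
        )
        import statsmodels.formula.api as smf
        import statsmodels.api as sm
        ref = smf.glm("y ~ C(grp) * C(period)", df,
                      family=sm.families.Poisson()).fit()
        assert fit.coefficients["Intercept"].b == pytest.approx(
            ref.params["Intercept"], abs=1e-8
        )
        assert fit.coefficients["grp[B]:period[pre]"].b == pytest.approx(
            ref.params["C(grp)[T.B]:C(period)[T.pre]"], abs=1e-8
        )

    def test_laplace_fit_matches_quadrature_oracle(self):
        """The Laplace-approximate mixed fit agrees with an exact
        Gauss-Hermite maximum-likelihood fit on a random-intercept model."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(16):
            u = rng.normal(0, 0.4)
            for x, beta in ((0, 0.0), (0, 0.0), (1, 0.8), (1, 0.8)):
                rows.append({"subject_id": f"s{i:02d}", "x": x,
                             "grp": "B" if x else "A",
                             "y": rng.poisson(np.exp(np.log(6) + beta + u))})
        df = pd.DataFrame(rows)
        fit = fit_count_model(
            ModelSpec("y", "poisson_log", fixed=("grp",), random=()), df
        )
        b0, b1, log_sd = _gh_poisson_mle(df)
        assert fit.converged
        assert fit.coefficients["Intercept"].b == pytest.approx(b0, abs=0.05)
        assert fit.coefficients["grp[B]"].b == pytest.approx(b1, abs=0.02)
        assert np.sqrt(fit.variance_components["subject"]) == pytest.approx(
            np.exp(log_sd), rel=0.10, abs=0.03
        )

    def test_null_simulation_coefficients_small(self):
        """With no factor effects the fixed-effect estimates hover near zero
        and the interaction is not spuriously significant."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(40):
            u = rng.normal(0, 0.3)
            for cs_type in ("CS+", "CS-"):
                for period in ("CS", "preCS"):
                    rows.append({"subject_id": f"s{i:02d}", "cs_type": cs_type,
                                 "period": period,
                                 "y": rng.poisson(np.exp(np.log(10) + u))})
        df = pd.DataFrame(rows)
        fit = fit_count_model(
            ModelSpec("y", "poisson_log", fixed=("cs_type", "period"),
                      random=("cs_type", "period")),
            df,
        )
        inter = fit.coefficients["cs_type[CS-]:period[preCS]"]
        assert abs(inter.b) < 0.2
        assert inter.p > 0.01

    def test_interaction_power_on_simulated_effect(self):
        """A 3x CS+ rate multiplier is detected as a cs_type x period
        interaction in the vast majority of replicates."""
        hits = 0
        n_reps = 25
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            rows = []
            for i in range(20):
                u = rng.normal(0, 0.3)
                for cs_type in ("CS+", "CS-"):
                    for period in ("CS", "preCS"):
                        mult = 3.0 if (cs_type == "CS+" and period == "CS") else 1.0
                        rows.append(
                            {"subject_id": f"s{i:02d}", "cs_type": cs_type,
                             "period": period,
                             "y": rng.poisson(np.exp(np.log(8) + u) * mult)}
                        )
            fit = fit_count_model(
                ModelSpec("y", "poisson_log", fixed=("cs_type", "period"),
                          random=("cs_type", "period")),
                pd.DataFrame(rows),
            )
            if fit.coefficients["cs_type[CS-]:period[preCS]"].p < 0.05:
                hits += 1
        assert hits / n_reps >= 0.8

    def test_gaussian_family_for_sqrt_proportions(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(24):
            u = rng.normal(0, 0.05)
            for period, mu in (("Pre-CS", 0.1), ("CS+", 0.3)):
                p = np.clip(mu + u + rng.normal(0, 0.05), 0, 1)
                rows.append({"subject_id": f"s{i:02d}", "cs_period": period,
                             "prop": p})
        df = pd.DataFrame(rows)
        df["sqrt_prop"] = sqrt_prop(df["prop"])
        fit = fit_count_model(
            ModelSpec("sqrt_prop", "gaussian_identity", fixed=("cs_period",),
                      random=()),
            df,
        )
        assert fit.converged
        slope = [c for name, c in fit.coefficients.items() if "Pre" in name]
        assert slope and slope[0].b < 0  # Pre-CS below CS+ on the sqrt scale

    def test_single_subject_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "a"], "grp": ["A", "B"],
                           "y": [1, 2]})
        with pytest.raises(ValueError, match="2 subjects"):
            fit_count_model(ModelSpec("y", fixed=("grp",)), df)
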