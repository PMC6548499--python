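"""Statistical layer: transforms, simple tests, and mixed-effects count models.

Count responses (press frequencies) are modeled with a Poisson distribution
and log link; proportion responses are square-root transformed to correct
positive skew and modeled with a Gaussian identity link. Fixed effects are
the full factorial of the named categorical manipulations; random effects
are by-subject uncorrelated intercepts, one variance component per
within-subject factor ("intercepts adjusted for the within-subject
manipulations"). Effect sizes are unstandardized coefficients ``b`` on the
link scale. All tests are two-sided at alpha = .05; no multiple-testing
correction is applied.

The Poisson mixed model is fit by Laplace-approximate maximum likelihood:
for candidate variance components, the joint penalized Poisson
log-likelihood is maximized over (beta, u) by Newton's method (it is
concave), and the marginal likelihood is approximated by the Laplace
determinant correction; the variance parameters are then optimized on the
log-standard-deviation scale. With an empty random structure the fit
reduces exactly to an IRLS Poisson GLM. Gaussian-family responses delegate
to statsmodels' linear mixed model (REML).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TTestResult",
    "CorrResult",
    "Coefficient",
    "FTestResult",
    "ModelSpec",
    "ModelFit",
    "sqrt_prop",
    "paired_t",
    "one_sample_t",
    "pearson_r",
    "build_fixed_design",
    "fit_count_model",
]


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class CorrResult(NamedTuple):
    r: float
    p: float


def sqrt_prop(values) -> np.ndarray:
    """Square-root transform for proportion data in [0, 1] (skew correction)."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("proportions must lie in [0, 1]")
    return np.sqrt(arr)


def paired_t(x, y) -> TTestResult:
    """Paired t-test on per-subject differences (second minus first).

    The difference is taken ``y - x`` — the post-minus-pre convention, so a
    positive t means the second condition is larger. Two-sided p,
    df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length samples, n >= 2")
    return one_sample_t(y - x, 0.0)


def one_sample_t(x, mu: float = 0.0) -> TTestResult:
    """One-sample t-test of the mean against ``mu``; two-sided, df = n - 1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("one_sample_t needs n >= 2")
    if np.ptp(x) == 0:  # zero variance: t is 0 when the mean hits mu
        if x[0] == mu:
            return TTestResult(0.0, x.size - 1, 1.0)
        t = np.inf if x[0] > mu else -np.inf
        return TTestResult(float(t), x.size - 1, 0.0)
    res = scipy.stats.ttest_1samp(x, mu)
    return TTestResult(float(res.statistic), x.size - 1, float(res.pvalue))


def pearson_r(x, y) -> CorrResult:
    """Pearson product-moment correlation with two-sided p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs equal-length samples, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r needs nonzero variance in both samples")
    res = scipy.stats.pearsonr(x, y)
    return CorrResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Mixed count model


@dataclass(frozen=True)
class ModelSpec:
    """Contract of the count/proportion mixed model.

    fixed: names of categorical factors entering as a full factorial.
    random: within-subject factors behind the by-subject uncorrelated random
    intercepts (one variance component per factor plus a plain subject
    intercept). An empty tuple keeps the plain by-subject intercept only;
    ``None`` drops random effects entirely (plain GLM/OLS).
    """

    response: str
    family: str = "poisson_log"
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] | None = None
    subject_col: str = "subject_id"

    def __post_init__(self) -> None:
        if self.family not in ("poisson_log", "gaussian_identity"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class Coefficient:
    b: float
    se: float
    stat: float
    p: float


@dataclass(frozen=True)
class FTestResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class ModelFit:
    """Fitted-model contract: link-scale coefficients, F-tests, diagnostics."""

    coefficients: dict[str, Coefficient]
    f_tests: dict[str, FTestResult] = field(default_factory=dict)
    converged: bool = True
    loglik: float = np.nan
    variance_components: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    warnings: list[str] = field(default_factory=list)

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.coefficients),
                "b": [c.b for c in self.coefficients.values()],
                "se": [c.se for c in self.coefficients.values()],
                "stat": [c.stat for c in self.coefficients.values()],
                "p": [c.p for c in self.coefficients.values()],
            }
        )


def build_fixed_design(
    data: pd.DataFrame, factors: tuple[str, ...]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Full-factorial treatment-coded design matrix.

    Returns (X, term_names, groups) where groups maps each factor/interaction
    label (e.g. ``"Drug:CS Period"``) to its column indices in X. The first
    level of each factor (sorted) is the reference.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["Intercept"]
    groups: dict[str, list[int]] = {}
    dummies: dict[str, dict[str, np.ndarray]] = {}
    for f in factors:
        levels = sorted(map(str, data[f].astype(str).unique()))
        dummies[f] = {
            lv: (data[f].astype(str) == lv).to_numpy(float) for lv in levels[1:]
        }
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            label = ":".join(combo)
            groups[label] = []
            for lvs in itertools.product(*(sorted(dummies[f]) for f in combo)):
                col = np.ones(len(data))
                for f, lv in zip(combo, lvs):
                    col = col * dummies[f][lv]
                name = ":".join(f"{f}[{lv}]" for f, lv in zip(combo, lvs))
                groups[label].append(len(names))
                names.append(name)
                cols.append(col)
    return np.column_stack(cols), names, groups


def _random_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], list[np.ndarray]]:
    """Indicator design for by-subject uncorrelated intercepts.

    One variance component for the plain subject intercept and one per
    within-subject factor (indicator columns for each subject x level cell).
    Returns (Z, component_names, column_index_arrays).
    """
    subj = data[spec.subject_col].astype(str)
    blocks, names, idx = [], [], []
    start = 0

    def add(component: str, key: pd.Series) -> None:
        nonlocal start
        d = pd.get_dummies(key, dtype=float)
        blocks.append(d.to_numpy())
        names.append(component)
        idx.append(np.arange(start, start + d.shape[1]))
        start += d.shape[1]

    add("subject", subj)
    for f in spec.random or ():
        add(f"subject:{f}", subj.str.cat(data[f].astype(str), sep="|"))
    return np.hstack(blocks), names, idx


def _poisson_loglik(y, eta):
    return float(np.sum(y * eta - np.exp(eta) - scipy.special.gammaln(y + 1)))


def _inner_newton(y, X, Z, d_inv, beta0, u0, max_iter=100, tol=1e-9):
    """Maximize the penalized Poisson log-likelihood jointly over (beta, u)."""
    p, q = X.shape[1], Z.shape[1]
    beta, u = beta0.copy(), u0.copy()

    def objective(beta, u):
        eta = X @ beta + Z @ u
        return _poisson_loglik(y, eta) - 0.5 * float(u @ (d_inv * u)), eta

    f_cur, eta = objective(beta, u)
    for _ in range(max_iter):
        mu = np.exp(eta)
        grad = np.concatenate([X.T @ (y - mu), Z.T @ (y - mu) - d_inv * u])
        Xw = X * mu[:, None]
        Zw = Z * mu[:, None]
        H = np.block([[X.T @ Xw, X.T @ Zw], [Zw.T @ X, Z.T @ Zw + np.diag(d_inv)]])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            b_new = beta + t * step[:p]
            u_new = u + t * step[p:]
            f_new, eta_new = objective(b_new, u_new)
            if f_new >= f_cur - 1e-12:
                break
            t /= 2.0
        moved = abs(f_new - f_cur)
        beta, u, eta, f_cur = b_new, u_new, eta_new, f_new
        if moved < tol and float(np.max(np.abs(grad))) < 1e-6:
            return beta, u, eta, f_cur, True
    return beta, u, eta, f_cur, False


def _laplace_marginal(y, X, Z, d_inv, beta0, u0):
    beta, u, eta, f_pen, ok = _inner_newton(y, X, Z, d_inv, beta0, u0)
    mu = np.exp(eta)
    H_uu = (Z * mu[:, None]).T @ Z + np.diag(d_inv)
    sign, logdet_h = np.linalg.slogdet(H_uu)
    logdet_d = -float(np.sum(np.log(d_inv)))  # log det D
    ll = f_pen - 0.5 * logdet_d - 0.5 * logdet_h
    return ll, beta, u, mu, ok


def fit_count_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit the specified mixed-effects model to a tidy response table.

    Poisson/log responses use the in-house Laplace fit (exact IRLS GLM when
    the random structure is empty); Gaussian responses use statsmodels
    (MixedLM, or OLS without random effects). Wald F-tests are reported for
    every fixed-effect term group spanning more than one coefficient, i.e.
    factors or interactions with at least three cells. Non-convergence is
    flagged, never silent.
    """
    notes: list[str] = []
    data = data.reset_index(drop=True)
    if data[spec.subject_col].nunique() < 2:
        raise ValueError("fit_count_model needs at least 2 subjects")
    cells = data.groupby([*spec.fixed], observed=True).size() if spec.fixed else None
    if cells is not None:
        n_expected = int(np.prod([data[f].nunique() for f in spec.fixed]))
        if len(cells) < n_expected:
            notes.append("not all factor combinations are represented")

    if spec.family == "gaussian_identity":
        return _fit_gaussian(spec, data, notes)

    y = data[spec.response].to_numpy(float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("poisson_log family requires non-negative integer counts")
    X, names, groups = build_fixed_design(data, spec.fixed)

    if spec.random is None:
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        V = np.asarray(glm.cov_params())
        fit = _package_fit(
            np.asarray(glm.params), V, names, groups, len(y),
            float(glm.llf), {}, bool(glm.converged), notes,
        )
        return fit

    Z, comp_names, comp_idx = _random_design(data, spec)
    q = Z.shape[1]

    glm0 = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    beta0 = np.asarray(glm0.params)
    u0 = np.zeros(q)

    def d_inv_from(log_sd: np.ndarray) -> np.ndarray:
        var = np.exp(2.0 * np.clip(log_sd, -8.0, 4.0))
        d = np.empty(q)
        for v, idx in zip(var, comp_idx):
            d[idx] = v
        return 1.0 / d

    def neg_marginal(log_sd: np.ndarray) -> float:
        ll, *_ = _laplace_marginal(y, X, Z, d_inv_from(log_sd), beta0, u0)
        return -ll

    x0 = np.full(len(comp_names), np.log(0.3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = scipy.optimize.minimize(
            neg_marginal, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
    d_inv = d_inv_from(opt.x)
    ll, beta, u, mu, inner_ok = _laplace_marginal(y, X, Z, d_inv, beta0, u0)

    # beta covariance from the joint Hessian at the optimum
    Xw = X * mu[:, None]
    Zw = Z * mu[:, None]
    A = X.T @ Xw
    B = X.T @ Zw
    C = Z.T @ Zw + np.diag(d_inv)
    V = np.linalg.inv(A - B @ np.linalg.solve(C, B.T))

    sds = np.exp(np.clip(opt.x, -8.0, 4.0))
    vcs = {name: float(sd**2) for name, sd in zip(comp_names, sds)}
    converged = bool(opt.success and inner_ok)
    if not converged:
        notes.append(f"optimizer status: {opt.message}; inner Newton ok: {inner_ok}")
    return _package_fit(beta, V, names, groups, len(y), float(ll), vcs,
                        converged, notes)


def _package_fit(beta, V, names, groups, n_obs, loglik, vcs, converged, notes):
    se = np.sqrt(np.clip(np.diag(V), 0, None))
    coefs = {}
    for i, name in enumerate(names):
        z = beta[i] / se[i] if se[i] > 0 else np.nan
        p = 2.0 * scipy.stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        coefs[name] = Coefficient(float(beta[i]), float(se[i]), float(z), float(p))
    p_fixed = len(names)
    f_tests = {}
    for label, idx in groups.items():
        if len(idx) < 2:
            continue
        b_g = beta[idx]
        V_g = V[np.ix_(idx, idx)]
        try:
            stat = float(b_g @ np.linalg.solve(V_g, b_g)) / len(idx)
        except np.linalg.LinAlgError:
            continue
        df2 = max(n_obs - p_fixed, 1)
        f_tests[label] = FTestResult(
            stat, len(idx), df2, float(scipy.stats.f.sf(stat, len(idx), df2))
        )
    return ModelFit(coefs, f_tests, converged, loglik, vcs, n_obs, notes)


def _fit_gaussian(spec: ModelSpec, data: pd.DataFrame, notes: list[str]) -> ModelFit:
    data = data.dropna(subset=[spec.response]).copy()
    data["_resp"] = data[spec.response].astype(float)
    rhs = " * ".join(f"C(Q('{f}'))" for f in spec.fixed) if spec.fixed else "1"
    formula = f"_resp ~ {rhs}"
    if spec.random is None:
        res = smf.ols(formula, data=data).fit()
        converged = True
        vcs = {}
    else:
        vc = {f: f"0 + C(Q('{f}'))" for f in spec.random} or None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(
                formula, data=data, groups=data[spec.subject_col],
                re_formula="1", vc_formula=vc,
            ).fit()
        converged = bool(res.converged)
        vcs = {"subject": float(res.cov_re.iloc[0, 0])}
        vcs.update({k: float(v) for k, v in res.vcomp_to_dict().items()}
                   if hasattr(res, "vcomp_to_dict") else {})
    if not converged:
        notes.append("gaussian mixed model did not converge")
    params = res.params
    bse = res.bse
    pvals = res.pvalues
    coefs = {
        name: Coefficient(float(params[name]), float(bse[name]),
                          float(params[name] / bse[name]) if bse[name] > 0 else np.nan,
                          float(pvals[name]))
        for name in params.index
        if not name.startswith("Group") and name != "Group Var"
    }
    return ModelFit(coefs, {}, converged, float(res.llf), vcs, len(data), notes)
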