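"""Log-scale information-theoretic inference on the per-bear table.

The response is the natural log of the MCP95 area (km²). A predefined
candidate set of linear models (sex, log mass, standardised linear size
metrics, PC scores, sampling-effort covariates, sex x mass interaction) is
compared with AICc,

    AICc = -2 ln L + 2K + 2K(K+1) / (n - K - 1),

where K counts the intercept, slopes and the residual variance. Akaike
weights are ``exp(-delta_i/2)`` renormalised over the set; evidence ratios
are ``w_best / w_i``. All candidates are fit on the identical complete-case
subset so their likelihoods are comparable. Model-averaged coefficients use
natural averaging (weights renormalised over the models containing each
term) with unconditional standard errors
``sqrt(sum w (se² + (beta - beta_bar)²))``.

Sex is coded F=0, M=1 (female reference). Back-transformed coefficients are
reported as male:female ratios, ``base**beta`` with Wald 95% intervals.
Distributional contrasts between the sexes use the Fligner–Killeen test,
a permutation energy-distance test, and quantile regression at
tau = 0.25/0.50/0.75 (sex-only design, solved exactly via group
check-loss quantiles; bootstrap percentile CIs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InferenceError, ParameterError, SingularDesignError

TERMS = (
    "sex", "log_mass", "z_body_length", "z_chest_circ", "pc1", "pc2",
    "log_n_fixes", "tracking_days", "sex:log_mass",
)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    terms: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = set(self.terms) - set(TERMS)
        if unknown:
            raise ParameterError(f"unknown model terms: {sorted(unknown)}")
        if "sex:log_mass" in self.terms and not {"sex", "log_mass"} <= set(self.terms):
            raise ParameterError("interaction requires both main effects")


def candidate_models() -> list[ModelSpec]:
    """The default candidate set: null, mass, sex, additive, interaction."""
    return [
        ModelSpec("Sex", ("sex",)),
        ModelSpec("Additive", ("sex", "log_mass")),
        ModelSpec("Interaction", ("sex", "log_mass", "sex:log_mass")),
        ModelSpec("Mass", ("log_mass",)),
        ModelSpec("Null", ()),
    ]


def _design(table: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Build the design columns (no intercept) for the requested terms.

    ``z_*`` covariates are standardised (mean 0, SD 1 with n-1) on the rows
    that end up in the fit; ``log_*`` are natural logs.
    """
    cols = {}
    for term in terms:
        if term == "sex":
            cols["sex_M"] = (table["sex"] == "M").astype(float).where(table["sex"].notna())
        elif term == "log_mass":
            cols["log_mass"] = np.log(table["mass_kg"])
        elif term == "z_body_length":
            cols["z_body_length"] = table["body_length_cm"]
        elif term == "z_chest_circ":
            cols["z_chest_circ"] = table["chest_circ_cm"]
        elif term == "pc1":
            cols["pc1"] = table["pc1"]
        elif term == "pc2":
            cols["pc2"] = table["pc2"]
        elif term == "log_n_fixes":
            cols["log_n_fixes"] = np.log(table["n_fixes"].astype(float))
        elif term == "tracking_days":
            cols["tracking_days"] = table["tracking_days"].astype(float)
        elif term == "sex:log_mass":
            pass  # built after mains, below
    x = pd.DataFrame(cols, index=table.index)
    if "sex:log_mass" in terms:
        x["sex_M:log_mass"] = x["sex_M"] * x["log_mass"]
    return x


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    llf: float
    n: int
    K: int                      # intercept + slopes + residual variance
    resid: pd.Series
    leverage: np.ndarray
    cooks_d: np.ndarray
    row_index: pd.Index
    base: str = "e"             # log base of the response, for back-transforms

    @property
    def aicc(self) -> float:
        n, k = self.n, self.K
        if n - k - 1 <= 0:
            raise InferenceError(f"n={n} too small for K={k} (AICc undefined)")
        return -2.0 * self.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_lm(
    table: pd.DataFrame,
    spec: ModelSpec,
    response: str = "log_mcp",
    base: str = "e",
) -> FitResult:
    """OLS fit of one candidate model on its complete cases."""
    x = _design(table, spec.terms)
    data = pd.concat([table[response].rename("_y"), x], axis=1).dropna()
    y = data["_y"].to_numpy()
    xmat = data.drop(columns="_y")
    for col in xmat.columns:
        if col.startswith("z_"):
            v = xmat[col]
            xmat[col] = (v - v.mean()) / v.std(ddof=1)
    exog = sm.add_constant(xmat, has_constant="add")
    n, p = exog.shape
    if n <= p + 1:
        raise InferenceError(f"model {spec.name!r}: n={n} <= K={p + 1}")
    if np.linalg.matrix_rank(exog.to_numpy()) < p:
        raise SingularDesignError(
            f"model {spec.name!r}: design is rank deficient over columns {list(exog.columns)}"
        )
    res = sm.OLS(y, exog).fit()
    infl = res.get_influence()
    # R^2 of an (effectively) constant response is reported as 0
    tss = float(((y - y.mean()) ** 2).sum())
    varying = tss > 1e-12 * max(1.0, float((y**2).sum()))
    return FitResult(
        spec=spec,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared) if varying else 0.0,
        adj_r2=float(res.rsquared_adj) if varying else 0.0,
        llf=float(res.llf),
        n=n,
        K=p + 1,
        resid=pd.Series(res.resid, index=data.index),
        leverage=infl.hat_matrix_diag,
        cooks_d=infl.cooks_distance[0],
        row_index=data.index,
        base=base,
    )


def aicc_weights(delta: np.ndarray) -> np.ndarray:
    w = np.exp(-0.5 * np.asarray(delta, dtype=float))
    return w / w.sum()


def aicc_table(
    table: pd.DataFrame, specs: Iterable[ModelSpec], response: str = "log_mcp"
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit all candidates on the common complete-case subset and rank by AICc."""
    specs = list(specs)
    if len(specs) < 2:
        raise ParameterError("need >= 2 candidate models")
    all_terms = sorted({t for s in specs for t in s.terms})
    common = pd.concat(
        [table[response].rename("_y"), _design(table, all_terms)], axis=1
    ).dropna().index
    sub = table.loc[common]
    fits = {s.name: fit_lm(sub, s, response) for s in specs}
    rows = []
    for s in specs:
        f = fits[s.name]
        rows.append({"model": s.name, "K": f.K, "AICc": f.aicc, "R2": f.r2, "n_used": f.n})
    out = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    out["dAICc"] = out["AICc"] - out["AICc"].min()
    out["weight"] = aicc_weights(out["dAICc"].to_numpy())
    out["evidence_ratio"] = out["weight"].iloc[0] / out["weight"]
    return out, fits


def model_average(
    selection: pd.DataFrame, fits: dict[str, FitResult]
) -> pd.DataFrame:
    """Natural model-averaged coefficients with unconditional SEs.

    For each coefficient, weights are renormalised over the models that
    contain it; the unconditional SE folds in the between-model spread.
    """
    weights = selection.set_index("model")["weight"]
    terms: dict[str, list[tuple[float, float, float]]] = {}
    for name, fit in fits.items():
        w = float(weights[name])
        for term in fit.params.index:
            terms.setdefault(term, []).append((w, float(fit.params[term]), float(fit.bse[term])))
    rows = []
    for term, entries in terms.items():
        w = np.array([e[0] for e in entries])
        b = np.array([e[1] for e in entries])
        se = np.array([e[2] for e in entries])
        w = w / w.sum()
        bbar = float(np.sum(w * b))
        use = math.sqrt(float(np.sum(w * (se**2 + (b - bbar) ** 2))))
        rows.append({
            "term": term, "estimate": bbar, "unconditional_se": use,
            "ci_low": bbar - 1.96 * use, "ci_high": bbar + 1.96 * use,
            "weight_sum": float(np.sum([e[0] for e in entries])),
        })
    return pd.DataFrame(rows).set_index("term")


def backtransform_ratio(beta: float, se: float = 0.0, base: str = "e"):
    """Back-transform a log-scale contrast to a multiplicative ratio with
    a Wald 95% CI: ``ratio = base**beta``, CI ``base**(beta ± 1.96 se)``."""
    if base == "e":
        f = math.exp
    elif base in ("10", 10):
        f = lambda v: 10.0**v
    else:
        raise ParameterError("base must be 'e' or 10")
    return f(beta), (f(beta - 1.96 * se), f(beta + 1.96 * se))


# ---------------------------------------------------------------------------
# Quantile regression (sex-only design)
# ---------------------------------------------------------------------------

def check_loss_quantile(x: np.ndarray, tau: float) -> float:
    """Exact minimiser of the pinball (check) loss for a sample.

    Returns the order statistic ``x_(ceil(n tau))`` when ``n tau`` is not an
    integer; when it is, the minimiser is the interval
    ``[x_(n tau), x_(n tau + 1)]`` and the lower endpoint is returned.
    """
    if not 0 < tau < 1:
        raise ParameterError("tau must be in (0, 1)")
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n == 0:
        raise InferenceError("empty sample")
    k = n * tau
    idx = int(round(k)) if abs(k - round(k)) < 1e-9 else int(math.ceil(k))
    return float(xs[max(idx, 1) - 1])


def quantile_fits(
    table: pd.DataFrame,
    taus: Sequence[float] = (0.25, 0.50, 0.75),
    response: str = "log_mcp",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[float, dict]:
    """Quantile regression of the response on sex, per tau.

    For this single binary predictor the check-loss solution is exact:
    the intercept is the female tau-quantile and the sex coefficient the
    male-female quantile difference. CIs are case-resampling bootstrap
    percentile intervals (within-sex resampling), seeded.
    """
    data = table.dropna(subset=[response, "sex"])
    xf = data.loc[data["sex"] == "F", response].to_numpy()
    xm = data.loc[data["sex"] == "M", response].to_numpy()
    if len(xf) == 0 or len(xm) == 0:
        raise InferenceError("both sexes must be present for quantile fits")
    rng = np.random.default_rng(seed)
    bf = rng.integers(0, len(xf), size=(n_boot, len(xf)))
    bm = rng.integers(0, len(xm), size=(n_boot, len(xm)))
    out = {}
    for tau in taus:
        beta = check_loss_quantile(xm, tau) - check_loss_quantile(xf, tau)
        boots = np.array(
            [check_loss_quantile(xm[bm[i]], tau) - check_loss_quantile(xf[bf[i]], tau)
             for i in range(n_boot)]
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out[float(tau)] = {
            "beta": float(beta),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "ratio": math.exp(beta),
            "intercept": check_loss_quantile(xf, tau),
        }
    return out


# ---------------------------------------------------------------------------
# Distributional comparisons
# ---------------------------------------------------------------------------

def dispersion_test(groups: Sequence[np.ndarray]):
    """Fligner–Killeen homogeneity-of-variance test plus per-group IQRs.

    Returns ``(chi2, df, p, iqrs)``; the statistic is referred to a
    chi-square law with (number of groups - 1) df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        raise InferenceError("dispersion test needs >= 2 groups with >= 3 values each")
    stat, p = stats.fligner(*groups)
    iqrs = [float(np.percentile(g, 75) - np.percentile(g, 25)) for g in groups]
    return float(stat), len(groups) - 1, float(p), iqrs


def energy_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample energy distance statistic
    ``E = 2 mean|xi - yj| - mean|xi - xi'| - mean|yj - yj'|``.

    All three means run over all ordered pairs (the V-statistic form), so
    E = 0 when the two samples are identical and E >= 0 in expectation
    under equal distributions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InferenceError("energy statistic needs >= 2 values per sample")
    dxy = np.abs(x[:, None] - y[None, :]).mean()
    dxx = np.abs(x[:, None] - x[None, :]).mean()
    dyy = np.abs(y[:, None] - y[None, :]).mean()
    return float(2.0 * dxy - dxx - dyy)


def energy_perm_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Permutation energy-distance test of equal distributions.

    Labels of the pooled sample are permuted ``n_perm`` times;
    ``p = (1 + #{E_perm >= E_obs}) / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    obs = energy_stat(x, y)
    pooled = np.concatenate([x, y])
    n = nx + ny
    dist = np.abs(pooled[:, None] - pooled[None, :])
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 256
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(m)])
        sub = dist[perms[:, :, None], perms[:, None, :]]  # (m, n, n)
        wx = sub[:, :nx, :nx].mean(axis=(1, 2))
        wy = sub[:, nx:, nx:].mean(axis=(1, 2))
        cross = sub[:, :nx, nx:].mean(axis=(1, 2))
        e = 2.0 * cross - wx - wy
        count += int(np.sum(e >= obs - 1e-12))
        done += m
    p = (1.0 + count) / (n_perm + 1.0)
    return obs, float(p)


# ---------------------------------------------------------------------------
# Diagnostics and robustness refits
# ---------------------------------------------------------------------------

def diagnostics(fit: FitResult, table: pd.DataFrame, cook_threshold: float | None = None) -> dict:
    """Influence screening and a leave-out-influential refit.

    Flags observations with Cook's distance above ``4/n`` (default), then
    refits the same model without them and reports the sex coefficient's
    sign and CI from both fits.
    """
    thr = 4.0 / fit.n if cook_threshold is None else cook_threshold
    flagged_pos = np.nonzero(fit.cooks_d > thr)[0]
    flagged_idx = fit.row_index[flagged_pos]
    report = {
        "cook_threshold": thr,
        "influential_ids": (
            table.loc[flagged_idx, "animal_id"].tolist()
            if "animal_id" in table.columns else list(flagged_idx)
        ),
        "max_cooks_d": float(fit.cooks_d.max()),
        "max_leverage": float(fit.leverage.max()),
    }
    if "sex_M" in fit.params.index:
        b, se = float(fit.params["sex_M"]), float(fit.bse["sex_M"])
        report["sex_coef"] = {"estimate": b, "ci": (b - 1.96 * se, b + 1.96 * se)}
        if len(flagged_idx) and fit.n - len(flagged_idx) > fit.K:
            refit = fit_lm(table.drop(index=flagged_idx), fit.spec)
            b2, se2 = float(refit.params["sex_M"]), float(refit.bse["sex_M"])
            report["sex_coef_without_influential"] = {
                "estimate": b2,
                "ci": (b2 - 1.96 * se2, b2 + 1.96 * se2),
                "sign_agrees": (b > 0) == (b2 > 0),
            }
    return report


def robustness_refits(table: pd.DataFrame, terms: tuple[str, ...] = ("sex",)) -> dict:
    """Scale/link robustness checks on the *raw* MCP response.

    (i) OLS on untransformed mcp_km2 with HC3 covariance; (ii) Gamma GLM
    with a log link (IRLS). Returns the sex coefficient and CI from each —
    an agreement report, not a hypothesis decision.
    """
    if table["sex"].dropna().nunique() < 2:
        raise InferenceError("robustness refits need both sexes in the table")
    x = _design(table, terms)
    data = pd.concat([table["mcp_km2"].rename("_y"), x], axis=1).dropna()
    if (data["_y"] <= 0).any():
        raise InferenceError("mcp_km2 must be positive for the Gamma refit")
    exog = sm.add_constant(data.drop(columns="_y"), has_constant="add")
    y = data["_y"].to_numpy()

    ols_cls = sm.OLS(y, exog).fit()
    ols_hc3 = sm.OLS(y, exog).fit(cov_type="HC3")
    gamma = sm.GLM(y, exog, family=sm.families.Gamma(link=sm.families.links.Log())).fit()

    def coef(res, name="sex_M"):
        b, se = float(res.params[name]), float(res.bse[name])
        return {"estimate": b, "se": se, "ci": (b - 1.96 * se, b + 1.96 * se)}

    return {
        "ols_hc3": coef(ols_hc3),
        "ols_classical_se": float(ols_cls.bse["sex_M"]),
        "gamma_log": coef(gamma),
        "signs_agree": (ols_hc3.params["sex_M"] > 0) == (gamma.params["sex_M"] > 0),
    }
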