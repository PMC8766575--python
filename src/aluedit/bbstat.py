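"""Beta-binomial regression with likelihood-ratio tests.

Counts k_i of n_i trials (edited reads of informative reads at a site,
or back-splice reads of total junction reads in a gene) are modeled as
beta-binomial with mean mu_i = logistic(x_i' beta) and a shared
intraclass correlation rho in [0, 1): the Beta mixing parameters are
a_i = mu_i (1-rho)/rho and b_i = (1-mu_i)(1-rho)/rho, so rho -> 0
recovers the plain binomial likelihood. The design matrix carries an
intercept, a tumor indicator and fixed-effect patient indicators
(first patient as reference), mirroring a paired tumor-normal design
with patient as covariate. Significance of the condition term comes
from a likelihood-ratio test against the model without it, chi-square
with one degree of freedom, with Benjamini-Hochberg correction across
units and a strict FDR < 0.05 call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

RHO_MIN, RHO_MAX = 1e-6, 1.0 - 1e-6
_BINOMIAL_RHO = 1e-9  # below this, evaluate the binomial limit directly


def build_design(
    condition: np.ndarray, patient: np.ndarray, include_condition: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, tumor indicator, patient dummies
    (reference = first patient in order of appearance)."""
    patients = list(dict.fromkeys(patient))
    cols = [np.ones(len(condition))]
    names = ["intercept"]
    if include_condition:
        cols.append((np.asarray(condition) == "tumor").astype(float))
        names.append("condition_tumor")
    for p in patients[1:]:
        cols.append((np.asarray(patient) == p).astype(float))
        names.append(f"patient_{p}")
    return np.column_stack(cols), names


def bb_loglik(
    k: np.ndarray, n: np.ndarray, X: np.ndarray, beta: np.ndarray, rho: float
) -> float:
    """Beta-binomial log-likelihood in the (mu, rho) parameterization."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"dispersion rho must lie in [0, 1), got {rho}")
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = X @ beta
    mu = special.expit(eta)
    binom_coef = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    if rho < _BINOMIAL_RHO:
        # binomial limit, written to tolerate mu at the boundaries
        with np.errstate(divide="ignore", invalid="ignore"):
            term = k * np.log(mu) + (n - k) * np.log1p(-mu)
        term = np.where((k == 0) & (mu == 0.0), 0.0, term)
        term = np.where((k == n) & (mu == 1.0), 0.0, term)
        return float(np.sum(binom_coef + term))
    # keep mu off the boundaries so the Beta parameters stay positive
    # when the optimizer wanders to extreme coefficients
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return float(
        np.sum(binom_coef + special.betaln(k + a, n - k + b) - special.betaln(a, b))
    )


@dataclass
class BetaBinomialFit:
    """Maximum-likelihood fit of one unit (site or gene)."""

    coefficients: dict[str, float]
    rho: float
    loglik: float
    converged: bool
    degenerate: bool
    n_obs: int
    data_key: int  # hash of (k, n) to guard LRT pairing

    @property
    def condition_effect(self) -> float | None:
        return self.coefficients.get("condition_tumor")


def _data_key(k: np.ndarray, n: np.ndarray) -> int:
    return hash((tuple(np.asarray(k, dtype=int)), tuple(np.asarray(n, dtype=int))))


def fit_bb_regression(
    observations: pd.DataFrame,
    include_condition: bool = True,
) -> BetaBinomialFit:
    """Fit the beta-binomial regression for one unit.

    ``observations`` needs columns k, n, condition, patient_id. The
    optimizer is L-BFGS-B from a fixed start (intercept at the logit of
    the pooled rate, other coefficients 0, rho = 0.01), so the fit is
    deterministic given the data. Units with k identically 0 or
    identically n are returned as flagged boundary fits.
    """
    k = observations["k"].to_numpy(dtype=float)
    n = observations["n"].to_numpy(dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n for every observation")
    X, names = build_design(
        observations["condition"].to_numpy(),
        observations["patient_id"].to_numpy(),
        include_condition,
    )
    key = _data_key(k, n)

    if k.sum() == 0 or (n - k).sum() == 0:
        # boundary: no variation in the success indicator at all
        pooled = np.clip(k.sum() / max(n.sum(), 1.0), 1e-9, 1 - 1e-9)
        beta = np.zeros(X.shape[1])
        beta[0] = special.logit(pooled)
        ll = bb_loglik(k, n, X, beta, RHO_MIN)
        return BetaBinomialFit(
            coefficients=dict(zip(names, beta)),
            rho=RHO_MIN,
            loglik=ll,
            converged=False,
            degenerate=True,
            n_obs=len(k),
            data_key=key,
        )

    pooled = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = special.logit(pooled)
    x0[-1] = 0.01  # rho start

    def negll(theta: np.ndarray) -> float:
        return -bb_loglik(k, n, X, theta[:-1], theta[-1])

    bounds = [(None, None)] * X.shape[1] + [(RHO_MIN, RHO_MAX)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
    beta = res.x[:-1]
    return BetaBinomialFit(
        coefficients=dict(zip(names, beta)),
        rho=float(res.x[-1]),
        loglik=-float(res.fun),
        converged=bool(res.success),
        degenerate=False,
        n_obs=len(k),
        data_key=key,
    )


def lrt_condition(
    full: BetaBinomialFit, reduced: BetaBinomialFit
) -> tuple[float, float]:
    """Likelihood-ratio test of the condition term, chi-square df = 1."""
    if full.data_key != reduced.data_key or full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced fits are not from the same data")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def estimate_dispersion_moment(
    k: np.ndarray, n: np.ndarray, mu: np.ndarray, n_params: int
) -> float:
    """Degrees-of-freedom-corrected Pearson moment estimate of rho.

    Solves sum_i r_i^2 / (1 + (n_i - 1) rho) = N - p with
    r_i^2 = (k_i - n_i mu_i)^2 / (n_i mu_i (1 - mu_i)), the beta-binomial
    variance identity. The df correction undoes the downward bias of
    joint ML when many mean parameters (patient effects) are fitted to
    few observations.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    r2 = (k - n * mu) ** 2 / np.maximum(n * mu * (1.0 - mu), 1e-12)
    target = len(k) - n_params
    if target <= 0:
        return RHO_MIN

    def excess(rho: float) -> float:
        return float(np.sum(r2 / (1.0 + (n - 1.0) * rho)) - target)

    if excess(0.0) <= 0.0:
        return RHO_MIN
    if excess(RHO_MAX) >= 0.0:
        return RHO_MAX
    return float(optimize.brentq(excess, 0.0, RHO_MAX))


def _fit_mean_fixed_rho(
    k: np.ndarray, n: np.ndarray, X: np.ndarray, rho: float, x0: np.ndarray | None = None
):
    if x0 is None:
        pooled = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
        x0 = np.zeros(X.shape[1])
        x0[0] = special.logit(pooled)
    return optimize.minimize(
        lambda b: -bb_loglik(k, n, X, b, rho), x0, method="L-BFGS-B"
    )


def ql_condition_test(observations: pd.DataFrame) -> dict:
    """Quasi-likelihood test of the condition term.

    Estimates the shared dispersion by the df-corrected moment equation
    (two alternating iterations with the full mean model), refits full
    and reduced mean models at that fixed rho, and refers twice the
    log-likelihood-ratio to F(1, N - p_full) — the residual-df reference
    that keeps the test calibrated when patient effects leave only two
    observations per patient (plain chi-square(1) is anticonservative
    there). Falls back to chi-square(1) when no residual df remain.

    Returns statistic, p_value, condition_effect, rho, converged.
    """
    k = observations["k"].to_numpy(dtype=float)
    n = observations["n"].to_numpy(dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n for every observation")
    cond = observations["condition"].to_numpy()
    pat = observations["patient_id"].to_numpy()
    Xf, names = build_design(cond, pat, include_condition=True)
    Xr, _ = build_design(cond, pat, include_condition=False)

    rho = 0.01
    full = _fit_mean_fixed_rho(k, n, Xf, rho)
    for _ in range(2):
        mu = np.clip(special.expit(Xf @ full.x), 1e-12, 1 - 1e-12)
        rho = max(estimate_dispersion_moment(k, n, mu, Xf.shape[1]), RHO_MIN)
        full = _fit_mean_fixed_rho(k, n, Xf, rho, x0=full.x)
    reduced = _fit_mean_fixed_rho(k, n, Xr, rho)
    stat = max(0.0, 2.0 * (-full.fun + reduced.fun))
    resid_df = len(k) - Xf.shape[1]
    if resid_df >= 1:
        p = float(stats.f.sf(stat, 1, resid_df))
    else:
        p = float(stats.chi2.sf(stat, df=1))
    effect_idx = names.index("condition_tumor")
    return {
        "statistic": stat,
        "p_value": p,
        "condition_effect": float(full.x[effect_idx]),
        "rho": rho,
        "converged": bool(full.success and reduced.success),
    }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    observations: pd.DataFrame,
    unit_col: str = "unit_id",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-unit differential test of tumor vs normal proportions.

    For every unit: the quasi-likelihood condition test (df-corrected
    moment dispersion, F reference — see ``ql_condition_test``),
    observed mean proportion per condition and their difference
    (tumor - normal). Degenerate units (k identically 0 or n) are
    reported with p = 1 rather than dropped. BH correction across
    units; significant iff FDR-adjusted p < fdr (strict).
    """
    rows = []
    for unit_id, group in observations.groupby(unit_col, sort=True):
        with np.errstate(invalid="ignore"):
            prop = group["k"] / group["n"].replace(0, np.nan)
        mean_tumor = float(prop[group["condition"] == "tumor"].mean())
        mean_normal = float(prop[group["condition"] == "normal"].mean())
        k = group["k"].to_numpy(dtype=float)
        n = group["n"].to_numpy(dtype=float)
        if k.sum() == 0 or (n - k).sum() == 0:
            res = {
                "statistic": 0.0, "p_value": 1.0, "condition_effect": 0.0,
                "rho": RHO_MIN, "converged": False,
            }
            degenerate = True
        else:
            res = ql_condition_test(group)
            degenerate = False
        rows.append(
            {
                "unit_id": unit_id,
                "condition_effect": res["condition_effect"],
                "lrt_stat": res["statistic"],
                "p_value": res["p_value"],
                "mean_tumor": mean_tumor,
                "mean_normal": mean_normal,
                "difference": mean_tumor - mean_normal,
                "rho": res["rho"],
                "converged": res["converged"],
                "degenerate": degenerate,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "condition_effect", "lrt_stat", "p_value",
            "mean_tumor", "mean_normal", "difference", "rho",
            "converged", "degenerate",
        ],
    )
    if len(result):
        result["fdr_adjusted_p"] = bh_adjust(result["p_value"].to_numpy())
        result["significant"] = result["fdr_adjusted_p"] < fdr
    else:
        result["fdr_adjusted_p"] = []
        result["significant"] = []
    return result
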