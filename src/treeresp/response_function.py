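"""Response-function fitting: quadratic, linear, Gaussian, AIC comparison.

Curves regress individual predicted performance (PMAI) on a single climatic
gradient variable, at the population level (all individuals pooled) and per
half-sib family.  The quadratic is fit internally on a standardized climate
axis for conditioning and back-transformed, so reported coefficients and the
vertex are on the raw scale.

AIC is the least-squares form ``n * log(RSS / n) + 2 * k`` with ``k`` the
number of mean parameters (the additive Gaussian constant is dropped, which
cancels in comparisons on identical data).  Ties are broken toward the
simpler family in the order linear < quadratic < gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats

_FAMILY_ORDER = {"linear": 0, "quadratic": 1, "gaussian": 2}


class FitError(ValueError):
    pass


@dataclass
class ResponseCurve:
    level: str  # "population" or a family id
    model: str  # linear | quadratic | gaussian
    params: dict
    n_obs: int
    rss: float
    r2: float
    adj_r2: float
    p_value: float
    aic: float
    vertex: Optional[tuple]  # (c*, v*) when the curve has an interior maximum
    converged: bool = True
    data_key: tuple = ()

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        p = self.params
        if self.model == "linear":
            return p["beta0"] + p["beta1"] * c
        if self.model == "quadratic":
            return p["beta0"] + p["beta1"] * c + p["beta2"] * c * c
        return p["amplitude"] * np.exp(-((c - p["mode"]) ** 2) / (2 * p["scale"] ** 2))


def _data_key(c: np.ndarray, v: np.ndarray) -> tuple:
    return (len(c), round(float(np.sum(c)), 9), round(float(np.sum(v)), 9))


def aic_from_rss(n: int, rss: float, k: int) -> float:
    """Least-squares AIC, constant dropped (documented in the module docstring)."""
    if rss <= 0:
        return -np.inf
    return n * float(np.log(rss / n)) + 2 * k


def _check_inputs(c, v, min_distinct: int):
    c = np.asarray(c, dtype=float)
    v = np.asarray(v, dtype=float)
    if c.shape != v.shape or c.ndim != 1:
        raise FitError("c and v must be equal-length 1-d arrays")
    if len(np.unique(c)) < min_distinct:
        raise FitError(
            f"need at least {min_distinct} distinct climate values, "
            f"got {len(np.unique(c))}"
        )
    return c, v


def _ols_stats(y: np.ndarray, fitted: np.ndarray, k: int) -> tuple:
    """(rss, r2, adj_r2, F p-value) for a mean model with k parameters."""
    n = len(y)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - k
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    if tss <= 0 or rss <= 0 or dof <= 0 or k < 2:
        pval = np.nan if k < 2 else (0.0 if rss <= 0 < tss else 1.0)
    else:
        f = ((tss - rss) / (k - 1)) / (rss / dof)
        pval = float(stats.f.sf(f, k - 1, dof))
    return rss, r2, adj_r2, pval


def _polyfit(c: np.ndarray, v: np.ndarray, degree: int, standardize: bool) -> np.ndarray:
    """OLS polynomial coefficients (ascending) on the raw climate scale."""
    if standardize and np.std(c) > 0:
        mu, sd = float(np.mean(c)), float(np.std(c))
        z = (c - mu) / sd
        g = np.polynomial.polynomial.polyfit(z, v, degree)
        # back-transform p(z) with z = (c - mu)/sd to raw-scale coefficients
        poly = np.polynomial.Polynomial(g)(
            np.polynomial.Polynomial([-mu / sd, 1.0 / sd])
        )
        coef = poly.coef
        if len(coef) < degree + 1:
            coef = np.pad(coef, (0, degree + 1 - len(coef)))
        return coef
    return np.polynomial.polynomial.polyfit(c, v, degree)


def fit_linear(c, v, level: str = "population") -> ResponseCurve:
    c, v = _check_inputs(c, v, 2)
    b = _polyfit(c, v, 1, standardize=False)
    fitted = b[0] + b[1] * c
    rss, r2, adj, pval = _ols_stats(v, fitted, 2)
    return ResponseCurve(
        level, "linear", {"beta0": float(b[0]), "beta1": float(b[1])},
        len(v), rss, r2, adj, pval, aic_from_rss(len(v), rss, 2), None,
        data_key=_data_key(c, v),
    )


def fit_quadratic(c, v, level: str = "population", standardize: bool = True) -> ResponseCurve:
    """OLS fit of ``v = b0 + b1 c + b2 c^2`` with vertex, adjusted R2 and F-test."""
    c, v = _check_inputs(c, v, 3)
    b = _polyfit(c, v, 2, standardize)
    fitted = b[0] + b[1] * c + b[2] * c * c
    rss, r2, adj, pval = _ols_stats(v, fitted, 3)
    vertex = None
    if b[2] < 0:
        c_star = -b[1] / (2.0 * b[2])
        vertex = (float(c_star), float(b[0] + b[1] * c_star + b[2] * c_star**2))
    return ResponseCurve(
        level, "quadratic",
        {"beta0": float(b[0]), "beta1": float(b[1]), "beta2": float(b[2])},
        len(v), rss, r2, adj, pval, aic_from_rss(len(v), rss, 3), vertex,
        data_key=_data_key(c, v),
    )


def fit_gaussian(c, v, level: str = "population") -> ResponseCurve:
    """Nonlinear least squares for ``v = A exp(-(c - m)^2 / (2 s^2))``.

    Initialization: A = max(v), m = argmax location, s = half the climate
    range.  Non-convergence is flagged with an AIC of +inf so the curve can
    participate in (and lose) model comparison.
    """
    c, v = _check_inputs(c, v, 4)
    if np.max(v) <= 0:
        raise FitError("Gaussian model needs a positive amplitude")

    def model(x, amp, mode, scale):
        return amp * np.exp(-((x - mode) ** 2) / (2 * scale**2))

    p0 = (float(np.max(v)), float(c[np.argmax(v)]), float(np.ptp(c)) / 2 or 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, c, v, p0=p0,
            bounds=([1e-8, -np.inf, 1e-8], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        popt, converged = p0, False
    fitted = model(c, *popt)
    rss, r2, adj, pval = _ols_stats(v, fitted, 3)
    amp, mode, scale = (float(x) for x in popt)
    return ResponseCurve(
        level, "gaussian", {"amplitude": amp, "mode": mode, "scale": scale},
        len(v), rss, r2, adj, pval,
        aic_from_rss(len(v), rss, 3) if converged else np.inf,
        (mode, amp) if converged else None, converged,
        data_key=_data_key(c, v),
    )


def compare_models(curves: Sequence[ResponseCurve]) -> pd.DataFrame:
    """Delta-AIC table over curves fit to identical data; best model first.

    Raises if the curves were not fit on the same (c, v) data.  Ties go to
    the simpler model family (linear < quadratic < gaussian).
    """
    keys = {cu.data_key for cu in curves}
    if len(keys) != 1:
        raise FitError("model comparison requires fits on identical data")
    ordered = sorted(curves, key=lambda cu: (cu.aic, _FAMILY_ORDER[cu.model]))
    best_aic = ordered[0].aic
    return pd.DataFrame(
        {
            "model": [cu.model for cu in ordered],
            "aic": [cu.aic for cu in ordered],
            "delta_aic": [cu.aic - best_aic for cu in ordered],
            "selected": [i == 0 for i in range(len(ordered))],
        }
    )


def fit_all_levels(
    perf: pd.DataFrame,
    climate: pd.DataFrame,
    variable: str,
    min_obs: int = 4,
    standardize: bool = True,
    site_means: bool = False,
) -> tuple:
    """Population curve plus one quadratic per half-sib family.

    ``perf`` is a (trimmed) performance table with ``family``, ``site`` and
    ``pmai`` columns; ``climate`` supplies the gradient variable per site.
    Families with fewer than ``min_obs`` observations (or < 3 distinct
    climate values) are skipped with a warning.  Returns ``(curves, table)``
    where the table mirrors one row per fit: level, N_b, coefficients,
    vertex, adjusted R2, p-value.
    """
    if variable not in climate.columns:
        raise FitError(f"climate table lacks variable {variable!r}")
    cvals = climate.set_index("site")[variable]
    df = perf.copy()
    df["c"] = df["site"].map(cvals)
    if df["c"].isna().any():
        bad = sorted(df.loc[df["c"].isna(), "site"].unique())
        raise FitError(f"sites missing from climate table: {bad}")
    if site_means:
        df = df.groupby(["family", "site"], as_index=False).agg(
            pmai=("pmai", "mean"), c=("c", "first")
        )

    curves = {}
    pooled = (
        df.groupby("site", as_index=False).agg(pmai=("pmai", "mean"), c=("c", "first"))
        if site_means
        else df
    )
    curves["population"] = fit_quadratic(
        pooled["c"], pooled["pmai"], "population", standardize
    )
    for fam, grp in df.groupby("family", sort=True):
        if len(grp) < min_obs or grp["c"].nunique() < 3:
            warnings.warn(f"family {fam}: too few observations, skipped")
            continue
        curves[fam] = fit_quadratic(grp["c"], grp["pmai"], str(fam), standardize)

    rows = []
    for cu in curves.values():
        c_star, v_star = cu.vertex if cu.vertex else (np.nan, np.nan)
        rows.append(
            {
                "level": cu.level,
                "n_obs": cu.n_obs,
                "beta0": cu.params["beta0"],
                "beta1": cu.params["beta1"],
                "beta2": cu.params["beta2"],
                "c_star": c_star,
                "v_star": v_star,
                "r2_adj": cu.adj_r2,
                "p_value": cu.p_value,
                "aic": cu.aic,
            }
        )
    return curves, pd.DataFrame(rows)
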