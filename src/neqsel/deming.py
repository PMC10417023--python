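"""Errors-in-variables (generalized Deming) regression and agreement stats.

Ordinary least squares attenuates the slope when the predictor itself is
measured with error.  Generalized Deming regression models both axes as
noisy observations of latent values,

    x_i = xi_i + delta_i,            delta_i ~ N(0, x_se_i^2)
    y_i = a + b*xi_i + eps_i,        eps_i   ~ N(0, y_se_i^2)

and minimizes

    S = sum_i [ (x_i - xi_i)^2 / x_se_i^2
              + (y_i - a - b*xi_i)^2 / y_se_i^2 ].

Profiling out the latent xi_i and the intercept leaves a one-dimensional
objective in the slope,

    S(b) = sum_i (y_i - a(b) - b*x_i)^2 / (y_se_i^2 + b^2 * x_se_i^2),

which this module minimizes directly (Brent).  With equal constant SEs on
both axes this reduces to orthogonal regression and matches the classical
closed form; as x_se -> 0 it tends to weighted OLS of y on x.  The slope's
95% CI comes from a leave-one-out jackknife; a statistically significant
linear relationship is declared when that CI excludes zero.

Agreement statistics (R^2, RMSE, MAE) are computed against the identity
line y = x, not against the fitted line: they measure how well calculated
values reproduce experimental ones, not merely how linear the cloud is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ._constants import Z_95
from .exceptions import ContractError, DegenerateFitError, InsufficientDataError

__all__ = ["DemingRegression", "DemingResults", "agreement_stats", "validate"]

_MAX_REFINE = 100
_REL_TOL = 1e-10


def _sanitize_se(se: np.ndarray, axis_name: str) -> np.ndarray:
    se = np.asarray(se, dtype=float).copy()
    if np.any(se < 0) or not np.all(np.isfinite(se)):
        raise DegenerateFitError(f"{axis_name} SEs must be finite and >= 0")
    positive = se[se > 0]
    fill = positive.min() if positive.size else 1.0
    se[se == 0] = fill
    return se


def _profile_objective(b: float, x, y, vx, vy) -> float:
    w = 1.0 / (vy + b * b * vx)
    a = np.sum(w * (y - b * x)) / np.sum(w)
    r = y - a - b * x
    return float(np.sum(w * r * r))


def _fit_slope(x, y, vx, vy) -> tuple[float, float]:
    # Candidate starts: weighted OLS slope and the lambda-form closed
    # solution with averaged variance ratio; Brent around the best.
    wy = 1.0 / vy
    xb = np.sum(wy * x) / np.sum(wy)
    yb = np.sum(wy * y) / np.sum(wy)
    sxx = np.sum(wy * (x - xb) ** 2)
    sxy = np.sum(wy * (x - xb) * (y - yb))
    if sxx == 0:
        raise DegenerateFitError("x values are effectively constant")
    b_ols = sxy / sxx
    lam = np.mean(vy) / np.mean(vx)
    syy = np.sum(wy * (y - yb) ** 2)
    disc = np.sqrt((syy - lam * sxx) ** 2 + 4.0 * lam * sxy**2)
    b_dem = (syy - lam * sxx + disc) / (2.0 * sxy) if sxy != 0 else b_ols
    candidates = [b for b in (b_ols, b_dem) if np.isfinite(b)] or [0.0]
    b0 = min(candidates, key=lambda b: _profile_objective(b, x, y, vx, vy))
    # Expand around the best candidate until the minimum is bracketed,
    # then polish with Brent.
    span = max(1.0, 4.0 * abs(b0))
    f0 = _profile_objective(b0, x, y, vx, vy)
    for _ in range(60):
        lo, hi = b0 - span, b0 + span
        f_lo = _profile_objective(lo, x, y, vx, vy)
        f_hi = _profile_objective(hi, x, y, vx, vy)
        if f_lo > f0 and f_hi > f0:
            break
        # Shift towards the descending side and widen.
        if f_lo <= f0:
            b0, f0 = lo, f_lo
        else:
            b0, f0 = hi, f_hi
        span *= 2.0
    else:
        # Objective flattens towards +-infinity (near-vertical data):
        # return the best point found rather than chase the asymptote.
        w = 1.0 / (vy + b0 * b0 * vx)
        return b0, float(np.sum(w * (y - b0 * x)) / np.sum(w))
    res = minimize_scalar(
        _profile_objective,
        args=(x, y, vx, vy),
        bracket=(lo, b0, hi),
        method="brent",
        options={"xtol": 1e-13},
    )
    b = float(res.x)
    w = 1.0 / (vy + b * b * vx)
    a = float(np.sum(w * (y - b * x)) / np.sum(w))
    return b, a


def agreement_stats(x, y) -> tuple[float, float, float]:
    """(R^2, RMSE, MAE) of calculated y against experimental x.

    R^2 is the squared Pearson correlation of (x, y); RMSE and MAE are
    deviations from the identity line.  With zero variance on either axis
    the correlation is undefined and R^2 is returned as NaN while
    RMSE/MAE are still computed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ContractError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise InsufficientDataError("agreement stats need >= 2 points")
    d = y - x
    rmse = float(np.sqrt(np.mean(d * d)))
    mae = float(np.mean(np.abs(d)))
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), rmse, mae
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r, rmse, mae


@dataclass(frozen=True)
class DemingResults:
    """Fitted generalized Deming regression with agreement diagnostics."""

    slope: float
    intercept: float
    slope_se: float
    slope_ci_low: float
    slope_ci_high: float
    r2: float
    rmse: float
    mae: float
    n: int
    label: str = ""

    @property
    def significant(self) -> bool:
        """True when the 95% slope CI excludes zero."""
        return self.slope_ci_low > 0.0 or self.slope_ci_high < 0.0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": [self.slope_ci_low, self.slope_ci_high],
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "n": self.n,
            "significant": self.significant,
        }

    def summary(self) -> str:
        sig = "yes" if self.significant else "no"
        lines = [
            f"Generalized Deming regression{f' [{self.label}]' if self.label else ''}",
            f"  n points            {self.n:>10d}",
            f"  slope               {self.slope:>10.4f}",
            f"  slope 95% CI        [{self.slope_ci_low:.4f}, {self.slope_ci_high:.4f}]",
            f"  intercept (kJ/mol)  {self.intercept:>10.4f}",
            f"  significant slope   {sig:>10s}",
            f"  R^2                 {self.r2:>10.4f}",
            f"  RMSE (kJ/mol)       {self.rmse:>10.4f}",
            f"  MAE (kJ/mol)        {self.mae:>10.4f}",
        ]
        return "\n".join(lines)


class DemingRegression:
    """Errors-in-variables straight-line model ``y = a + b*x``.

    Parameters
    ----------
    y, x
        Calculated (response) and experimental (predictor) values, kJ/mol.
    y_se, x_se
        Per-point standard errors.  Zero SEs are replaced by the smallest
        positive SE on the same axis (or 1 when that axis has none), so an
        exactly-known point keeps the largest weight without producing an
        infinite one.
    label
        Free-text tag carried into the results (e.g. the estimator name).
    """

    def __init__(self, y, x, y_se=None, x_se=None, label: str = ""):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        n = self.x.size
        if self.y.size != n:
            raise ContractError(f"length mismatch: x has {n}, y has {self.y.size}")
        if n < 3:
            raise InsufficientDataError(f"Deming regression needs n >= 3, got {n}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DegenerateFitError("x and y must be finite")
        if np.all(self.x == self.x[0]):
            raise DegenerateFitError("all x values identical: slope undefined")
        self.x_se = _sanitize_se(
            np.zeros(n) if x_se is None else np.broadcast_to(x_se, (n,)), "x"
        )
        self.y_se = _sanitize_se(
            np.zeros(n) if y_se is None else np.broadcast_to(y_se, (n,)), "y"
        )
        self.label = label

    @classmethod
    def from_dataframe(
        cls,
        frame,
        y: str = "y",
        x: str = "x",
        y_se: str | None = "y_se",
        x_se: str | None = "x_se",
        label: str = "",
    ) -> "DemingRegression":
        return cls(
            frame[y].to_numpy(),
            frame[x].to_numpy(),
            frame[y_se].to_numpy() if y_se and y_se in frame else None,
            frame[x_se].to_numpy() if x_se and x_se in frame else None,
            label=label,
        )

    def fit(self) -> DemingResults:
        """Fit slope and intercept; jackknife the slope for its 95% CI."""
        vx, vy = self.x_se**2, self.y_se**2
        b, a = _fit_slope(self.x, self.y, vx, vy)
        n = self.x.size
        loo = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            loo[i], _ = _fit_slope(self.x[keep], self.y[keep], vx[keep], vy[keep])
        se_jack = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
        r2, rmse, mae = agreement_stats(self.x, self.y)
        return DemingResults(
            slope=b,
            intercept=a,
            slope_se=se_jack,
            slope_ci_low=b - Z_95 * se_jack,
            slope_ci_high=b + Z_95 * se_jack,
            r2=r2,
            rmse=rmse,
            mae=mae,
            n=n,
            label=self.label,
        )


def validate(
    calculated, experimental, on=("compound_i", "compound_j", "target")
) -> tuple[dict[str, DemingResults], "pd.DataFrame", list[str]]:
    """Per-method Deming validation of a calculated table against experiment.

    Joins the two long-format tables on ``on`` (the experimental table has
    no ``method`` column; each calculated method is validated against the
    same experimental values with x = experimental, y = calculated) and
    fits one :class:`DemingRegression` per method.  The calculated tables
    use column ``ddg`` or ``dS`` as the value; SEs come from ``se``.

    Returns ``(results_by_method, joined_points, diagnostics)``.
    """
    value_col = "dS" if "dS" in calculated.columns else "ddg"
    on = list(on)
    calc = calculated.rename(columns={value_col: "y", "se": "y_se"})
    exp = experimental.rename(columns={value_col: "x", "se": "x_se"})
    exp_cols = on + ["x", "x_se"]
    joined = calc.merge(exp[exp_cols], on=on, how="outer", indicator=True)
    diagnostics = [
        f"unmatched row ({side}): " + ", ".join(str(r[c]) for c in on)
        for _, r in joined[joined["_merge"] != "both"].iterrows()
        for side in [r["_merge"]]
    ]
    matched = joined[joined["_merge"] == "both"].drop(columns="_merge")
    if matched.empty:
        raise ContractError("calculated and experimental tables do not join")
    results: dict[str, DemingResults] = {}
    methods = sorted(matched["method"].unique()) if "method" in matched else [""]
    for method in methods:
        sub = matched[matched["method"] == method] if method else matched
        model = DemingRegression.from_dataframe(sub, label=method or "all")
        results[method or "all"] = model.fit()
    keep = [c for c in on + ["method", "x", "x_se", "y", "y_se"] if c in matched]
    return results, matched[keep].reset_index(drop=True), diagnostics
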