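"""Interaction-window transform and mixed-effects growth-curve model.

Each user's chronological sentiment series is collapsed into ``n_windows``
(default 100) contiguous proportional segments -- window 1 averages the
first 1% of a user's comments, window 100 the last 1% -- so trajectories are
comparable across users with very different activity levels.  The growth
model then regresses window sentiment on the window index with a per-user
random intercept, controlling for synchrony (common power), tenure (days
active), average word count and health-language percentage, and includes the
window x common-power x days-active moderation structure: the three-way term
captures whether synchrony steepens or flattens a user's sentiment slope
depending on community tenure.

All continuous variables (including the response) are z-standardized across
the analysis table before fitting, so coefficients are standardized betas.
Variance components are summarized by the intraclass correlation
``tau00 / (tau00 + sigma2)`` and by marginal/conditional R^2 in the usual
variance-partition sense for random-intercept models (fixed-effects variance
vs fixed-plus-random variance over total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "GrowthFit",
    "window_transform",
    "build_windowed_table",
    "fit_growth_model",
    "interaction_surface",
    "MODEL_TERMS",
]

# fixed-effect rows of the fitted model, in report order
MODEL_TERMS = (
    "Intercept",
    "window",
    "common_power",
    "days_active",
    "health_pct",
    "word_count",
    "window:common_power",
    "window:days_active",
    "common_power:days_active",
    "window:common_power:days_active",
)


def window_transform(x: np.ndarray, n_windows: int = 100) -> np.ndarray:
    """Means over ``n_windows`` contiguous near-equal chronological segments.

    When the length is not divisible, the remainder observations are spread
    one-per-window over the *earliest* windows (deterministic and
    order-preserving).  The weighted mean of the window means, weighted by
    segment sizes, reproduces the series mean exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("need a 1-d series")
    n = x.size
    if n < n_windows:
        raise ValueError(f"series length {n} < n_windows {n_windows}")
    base, rem = divmod(n, n_windows)
    sizes = np.full(n_windows, base, dtype=int)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return np.array([x[edges[i] : edges[i + 1]].mean() for i in range(n_windows)])


def window_sizes(n: int, n_windows: int = 100) -> np.ndarray:
    """Segment sizes used by :func:`window_transform`."""
    base, rem = divmod(n, n_windows)
    sizes = np.full(n_windows, base, dtype=int)
    sizes[:rem] += 1
    return sizes


def build_windowed_table(
    users: list[dict],
    n_windows: int = 100,
) -> pd.DataFrame:
    """Assemble the per-window analysis table from per-user inputs.

    Each element of ``users`` is a mapping with keys ``user_id``,
    ``sentiment`` (chronological vector), ``common_power_frac``,
    ``days_active``, ``mean_word_count``, ``mean_health_pct``.  Users whose
    series is shorter than ``n_windows`` raise (callers flag and drop them
    explicitly rather than silently losing data).
    """
    frames = []
    for u in users:
        wm = window_transform(np.asarray(u["sentiment"], float), n_windows)
        frames.append(
            pd.DataFrame(
                {
                    "user_id": u["user_id"],
                    "window_index": np.arange(1, n_windows + 1),
                    "window_sentiment": wm,
                    "common_power_frac": float(u["common_power_frac"]),
                    "days_active": float(u["days_active"]),
                    "mean_word_count": float(u["mean_word_count"]),
                    "mean_health_pct": float(u["mean_health_pct"]),
                }
            )
        )
    if not frames:
        raise ValueError("no users supplied")
    return pd.concat(frames, ignore_index=True)


@dataclass
class GrowthFit:
    """Standardized fixed effects with CIs and variance-component summary."""

    coefficients: pd.DataFrame  # index: term; columns: beta, ci_low, ci_high, p
    sigma2: float
    tau00: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_users: int
    n_obs: int
    converged: bool = True
    notes: dict = field(default_factory=dict)

    def summary_table(self) -> pd.DataFrame:
        """Human-readable coefficient table in the canonical row order."""
        return self.coefficients.round(4)


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance predictor; design would be rank-deficient")
    return (x - x.mean()) / sd


_FORMULA = (
    "z_sent ~ window * common_power * days_active + health_pct + word_count"
)

def fit_growth_model(data: pd.DataFrame, n_windows: int = 100) -> GrowthFit:
    """Fit the random-intercept growth model on a windowed table.

    ``data`` must contain ``user_id``, ``window_index``, ``window_sentiment``,
    ``common_power_frac``, ``days_active``, ``mean_word_count``,
    ``mean_health_pct``.  All continuous variables are z-scored across the
    table; the fit itself is REML via statsmodels MixedLM.  Raises on
    rank-deficient designs or non-convergence.
    """
    required = {
        "user_id",
        "window_index",
        "window_sentiment",
        "common_power_frac",
        "days_active",
        "mean_word_count",
        "mean_health_pct",
    }
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if data["user_id"].nunique() < 2:
        raise ValueError("need at least 2 users")
    df = pd.DataFrame(
        {
            "user_id": data["user_id"].to_numpy(),
            "z_sent": _z(data["window_sentiment"].to_numpy(float)),
            "window": _z(data["window_index"].to_numpy(float)),
            "common_power": _z(data["common_power_frac"].to_numpy(float)),
            "days_active": _z(data["days_active"].to_numpy(float)),
            "word_count": _z(data["mean_word_count"].to_numpy(float)),
            "health_pct": _z(data["mean_health_pct"].to_numpy(float)),
        }
    )
    model = smf.mixedlm(_FORMULA, df, groups=df["user_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    if np.any(~np.isfinite(result.params)):
        raise RuntimeError("growth model failed to converge (non-finite params)")

    fe = result.fe_params
    ci = result.conf_int().loc[fe.index]
    pvals = result.pvalues.loc[fe.index]
    coef = pd.DataFrame(
        {
            "beta": fe,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": pvals,
        }
    )
    order = [t for t in MODEL_TERMS if t in coef.index]
    coef = coef.loc[order + [t for t in coef.index if t not in order]]

    sigma2 = float(result.scale)
    tau00 = float(result.cov_re.iloc[0, 0])
    icc = tau00 / (tau00 + sigma2)
    # variance explained by fixed effects over total (marginal), and by
    # fixed + random intercept over total (conditional)
    exog = result.model.exog
    fitted_fixed = exog @ fe.to_numpy()
    var_f = float(np.var(fitted_fixed))
    total = var_f + tau00 + sigma2
    return GrowthFit(
        coefficients=coef,
        sigma2=sigma2,
        tau00=tau00,
        icc=float(icc),
        r2_marginal=var_f / total,
        r2_conditional=(var_f + tau00) / total,
        n_users=int(data["user_id"].nunique()),
        n_obs=int(len(df)),
        converged=bool(result.converged),
    )


def interaction_surface(
    fit: GrowthFit,
    common_power_grid: np.ndarray = (-1.0, 0.0, 1.0),
    days_active_grid: np.ndarray = (-1.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Model-implied sentiment-vs-window slope over a moderator grid.

    Grids are in standardized units (e.g. +/-1 SD).  The slope at
    (cp, days) is the linear combination

        b_window + b_w:cp * cp + b_w:days * days + b_w:cp:days * cp * days.

    Grid points beyond |2| SD are flagged as extrapolation.
    """
    b = fit.coefficients["beta"]

    def term(name):
        return float(b[name]) if name in b.index else 0.0

    rows = []
    for cp in np.atleast_1d(common_power_grid):
        for da in np.atleast_1d(days_active_grid):
            slope = (
                term("window")
                + term("window:common_power") * cp
                + term("window:days_active") * da
                + term("window:common_power:days_active") * cp * da
            )
            rows.append(
                {
                    "common_power": float(cp),
                    "days_active": float(da),
                    "window_slope": slope,
                    "extrapolated": bool(abs(cp) > 2 or abs(da) > 2),
                }
            )
    return pd.DataFrame(rows)
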