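"""Per-user synchrony statistics and group-level tests.

The unit of analysis is a user's cross-spectrum against their peer stream.
Three summaries describe synchrony from different angles:

* **common power fraction** -- share of reliable (inside-COI) points of the
  cross-wavelet plot flagged significant against the red-noise null: matched
  sentiment *intensity*;
* **coherence fraction** -- same share for wavelet coherence against its
  Monte Carlo null: *correlated* (phase-locked) sentiment change;
* **mean relative-phase angle** -- circular mean of the cross-spectrum phase
  over significant common-power points: 0 deg = in-phase co-fluctuation,
  180 deg = antiphase, sign = lead/lag.

Fractions are stored in [0, 1]; display scaling is left to callers.  The
*shuffled baseline* repeats the identical pipeline after permuting the
user's own series (destroying temporal alignment with the peers while
keeping both marginal distributions), and paired t tests compare real
against shuffled cohorts.  Band summaries split the period axis into
low (20-32 interactions), medium (10-20) and high (<10) frequency bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .wavelet_core import (
    CrossSpectrum,
    WaveletGrid,
    estimate_ar1,
    morlet_cwt,
    percentile_transform,
    reliable_mask,
    wtc,
    wtc_significance_mc,
    xwt,
    xwt_significance,
)

__all__ = [
    "BandDefinition",
    "SynchronyMetrics",
    "analyze_pair",
    "shuffled_baseline",
    "common_power_fraction",
    "coherence_fraction",
    "mean_rp_angle",
    "band_fractions",
    "paired_synchrony_test",
    "band_anova",
    "correlate_metrics",
    "circular_mean_deg",
]


@dataclass(frozen=True)
class BandDefinition:
    """Period bands (interaction units): low closed [20, 32], medium
    [10, 20), high (0, 10)."""

    low: tuple[float, float] = (20.0, 32.0)
    medium: tuple[float, float] = (10.0, 20.0)
    high: tuple[float, float] = (0.0, 10.0)

    def rows(self, periods: np.ndarray, band: str) -> np.ndarray:
        lo, hi = getattr(self, band)
        if band == "low":  # closed on both stated endpoints
            return (periods >= lo) & (periods <= hi)
        return (periods >= lo) & (periods < hi)

    @property
    def names(self) -> tuple[str, ...]:
        return ("low", "medium", "high")


DEFAULT_BANDS = BandDefinition()


@dataclass
class SynchronyMetrics:
    """Per-user synchrony summary; fractions in [0,1], RP angle wrapped to
    (-180, 180], NaN marks a metric that could not be computed."""

    user_id: str = ""
    common_power_frac: float = np.nan
    coherence_frac: float = np.nan
    rp_angle_deg: float = np.nan
    band_common_power: dict = field(default_factory=dict)
    band_coherence: dict = field(default_factory=dict)
    band_rp: dict = field(default_factory=dict)
    pearson_r: float = np.nan

    def to_row(self) -> dict:
        row = {
            "user_id": self.user_id,
            "common_power_frac": self.common_power_frac,
            "coherence_frac": self.coherence_frac,
            "rp_angle_deg": self.rp_angle_deg,
            "pearson_r": self.pearson_r,
        }
        for b, v in self.band_common_power.items():
            row[f"common_power_{b}"] = v
        for b, v in self.band_coherence.items():
            row[f"coherence_{b}"] = v
        for b, v in self.band_rp.items():
            row[f"rp_{b}"] = v
        return row


def _reliable(cross: CrossSpectrum) -> np.ndarray:
    rel = reliable_mask(cross.grid, cross.coi)
    if not rel.any():
        raise ValueError("no reliable (inside-COI) points")
    return rel


def common_power_fraction(cross: CrossSpectrum) -> float:
    """Fraction of reliable points with significant common power."""
    if cross.sig_power is None:
        raise ValueError("sig_power mask not computed")
    rel = _reliable(cross)
    return float(cross.sig_power[rel].mean())


def coherence_fraction(cross: CrossSpectrum) -> float:
    """Fraction of reliable points with significant coherence."""
    if cross.sig_coherence is None:
        raise ValueError("sig_coherence mask not computed")
    rel = _reliable(cross)
    return float(cross.sig_coherence[rel].mean())


def circular_mean_deg(angles_rad: np.ndarray) -> float:
    """Circular mean of phase angles, in degrees wrapped to (-180, 180]."""
    a = np.asarray(angles_rad, float)
    if a.size == 0:
        return float("nan")
    mean = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
    deg = np.degrees(mean)
    if deg <= -180.0:
        deg += 360.0
    return float(deg)


def mean_rp_angle(cross: CrossSpectrum, mask: np.ndarray | None = None) -> float:
    """Unweighted circular mean of relative phase over significant reliable
    common-power points, degrees; NaN when no point is significant."""
    if mask is None:
        if cross.sig_power is None:
            raise ValueError("sig_power mask not computed")
        mask = cross.sig_power
    sel = mask & _reliable(cross)
    if not sel.any():
        return float("nan")
    return circular_mean_deg(cross.phase[sel])


def band_fractions(
    cross: CrossSpectrum,
    bands: BandDefinition = DEFAULT_BANDS,
    which: str = "power",
) -> dict[str, float]:
    """Per-band significant fraction (COI-restricted) for ``power`` or
    ``coherence`` masks."""
    mask = cross.sig_power if which == "power" else cross.sig_coherence
    if mask is None:
        raise ValueError(f"sig_{which} mask not computed")
    rel = _reliable(cross)
    periods = cross.grid.periods
    out = {}
    for b in bands.names:
        rows = bands.rows(periods, b)
        if not rows.any():
            raise ValueError(f"grid has no rows in band {b!r}")
        sel = rel[rows, :]
        out[b] = float(mask[rows, :][sel].mean()) if sel.any() else float("nan")
    return out


def band_rp_angles(
    cross: CrossSpectrum, bands: BandDefinition = DEFAULT_BANDS
) -> dict[str, float]:
    """Per-band circular-mean RP over significant reliable points."""
    if cross.sig_power is None:
        raise ValueError("sig_power mask not computed")
    rel = _reliable(cross)
    periods = cross.grid.periods
    out = {}
    for b in bands.names:
        rows = bands.rows(periods, b)
        sel = (cross.sig_power & rel)[rows, :]
        out[b] = circular_mean_deg(cross.phase[rows, :][sel]) if sel.any() else float("nan")
    return out


def analyze_pair(
    x: np.ndarray,
    y: np.ndarray,
    user_id: str = "",
    grid: WaveletGrid | None = None,
    alpha: float = 0.05,
    bands: BandDefinition = DEFAULT_BANDS,
    compute_wtc: bool = True,
    wtc_crit: np.ndarray | None = None,
    wtc_nsim: int = 200,
    seed: int = 0,
) -> tuple[SynchronyMetrics, CrossSpectrum]:
    """Full single-user synchrony pipeline.

    percentile transform -> Morlet CWT of both series -> XWT with AR(1)
    red-noise significance -> (optionally) WTC with Monte Carlo significance
    -> COI-restricted summary metrics.  ``wtc_crit`` lets callers supply
    precomputed per-scale critical values (e.g. a cohort-level cache);
    otherwise they are simulated here with ``wtc_nsim`` draws.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    px = percentile_transform(x)
    py = percentile_transform(y)
    if grid is None:
        grid = WaveletGrid.for_length(n)
    sa = morlet_cwt(px, grid)
    sb = morlet_cwt(py, grid)
    cross = xwt(sa, sb)
    phi_a = estimate_ar1(px)
    phi_b = estimate_ar1(py)
    xwt_significance(cross, phi_a, phi_b, alpha)
    metrics = SynchronyMetrics(user_id=user_id)
    metrics.common_power_frac = common_power_fraction(cross)
    metrics.rp_angle_deg = mean_rp_angle(cross)
    metrics.band_common_power = band_fractions(cross, bands, "power")
    metrics.band_rp = band_rp_angles(cross, bands)
    metrics.pearson_r = float(stats.pearsonr(x, y)[0])
    if compute_wtc:
        cross.coherence = wtc(sa, sb)
        if wtc_crit is None:
            wtc_crit = wtc_significance_mc(
                phi_a, phi_b, n, grid, nsim=wtc_nsim, alpha=alpha, seed=seed
            )
        cross.sig_coherence = cross.coherence > wtc_crit[:, None]
        metrics.coherence_frac = coherence_fraction(cross)
        metrics.band_coherence = band_fractions(cross, bands, "coherence")
    return metrics, cross


def shuffled_baseline(
    pair,
    seed: int,
    strategy: str = "shuffle-self",
    **kwargs,
) -> tuple[SynchronyMetrics, CrossSpectrum]:
    """Identical pipeline on order-destroyed data.

    ``pair`` is any object with ``self_sentiment``/``peer_sentiment``
    vectors.  ``shuffle-self`` permutes only the user's own series (the
    conservative default: alignment is destroyed, both marginals kept);
    ``shuffle-both`` permutes each side independently.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(pair.self_sentiment, float)
    y = np.asarray(pair.peer_sentiment, float)
    if strategy == "shuffle-self":
        x = rng.permutation(x)
    elif strategy == "shuffle-both":
        x = rng.permutation(x)
        y = rng.permutation(y)
    else:
        raise ValueError(f"unknown shuffle strategy {strategy!r}")
    uid = getattr(pair, "user_id", "")
    return analyze_pair(x, y, user_id=uid, **kwargs)


class PairedTestResult(NamedTuple):
    t: float
    df: int
    p: float
    d_av: float
    d_z: float


def paired_synchrony_test(real: np.ndarray, shuffled: np.ndarray) -> PairedTestResult:
    """Two-tailed paired t test of real vs shuffled metrics with effect sizes.

    Reports both Cohen's d conventions for paired designs: ``d_av`` (mean
    difference over the average of the two condition SDs) and ``d_z`` (mean
    difference over the SD of the differences).
    """
    a = np.asarray(real, float)
    b = np.asarray(shuffled, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    diff = a - b
    sd_diff = diff.std(ddof=1)
    if sd_diff == 0:
        raise ValueError("zero variance of differences")
    t, p = stats.ttest_rel(a, b)
    d_z = float(diff.mean() / sd_diff)
    d_av = float(diff.mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2.0))
    return PairedTestResult(float(t), a.size - 1, float(p), d_av, d_z)


class RmAnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float
    pairwise: dict


def band_anova(values: np.ndarray, labels: tuple[str, ...] | None = None) -> RmAnovaResult:
    """One-way repeated-measures ANOVA across frequency bands.

    ``values`` is (n_subjects x n_bands) with complete cases.  The F test
    uses the conventional within-subject error term with df1 = k - 1 and
    df2 = (n - 1)(k - 1); follow-up pairwise comparisons are paired t tests
    for each band pair.
    """
    y = np.asarray(values, float)
    if y.ndim != 2 or y.shape[1] < 2 or y.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 bands")
    if not np.all(np.isfinite(y)):
        raise ValueError("complete cases required (drop NaN rows first)")
    n, k = y.shape
    grand = y.mean()
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_band = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_band
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_band = ss_band / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        f_val, p = (0.0, 1.0) if ss_band == 0 else (np.inf, 0.0)
    else:
        f_val = ms_band / ms_err
        p = float(stats.f.sf(f_val, df1, df2))
    labels = labels or tuple(f"band{i}" for i in range(k))
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = y[:, i] - y[:, j]
            if diff.std(ddof=1) == 0:
                pairwise[(labels[i], labels[j])] = (0.0, 1.0)
            else:
                t, pt = stats.ttest_rel(y[:, i], y[:, j])
                pairwise[(labels[i], labels[j])] = (float(t), float(pt))
    return RmAnovaResult(float(f_val), df1, df2, float(p), pairwise)


def correlate_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation table across per-user metric columns.

    Listwise deletion on missing values; returns a frame with a
    (variable, statistic) MultiIndex over rows, statistics ``r`` and ``p``,
    mirroring the conventional construct-validity correlation matrix.
    """
    df = metrics.dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 complete cases")
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.full((len(cols), len(cols)), np.nan), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                rr, pp = stats.pearsonr(df[a], df[b])
                r.loc[a, b] = r.loc[b, a] = rr
                p.loc[a, b] = p.loc[b, a] = pp
    out = pd.concat({"r": r, "p": p}, axis=0).swaplevel().sort_index()
    out.index.names = ["variable", "statistic"]
    return out.loc[cols]
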