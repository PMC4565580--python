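"""Time-course analysis of nuclear/cytoplasmic signal under treatment.

Operates on population summaries (mean/SEM/n per group and time):

* fold-change curves of treated relative to time-matched untreated groups,
  with delta-method SEM propagation;
* initial degradation rate as the slope of the fold curve between the 1 and
  2 hr points, and per-phase rates relative to G1 across replicates;
* curve-shape characterization (flat / rise-fall / rise-plateau);
* the two-tailed unpaired Welch t-test (unequal variances, Welch-Satterthwaite
  degrees of freedom) used for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "compute_fold_change",
    "estimate_degradation_slope",
    "relative_rates_vs_G1",
    "characterize_curve",
    "welch_t_test",
]


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_two_sided: float


def compute_fold_change(treated: pd.DataFrame, untreated: pd.DataFrame) -> pd.DataFrame:
    """Pointwise ratio of treated to time-matched untreated population means.

    Both inputs are summaries with columns ``time_hr``, ``mean``, ``sem``.
    The fold SEM uses first-order (delta-method) error propagation:
    var(f)/f^2 = (sem_T/m_T)^2 + (sem_U/m_U)^2.  A treated time point without
    a matching untreated point raises, naming the time.
    """
    u = untreated.set_index("time_hr")
    rows = []
    for _, r in treated.sort_values("time_hr").iterrows():
        t = r["time_hr"]
        if t not in u.index:
            raise ValueError(f"no time-matched untreated summary at t={t} hr")
        mu = u.loc[t, "mean"]
        if mu <= 0:
            raise ValueError(f"untreated mean must be > 0 at t={t} hr")
        fold = r["mean"] / mu
        rel_var = (r["sem"] / r["mean"]) ** 2 + (u.loc[t, "sem"] / mu) ** 2
        rows.append({"time_hr": t, "fold": fold, "sem_fold": abs(fold) * np.sqrt(rel_var)})
    return pd.DataFrame(rows)


def estimate_degradation_slope(curve: pd.DataFrame, t_start: float = 1.0, t_end: float = 2.0) -> float:
    """Initial degradation rate: slope of the line through the fold values at
    the 1 and 2 hr population averages (fold/hr)."""
    by_time = curve.set_index("time_hr")["fold"]
    missing = [t for t in (t_start, t_end) if t not in by_time.index]
    if missing:
        raise ValueError(f"curve is missing required time point(s): {missing}")
    return float((by_time[t_end] - by_time[t_start]) / (t_end - t_start))


def relative_rates_vs_G1(slopes: pd.DataFrame) -> pd.DataFrame:
    """Per-phase degradation rates relative to G1, across replicates.

    ``slopes`` has columns ``replicate``, ``phase``, ``slope``.  Within each
    replicate the ratio is slope(phase)/slope(G1); across replicates the mean,
    SEM and a Welch test of the phase's ratios against the G1 ratios
    (identically 1) are reported.  A zero G1 slope in any replicate raises.
    """
    wide = slopes.pivot(index="replicate", columns="phase", values="slope")
    if "G1" not in wide:
        raise ValueError("slopes must include phase G1 in every replicate")
    if (wide["G1"] == 0).any():
        raise ValueError("G1 slope of zero: relative rate undefined")
    ratios = wide.div(wide["G1"], axis=0)
    rows = []
    for phase in ratios.columns:
        vals = ratios[phase].dropna().to_numpy()
        n = len(vals)
        sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        if phase == "G1":
            p = np.nan
        else:
            p = welch_t_test(vals, ratios["G1"].dropna().to_numpy()).p_two_sided
        rows.append(
            {"phase": phase, "ratio_mean": vals.mean(), "ratio_sem": sem, "n": n, "p_vs_G1": p}
        )
    return pd.DataFrame(rows)


def characterize_curve(curve: pd.DataFrame, band: float = 0.10) -> dict:
    """Classify the shape of a fold-change curve.

    * ``flat`` if the peak fold is within ``band`` of 1;
    * ``rise-plateau`` if the terminal fold stays within ``band`` of the peak;
    * ``rise-fall`` otherwise.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 time points to characterize a curve")
    c = curve.sort_values("time_hr")
    folds = c["fold"].to_numpy()
    peak_idx = int(np.argmax(folds))
    peak = float(folds[peak_idx])
    terminal = float(folds[-1])
    if abs(peak - 1.0) <= band:
        shape = "flat"
    elif terminal >= (1.0 - band) * peak:
        shape = "rise-plateau"
    else:
        shape = "rise-fall"
    return {
        "peak_fold": peak,
        "peak_time": float(c["time_hr"].iloc[peak_idx]),
        "terminal_fold": terminal,
        "shape": shape,
    }


def welch_t_test(group_a, group_b) -> WelchResult:
    """Two-tailed unpaired t-test assuming unequal variances.

    Degenerate variances: if both groups have zero variance the result is
    t = 0, p = 1 for equal means and t = +/-inf, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return WelchResult(np.copysign(np.inf, a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0)
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    # Welch-Satterthwaite degrees of freedom; a zero-variance group simply
    # contributes nothing to the denominator
    df_den = 0.0
    if sa > 0:
        df_den += sa**2 / (len(a) - 1)
    if sb > 0:
        df_den += sb**2 / (len(b) - 1)
    df = (sa + sb) ** 2 / df_den
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))
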