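"""Behavioural analysis of stop-signal anticipation sessions.

Covers the standard analysis chain: per-level RT/accuracy summaries with
Tukey-fence outlier exclusion, the integration-method estimate of the
stop-signal reaction time (SSRT), normalized inhibition functions (ZRFT) with
a cumulative Weibull fit, and the group-level linear-contrast and paired-t
statistics.

The integration method treats stopping as a race: if a fraction p of Stop
trials escaped inhibition, the Stop process must finish at about the p-th
quantile of the Go RT distribution, so

    SSRT = GoRT_(ceil(p * n_go)) - mean(SSD),

the ceil(p*n)-th fastest Go RT minus the mean stop-signal delay.  The ZRFT
transform expresses each stop-signal delay as a Z score of the relative
finishing time, (mean GoRT - SSD - SSRT) / SD(GoRT), so inhibition functions
can be pooled across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .race import SessionData

__all__ = [
    "flag_outliers",
    "flag_session_outliers",
    "rt_summary",
    "ssrt_integration",
    "inhibition_function",
    "InhibitionFunction",
    "WeibullFit",
    "linear_contrast",
    "paired_t",
]


def flag_outliers(rts) -> np.ndarray:
    """Tukey-fence outlier flags for one level's Go RTs.

    An RT is flagged iff it lies more than 1.5 * IQR below the 25th or above
    the 75th percentile (linear-interpolation quantiles).  Fewer than 4 RTs:
    nothing is flagged and a warning is issued.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        return np.zeros(0, dtype=bool)
    if rts.size < 4:
        warnings.warn("fewer than 4 RTs: outlier rule not applied")
        return np.zeros(rts.size, dtype=bool)
    q25, q75 = np.quantile(rts, [0.25, 0.75])
    iqr = q75 - q25
    return (rts < q25 - 1.5 * iqr) | (rts > q75 + 1.5 * iqr)


def flag_session_outliers(session: SessionData) -> pd.Series:
    """Per-trial outlier flags, applying the Tukey rule per p_stop level."""
    df = session.trials
    flags = pd.Series(False, index=df.index)
    for lev, grp in df[df["trial_type"] == "go"].groupby("level"):
        rts = grp["rt"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags.loc[grp.index] = flag_outliers(rts)
    return flags


def rt_summary(session: SessionData, flags: pd.Series | None = None) -> pd.DataFrame:
    """Per-level Go RT mean with 95% t-CI and Stop accuracy.

    Levels without Go trials are absent from the table.  `flags` marks trials
    to exclude (defaults to the per-level Tukey rule).
    """
    df = session.trials
    if flags is None:
        flags = flag_session_outliers(session)
    rows = []
    for lev, grp in df.groupby("level"):
        go = grp[(grp["trial_type"] == "go") & ~flags.loc[grp.index]]
        if len(go) == 0:
            continue
        rts = go["rt"].to_numpy()
        mean = rts.mean()
        if len(rts) > 1 and rts.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, len(rts) - 1) * rts.std(ddof=1) / np.sqrt(len(rts))
        else:
            half = 0.0
        stop = grp[grp["trial_type"] == "stop"]
        n_stop = len(stop)
        acc = (stop["outcome"] == "StopSuccess").mean() if n_stop else np.nan
        rows.append(
            {
                "level": lev,
                "p_stop": grp["p_stop"].iloc[0],
                "n_go": len(rts),
                "mean_rt": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n_stop": n_stop,
                "stop_accuracy": acc,
                "n_outliers": int(flags.loc[grp.index].sum()),
            }
        )
    return pd.DataFrame(rows)


def ssrt_integration(
    session: SessionData, flags: pd.Series | None = None, exclude_outliers: bool = True
) -> float:
    """Integration-method SSRT across all p_stop > 0 conditions pooled (ms)."""
    df = session.trials
    stop = df[df["trial_type"] == "stop"]
    go = df[(df["trial_type"] == "go") & (df["level"] > 0)]
    if exclude_outliers:
        if flags is None:
            flags = flag_session_outliers(session)
        go = go[~flags.loc[go.index]]
    if len(stop) < 1 or len(go) < 10:
        raise ValueError("need at least 1 Stop trial and 10 p>0 Go trials")
    p_respond = (stop["outcome"] == "StopFailure").mean()
    if p_respond in (0.0, 1.0):
        raise ValueError(
            f"integration estimator undefined: p_respond = {p_respond:.0f} "
            f"({len(stop)} Stop trials); staircase did not bracket performance"
        )
    rts = np.sort(go["rt"].to_numpy())
    k = int(np.ceil(p_respond * len(rts)))
    quantile_rt = rts[k - 1]
    return float(quantile_rt - stop["ssd"].mean())


@dataclass
class WeibullFit:
    """Cumulative Weibull W(z) = gamma - (gamma - delta) * exp(-((z-z0)/alpha)^beta).

    z0 anchors the curve at the smallest observed ZRFT so the power term is
    defined for the whole (possibly negative) ZRFT range.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    z0: float
    r2: float

    def predict(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = np.maximum(z - self.z0, 0.0)
        return self.gamma - (self.gamma - self.delta) * np.exp(-((u / self.alpha) ** self.beta))


@dataclass
class InhibitionFunction:
    points: pd.DataFrame  # ssd, zrft, p_stop_success, n
    weibull: WeibullFit | None

    def plot(self, ax=None):
        """Inhibition function on the ZRFT scale with the Weibull fit overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.points.sort_values("zrft")
        ax.scatter(pts["zrft"], pts["p_stop_success"], s=4 * np.sqrt(pts["n"]),
                   color="0.3", zorder=3)
        if self.weibull is not None:
            z = np.linspace(pts["zrft"].min(), pts["zrft"].max(), 200)
            ax.plot(z, self.weibull.predict(z), color="k",
                    label=f"Weibull fit (R$^2$={self.weibull.r2:.2f})")
            ax.legend(frameon=False)
        ax.set_xlabel("ZRFT (early stop-signal $\\rightarrow$)")
        ax.set_ylabel("P(stop success)")
        ax.set_ylim(-0.02, 1.02)
        return ax


def _session_inhibition_points(session: SessionData, flags=None) -> pd.DataFrame:
    df = session.trials
    stop = df[df["trial_type"] == "stop"]
    go = df[(df["trial_type"] == "go") & (df["level"] > 0)]
    if flags is None:
        flags = flag_session_outliers(session)
    go = go[~flags.loc[go.index]]
    ssrt = ssrt_integration(session, flags=flags)
    mu, sd = go["rt"].mean(), go["rt"].std(ddof=1)
    pts = (
        stop.assign(success=stop["outcome"] == "StopSuccess")
        .groupby("ssd")["success"]
        .agg(p_stop_success="mean", n="size")
        .reset_index()
    )
    pts["zrft"] = (mu - pts["ssd"] - ssrt) / sd
    return pts[["ssd", "zrft", "p_stop_success", "n"]]


def inhibition_function(
    sessions: SessionData | list[SessionData], n_bins: int | None = None
) -> InhibitionFunction:
    """Inhibition function on the ZRFT scale, with a cumulative Weibull fit.

    Stop trials are binned by SSD within each session (by default at the
    distinct staircase SSDs, or into `n_bins` equal-count bins), converted to
    ZRFT, pooled across sessions, and fit by bounded least squares weighted by
    the number of Stop trials per point.  With fewer than 3 distinct points
    the fit is skipped and the points are returned alone.
    """
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    pts = pd.concat([_session_inhibition_points(s) for s in sessions], ignore_index=True)

    if n_bins is not None and len(pts) > n_bins:
        ranks = pts["zrft"].rank(method="first")
        binid = np.ceil(ranks / len(pts) * n_bins).astype(int)
        pts = (
            pts.assign(_bin=binid, _w=pts["n"])
            .groupby("_bin")
            .apply(
                lambda g: pd.Series(
                    {
                        "ssd": np.average(g["ssd"], weights=g["_w"]),
                        "zrft": np.average(g["zrft"], weights=g["_w"]),
                        "p_stop_success": np.average(g["p_stop_success"], weights=g["_w"]),
                        "n": g["_w"].sum(),
                    }
                ),
                include_groups=False,
            )
            .reset_index(drop=True)
        )

    if pts["zrft"].nunique() < 3:
        return InhibitionFunction(points=pts, weibull=None)

    z = pts["zrft"].to_numpy()
    y = pts["p_stop_success"].to_numpy()
    w = np.sqrt(pts["n"].to_numpy().astype(float))
    z0 = z.min()

    def model(theta):
        alpha, beta, gamma, delta = theta
        u = np.maximum(z - z0, 0.0)
        return gamma - (gamma - delta) * np.exp(-((u / alpha) ** beta))

    res = optimize.least_squares(
        lambda th: w * (model(th) - y),
        x0=[1.0, 2.0, 1.0, 0.0],
        bounds=([1e-6, 1e-6, 0.5, 0.0], [np.inf, np.inf, 1.0, 0.5]),
    )
    yhat = model(res.x)
    ss_res = np.sum(w**2 * (y - yhat) ** 2)
    ss_tot = np.sum(w**2 * (y - np.average(y, weights=w**2)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    fit = WeibullFit(*res.x, z0=z0, r2=float(r2))
    return InhibitionFunction(points=pts, weibull=fit)


def linear_contrast(level_means: np.ndarray, weights=(-3, -1, 1, 3)) -> tuple[float, float]:
    """Within-subject linear trend test over ordered levels.

    `level_means` is subjects x levels.  Each subject's trend score is the
    weighted sum of their level means with centred linear weights; under the
    null the scores have mean zero, giving F(1, n-1) = n * mean(s)^2 / var(s).
    """
    m = np.asarray(level_means, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D subjects x levels array with >= 2 subjects")
    w = np.asarray(weights, dtype=float)
    if len(w) != m.shape[1]:
        raise ValueError("weight length must match the number of levels")
    s = m @ w
    n = len(s)
    var = s.var(ddof=1)
    if var == 0:
        if s.mean() == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance contrast scores with nonzero mean")
        return np.inf, 0.0
    F = n * s.mean() ** 2 / var
    p = float(stats.f.sf(F, 1, n - 1))
    return float(F), p


def paired_t(x, y) -> tuple[float, float]:
    """Classical paired t test; errors on degenerate zero-variance differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = float(2 * stats.t.sf(abs(t), len(d) - 1))
    return float(t), p
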