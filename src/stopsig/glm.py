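"""First- and second-level GLM for the stop-signal anticipation task.

First level: event regressors for StopSuccess, StopFailure and Go trials with
stop-signal probability > 0 (baseline Go trials are the implicit baseline),
plus z-scored RT and p_stop parametric modulators on the p>0 Go trials, rest
boxcars, outlier impulses, a discrete-cosine high-pass basis (cutoff 128 s)
and an intercept.  Serial correlation is handled by iterated AR(1)
prewhitening in the Cochrane-Orcutt style: the pooled lag-1 autocorrelation
of the residuals drives the whitening filter, iterated with a bias
correction (the raw residual autocorrelation is pulled toward zero by the
design projection) until it matches its white-noise expectation.  The scheme
matches restricted-maximum-likelihood AR(1) weighting in expectation for
this model class while remaining a plain linear solve per pass.

Second level: one-sample t over per-subject contrast estimates, and the
stop-signal-probability x RT-bin repeated-measures ANOVA with
Greenhouse-Geisser correction (F ratios from statsmodels' AnovaRM; epsilon
computed here from the within-subject covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from . import hemo
from .bold import event_impulse_times, standardized_modulators
from .race import SessionData
from .task import TrialSequence

__all__ = [
    "DesignMatrix",
    "build_design_matrix",
    "FirstLevelGLM",
    "FirstLevelResults",
    "ContrastResult",
    "group_t",
    "rm_anova_2way",
    "permutation_cluster_test",
    "CONTRASTS",
]

TASK_COLUMNS = ("stop_success", "stop_failure", "go_exp", "rt_mod", "pstop_mod")


@dataclass
class DesignMatrix:
    """Scan x regressor design with names, frame times and diagnostics."""

    frame: pd.DataFrame            # index: frame times (s)
    n_task: int                    # number of leading task columns
    modulator_correlation: float   # |r| between the two parametric modulators
    vifs: pd.Series                # variance-inflation factors for task columns

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", float_format="%.8g")


def _check_rank(X: pd.DataFrame) -> None:
    m = X.to_numpy()
    rank = np.linalg.matrix_rank(m)
    if rank < m.shape[1]:
        # name the offending columns via QR pivoting
        _, r = np.linalg.qr(m)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def build_design_matrix(
    sequence: TrialSequence,
    session: SessionData,
    tr: float,
    n_scans: int,
    oversampling: int = 16,
    high_pass_s: float = 128.0,
    outlier_flags: pd.Series | None = None,
    nuisance: pd.DataFrame | None = None,
    impulse_timing: str = "response",
) -> DesignMatrix:
    """Assemble the first-level design matrix for one session."""
    cfg = sequence.config
    df = session.trials
    times = event_impulse_times(session, cfg.target_rt, impulse_timing)
    frame_times = np.arange(n_scans) * tr
    cols: dict[str, np.ndarray] = {}

    def reg(mask, amplitudes=None):
        t = times[mask].to_numpy()
        a = np.ones(len(t)) if amplitudes is None else np.asarray(amplitudes, float)
        return hemo.event_regressor(t, a, n_scans, tr, oversampling)

    is_outlier = (
        outlier_flags.reindex(df.index, fill_value=False)
        if outlier_flags is not None
        else pd.Series(False, index=df.index)
    )
    ss = (df["outcome"] == "StopSuccess") & ~is_outlier
    sf = (df["outcome"] == "StopFailure") & ~is_outlier
    go_exp = (df["trial_type"] == "go") & (df["level"] > 0) & ~is_outlier

    if ss.any():
        cols["stop_success"] = reg(ss)
    if sf.any():
        cols["stop_failure"] = reg(sf)
    if go_exp.any():
        cols["go_exp"] = reg(go_exp)
        mods = standardized_modulators(session)
        mods = mods.loc[mods.index.intersection(df.index[go_exp])]
        # re-standardize over the retained parent events
        for name, col in (("rt_mod", "rt"), ("pstop_mod", "pstop")):
            x = mods[col].to_numpy()
            x = x - x.mean()
            cols[name] = hemo.event_regressor(
                times[mods.index].to_numpy(), x, n_scans, tr, oversampling
            )

    n_task = len(cols)

    # conditions of no interest
    rest_windows = _rest_windows(sequence)
    if rest_windows:
        onsets = np.array([w[0] for w in rest_windows])
        durs = np.array([w[1] for w in rest_windows])
        cols["rest"] = hemo.event_regressor(
            onsets, np.ones(len(onsets)), n_scans, tr, oversampling, durations_s=durs
        )
    if is_outlier.any():
        cols["outlier"] = reg(is_outlier)

    if nuisance is not None:
        for name in nuisance.columns:
            cols[f"nuis_{name}"] = np.asarray(nuisance[name], float)

    drift = hemo.dct_basis(n_scans, tr, high_pass_s)
    for k in range(drift.shape[1]):
        cols[f"dct_{k + 1}"] = drift[:, k]
    cols["constant"] = np.ones(n_scans)

    X = pd.DataFrame(cols, index=frame_times)
    _check_rank(X)

    if "rt_mod" in X and "pstop_mod" in X:
        mod_corr = float(abs(np.corrcoef(X["rt_mod"], X["pstop_mod"])[0, 1]))
    else:
        mod_corr = np.nan
    vifs = _vif(X, [c for c in TASK_COLUMNS if c in X])
    return DesignMatrix(frame=X, n_task=n_task, modulator_correlation=mod_corr, vifs=vifs)


def _rest_windows(sequence: TrialSequence) -> list[tuple[float, float]]:
    """(onset, duration) of the scheduled rest blocks, from onset gaps."""
    cfg = sequence.config
    pitch = cfg.trial_pitch_ms / 1000.0
    onsets = np.array([t.onset for t in sequence.trials])
    out = []
    for i in range(len(onsets) - 1):
        gap = onsets[i + 1] - onsets[i] - pitch
        if gap > 1e-6:
            out.append((onsets[i] + pitch, gap))
    return out


def _vif(X: pd.DataFrame, cols: list[str]) -> pd.Series:
    out = {}
    m = X.to_numpy()
    for c in cols:
        j = X.columns.get_loc(c)
        y = m[:, j]
        others = np.delete(m, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        denom = ((y - y.mean()) ** 2).sum()
        r2 = 1 - (resid**2).sum() / denom if denom > 0 else 0.0
        out[c] = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# model / results


@dataclass
class ContrastResult:
    weights: np.ndarray
    estimate: pd.Series   # per region
    se: pd.Series
    t: pd.Series
    p: pd.Series

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimate, "se": self.se, "t": self.t, "p": self.p}
        )

    def ci(self, alpha: float = 0.05, dof: int | None = None) -> pd.DataFrame:
        if dof is None:
            raise ValueError("dof required for confidence intervals")
        half = stats.t.ppf(1 - alpha / 2, dof) * self.se
        return pd.DataFrame({"low": self.estimate - half, "high": self.estimate + half})


CONTRASTS = {
    "stop_success_gt_failure": {"stop_success": 1.0, "stop_failure": -1.0},
    "stop_success_gt_baseline": {"stop_success": 1.0},
    "pstop_effect": {"pstop_mod": 1.0},
    "rt_effect": {"rt_mod": 1.0},
}


class FirstLevelGLM:
    """Mass-univariate first-level model: Y (region x scan) against a design.

    `fit` performs the two-pass AR(1) prewhitened least-squares described in
    the module docstring and returns a `FirstLevelResults`.
    """

    def __init__(self, Y, design: DesignMatrix):
        if isinstance(Y, pd.DataFrame):
            self.region_names = list(Y.index)
            Y = Y.to_numpy()
        else:
            Y = np.atleast_2d(np.asarray(Y, dtype=float))
            self.region_names = [f"region_{i}" for i in range(Y.shape[0])]
        self.Y = Y.T  # scans x regions internally
        self.design = design
        n_scans, n_reg = self.design.frame.shape
        if self.Y.shape[0] != n_scans:
            raise ValueError("Y and design disagree on the number of scans")
        if n_scans <= n_reg:
            raise ValueError("more regressors than scans")

    def fit(self, prewhiten: bool = True, max_iter: int = 4) -> "FirstLevelResults":
        X = self.design.matrix
        Y = self.Y
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        rho_regions = _lag1_autocorr(resid)
        rho = 0.0
        Xw = X
        if prewhiten:
            # fixed-point iteration: raise rho until the whitened residuals'
            # lag-1 autocorrelation matches its null (white-noise) expectation
            # tr(L M)/tr(M) for the current whitened design — the raw residual
            # autocorrelation is biased low by the projection, so targeting
            # zero would under-whiten
            for _ in range(max_iter):
                r = float(np.mean(_lag1_autocorr(resid)))
                r0 = _null_resid_lag1(Xw)
                if abs(r - r0) < 1e-3:
                    break
                rho = float(np.clip(rho + (r - r0), -0.99, 0.99))
                Xw = _ar1_whiten(X, rho)
                Yw = _ar1_whiten(Y, rho)
                beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
                resid = Yw - Xw @ beta
        dof = X.shape[0] - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        return FirstLevelResults(
            model=self,
            params=pd.DataFrame(beta, index=self.design.names, columns=self.region_names),
            sigma2=pd.Series(sigma2, index=self.region_names),
            rho=rho,
            rho_regions=pd.Series(rho_regions, index=self.region_names),
            dof=dof,
            _xtx_inv=xtx_inv,
            residuals=resid,
        )


def _null_resid_lag1(X: np.ndarray) -> float:
    """Expected lag-1 autocorrelation of OLS residuals under white noise.

    With M = I - X(X'X)^-1 X' and L the symmetrized lag-1 operator, this is
    tr(L M)/tr(M) = -tr(Q'(LQ))/(n - p) for an orthonormal basis Q of col(X);
    slightly negative, because the projection absorbs smooth noise.
    """
    n, p = X.shape
    q, _ = np.linalg.qr(X)
    lq = np.zeros_like(q)
    lq[:-1] += 0.5 * q[1:]
    lq[1:] += 0.5 * q[:-1]
    return float(-(q * lq).sum() / (n - p))


def _lag1_autocorr(resid: np.ndarray) -> np.ndarray:
    num = (resid[1:] * resid[:-1]).sum(axis=0)
    den = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -0.99, 0.99)


def _ar1_whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) whitening filter along axis 0."""
    W = np.empty_like(A, dtype=float)
    W[0] = np.sqrt(1.0 - rho**2) * A[0]
    W[1:] = A[1:] - rho * A[:-1]
    return W


@dataclass
class FirstLevelResults:
    model: FirstLevelGLM
    params: pd.DataFrame        # regressor x region
    sigma2: pd.Series
    rho: float
    rho_regions: pd.Series
    dof: int
    _xtx_inv: np.ndarray
    residuals: np.ndarray

    def contrast(self, weights) -> ContrastResult:
        """Linear contrast of the regression coefficients.

        `weights` is a name->weight mapping (missing names get 0), a contrast
        name from `CONTRASTS`, or a full-length weight vector.
        """
        names = self.model.design.names
        if isinstance(weights, str):
            weights = CONTRASTS[weights]
        if isinstance(weights, dict):
            missing = set(weights) - set(names)
            if missing:
                raise ValueError(f"unknown regressors in contrast: {sorted(missing)}")
            w = np.array([weights.get(nm, 0.0) for nm in names])
        else:
            w = np.asarray(weights, dtype=float)
            if len(w) != len(names):
                raise ValueError("contrast weight length must match regressor count")
        if not np.any(w):
            raise ValueError("contrast weights are all zero")
        est = w @ self.params.to_numpy()
        var_unit = float(w @ self._xtx_inv @ w)
        se = np.sqrt(var_unit * self.sigma2.to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, est / se, np.nan)
        p = 2 * stats.t.sf(np.abs(t), self.dof)
        idx = self.model.region_names
        return ContrastResult(
            weights=w,
            estimate=pd.Series(est, index=idx),
            se=pd.Series(se, index=idx),
            t=pd.Series(t, index=idx),
            p=pd.Series(p, index=idx),
        )

    def summary(self) -> str:
        lines = [
            "First-level GLM (AR(1)-prewhitened least squares)",
            f"  scans: {self.model.Y.shape[0]}  regressors: {len(self.model.design.names)}"
            f"  dof: {self.dof}",
            f"  pooled AR(1) rho: {self.rho:.3f}",
            f"  modulator |r|: {self.model.design.modulator_correlation:.3f}",
            "",
            self.params.round(4).to_string(),
        ]
        return "\n".join(lines)


def group_t(values) -> tuple[float, float]:
    """Second-level one-sample t test of per-subject estimates against zero."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D array with n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across subjects: t undefined")
    t = v.mean() / (sd / np.sqrt(len(v)))
    p = float(2 * stats.t.sf(abs(t), len(v) - 1))
    return float(t), p


def _gg_epsilon(cells: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by contrast matrix C.

    `cells` is subjects x conditions; C maps conditions to the effect's
    (k-1)-dimensional contrast space (rows orthonormal).
    """
    S = np.cov(cells @ C.T, rowvar=False)
    S = np.atleast_2d(S)
    lam = np.linalg.eigvalsh(S)
    lam = np.clip(lam, 0, None)
    q = S.shape[0]
    denom = q * (lam**2).sum()
    if denom == 0:
        return 1.0
    return float(lam.sum() ** 2 / denom)


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def rm_anova_2way(values: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA (p_stop x rt_bin) with GG correction.

    `values` is subjects x p_stop levels x rt bins, complete (no missing
    cells).  F ratios and uncorrected dof come from statsmodels' AnovaRM;
    Greenhouse-Geisser epsilon, computed from the within-subject covariance of
    the effect contrasts, corrects the p_stop main effect and the interaction
    (the 2-level RT factor needs none).  Returns one row per effect with
    F, corrected dof, epsilon and the corrected p value.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3:
        raise ValueError("values must be subjects x p_stop x rt_bin")
    if np.isnan(v).any():
        raise ValueError("missing cells are not supported")
    n, a, b = v.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), a * b),
            "p_stop": np.tile(np.repeat(np.arange(a), b), n),
            "rt_bin": np.tile(np.arange(b), n * a),
            "value": v.reshape(-1),
        }
    )
    if np.allclose(v, v.mean(axis=(1, 2), keepdims=True)):
        # constant within subject: all effects are exactly zero
        rows = []
        for effect, df1 in (("p_stop", a - 1), ("rt_bin", b - 1), ("p_stop:rt_bin", (a - 1) * (b - 1))):
            rows.append({"effect": effect, "F": 0.0, "df1": float(df1),
                         "df2": float(df1 * (n - 1)), "epsilon": 1.0, "p": 1.0})
        return pd.DataFrame(rows).set_index("effect")

    res = AnovaRM(long, "value", "subject", within=["p_stop", "rt_bin"]).fit()
    tab = res.anova_table  # F Value, Num DF, Den DF, Pr > F

    Ca = _helmert(a)
    Cb = _helmert(b)
    cells_a = v.mean(axis=2)            # subjects x a
    cells_b = v.mean(axis=1)            # subjects x b
    cells_ab = v.reshape(n, a * b)      # subjects x (a*b), b fastest
    C_inter = np.kron(Ca, Cb)
    eps = {
        "p_stop": _gg_epsilon(cells_a, Ca),
        "rt_bin": 1.0 if b == 2 else _gg_epsilon(cells_b, Cb),
        "p_stop:rt_bin": _gg_epsilon(cells_ab, C_inter),
    }

    rows = []
    for effect in ("p_stop", "rt_bin", "p_stop:rt_bin"):
        F = float(tab.loc[effect, "F Value"])
        df1 = float(tab.loc[effect, "Num DF"])
        df2 = float(tab.loc[effect, "Den DF"])
        e = eps[effect] if effect != "rt_bin" else 1.0
        p = float(stats.f.sf(F, df1 * e, df2 * e))
        rows.append(
            {"effect": effect, "F": F, "df1": df1 * e, "df2": df2 * e,
             "epsilon": e, "p": p}
        )
    return pd.DataFrame(rows).set_index("effect")


def rt_bin_cell_means(session: SessionData) -> np.ndarray | None:
    """Per-level (slow/fast) RT-bin assignment helper for ROI cell means.

    Returns a levels x 2 table of mean RTs per (p_stop level, RT bin) for the
    p>0 Go trials of one session, median-split within each level; None when a
    level has fewer than 2 Go trials.
    """
    df = session.trials
    go = df[(df["trial_type"] == "go") & (df["level"] > 0)]
    levels = sorted(go["level"].unique())
    out = np.full((len(levels), 2), np.nan)
    for i, lev in enumerate(levels):
        rts = go.loc[go["level"] == lev, "rt"].to_numpy()
        if len(rts) < 2:
            return None
        med = np.median(rts)
        fast, slow = rts[rts <= med], rts[rts > med]
        if len(slow) == 0:
            return None
        out[i] = [fast.mean(), slow.mean()]
    return out


def permutation_cluster_test(estimates, threshold: float = 2.0,
                             n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Group-level permutation max-cluster-mass test along a 1-D voxel axis.

    A nonparametric stand-in for random-field cluster inference on the tiled
    phantom: `estimates` is subjects x voxels (per-voxel contrast estimates).
    Contiguous runs of voxels with one-sample |t| > `threshold` form clusters
    whose mass is the summed |t|; the null maximum-mass distribution comes
    from random sign flips of whole subjects.  Returns one row per observed
    cluster with (start, end, mass, p).
    """
    X = np.asarray(estimates, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("estimates must be subjects x voxels with >= 2 subjects")
    n, v = X.shape
    rng = np.random.default_rng(seed)

    def tmap(mat):
        sd = mat.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return mat.mean(axis=0) / (sd / np.sqrt(n))

    def clusters(t):
        mask = np.abs(t) > threshold
        out = []
        i = 0
        while i < v:
            if mask[i]:
                j = i
                while j + 1 < v and mask[j + 1]:
                    j += 1
                out.append((i, j, float(np.abs(t[i : j + 1]).sum())))
                i = j + 1
            else:
                i += 1
        return out

    observed = clusters(tmap(X))
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)[:, None]
        null_max[k] = max((m for *_, m in clusters(tmap(signs * X))), default=0.0)
    rows = [
        {"start": a, "end": b, "mass": m, "p": float((null_max >= m).mean())}
        for a, b, m in observed
    ]
    return pd.DataFrame(rows, columns=["start", "end", "mass", "p"])
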