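"""Psychophysiological interaction (PPI) analysis.

A PPI tests whether the coupling between a seed region and a sink region
changes with the psychological context — here, successful versus failed
stopping.  Because BOLD is a haemodynamically blurred readout of neural
activity, the interaction must be formed at the neural level: the seed's BOLD
series (first eigenvariate of its voxels) is deconvolved against the canonical
HRF, multiplied point-by-point with a +1/-1 context vector marking StopSuccess
and StopFailure onsets, reconvolved, and entered — together with the
physiological (seed) and psychological (context) regressors — into a
prewhitened regression on the sink series.  The interaction coefficient is the
PPI: a change in regression slope between the two contexts.

Deconvolution is a generalized-ridge inverse of the HRF convolution operator
on a microtime grid (TR/16): minimize ||Hx - y||^2 + lambda ||Dx||^2 with D a
first-difference smoother, the regularized shrinkage playing the role of an
empirical-Bayes prior on the neural signal; lambda can be fixed or chosen by
generalized cross-validation (GCV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.linalg import splu

from . import hemo
from .glm import group_t  # noqa: F401  (re-exported: second level of the PPI)

__all__ = [
    "SeedSeries",
    "extract_eigenvariate",
    "DeconvolutionOperator",
    "deconvolve",
    "ppi_regressors",
    "task_nuisance_regressors",
    "PPIModel",
    "PPIResult",
]


@dataclass
class SeedSeries:
    """Unit-variance summary time series of a seed region."""

    series: np.ndarray
    name: str = "seed"


def extract_eigenvariate(voxel_matrix: np.ndarray, name: str = "seed") -> SeedSeries:
    """First eigenvariate of a voxel x scan matrix, scaled to unit variance.

    The sign is chosen so the eigenvariate correlates positively with the
    across-voxel mean series; if that mean is (numerically) zero — e.g. voxels
    split evenly into +s and -s — the first voxel's series breaks the tie.
    """
    V = np.asarray(voxel_matrix, dtype=float)
    if V.ndim != 2 or V.shape[0] < 1:
        raise ValueError("voxel_matrix must be 2-D with at least one voxel")
    if not np.any(V):
        raise ValueError("all-zero voxel matrix has no eigenvariate")
    Vc = V - V.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Vc, full_matrices=False)
    e = vt[0]
    ref = Vc.mean(axis=0)
    align = float(e @ ref)
    if abs(align) < 1e-12 * np.linalg.norm(e) * max(np.linalg.norm(ref), 1e-300):
        align = float(e @ Vc[0])
    if align < 0:
        e = -e
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate eigenvariate (zero variance)")
    return SeedSeries(series=e / sd, name=name)


class DeconvolutionOperator:
    """Cached generalized-ridge deconvolution for a fixed (n_scans, tr) geometry.

    Builds the sparse HRF convolution-and-sample operator H (scan x microtime)
    and the first-difference smoother D once; factorizations of
    H'H + lambda D'D are cached per lambda so whole cohorts with a shared scan
    geometry reuse a single factorization.
    """

    def __init__(self, n_scans: int, tr: float, oversampling: int = 16):
        self.n_scans = n_scans
        self.tr = tr
        self.oversampling = oversampling
        self.n_micro = n_scans * oversampling
        dt = tr / oversampling
        h = hemo.canonical_hrf(dt)
        # full convolution matrix row i: sum_j h[i*os - j] x[j]
        rows, cols_, vals = [], [], []
        for i in range(n_scans):
            base = i * oversampling
            jmax = min(base, self.n_micro - 1)
            jmin = max(0, base - len(h) + 1)
            j = np.arange(jmin, jmax + 1)
            rows.append(np.full(len(j), i))
            cols_.append(j)
            vals.append(h[base - j])
        self.H = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols_))),
            shape=(n_scans, self.n_micro),
        )
        D = sparse.diags([-np.ones(self.n_micro - 1), np.ones(self.n_micro - 1)],
                         offsets=[0, 1], shape=(self.n_micro - 1, self.n_micro))
        self._HtH = (self.H.T @ self.H).tocsc()
        self._DtD = (D.T @ D).tocsc()
        self._lu_cache: dict[float, object] = {}

    def _factor(self, lam: float):
        key = float(lam)
        if key not in self._lu_cache:
            A = (self._HtH + lam * self._DtD).tocsc()
            self._lu_cache[key] = splu(A)
        return self._lu_cache[key]

    def solve(self, y: np.ndarray, lam: float) -> np.ndarray:
        """Deconvolved microtime neural estimate for one scan series."""
        y = np.asarray(y, dtype=float)
        if len(y) != self.n_scans:
            raise ValueError("series length must equal n_scans")
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        if not np.any(y):
            return np.zeros(self.n_micro)
        rhs = self.H.T @ y
        return self._factor(max(lam, 1e-10)).solve(rhs)

    def gcv(self, y: np.ndarray, lambdas=None, n_probes: int = 12, seed: int = 0) -> float:
        """Pick lambda by generalized cross-validation over a log grid.

        GCV(lam) = n ||y - H x_lam||^2 / (n - tr(Hat_lam))^2, the hat-matrix
        trace estimated by Hutchinson probing with a fixed-seed +-1 ensemble.
        """
        if lambdas is None:
            lambdas = np.logspace(-2, 3, 11)
        rng = np.random.default_rng(seed)
        probes = rng.choice([-1.0, 1.0], size=(n_probes, self.n_scans))
        best_lam, best_score = lambdas[0], np.inf
        for lam in lambdas:
            lu = self._factor(lam)
            x = lu.solve(self.H.T @ y)
            rss = float(((y - self.H @ x) ** 2).sum())
            tr_hat = 0.0
            for u in probes:
                v = self.H.T @ u
                tr_hat += float(v @ lu.solve(v))
            tr_hat /= n_probes
            denom = max(self.n_scans - tr_hat, 1e-6)
            score = self.n_scans * rss / denom**2
            if score < best_score:
                best_lam, best_score = lam, score
        return float(best_lam)


def deconvolve(
    series: SeedSeries | np.ndarray,
    n_scans: int | None = None,
    tr: float = 1.6,
    lam: float | str = "gcv",
    oversampling: int = 16,
    operator: DeconvolutionOperator | None = None,
) -> np.ndarray:
    """Deconvolve a scan-resolution series to a microtime neural estimate.

    `lam` is either a non-negative ridge weight or "gcv".  Pass a shared
    `DeconvolutionOperator` to amortize the sparse factorization across many
    series with the same geometry.
    """
    y = series.series if isinstance(series, SeedSeries) else np.asarray(series, float)
    y = y - y.mean()
    if operator is None:
        operator = DeconvolutionOperator(n_scans or len(y), tr, oversampling)
    lam_val = operator.gcv(y) if lam == "gcv" else float(lam)
    return operator.solve(y, lam_val)


def ppi_regressors(
    neural_micro: np.ndarray,
    stop_success_onsets: np.ndarray,
    stop_failure_onsets: np.ndarray,
    tr: float,
    n_scans: int,
    oversampling: int = 16,
    center_psych: bool = False,
) -> pd.DataFrame:
    """Physiological, psychological and interaction regressors at scan resolution.

    The psychological vector carries +1 impulses at StopSuccess onsets and -1
    at StopFailure onsets on the microtime grid (optionally mean-centered over
    impulses for unbalanced designs); the interaction is its elementwise
    product with the neural estimate.  All three are HRF-convolved and read
    out at the scan times.
    """
    ss = np.asarray(stop_success_onsets, dtype=float)
    sf = np.asarray(stop_failure_onsets, dtype=float)
    if ss.size + sf.size == 0:
        raise ValueError("no Stop events: PPI psychological vector is empty")
    n_micro = n_scans * oversampling
    if len(neural_micro) != n_micro:
        raise ValueError("neural series length must be n_scans * oversampling")
    psych = np.zeros(n_micro)
    idx_ss = hemo.microtime_index(ss, tr, oversampling)
    idx_sf = hemo.microtime_index(sf, tr, oversampling)
    if (idx_ss >= n_micro).any() or (idx_sf >= n_micro).any():
        raise ValueError("Stop events fall outside the scanned window")
    np.add.at(psych, idx_ss, 1.0)
    np.add.at(psych, idx_sf, -1.0)
    if center_psych:
        nz = psych != 0
        psych[nz] -= psych[nz].mean()
    inter = neural_micro * psych
    out = {
        "physio": hemo.convolve_to_scans(neural_micro, tr, oversampling),
        "psych": hemo.convolve_to_scans(psych, tr, oversampling),
        "ppi": hemo.convolve_to_scans(inter, tr, oversampling),
    }
    return pd.DataFrame(out, index=np.arange(n_scans) * tr)


def task_nuisance_regressors(session, tr: float, n_scans: int,
                             oversampling: int = 16) -> pd.DataFrame:
    """HRF-convolved task condition regressors (StopSuccess, StopFailure, Go p>0).

    Passed as nuisance covariates to `PPIModel`, these absorb the sink's own
    evoked responses so the interaction term is estimated from the seed's
    ongoing-activity transmission only — the generalized-PPI safeguard against
    evoked-response confounds.
    """
    from .bold import event_impulse_times

    df = session.trials
    times = event_impulse_times(session, session.sequence.config.target_rt)
    cols = {}
    for name, mask in (
        ("stop_success", df["outcome"] == "StopSuccess"),
        ("stop_failure", df["outcome"] == "StopFailure"),
        ("go_exp", (df["trial_type"] == "go") & (df["level"] > 0)),
    ):
        if mask.any():
            cols[name] = hemo.event_regressor(
                times[mask].to_numpy(), np.ones(int(mask.sum())), n_scans, tr, oversampling
            )
    return pd.DataFrame(cols, index=np.arange(n_scans) * tr)


@dataclass
class PPIResult:
    """Sink-region PPI regression estimates and the interaction verdict."""

    beta: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    dof: int
    rho: float
    alpha: float
    sink: str = "sink"

    @property
    def sign(self) -> str:
        if self.p["ppi"] < self.alpha:
            return "positive" if self.beta["ppi"] > 0 else "negative"
        return "null"

    def summary(self) -> str:
        lines = [
            f"PPI regression on sink {self.sink!r} "
            f"(AR(1) rho={self.rho:.3f}, dof={self.dof})",
            pd.DataFrame({"beta": self.beta, "se": self.se, "t": self.t, "p": self.p})
            .round(4)
            .to_string(),
            f"interaction: {self.sign} at alpha={self.alpha}",
        ]
        return "\n".join(lines)


class PPIModel:
    """Prewhitened regression of a sink series on the three PPI regressors."""

    def __init__(
        self,
        sink: np.ndarray,
        regressors: pd.DataFrame,
        nuisance: pd.DataFrame | None = None,
        sink_name: str = "sink",
    ):
        self.sink = np.asarray(sink, dtype=float)
        if len(self.sink) != len(regressors):
            raise ValueError("sink and regressors disagree on scan count")
        X = regressors[["physio", "psych", "ppi"]].copy()
        if nuisance is not None:
            for c in nuisance.columns:
                X[f"nuis_{c}"] = np.asarray(nuisance[c], float)
        X["constant"] = 1.0
        cond = np.linalg.cond(X.to_numpy())
        if cond > 1e8:
            raise ValueError(f"collinear PPI regressors (condition number {cond:.2e})")
        self.X = X
        self.sink_name = sink_name

    def fit(self, alpha: float = 0.05, prewhiten: bool = True) -> PPIResult:
        X = self.X.to_numpy()
        y = self.sink
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rho = 0.0
        if prewhiten:
            den = float((resid**2).sum())
            rho = float(np.clip((resid[1:] * resid[:-1]).sum() / den, -0.99, 0.99)) if den else 0.0
            if abs(rho) > 1e-12:
                Xw = np.empty_like(X)
                Xw[0] = np.sqrt(1 - rho**2) * X[0]
                Xw[1:] = X[1:] - rho * X[:-1]
                yw = np.empty_like(y)
                yw[0] = np.sqrt(1 - rho**2) * y[0]
                yw[1:] = y[1:] - rho * y[:-1]
                X, y = Xw, yw
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
        dof = X.shape[0] - X.shape[1]
        sigma2 = float((resid**2).sum() / dof)
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        t = beta / se
        p = 2 * stats.t.sf(np.abs(t), dof)
        names = list(self.X.columns)
        return PPIResult(
            beta=pd.Series(beta, index=names),
            se=pd.Series(se, index=names),
            t=pd.Series(t, index=names),
            p=pd.Series(p, index=names),
            dof=dof,
            rho=rho,
            alpha=alpha,
            sink=self.sink_name,
        )
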