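"""Hemodynamic forward model shared by the BOLD synthesizer, the GLM and the PPI stage.

The canonical haemodynamic response function (HRF) is the usual difference of
two gamma densities: a positive lobe peaking ~5 s after a neural event and a
small undershoot peaking ~15 s later, with the undershoot scaled to 1/6 of the
positive lobe.  Event regressors are built on a "microtime" grid (an oversampled
time axis, default 16 samples per TR), convolved with the HRF sampled on that
grid, and then read out at the scan acquisition times.  Low-frequency drift is
spanned by a discrete cosine basis up to a cutoff period.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "canonical_hrf",
    "microtime_index",
    "neural_impulses",
    "convolve_to_scans",
    "event_regressor",
    "dct_basis",
]

HRF_DURATION = 32.0  # seconds of kernel support

# canonical double-gamma parameters: response/undershoot peak delays (s),
# dispersions (s), and undershoot ratio
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_PEAK_DISP = 1.0
_UNDERSHOOT_DISP = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def canonical_hrf(dt: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Canonical double-gamma HRF sampled every `dt` seconds over `duration` s.

    The kernel is scaled to unit peak; it is exactly zero at t = 0 because both
    gamma densities have shape > 1.

    Parameters
    ----------
    dt : sampling interval in seconds, 0 < dt <= 1.6.
    duration : kernel support in seconds (default 32 s).
    """
    if not 0.0 < dt <= 1.6:
        raise ValueError(f"dt must be in (0, 1.6] s, got {dt}")
    t = np.arange(0.0, duration, dt)
    h = (
        _gamma_dist.pdf(t, _PEAK_DELAY / _PEAK_DISP, scale=_PEAK_DISP)
        - _UNDERSHOOT_RATIO
        * _gamma_dist.pdf(t, _UNDERSHOOT_DELAY / _UNDERSHOOT_DISP, scale=_UNDERSHOOT_DISP)
    )
    return h / h.max()


def microtime_index(times_s: np.ndarray, tr: float, oversampling: int) -> np.ndarray:
    """Map event times (s) to indices on the oversampled microtime grid."""
    dt = tr / oversampling
    return np.round(np.asarray(times_s, dtype=float) / dt).astype(int)


def neural_impulses(
    onsets_s: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
    oversampling: int = 16,
    durations_s: np.ndarray | None = None,
) -> np.ndarray:
    """Neural-level microtime series: impulses (or boxcars) at the given times.

    Events must fall inside the scanned window [0, n_scans * tr).
    """
    n_micro = n_scans * oversampling
    dt = tr / oversampling
    x = np.zeros(n_micro)
    onsets_s = np.asarray(onsets_s, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if onsets_s.size and (onsets_s.min() < 0 or onsets_s.max() >= n_scans * tr):
        raise ValueError("event onset outside the scanned window")
    idx = microtime_index(onsets_s, tr, oversampling)
    idx = np.clip(idx, 0, n_micro - 1)
    if durations_s is None:
        np.add.at(x, idx, amplitudes)
    else:
        lengths = np.maximum(1, np.round(np.asarray(durations_s) / dt).astype(int))
        for i, a, ln in zip(idx, amplitudes, lengths):
            x[i : min(i + ln, n_micro)] += a
    return x


def convolve_to_scans(
    neural_micro: np.ndarray, tr: float, oversampling: int = 16,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve a microtime neural series with the HRF and read out at scan times.

    Scan i is read at t = i * TR (microtime sample i * oversampling)."""
    dt = tr / oversampling
    if hrf is None:
        hrf = canonical_hrf(dt)
    bold = np.convolve(neural_micro, hrf)[: len(neural_micro)]
    return bold[::oversampling] * 1.0


def event_regressor(
    onsets_s: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
    oversampling: int = 16,
    durations_s: np.ndarray | None = None,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved scan-resolution regressor for a set of weighted events."""
    x = neural_impulses(onsets_s, amplitudes, n_scans, tr, oversampling, durations_s)
    return convolve_to_scans(x, tr, oversampling, hrf)


def dct_basis(n_scans: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete cosine drift basis with periods longer than `cutoff_s` seconds.

    Returns an (n_scans, k) array, k = floor(2 * n_scans * tr / cutoff_s),
    excluding the constant term (modelled separately as an intercept).
    """
    order = int(np.floor(2.0 * n_scans * tr / cutoff_s))
    t = np.arange(n_scans)
    basis = np.empty((n_scans, max(order, 0)))
    for k in range(1, order + 1):
        basis[:, k - 1] = np.sqrt(2.0 / n_scans) * np.cos(
            np.pi * k * (2 * t + 1) / (2 * n_scans)
        )
    return basis
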