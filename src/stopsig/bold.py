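"""Region-level BOLD synthesis with planted, recoverable effects.

Each region's neural signal is a train of impulses at the (response-locked)
event times, scaled by per-condition amplitudes plus modulator slopes, with an
optional condition-dependent coupling onto a designated seed region's neural
signal.  Neural signals are convolved with the canonical HRF, sampled at the
TR, and corrupted with AR(1) Gaussian noise.  Because the generative model is
exactly the model the GLM fits, noiseless synthesis is recovered to machine
precision — the ground truth is part of the dataset so every downstream stage
can be tested by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import hemo
from .race import SessionData
from .task import TrialSequence

__all__ = ["RegionSpec", "BOLDDataset", "synthesize_bold", "default_regions",
           "tile_region", "export_phantom_nifti"]


@dataclass(frozen=True)
class RegionSpec:
    """Planted effect sizes for one synthetic region (arbitrary signal units).

    `amp_go` applies to Go trials with p_stop > 0 only; baseline (0 % cue) Go
    trials are the implicit baseline and evoke nothing.  `slope_pstop` and
    `slope_rt` scale the z-scored parametric modulators on those Go trials.
    `coupling_seed` adds a constant gain on the seed region's neural signal and
    `coupling_delta` the change of that gain between StopSuccess (+) and
    StopFailure (-) contexts.

    `neural_noise_sd` is the standard deviation of ongoing neural fluctuation
    (an exponentially correlated process at microtime, time constant
    `neural_noise_tau` s) added to the region's neural signal *before* HRF
    convolution.  For a seed region this ongoing activity is what propagates
    to coupled sinks and makes a condition-dependent coupling change
    identifiable over and above the evoked responses.  `noise_sd` is
    measurement noise at scan resolution (AR(1) with lag-1 correlation
    `ar1_rho`); for a seed meant to mimic an eigenvariate summary of many
    voxels it should be small, since averaging suppresses voxel noise.
    """

    name: str
    amp_stop_success: float = 0.0
    amp_stop_failure: float = 0.0
    amp_go: float = 0.0
    slope_pstop: float = 0.0
    slope_rt: float = 0.0
    coupling_seed: float = 0.0
    coupling_delta: float = 0.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    neural_noise_sd: float = 0.0
    neural_noise_tau: float = 0.8

    def __post_init__(self):
        if self.noise_sd < 0 or self.neural_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.neural_noise_tau <= 0:
            raise ValueError("neural_noise_tau must be positive")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")


def default_regions() -> list[RegionSpec]:
    """Default synthetic region set mirroring the planted-effect taxonomy.

    A striatum-like seed responding more to StopSuccess than StopFailure and
    scaling with stop-signal probability; an M1-like sink whose coupling with
    the seed turns more negative during successful stopping; an SMC-like sink
    with the opposite coupling change; a parietal-like region driven by
    response time only; and a pure-noise control.
    """
    return [
        RegionSpec("striatum", amp_stop_success=1.0, amp_stop_failure=0.3,
                   amp_go=0.2, slope_pstop=0.5, noise_sd=0.3, neural_noise_sd=1.0),
        RegionSpec("m1", amp_go=0.8, amp_stop_failure=0.6, slope_rt=0.3,
                   coupling_seed=0.2, coupling_delta=-0.8, noise_sd=1.0),
        RegionSpec("smc", amp_stop_success=0.6, slope_pstop=0.3,
                   coupling_seed=0.2, coupling_delta=0.8, noise_sd=1.0),
        RegionSpec("parietal", amp_go=0.4, slope_rt=0.5, noise_sd=1.0),
        RegionSpec("control", noise_sd=1.0),
    ]


@dataclass
class BOLDDataset:
    signal: pd.DataFrame          # regions (rows) x scans (columns)
    tr: float
    ground_truth: list[RegionSpec]
    sequence: TrialSequence
    session: SessionData
    seed: int
    seed_region: str | None = None

    @property
    def n_scans(self) -> int:
        return self.signal.shape[1]

    def region(self, name: str) -> np.ndarray:
        return self.signal.loc[name].to_numpy()

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.signal.to_csv(path, sep="\t", float_format="%.8g")
        if sidecar_path is not None:
            meta = {
                "tr": self.tr,
                "n_scans": self.n_scans,
                "regions": [asdict(r) for r in self.ground_truth],
                "seed": self.seed,
                "seed_region": self.seed_region,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def event_impulse_times(
    session: SessionData, target_rt_ms: float, impulse_timing: str = "response"
) -> pd.Series:
    """Time (s) of the neural impulse for each trial.

    'response': at the response (onset + RT; target RT for StopSuccess, which
    has no overt response).  'onset': at trial onset for every trial.
    """
    df = session.trials
    if impulse_timing == "onset":
        return df["onset"].astype(float)
    if impulse_timing != "response":
        raise ValueError("impulse_timing must be 'response' or 'onset'")
    rt = df["rt"].fillna(target_rt_ms)
    return df["onset"] + rt / 1000.0


def standardized_modulators(session: SessionData) -> pd.DataFrame:
    """Z-scored RT and p_stop modulators over the p>0 Go trials (parent events)."""
    df = session.trials
    go = df[(df["trial_type"] == "go") & (df["level"] > 0)]
    out = pd.DataFrame(index=go.index)
    for name, col in (("rt", go["rt"]), ("pstop", go["p_stop"])):
        x = col.to_numpy(dtype=float)
        sd = x.std()
        out[name] = (x - x.mean()) / sd if sd > 0 else 0.0
    return out


def synthesize_bold(
    sequence: TrialSequence,
    session: SessionData,
    regions: list[RegionSpec],
    tr: float = 1.6,
    seed: int = 0,
    n_scans: int | None = None,
    oversampling: int = 16,
    seed_region: str | None = None,
    impulse_timing: str = "response",
) -> BOLDDataset:
    """Forward-model region x scan BOLD signals for one session.

    When `n_scans` is omitted it is chosen to cover the last neural event plus
    the 32-s HRF tail; an explicit shorter value truncates the tail (events
    themselves must stay inside the scanned window).
    """
    region_names = [r.name for r in regions]
    if any(r.coupling_delta != 0 or r.coupling_seed != 0 for r in regions):
        if seed_region is None or seed_region not in region_names:
            raise ValueError(
                f"coupling requested but seed region {seed_region!r} is not "
                f"among {region_names}"
            )

    cfg = sequence.config
    times = event_impulse_times(session, cfg.target_rt, impulse_timing)
    if n_scans is None:
        n_scans = int(np.ceil((times.max() + hemo.HRF_DURATION) / tr)) + 1
    n_micro = n_scans * oversampling
    dtm = tr / oversampling

    df = session.trials
    mods = standardized_modulators(session)

    # per-event amplitude for each region
    def region_neural(spec: RegionSpec) -> np.ndarray:
        amp = pd.Series(0.0, index=df.index)
        amp[df["outcome"] == "StopSuccess"] += spec.amp_stop_success
        amp[df["outcome"] == "StopFailure"] += spec.amp_stop_failure
        go_exp = (df["trial_type"] == "go") & (df["level"] > 0)
        amp[go_exp] += spec.amp_go
        amp.loc[mods.index] += spec.slope_pstop * mods["pstop"] + spec.slope_rt * mods["rt"]
        active = amp != 0
        return hemo.neural_impulses(
            times[active].to_numpy(), amp[active].to_numpy(), n_scans, tr, oversampling
        )

    rng = np.random.default_rng(seed)
    neural = {}
    for spec in regions:
        x = region_neural(spec)
        if spec.neural_noise_sd > 0:
            x = x + _ou_noise(n_micro, dtm, spec.neural_noise_tau,
                              spec.neural_noise_sd, rng)
        neural[spec.name] = x

    # condition context at microtime: +1 during StopSuccess trials, -1 during
    # StopFailure trials, 0 elsewhere (boxcar over the trial pitch)
    if seed_region is not None:
        context = np.zeros(n_micro)
        pitch_n = max(1, int(round(cfg.trial_pitch_ms / 1000.0 / dtm)))
        for _, row in df[df["trial_type"] == "stop"].iterrows():
            i0 = int(round(row["onset"] / dtm))
            sign = 1.0 if row["outcome"] == "StopSuccess" else -1.0
            context[i0 : i0 + pitch_n] = sign
        seed_neural = neural[seed_region]
        for spec in regions:
            if spec.name == seed_region:
                continue
            gain = spec.coupling_seed + context * spec.coupling_delta
            if spec.coupling_seed != 0 or spec.coupling_delta != 0:
                neural[spec.name] = neural[spec.name] + gain * seed_neural

    rows = {}
    for spec in regions:
        y = hemo.convolve_to_scans(neural[spec.name], tr, oversampling)
        if spec.noise_sd > 0:
            y = y + spec.noise_sd * _ar1_noise(n_scans, spec.ar1_rho, rng)
        rows[spec.name] = y
    signal = pd.DataFrame(rows).T
    signal.columns = range(n_scans)
    return BOLDDataset(
        signal=signal, tr=tr, ground_truth=list(regions), sequence=sequence,
        session=session, seed=seed if isinstance(seed, int) else -1,
        seed_region=seed_region,
    )


def _ou_noise(n: int, dt: float, tau: float, sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """Exponentially correlated (Ornstein-Uhlenbeck-like) noise at microtime."""
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    w = rng.normal(0.0, sd * np.sqrt(1.0 - a**2), size=n)
    w[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -a], w)


def _ar1_noise(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with unit marginal variance."""
    e = np.empty(n)
    e[0] = rng.normal()
    innov_sd = np.sqrt(1.0 - rho**2)
    w = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + w[t - 1]
    return e


def tile_region(
    dataset: BOLDDataset, region: str, n_voxels: int, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Tile one region into a voxel x scan matrix by adding independent noise.

    A thin phantom helper for eigenvariate extraction: every voxel is the
    region series plus i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    base = dataset.region(region)
    return base[None, :] + rng.normal(0.0, noise_sd, size=(n_voxels, len(base)))


def export_phantom_nifti(dataset: BOLDDataset, region: str, path,
                         side: int = 3, noise_sd: float = 0.5, seed: int = 0):
    """Write a side^3-voxel tiled phantom of one region as 4-D NIfTI.

    Interoperability demo only (4-mm isotropic voxels, TR in the time zoom);
    requires nibabel.
    """
    import nibabel as nib

    vox = tile_region(dataset, region, side**3, noise_sd, seed)
    data = vox.reshape(side, side, side, dataset.n_scans).astype("float32")
    img = nib.Nifti1Image(data, np.diag([4.0, 4.0, 4.0, 1.0]))
    img.header.set_zooms((4.0, 4.0, 4.0, dataset.tr))
    nib.save(img, str(path))
    return path
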