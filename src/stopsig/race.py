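"""Independent horse-race simulation of stop-signal task behaviour.

Each trial is a race between a Go process and a Stop process.  The Go
finishing time is ex-Gaussian,

    T_go = go_mu + slow_slope * p_stop + Normal(0, go_sigma) + Exp(go_tau),

where the linear `slow_slope * p_stop` term implements proactive slowing:
responses are delayed in proportion to the cued stop-signal probability.  On
Stop trials a stop-signal appears at the staircase-controlled SSD and stopping
succeeds iff SSD + T_ssrt <= T_go, with T_ssrt ~ Normal(ssrt_mu, ssrt_sigma);
with probability `p_trigger_fail` the Stop process is never triggered and the
trial fails regardless of the SSD.  The race is independent (no inhibition of
the Go accumulator by the Stop process): the behavioural measures analysed
downstream depend only on race-consistent outcome logic.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .staircase import Staircase
from .task import TrialSequence

__all__ = [
    "SubjectParams",
    "SessionData",
    "sample_subject",
    "simulate_session",
    "simulate_cohort",
    "default_population",
]


@dataclass(frozen=True)
class SubjectParams:
    """Generative behavioural parameters for one subject (all times in ms)."""

    go_mu: float = 775.0        # Gaussian mean of the Go finishing time at p_stop = 0
    go_sigma: float = 40.0      # Gaussian SD
    go_tau: float = 30.0        # exponential tail
    slow_slope: float = 90.0    # proactive slowing, ms per unit p_stop
    ssrt_mu: float = 320.0      # mean stop-signal reaction time
    ssrt_sigma: float = 30.0
    p_trigger_fail: float = 0.0

    def __post_init__(self):
        if min(self.go_sigma, self.go_tau, self.ssrt_sigma) < 0:
            raise ValueError("scale parameters must be non-negative")
        if not 0.0 <= self.p_trigger_fail <= 1.0:
            raise ValueError("p_trigger_fail must be in [0, 1]")
        if self.slow_slope < 0:
            raise ValueError("slow_slope must be non-negative")


# lower/upper truncation for each field when sampling a population
_FIELD_RANGES = {
    "go_mu": (0.0, np.inf),
    "go_sigma": (0.0, np.inf),
    "go_tau": (0.0, np.inf),
    "slow_slope": (0.0, np.inf),
    "ssrt_mu": (0.0, np.inf),
    "ssrt_sigma": (0.0, np.inf),
    "p_trigger_fail": (0.0, 1.0),
}


def default_population() -> tuple[SubjectParams, SubjectParams]:
    """Default cohort: (means, between-subject SDs).

    Means give ~805 ms baseline responses, ~22 ms average proactive slowing
    over the p > 0 cues and a stopping latency around 320 ms; SDs produce
    subject scatter comparable to group confidence intervals a few ms wide at
    n = 24.
    """
    means = SubjectParams()
    sds = SubjectParams(
        go_mu=15.0, go_sigma=5.0, go_tau=5.0, slow_slope=20.0,
        ssrt_mu=20.0, ssrt_sigma=5.0, p_trigger_fail=0.0,
    )
    return means, sds


def sample_subject(
    population_means: SubjectParams,
    population_sds: SubjectParams,
    seed: int | np.random.Generator,
) -> SubjectParams:
    """Draw one subject's parameters from truncated normals around the means."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = {}
    for f in fields(SubjectParams):
        mu = getattr(population_means, f.name)
        sd = getattr(population_sds, f.name)
        if sd < 0:
            raise ValueError(f"negative population SD for {f.name}")
        lo, hi = _FIELD_RANGES[f.name]
        if sd == 0:
            values[f.name] = float(np.clip(mu, lo, hi))
            continue
        for _ in range(1000):
            x = rng.normal(mu, sd)
            if lo <= x <= hi:
                break
        else:  # pathological mean/sd combination: fall back to clipping
            x = np.clip(x, lo, hi)
        values[f.name] = float(x)
    return SubjectParams(**values)


@dataclass
class SessionData:
    """Per-trial behavioural outcomes of one simulated session."""

    sequence: TrialSequence
    trials: pd.DataFrame  # index, block_id, level, p_stop, trial_type, onset, ssd, rt, outcome
    subject: SubjectParams
    seed: int

    def to_tsv(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def go_rts(self, levels: str = "all") -> pd.Series:
        """Go-trial response times; `levels` is 'all', 'baseline' or 'pstop'."""
        df = self.trials
        m = df["trial_type"] == "go"
        if levels == "baseline":
            m &= df["level"] == 0
        elif levels == "pstop":
            m &= df["level"] > 0
        return df.loc[m, "rt"]

    def staircase_trace(self) -> pd.DataFrame:
        df = self.trials
        stop = df[df["trial_type"] == "stop"]
        return stop[["index", "level", "ssd", "outcome"]].reset_index(drop=True)

    def plot_staircases(self, ax=None):
        """SSD trajectory per probability level over the session's Stop trials."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = self.staircase_trace()
        for lev, grp in trace.groupby("level"):
            label = self.sequence.config.levels[lev][0]
            ax.step(grp["index"], grp["ssd"], where="post", label=label)
        ax.axhline(self.sequence.config.ssd_init, color="0.7", ls=":", lw=1)
        ax.set_xlabel("trial")
        ax.set_ylabel("SSD (ms)")
        ax.legend(frameon=False, title="cue")
        return ax


def simulate_session(
    sequence: TrialSequence,
    subject: SubjectParams,
    seed: int | np.random.Generator,
) -> SessionData:
    """Run the race over one trial sequence, driving a per-level staircase."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seed_val = seed if isinstance(seed, int) else -1
    cfg = sequence.config
    stairs = {
        lev: Staircase(lev, cfg.ssd_init, cfg.staircase_step, cfg.ssd_bounds)
        for lev in range(1, len(cfg.levels))
    }

    n = len(sequence.trials)
    # pre-draw the noise streams in trial order for speed and reproducibility
    gauss = rng.normal(0.0, subject.go_sigma, size=n) if subject.go_sigma > 0 else np.zeros(n)
    expo = rng.exponential(subject.go_tau, size=n) if subject.go_tau > 0 else np.zeros(n)
    ssrt_noise = (
        rng.normal(0.0, subject.ssrt_sigma, size=n) if subject.ssrt_sigma > 0 else np.zeros(n)
    )
    trig = rng.random(size=n)

    rows = []
    for i, t in enumerate(sequence.trials):
        p = cfg.levels[t.level][1]
        t_go = subject.go_mu + subject.slow_slope * p + gauss[i] + expo[i]
        rec = {
            "index": t.index, "block_id": t.block_id, "level": t.level,
            "p_stop": p, "trial_type": t.trial_type, "onset": t.onset,
            "ssd": np.nan, "rt": np.nan, "outcome": "Go",
        }
        if t.trial_type == "go":
            rec["rt"] = t_go
        else:
            sc = stairs[t.level]
            ssd = sc.ssd
            rec["ssd"] = ssd
            triggered = trig[i] >= subject.p_trigger_fail
            t_ssrt = subject.ssrt_mu + ssrt_noise[i]
            success = triggered and (ssd + t_ssrt <= t_go)
            if success:
                rec["outcome"] = "StopSuccess"
            else:
                rec["outcome"] = "StopFailure"
                rec["rt"] = t_go
            sc.update(success)
        rows.append(rec)

    trials = pd.DataFrame(rows)
    return SessionData(sequence=sequence, trials=trials, subject=subject, seed=seed_val)


def simulate_cohort(
    sequence: TrialSequence,
    n_subjects: int,
    seed: int,
    population: tuple[SubjectParams, SubjectParams] | None = None,
) -> list[SessionData]:
    """Simulate `n_subjects` independent sessions on a shared trial sequence."""
    means, sds = population if population is not None else default_population()
    ss = np.random.SeedSequence(seed)
    sessions = []
    for child in ss.spawn(n_subjects):
        rng = np.random.default_rng(child)
        subj = sample_subject(means, sds, rng)
        sessions.append(simulate_session(sequence, subj, rng))
    return sessions
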