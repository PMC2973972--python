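"""Trial-sequence construction for the stop-signal anticipation task.

The task: on every trial a bar rises at constant speed and must be stopped (by
a button press) as close as possible to a target line that the bar reaches in
800 ms, so responses are timed rather than speeded.  On Stop trials the bar
halts on its own before the target line — the stop-signal — and the response
must be withheld.  The probability of a stop-signal is cued by the colour of
the target line; the default parameterization uses five levels (0, 17, 20, 25
and 33 %).  Trials are organised in baseline blocks (0 % cues only) alternating
with experimental blocks (all other cues), 12-15 trials per block, with two
24-s rest blocks at one third and two thirds of the run.

`build_trial_sequence` produces a pseudorandomised, reproducible sequence whose
per-level Go/Stop counts match the configuration exactly, and (optionally)
screens candidate orders so that the eventual GLM regressors are not too
correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import hemo

__all__ = [
    "TaskConfig",
    "TrialSpec",
    "TrialSequence",
    "build_trial_sequence",
    "implied_stop_probability",
    "scheduled_duration",
]


class ConfigurationError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameterization of one session of the stop-signal anticipation task.

    `levels` maps cue labels to stop-signal probabilities (fractions); level 0
    is the baseline cue and must have p_stop = 0.  Go counts for p > 0 levels
    are implied by the Stop counts: n_go = n_stop * (1 - p) / p.
    """

    levels: tuple[tuple[str, float], ...] = (
        ("green", 0.0),
        ("yellow", 1.0 / 6.0),
        ("amber", 1.0 / 5.0),
        ("orange", 1.0 / 4.0),
        ("red", 1.0 / 3.0),
    )
    n_stop_per_level: tuple[int, ...] = (0, 6, 12, 18, 24)
    n_go_baseline: int = 234
    block_size_range: tuple[int, int] = (12, 15)
    target_rt: float = 800.0          # ms, time at which the bar hits the target line
    bar_travel_total: float = 1000.0  # ms, full bottom-to-top travel of the bar
    iti: float = 1000.0               # ms
    rest_blocks: tuple[tuple[float, float], ...] = ((1 / 3, 24.0), (2 / 3, 24.0))
    staircase_step: float = 25.0      # ms
    ssd_init: float = 550.0           # ms
    ssd_bounds: tuple[float, float] = (50.0, 775.0)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.n_stop_per_level):
            raise ConfigurationError("levels and n_stop_per_level length mismatch")
        for i, (label, p) in enumerate(self.levels):
            if i == 0:
                if p != 0.0:
                    raise ConfigurationError("baseline level must have p_stop = 0")
            elif not 0.0 < p < 1.0:
                raise ConfigurationError(
                    f"level {label!r}: p_stop must be strictly between 0 and 1"
                )
            if i == 0 and self.n_stop_per_level[i] != 0:
                raise ConfigurationError("baseline level cannot carry Stop trials")
        lo, hi = self.block_size_range
        if not (lo >= 1 and lo <= hi):
            raise ConfigurationError("invalid block_size_range")
        if self.staircase_step <= 0:
            raise ConfigurationError("staircase_step must be positive")
        if not self.ssd_bounds[0] <= self.ssd_init <= self.ssd_bounds[1]:
            raise ConfigurationError("ssd_init outside ssd_bounds")

    # ---- derived quantities -------------------------------------------------

    @property
    def trial_pitch_ms(self) -> float:
        """Onset-to-onset interval: full bar travel plus the intertrial interval."""
        return self.bar_travel_total + self.iti

    def n_go_per_level(self) -> tuple[int, ...]:
        """Go-trial counts implied by the Stop counts and probabilities."""
        out = [self.n_go_baseline]
        for (label, p), n_stop in zip(self.levels[1:], self.n_stop_per_level[1:]):
            n_go = n_stop * (1.0 - p) / p if p > 0 else 0.0
            if abs(n_go - round(n_go)) > 1e-9:
                raise ConfigurationError(
                    f"level {label!r}: n_stop={n_stop} and p={p} imply a "
                    f"non-integer Go count {n_go:.3f}"
                )
            out.append(int(round(n_go)))
        return tuple(out)

    def total_trials(self) -> int:
        return sum(self.n_go_per_level()) + sum(self.n_stop_per_level)

    def level_percent_labels(self) -> tuple[int, ...]:
        return tuple(int(round(100 * p)) for _, p in self.levels)

    # ---- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "levels": [[label, float(p)] for label, p in self.levels],
            "n_stop_per_level": list(self.n_stop_per_level),
            "n_go_baseline": self.n_go_baseline,
            "block_size_range": list(self.block_size_range),
            "target_rt": self.target_rt,
            "bar_travel_total": self.bar_travel_total,
            "iti": self.iti,
            "rest_blocks": [list(r) for r in self.rest_blocks],
            "staircase_step": self.staircase_step,
            "ssd_init": self.ssd_init,
            "ssd_bounds": list(self.ssd_bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        kw = dict(d)
        if "levels" in kw:
            kw["levels"] = tuple((str(l), float(p)) for l, p in kw["levels"])
        for key in ("n_stop_per_level",):
            if key in kw:
                kw[key] = tuple(int(v) for v in kw[key])
        for key in ("block_size_range", "ssd_bounds"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "rest_blocks" in kw:
            kw["rest_blocks"] = tuple(tuple(r) for r in kw["rest_blocks"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class TrialSpec:
    index: int
    block_id: int
    trial_type: str  # "go" | "stop"
    level: int       # index into TaskConfig.levels
    onset: float     # seconds from session start


@dataclass
class TrialSequence:
    """An ordered, fully timed trial list for one session."""

    config: TaskConfig
    trials: list[TrialSpec]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        rows = [
            {
                "onset": t.onset,
                "duration": cfg.bar_travel_total / 1000.0,
                "trial_type": t.trial_type,
                "level": t.level,
                "p_stop": cfg.levels[t.level][1],
                "block_id": t.block_id,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        """BIDS-style events table (tab separated, dot decimals, UTF-8)."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def level_counts(self) -> pd.DataFrame:
        df = self.to_frame()
        return (
            df.groupby(["level", "trial_type"]).size().unstack(fill_value=0)
        )


def implied_stop_probability(n_go: int, n_stop: int) -> int:
    """Stop-signal probability (integer percent) implied by per-level counts."""
    if n_go < 0 or n_stop < 0:
        raise ValueError("counts must be non-negative")
    if n_go + n_stop == 0:
        raise ValueError("n_go + n_stop must be positive")
    return int(round(100.0 * n_stop / (n_go + n_stop)))


def scheduled_duration(config: TaskConfig) -> float:
    """Total scheduled session duration in seconds (trials plus rest blocks)."""
    n = config.total_trials()
    rests = sum(d for _, d in config.rest_blocks) if n else 0.0
    return n * config.trial_pitch_ms / 1000.0 + rests


# ---------------------------------------------------------------------------
# sequence generation


def _partition_into_blocks(total: int, lo: int, hi: int, rng) -> list[int]:
    """Split `total` trials into blocks of size lo..hi, sizes randomised."""
    if total == 0:
        return []
    k_min = int(np.ceil(total / hi))
    k_max = total // lo
    if k_min > k_max:
        raise ConfigurationError(
            f"cannot partition {total} trials into blocks of {lo}..{hi}"
        )
    k = int(rng.integers(k_min, k_max + 1))
    sizes = np.full(k, lo)
    remaining = total - lo * k
    while remaining > 0:
        open_blocks = np.flatnonzero(sizes < hi)
        j = rng.choice(open_blocks)
        sizes[j] += 1
        remaining -= 1
    return sizes.tolist()


def _feasible_block_counts(total: int, lo: int, hi: int) -> set[int]:
    if total == 0:
        return {0}
    return set(range(int(np.ceil(total / hi)), total // lo + 1))


_MAX_CONSECUTIVE_STOPS = 2


def _order_experimental_pool(pool: list[tuple[str, int]], block_sizes: list[int], rng,
                             max_repair: int = 10_000) -> list[tuple[str, int]]:
    """Shuffle the experimental (type, level) pool subject to ordering rules.

    Rules: each experimental block opens with a Go trial, and no run of more
    than two consecutive Stop trials within a block.  Violations are repaired
    by swapping an offending Stop trial with a randomly chosen Go trial.
    """
    pool = list(pool)
    rng.shuffle(pool)
    starts = np.cumsum([0] + block_sizes[:-1])
    bounds = set(np.cumsum(block_sizes).tolist())  # block end indices

    def violations() -> list[int]:
        bad = []
        run = 0
        for i, (tt, _) in enumerate(pool):
            if i in starts:
                run = 0
                if tt == "stop":
                    bad.append(i)
            run = run + 1 if tt == "stop" else 0
            if run > _MAX_CONSECUTIVE_STOPS:
                bad.append(i)
        return bad

    for _ in range(max_repair):
        bad = violations()
        if not bad:
            return pool
        i = bad[0]
        go_positions = [j for j, (tt, _) in enumerate(pool) if tt == "go" and j not in starts]
        j = int(rng.choice(go_positions))
        pool[i], pool[j] = pool[j], pool[i]
    raise ConfigurationError("could not satisfy trial-ordering constraints")


def _candidate_sequence(config: TaskConfig, seed: int, draw: int) -> TrialSequence:
    rng = np.random.default_rng([seed, draw])
    n_go = config.n_go_per_level()
    lo, hi = config.block_size_range
    n_base = n_go[0]
    n_exp = sum(n_go[1:]) + sum(config.n_stop_per_level[1:])

    if n_exp == 0:
        base_sizes = _partition_into_blocks(n_base, lo, hi, rng)
        exp_sizes: list[int] = []
    elif n_base == 0:
        base_sizes = []
        exp_sizes = _partition_into_blocks(n_exp, lo, hi, rng)
    else:
        # prefer equal numbers of baseline and experimental blocks (strict
        # alternation); otherwise the closest feasible pair, interleaved evenly
        fb = sorted(_feasible_block_counts(n_base, lo, hi))
        fe = sorted(_feasible_block_counts(n_exp, lo, hi))
        best_diff = min(abs(b - e) for b in fb for e in fe)
        pairs = [(b, e) for b in fb for e in fe if abs(b - e) == best_diff]
        kb, ke = pairs[rng.integers(len(pairs))]
        base_sizes = _partition_into_blocks_fixed(n_base, lo, hi, kb, rng)
        exp_sizes = _partition_into_blocks_fixed(n_exp, lo, hi, ke, rng)

    exp_pool = [("go", lev) for lev in range(1, len(n_go)) for _ in range(n_go[lev])]
    exp_pool += [
        ("stop", lev)
        for lev in range(1, len(config.n_stop_per_level))
        for _ in range(config.n_stop_per_level[lev])
    ]
    if exp_sizes:
        exp_pool = _order_experimental_pool(exp_pool, exp_sizes, rng)

    # interleave baseline and experimental blocks as evenly as possible
    # (strict b, e, b, e, ... when the counts are equal), baseline first on ties
    keyed: list[tuple[float, str, int]] = [
        ((i + 0.5) / len(base_sizes), "base", i) for i in range(len(base_sizes))
    ] + [((j + 0.5) / len(exp_sizes) + 1e-9, "exp", j) for j in range(len(exp_sizes))]
    keyed.sort()
    blocks: list[list[tuple[str, int]]] = []
    exp_bounds = np.concatenate([[0], np.cumsum(exp_sizes)]).astype(int)
    for _, kind, j in keyed:
        if kind == "base":
            blocks.append([("go", 0)] * base_sizes[j])
        else:
            blocks.append(exp_pool[exp_bounds[j] : exp_bounds[j + 1]])

    # rest-block insertion: after the block boundary nearest each requested
    # fraction of the total trial count
    total = config.total_trials()
    cum = np.cumsum([len(b) for b in blocks])
    rest_after: dict[int, float] = {}
    for frac, dur in config.rest_blocks:
        if len(cum) == 0:
            continue
        j = int(np.argmin(np.abs(cum - frac * total)))
        rest_after[j] = rest_after.get(j, 0.0) + dur

    pitch = config.trial_pitch_ms / 1000.0
    trials: list[TrialSpec] = []
    t = 0.0
    idx = 0
    for b, block in enumerate(blocks):
        for tt, lev in block:
            trials.append(TrialSpec(idx, b, tt, lev, round(t, 6)))
            idx += 1
            t += pitch
        if b in rest_after:
            t += rest_after[b]
    return TrialSequence(config=config, trials=trials, seed=seed)


def _partition_into_blocks_fixed(total: int, lo: int, hi: int, k: int, rng) -> list[int]:
    sizes = np.full(k, lo)
    remaining = total - lo * k
    if remaining < 0 or remaining > k * (hi - lo):
        raise ConfigurationError("infeasible block partition")
    while remaining > 0:
        j = rng.choice(np.flatnonzero(sizes < hi))
        sizes[j] += 1
        remaining -= 1
    return sizes.tolist()


def regressor_correlation_screen(seq: TrialSequence, tr: float = 1.6) -> float:
    """Maximum pairwise |r| among the eventual GLM task regressors.

    Computed at design time (before behaviour is known): the Stop regressor,
    the Go p>0 regressor, and the stop-signal-probability parametric modulator,
    each convolved with the canonical HRF.  Response times are approximated by
    the target response time, which is what timed responding aims at.
    """
    cfg = seq.config
    df = seq.to_frame()
    n_scans = int(np.ceil(scheduled_duration(cfg) / tr)) + 1
    resp = df["onset"] + cfg.target_rt / 1000.0

    cols = []
    stop = df["trial_type"] == "stop"
    go_exp = (df["trial_type"] == "go") & (df["level"] > 0)
    for mask in (stop, go_exp):
        if mask.any():
            cols.append(
                hemo.event_regressor(resp[mask].to_numpy(), np.ones(mask.sum()), n_scans, tr)
            )
    if go_exp.any():
        p = df.loc[go_exp, "p_stop"].to_numpy()
        pc = p - p.mean()
        if np.ptp(pc) > 0:
            pc = pc / pc.std()
            cols.append(hemo.event_regressor(resp[go_exp].to_numpy(), pc, n_scans, tr))
    if len(cols) < 2:
        return 0.0
    corr = np.corrcoef(np.vstack(cols))
    return float(np.max(np.abs(corr[np.triu_indices_from(corr, k=1)])))


def build_trial_sequence(
    config: TaskConfig,
    seed: int,
    screen_regressors: bool = True,
    max_corr: float = 0.4,
    max_draws: int = 20,
    tr: float = 1.6,
) -> TrialSequence:
    """Build a pseudorandomised trial sequence for one session.

    Per-level Go and Stop counts match the configuration exactly; baseline
    blocks contain only 0 %-cue Go trials, experimental blocks only p > 0
    trials.  When `screen_regressors` is set, candidate orders are redrawn
    (deterministically, derived from `seed`) until the design-time GLM
    regressor correlations all fall below `max_corr`; if no candidate passes,
    the best one is returned with a warning.
    """
    config.n_go_per_level()  # validates count/probability consistency
    best: TrialSequence | None = None
    best_corr = np.inf
    n_draws = max_draws if screen_regressors else 1
    for draw in range(n_draws):
        seq = _candidate_sequence(config, seed, draw)
        if not screen_regressors:
            return seq
        c = regressor_correlation_screen(seq, tr=tr)
        if c < best_corr:
            best, best_corr = seq, c
        if c <= max_corr:
            return seq
    warnings.warn(
        f"no candidate order reached max regressor |r| <= {max_corr} "
        f"(best {best_corr:.3f}); returning the best candidate"
    )
    assert best is not None
    return best
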