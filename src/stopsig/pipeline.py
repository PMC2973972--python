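"""End-to-end orchestration: design -> simulate -> behavior -> bold -> glm -> ppi.

One call runs the whole synthetic study for a cohort of subjects, writes every
stage's outputs as TSV/JSON under an output directory, and records a manifest
(config hash, per-stage seeds, output paths, stage status) so a rerun with the
same config and master seed reproduces every file byte for byte.

Per-stage seeds derive from the master seed by a counter-based split:
``SeedSequence(master, spawn_key=(stage_index,))``, so any stage can be rerun
in isolation without consuming another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import bold as bold_mod
from . import glm as glm_mod
from . import ppi as ppi_mod
from .race import SubjectParams, default_population, sample_subject, simulate_session
from .task import TaskConfig, build_trial_sequence

__all__ = ["RunManifest", "run_pipeline", "generate_fixtures", "default_study_config",
           "stage_seed", "STAGES"]

log = logging.getLogger("stopsig")

STAGES = ("design", "simulate", "behavior", "bold", "glm", "ppi")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(master, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def default_study_config() -> dict:
    """Default study: canonical task, 24 subjects, default regions, TR 1.6 s."""
    means, sds = default_population()
    return {
        "task": TaskConfig().to_dict(),
        "n_subjects": 24,
        "tr": 1.6,
        "n_scans": 622,
        "population_means": vars(means).copy(),
        "population_sds": vars(sds).copy(),
        "regions": [vars(r).copy() for r in bold_mod.default_regions()],
        "seed_region": "striatum",
        "ppi_sinks": ["m1", "smc"],
        "ppi_lambda": 1.0,
        "contrasts": ["stop_success_gt_failure", "pstop_effect", "rt_effect"],
    }


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict
    outputs: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_config(config) -> dict:
    if config is None:
        return default_study_config()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config)
    base = default_study_config()
    base.update(user)
    return base


def run_pipeline(config=None, seed: int = 0, out_dir="runs/run", n_subjects=None):
    """Execute all six stages for one synthetic cohort.

    `config` is a YAML path, a dict of overrides, or None for the defaults.
    Returns the `RunManifest`; raises (with the stage name) on any stage error.
    """
    cfg = _load_config(config)
    if n_subjects is not None:
        cfg["n_subjects"] = int(n_subjects)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {st: stage_seed(seed, st) for st in STAGES}
    manifest = RunManifest(config_hash=_config_hash(cfg), master_seed=seed, stage_seeds=seeds)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    task_cfg = TaskConfig.from_dict(cfg["task"])
    tr, n_scans = float(cfg["tr"]), int(cfg["n_scans"])
    n_subj = int(cfg["n_subjects"])
    means = SubjectParams(**cfg["population_means"])
    sds = SubjectParams(**cfg["population_sds"])
    regions = [bold_mod.RegionSpec(**r) for r in cfg["regions"]]
    region_names = [r.name for r in regions]

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            manifest.status[name] = f"failed: {exc}"
            manifest.to_json(out / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed (seed {seeds[name]}): {exc}") from exc
        manifest.status[name] = "completed"
        manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, manifest.timings_s[name])

    state: dict = {}

    # ---- design ----
    def _design():
        seq = build_trial_sequence(task_cfg, seeds["design"])
        path = out / "events.tsv"
        seq.to_tsv(path)
        state["sequence"] = seq
        manifest.outputs["design"] = [str(path)]
        log.info("design: %d trials, %d stop", len(seq), sum(t.trial_type == "stop" for t in seq.trials))

    # ---- simulate ----
    def _simulate():
        seq = state["sequence"]
        ss = np.random.SeedSequence(seeds["simulate"])
        sessions, paths = [], []
        beh_dir = out / "sessions"
        beh_dir.mkdir(exist_ok=True)
        for i, child in enumerate(ss.spawn(n_subj)):
            rng = np.random.default_rng(child)
            subj = sample_subject(means, sds, rng)
            sess = simulate_session(seq, subj, rng)
            p = beh_dir / f"sub-{i + 1:02d}_behavior.tsv"
            sess.to_tsv(p)
            sessions.append(sess)
            paths.append(str(p))
        state["sessions"] = sessions
        manifest.outputs["simulate"] = paths

    # ---- behavior ----
    def _behavior():
        sessions = state["sessions"]
        rows, ssrts = [], []
        for i, sess in enumerate(sessions):
            summ = beh.rt_summary(sess)
            summ.insert(0, "subject", i + 1)
            rows.append(summ)
            ssrts.append({"subject": i + 1, "ssrt": beh.ssrt_integration(sess)})
        summary = pd.concat(rows, ignore_index=True)
        ssrt_df = pd.DataFrame(ssrts)
        inhib = beh.inhibition_function(sessions, n_bins=12)
        p1, p2, p3 = out / "summary.tsv", out / "ssrt.tsv", out / "inhibition.tsv"
        summary.to_csv(p1, sep="\t", index=False, float_format="%.6g")
        ssrt_df.to_csv(p2, sep="\t", index=False, float_format="%.6g")
        inhib.points.to_csv(p3, sep="\t", index=False, float_format="%.6g")
        outputs = [str(p1), str(p2), str(p3)]
        if inhib.weibull is not None:
            p4 = out / "inhibition_weibull.json"
            with open(p4, "w") as fh:
                json.dump(vars(inhib.weibull), fh, indent=1)
            outputs.append(str(p4))
        state["ssrt"] = ssrt_df
        manifest.outputs["behavior"] = outputs
        log.info("behavior: mean SSRT %.1f ms", ssrt_df["ssrt"].mean())

    # ---- bold ----
    def _bold():
        seq, sessions = state["sequence"], state["sessions"]
        ss = np.random.SeedSequence(seeds["bold"])
        datasets, paths = [], []
        bdir = out / "bold"
        bdir.mkdir(exist_ok=True)
        for i, (sess, child) in enumerate(zip(sessions, ss.spawn(n_subj))):
            ds = bold_mod.synthesize_bold(
                seq, sess, regions, tr=tr, n_scans=n_scans,
                seed=np.random.default_rng(child),
                seed_region=cfg["seed_region"],
            )
            ds.seed = seeds["bold"]
            p = bdir / f"sub-{i + 1:02d}_bold.tsv"
            sc = bdir / f"sub-{i + 1:02d}_bold.json"
            ds.to_tsv(p, sc)
            datasets.append(ds)
            paths += [str(p), str(sc)]
        state["bold"] = datasets
        manifest.outputs["bold"] = paths

    # ---- glm ----
    def _glm():
        seq, sessions, datasets = state["sequence"], state["sessions"], state["bold"]
        per_subject = {c: [] for c in cfg["contrasts"]}
        rows = []
        for i, (sess, ds) in enumerate(zip(sessions, datasets)):
            design = glm_mod.build_design_matrix(
                seq, sess, tr, ds.n_scans, outlier_flags=beh.flag_session_outliers(sess)
            )
            res = glm_mod.FirstLevelGLM(ds.signal, design).fit()
            for cname in cfg["contrasts"]:
                con = res.contrast(cname)
                for reg_name in region_names:
                    rows.append({
                        "subject": i + 1, "contrast": cname, "region": reg_name,
                        "estimate": con.estimate[reg_name], "se": con.se[reg_name],
                        "t": con.t[reg_name], "p": con.p[reg_name],
                    })
                per_subject[cname].append(con.estimate)
        first = pd.DataFrame(rows)
        grp_rows = []
        for cname, estimates in per_subject.items():
            mat = pd.concat(estimates, axis=1)  # region x subject
            for reg_name in region_names:
                t, p = glm_mod.group_t(mat.loc[reg_name].to_numpy())
                grp_rows.append({"contrast": cname, "region": reg_name,
                                 "mean": mat.loc[reg_name].mean(), "t": t, "p": p})
        group = pd.DataFrame(grp_rows)
        p1, p2 = out / "glm_first_level.tsv", out / "glm_group.tsv"
        first.to_csv(p1, sep="\t", index=False, float_format="%.6g")
        group.to_csv(p2, sep="\t", index=False, float_format="%.6g")
        manifest.outputs["glm"] = [str(p1), str(p2)]

    # ---- ppi ----
    def _ppi():
        sessions, datasets = state["sessions"], state["bold"]
        op = ppi_mod.DeconvolutionOperator(n_scans, tr)
        lam = float(cfg["ppi_lambda"])
        rows, group_rows = [], []
        betas = {sink: [] for sink in cfg["ppi_sinks"]}
        for i, (sess, ds) in enumerate(zip(sessions, datasets)):
            seed_y = ds.region(cfg["seed_region"])
            neural = ppi_mod.deconvolve(seed_y, tr=tr, lam=lam, operator=op)
            df = sess.trials
            ss_on = df.loc[df["outcome"] == "StopSuccess", "onset"].to_numpy()
            sf_on = df.loc[df["outcome"] == "StopFailure", "onset"].to_numpy()
            regs = ppi_mod.ppi_regressors(neural, ss_on, sf_on, tr, ds.n_scans)
            nuis = ppi_mod.task_nuisance_regressors(sess, tr, ds.n_scans)
            for sink in cfg["ppi_sinks"]:
                res = ppi_mod.PPIModel(ds.region(sink), regs, nuisance=nuis,
                                       sink_name=sink).fit()
                rows.append({
                    "subject": i + 1, "sink": sink,
                    "beta_ppi": res.beta["ppi"], "t_ppi": res.t["ppi"],
                    "beta_physio": res.beta["physio"], "beta_psych": res.beta["psych"],
                    "sign": res.sign,
                })
                betas[sink].append(res.beta["ppi"])
        for sink, vals in betas.items():
            t, p = glm_mod.group_t(np.asarray(vals))
            group_rows.append({"sink": sink, "mean_beta_ppi": float(np.mean(vals)),
                               "t": t, "p": p})
        p1, p2 = out / "ppi_first_level.tsv", out / "ppi_group.tsv"
        pd.DataFrame(rows).to_csv(p1, sep="\t", index=False, float_format="%.6g")
        pd.DataFrame(group_rows).to_csv(p2, sep="\t", index=False, float_format="%.6g")
        manifest.outputs["ppi"] = [str(p1), str(p2)]

    for name, fn in zip(STAGES, (_design, _simulate, _behavior, _bold, _glm, _ppi)):
        _run_stage(name, fn)

    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# hand-checkable fixtures


def worked_ssrt_example() -> tuple[pd.DataFrame, float]:
    """The 10-Go-RT / 4-Stop worked SSRT example and its hand-computed value.

    Ten sorted Go RTs 700..880 ms, four Stop trials at SSDs 500..575 ms of
    which two escaped inhibition: p_respond = 0.5, the 5th fastest Go RT is
    780 ms, mean SSD 537.5 ms, so SSRT = 242.5 ms.
    """
    go_rts = np.arange(700, 881, 20)
    ssds = [500.0, 525.0, 550.0, 575.0]
    outcomes = ["StopFailure", "StopSuccess", "StopFailure", "StopSuccess"]
    rows = []
    for i, rt in enumerate(go_rts):
        rows.append({"index": i, "block_id": 0, "level": 1, "p_stop": 0.25,
                     "trial_type": "go", "onset": 2.0 * i, "ssd": np.nan,
                     "rt": float(rt), "outcome": "Go"})
    for j, (ssd, oc) in enumerate(zip(ssds, outcomes)):
        rows.append({"index": 10 + j, "block_id": 0, "level": 1, "p_stop": 0.25,
                     "trial_type": "stop", "onset": 2.0 * (10 + j), "ssd": ssd,
                     "rt": 820.0 if oc == "StopFailure" else np.nan, "outcome": oc})
    return pd.DataFrame(rows), 242.5


def generate_fixtures(out_dir) -> list[str]:
    """Write the small hand-checkable fixtures used by the unit tests.

    Deterministic: running twice produces identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    trials, expected = worked_ssrt_example()
    p = out / "ssrt_worked_example.tsv"
    trials.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths.append(str(p))

    # staircase trace: deterministic alternating outcome pattern
    from .staircase import Staircase

    sc = Staircase(level=1, ssd_init=550.0)
    for ok in [True, True, False, True, False, False, True, True, True, False]:
        sc.update(ok)
    p = out / "staircase_trace.tsv"
    sc.trajectory().to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths.append(str(p))

    # noiseless BOLD round-trip set: tiny task, zero-noise regions
    cfg = TaskConfig(
        levels=(("green", 0.0), ("orange", 0.25)),
        n_stop_per_level=(0, 4),
        n_go_baseline=12,
        block_size_range=(12, 16),
        rest_blocks=(),
    )
    seq = build_trial_sequence(cfg, seed=7, screen_regressors=False)
    subj = SubjectParams(go_mu=780, go_sigma=0, go_tau=0, slow_slope=80,
                         ssrt_mu=260, ssrt_sigma=0)
    sess = simulate_session(seq, subj, seed=7)
    regions = [
        bold_mod.RegionSpec("a", amp_stop_success=1.0, amp_stop_failure=0.3,
                            amp_go=0.2, noise_sd=0.0),
        bold_mod.RegionSpec("b", amp_go=0.5, slope_rt=0.4, noise_sd=0.0),
    ]
    ds = bold_mod.synthesize_bold(seq, sess, regions, tr=1.6, seed=0)
    p1, p2, p3 = out / "roundtrip_bold.tsv", out / "roundtrip_bold.json", out / "roundtrip_events.tsv"
    ds.to_tsv(p1, p2)
    seq.to_tsv(p3)
    sess.to_tsv(out / "roundtrip_behavior.tsv")
    paths += [str(p1), str(p2), str(p3), str(out / "roundtrip_behavior.tsv")]
    return paths
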