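"""End-to-end orchestration: synth -> preprocess -> DDM -> cluster stats ->
grouping -> behavior, under one reproducible configuration.

The default configuration is desk-scale (m = 20 bins of 50 ms, 100
classifier iterations, 200 shuffles, stage 2 analyzed); the full-scale
constants (m = 100, 10-ms bins, 1000 iterations, 1000 shuffles) are one
``RunConfig.full_scale()`` away but are compute-cluster-grade.
Participant-level failures are logged into the report and the cohort run
continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import behavior as beh
from . import clusterstats as cs
from . import grouping as grp
from . import preprocess as pp
from . import synth
from .ddm import DDMConfig, build_real_and_shuffled

logger = logging.getLogger("telltale")


@dataclass
class RunConfig:
    """One knob set for a full cohort run.

    ``bin_ms * m_bins`` must equal the 1000-ms epoch length.
    """

    # DDM
    m_bins: int = 20
    bin_ms: float = 50.0
    n_iterations: int = 100
    n_shuffles: int = 200
    classifier: str = "lsq"
    features: str = "samples"
    # cluster statistics
    threshold_percentile: float = 95.0
    connectivity: int = 4
    min_cluster_size: int = 2
    # grouping
    d_c_percentile: float = 20.0
    # scope
    stages: tuple = (2,)
    seed: int = 0
    # synthetic cohort
    n_participants: int = 8
    group_mix: dict = field(default_factory=lambda: {"ZM": 0.5, "CS": 0.5})
    effect_size: float = 1.0
    effect_events: tuple = ("speech",)
    n_trials_per_stage: int = 80
    couple_receiver: bool = True
    iti_s: float = 1.5

    def validate(self) -> None:
        for name in ("m_bins", "n_iterations", "n_shuffles", "n_participants",
                     "n_trials_per_stage", "min_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if abs(self.bin_ms * self.m_bins - 1000.0) > 1e-9:
            raise ValueError("bin_ms * m_bins must equal the 1000 ms epoch")
        if not set(self.stages) <= {1, 2}:
            raise ValueError("stages must be a subset of {1, 2}")

    def ddm_config(self) -> DDMConfig:
        return DDMConfig(m_bins=self.m_bins, bin_ms=self.bin_ms,
                         n_iterations=self.n_iterations,
                         classifier=self.classifier, features=self.features)

    @classmethod
    def full_scale(cls, **overrides) -> "RunConfig":
        """The full-scale constants: 100 bins of 10 ms, 1000 holdout
        iterations, 1000 shuffles, 95th-percentile threshold."""
        base = dict(m_bins=100, bin_ms=10.0, n_iterations=1000, n_shuffles=1000,
                    n_trials_per_stage=80, stages=(1, 2))
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["effect_events"] = list(self.effect_events)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", (2,)))
        d["effect_events"] = tuple(d.get("effect_events", ("speech",)))
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _slot_seed(base_seed: int, pidx: int, stage: int, slot: int) -> int:
    return int(np.random.SeedSequence(
        [int(base_seed), int(pidx), int(stage), int(slot)]
    ).generate_state(1)[0])


def analyze_participant(
    rec: synth.ElectrodeRecording,
    trials: list[synth.TrialEvents],
    config: RunConfig,
    pidx: int = 0,
) -> dict:
    """Preprocess one recording and decode all six DDM slots per stage.

    Returns a dict with the selected channels, exclusions, and per stage:
    the six real DDMs, their significant clusters, the count vector and
    the maximal cell accuracy.
    """
    config.validate()
    dcfg = config.ddm_config()
    sel = pp.select_channels_from_recording(rec)
    pairs = {"ZM": sel.zm_pair, "CS": sel.cs_pair}
    calib_end = rec.calibration_marks[-1][2] if rec.calibration_marks else 0.0

    epochs_by_muscle = {}
    exclusions = {}
    for muscle, pair in pairs.items():
        env = pp.continuous_envelope(rec, pair)
        epoch_sets, excl = pp.epoch_trials(env, trials, muscle, rec.fs,
                                           calibration_end_s=calib_end)
        epochs_by_muscle[muscle] = epoch_sets
        exclusions[muscle] = excl

    stages_out = {}
    for stage in config.stages:
        slots = {}
        clusters = {}
        max_acc = float("nan")
        for k, (muscle, event) in enumerate(cs.SLOT_ORDER):
            eset = epochs_by_muscle[muscle].get((event, stage))
            if eset is None:
                raise RuntimeError(f"no retained trials for stage {stage}")
            seed = _slot_seed(config.seed, pidx, stage, k)
            real, shuffled = build_real_and_shuffled(
                eset, config.n_shuffles, seed=seed, config=dcfg)
            sig, null = cs.analyze_ddm_family(
                real, shuffled, config.threshold_percentile,
                config.connectivity, config.min_cluster_size)
            slots[(muscle, event)] = real
            clusters[(muscle, event)] = sig
            vals = real.defined_values
            vals = vals[~np.isnan(vals)]
            if vals.size:
                m = float(vals.max())
                max_acc = m if np.isnan(max_acc) else max(max_acc, m)
        stages_out[stage] = {
            "ddms": slots,
            "clusters": clusters,
            "count_vector": cs.count_vector(clusters),
            "max_accuracy": max_acc,
        }
    return {
        "selected_channels": sel,
        "exclusions": exclusions,
        "stages": stages_out,
    }


@dataclass
class CohortReport:
    """Full per-participant and cohort-level results of one run."""

    config: RunConfig
    participants: list
    cohort: dict

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["stages"] = list(self.config.stages)
        cfg["effect_events"] = list(self.config.effect_events)
        return _jsonable({"config": cfg, "participants": self.participants,
                          "cohort": self.cohort})

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else v
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def run_cohort(config: RunConfig, cohort: synth.Cohort | None = None) -> CohortReport:
    """Run the whole pipeline on a (generated or supplied) cohort.

    Deterministic: identical config (and cohort) reproduces the report
    exactly.  Participant failures are reported, not fatal.
    """
    config.validate()
    if cohort is None:
        cohort = synth.generate_cohort(
            config.n_participants, config.group_mix, base_seed=config.seed,
            n_trials_per_stage=config.n_trials_per_stage,
            effect_size=config.effect_size, effect_events=config.effect_events,
            couple_receiver=config.couple_receiver, iti_s=config.iti_s,
        )

    participants = []
    per_stage_counts: dict[int, dict[int, np.ndarray]] = {s: {} for s in config.stages}
    for i, profile in enumerate(cohort.profiles):
        t0 = time.time()
        entry: dict = {"id": profile.id, "liar_type": profile.liar_type}
        try:
            rec, trials = cohort.participant(i)
            res = analyze_participant(rec, trials, config, pidx=i)
            summ = beh.summarize_behavior(trials)
            entry["behavior"] = dataclasses.asdict(summ)
            entry["zm_pair"] = list(res["selected_channels"].zm_pair)
            entry["cs_pair"] = list(res["selected_channels"].cs_pair)
            entry["n_excluded"] = {m: len(v) for m, v in res["exclusions"].items()}
            entry["stages"] = {}
            for s, sres in res["stages"].items():
                per_stage_counts[s][i] = sres["count_vector"]
                entry["stages"][s] = {
                    "count_vector": sres["count_vector"].tolist(),
                    "max_accuracy": sres["max_accuracy"],
                    "n_significant": int(sres["count_vector"].sum()),
                }
            entry["trials"] = [dataclasses.asdict(t) for t in trials]
            logger.info("participant %s done in %.1f s", profile.id,
                        time.time() - t0)
        except Exception as exc:  # participant-level failure policy
            logger.exception("participant %s failed", profile.id)
            entry["error"] = f"{type(exc).__name__}: {exc}"
        participants.append(entry)

    ok = [p for p in participants if "error" not in p]
    cohort_out: dict = {
        "n_ok": len(ok),
        "excluded": [{"id": p["id"], "reason": p["error"]}
                     for p in participants if "error" in p],
    }

    # grouping per stage
    cohort_out["grouping"] = {}
    for s in config.stages:
        idx = sorted(per_stage_counts[s])
        if len(idx) >= 2:
            V = np.vstack([per_stage_counts[s][i] for i in idx])
            ga = grp.density_peak_grouping(V, cutoff_percentile=config.d_c_percentile)
            cohort_out["grouping"][s] = {
                "participant_idx": idx,
                "labels": ga.labels.tolist(),
                "prototypes": ga.prototypes,
                "rho": ga.rho.tolist(),
                "delta": ga.delta.tolist(),
                "d_c": ga.d_c,
                "group_tests": grp.group_characteristics(V, ga.labels),
            }

    # behavioral statistics
    if len(ok) >= 2:
        rows = []
        for p in ok:
            for t in p["trials"]:
                rows.append({
                    "participant_id": p["id"], "lied": int(t["is_lie"]),
                    "trial_idx": t["trial_idx"],
                    "has_incentive": int(t["stage"] == 2),
                })
        import pandas as pd

        try:
            cohort_out["lie_trend"] = beh.lie_trend_model(pd.DataFrame(rows))
        except ValueError as exc:
            cohort_out["lie_trend"] = {"error": str(exc)}

        stage_ref = config.stages[-1]
        acc = np.array([p["stages"][stage_ref]["max_accuracy"] for p in ok])
        det = np.array([p["behavior"]["detection_rate"] for p in ok])
        succ = np.array([p["behavior"]["successful_lying_rate"] for p in ok])
        keep = ~(np.isnan(acc) | np.isnan(det) | np.isnan(succ))
        if keep.sum() >= 4:
            cohort_out["machine_vs_human"] = beh.machine_vs_human(
                acc[keep], det[keep], succ[keep])
        cohort_out["mean_lie_rate"] = float(np.mean(
            [p["behavior"]["lie_rate"] for p in ok]))
        cohort_out["mean_max_accuracy"] = float(np.nanmean(acc))

    return CohortReport(config=config, participants=participants, cohort=cohort_out)
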