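"""Synthetic facial-sEMG cohorts for the two-person deception task.

The generator emulates the statistical structure the downstream analysis
assumes: an 8-electrode array over the right cheek (zygomaticus major, ZM,
electrodes 0-4) and eyebrow (corrugator supercilii, CS, electrodes 5-7)
regions sampled at 2000 samples/s, a calibration block of three voluntary
smiles followed by three frowns (3 s each, 3 s gaps), and an interleaved
Sender/Receiver word game in which the Sender hears "KAV" or "ETZ" and
either repeats it (truth) or says the other word (lie).

Signal model
------------
Each muscle is a single stochastic source: Gaussian noise band-limited to
20-450 Hz multiplied by a smooth activation envelope.  The envelope is a
low resting tone plus raised-cosine bursts — gesture bursts during
calibration and event-locked bursts (stimulus, speech, response) during
trials.  Sources are mixed linearly into the 8 electrodes with
distance-dependent gains (ZM gains dominate on electrodes 0-4, CS gains on
5-7) and white sensor noise is added.

Lie trials shift the telltale muscle's per-trial burst amplitude by
``effect_size`` standard deviations of the amplitude distribution in the
profile's ``effect_events``, so the standardized lie-vs-truth envelope
difference (Cohen's d) of the telltale muscle is approximately
``effect_size`` at any magnitude.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

FS = 2000
"""Sampling rate of the electrode array, samples/s."""

WORDS = ("KAV", "ETZ")
EVENTS = ("stimulus", "speech", "response")
LIAR_TYPES = ("ZM", "CS", "NULL")

#: calibration layout: 2 s lead-in, then six 3-s gestures with 3-s gaps
CALIBRATION_LEAD_S = 2.0
GESTURE_S = 3.0
GESTURE_GAP_S = 3.0
CALIBRATION_TOTAL_S = CALIBRATION_LEAD_S + 6 * (GESTURE_S + GESTURE_GAP_S)

#: receiver false-alarm probability, P(respond "lie" | truth trial)
RECEIVER_FALSE_ALARM = 0.5

# source-to-electrode gains (dimensionless); rows are overridden per
# participant with a small jitter that preserves the region dominance
ZM_GAINS = np.array([1.00, 0.85, 0.70, 0.55, 0.40, 0.12, 0.09, 0.07])
CS_GAINS = np.array([0.10, 0.08, 0.12, 0.09, 0.11, 0.90, 1.00, 0.70])

# envelope amplitudes, microvolts (RMS of the source during activation)
BASELINE_UV = 1.5
SENSOR_NOISE_UV = 2.0
CALIB_AMP_UV = 80.0
EVENT_AMP_UV = {"stimulus": 25.0, "speech": 35.0, "response": 25.0}
AMP_CV = 0.35  # trial-to-trial coefficient of variation of burst amplitude

BURST_DUR_S = 0.6
BURST_RAMP_S = 0.1
# burst onset relative to the 1-s analysis epoch of each event
BURST_OFFSET_S = {"stimulus": 0.15, "speech": 0.05, "response": 0.25}


class ProfileError(ValueError):
    """Raised when a participant profile violates its invariants."""


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one synthetic participant.

    ``liar_type`` names the telltale muscle ("ZM", "CS") or "NULL" for a
    participant with no planted lie/truth difference.  ``effect_size`` is
    the standardized amplitude difference of the telltale muscle's envelope
    between lie and truth trials, planted in ``effect_events``.
    """

    id: str
    liar_type: str = "NULL"
    effect_size: float = 0.0
    effect_events: frozenset = frozenset({"speech"})
    lie_base_rate: float = 0.5
    lie_drift: float = 0.002  # log-odds per trial, centered at mid-session
    rt_sender_mean_s: float = 1.9
    rt_receiver_mean_s: float = 4.4
    receiver_hit_rate: float = 0.485
    seed: int = 0

    def validate(self) -> None:
        if self.liar_type not in LIAR_TYPES:
            raise ProfileError(f"unknown liar_type {self.liar_type!r}")
        for p, name in [
            (self.lie_base_rate, "lie_base_rate"),
            (self.receiver_hit_rate, "receiver_hit_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ProfileError(f"{name} must be in [0, 1], got {p}")
        if self.effect_size < 0:
            raise ProfileError("effect_size must be >= 0")
        if self.liar_type == "NULL" and self.effect_size != 0:
            raise ProfileError("NULL profile implies effect_size = 0")
        if not set(self.effect_events) <= set(EVENTS):
            raise ProfileError(f"effect_events must be a subset of {EVENTS}")
        if self.rt_sender_mean_s <= 0 or self.rt_receiver_mean_s <= 0:
            raise ProfileError("reaction-time means must be positive")


@dataclass
class TrialEvents:
    """One trial of the Sender/Receiver word game (times in seconds from
    recording start, 0-based sample convention)."""

    trial_idx: int  # 1-based within participant, across both stages
    stage: int  # 1 = no incentives, 2 = monetary incentives
    word_heard: str
    word_said: str
    is_lie: bool
    receiver_said_lie: bool
    t_stimulus_s: float
    t_speech_s: float
    t_response_s: float

    def validate(self) -> None:
        if self.is_lie != (self.word_said != self.word_heard):
            raise ValueError("is_lie inconsistent with words")
        if not self.t_stimulus_s < self.t_speech_s < self.t_response_s:
            raise ValueError("event times must be strictly increasing")


@dataclass
class ElectrodeRecording:
    """Raw 8-channel sEMG plus calibration and trial marks.

    ``samples`` is [8 electrodes x T samples] in microvolts; electrodes 0-4
    sit over the cheek (ZM), 5-7 over the eyebrow (CS).
    """

    samples: np.ndarray
    fs: int = FS
    calibration_marks: list = field(default_factory=list)  # (gesture, start_s, end_s)
    trial_marks: list = field(default_factory=list)  # trial-onset sample indices
    source_envelopes: np.ndarray | None = None  # [2 x T] ground truth, ZM then CS

    def __post_init__(self):
        if self.samples.ndim != 2 or self.samples.shape[0] != 8:
            raise ValueError("recording must have exactly 8 electrode rows")
        if self.fs != FS:
            raise ValueError(f"sampling rate must be {FS}")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


# ---------------------------------------------------------------------------
# trial simulation (behavior only, no signals)


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, n: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and log-sd."""
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=n)


def simulate_trials(
    profile: ParticipantProfile,
    n_trials_per_stage: int,
    rng: np.random.Generator,
    t_start_s: float = CALIBRATION_TOTAL_S + 2.0,
    iti_s: float = 1.5,
) -> list[TrialEvents]:
    """Draw the event log for one participant (both stages).

    The lie indicator follows a logistic trend centered at mid-session,
    logit p_i = logit(lie_base_rate) + lie_drift * (i - (n+1)/2), so the
    session-average lie rate stays at ``lie_base_rate`` while later trials
    are more likely to be lies when ``lie_drift`` > 0.
    """
    profile.validate()
    if n_trials_per_stage < 2:
        raise ProfileError("n_trials_per_stage must be >= 2")
    n_total = 2 * n_trials_per_stage
    base = np.clip(profile.lie_base_rate, 1e-9, 1 - 1e-9)
    logit0 = np.log(base / (1 - base))
    idx = np.arange(1, n_total + 1)
    p_lie = 1.0 / (1.0 + np.exp(-(logit0 + profile.lie_drift * (idx - (n_total + 1) / 2))))

    rt_snd = np.maximum(_lognormal(rng, profile.rt_sender_mean_s, 0.40, n_total), 0.3)
    rt_rcv = np.maximum(_lognormal(rng, profile.rt_receiver_mean_s, 0.30, n_total), 0.4)
    heard = rng.integers(0, 2, n_total)
    lies = rng.random(n_total) < p_lie
    said_lie = rng.random(n_total)
    itis = iti_s + rng.uniform(-0.5, 0.5, n_total)

    trials: list[TrialEvents] = []
    t = float(t_start_s)
    for i in range(n_total):
        is_lie = bool(lies[i])
        w_heard = WORDS[heard[i]]
        w_said = WORDS[1 - heard[i]] if is_lie else w_heard
        p_say_lie = profile.receiver_hit_rate if is_lie else RECEIVER_FALSE_ALARM
        t_speech = t + rt_snd[i]
        t_resp = t_speech + rt_rcv[i]
        trials.append(
            TrialEvents(
                trial_idx=i + 1,
                stage=1 if i < n_trials_per_stage else 2,
                word_heard=w_heard,
                word_said=w_said,
                is_lie=is_lie,
                receiver_said_lie=bool(said_lie[i] < p_say_lie),
                t_stimulus_s=t,
                t_speech_s=t_speech,
                t_response_s=t_resp,
            )
        )
        t = t_resp + itis[i]
    return trials


# ---------------------------------------------------------------------------
# signal synthesis


def _band_noise(rng: np.random.Generator, n: int, fs: int) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to 20-450 Hz (4th-order Butterworth)."""
    sos = sps.butter(4, [20, 450], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / max(x.std(), 1e-12)


def _add_burst(env: np.ndarray, fs: int, onset_s: float, dur_s: float, amp: float,
               ramp_s: float = BURST_RAMP_S) -> None:
    """Add a raised-cosine (trapezoid with cosine ramps) burst in place."""
    n = int(round(dur_s * fs))
    i0 = int(round(onset_s * fs))
    if i0 < 0 or i0 + n > env.size or n <= 0:
        return
    t = np.arange(n) / fs
    shape = np.ones(n)
    nr = int(round(ramp_s * fs))
    if nr > 0:
        up = 0.5 * (1 - np.cos(np.pi * t[:nr] / ramp_s))
        shape[:nr] = up
        shape[-nr:] = up[::-1]
    env[i0:i0 + n] += amp * shape


def _calibration_marks() -> list[tuple[str, float, float]]:
    marks = []
    t = CALIBRATION_LEAD_S
    for gesture in ["smile"] * 3 + ["frown"] * 3:
        marks.append((gesture, t, t + GESTURE_S))
        t += GESTURE_S + GESTURE_GAP_S
    return marks


def _mixing_matrix(rng: np.random.Generator) -> np.ndarray:
    """Per-participant 8x2 gain matrix [electrodes x (ZM, CS)] with jitter
    that preserves strict region dominance of each source."""
    zm = ZM_GAINS + rng.normal(0, 0.06, 8)
    cs = CS_GAINS + rng.normal(0, 0.06, 8)
    zm[:5] = np.clip(zm[:5], 0.30, None)
    zm[5:] = np.clip(zm[5:], 0.02, 0.20)
    cs[5:] = np.clip(cs[5:], 0.30, None)
    cs[:5] = np.clip(cs[:5], 0.02, 0.20)
    return np.column_stack([zm, cs])


def synthesize_recording(
    profile: ParticipantProfile,
    trials: Sequence[TrialEvents],
    rng: np.random.Generator,
    keep_sources: bool = False,
) -> ElectrodeRecording:
    """Render the 8-electrode recording for a simulated event log."""
    profile.validate()
    t_end = trials[-1].t_response_s + 2.0
    n = int(np.ceil(t_end * FS))

    env = np.zeros((2, n))  # ZM, CS activation envelopes
    env += BASELINE_UV
    marks = _calibration_marks()
    for gesture, t0, t1 in marks:
        src = 0 if gesture == "smile" else 1
        amp = CALIB_AMP_UV * (1 + 0.1 * rng.standard_normal())
        _add_burst(env[src], FS, t0, t1 - t0, amp)

    telltale = {"ZM": 0, "CS": 1}.get(profile.liar_type, None)
    for tr in trials:
        epoch_start = {
            "stimulus": tr.t_stimulus_s,
            "speech": tr.t_speech_s,
            "response": tr.t_response_s - 1.0,
        }
        for ev in EVENTS:
            base_amp = EVENT_AMP_UV[ev]
            for src in (0, 1):
                z = rng.standard_normal()
                if (
                    tr.is_lie
                    and telltale == src
                    and ev in profile.effect_events
                ):
                    z = z + profile.effect_size
                amp = base_amp * (1.0 + AMP_CV * z)
                amp = max(amp, 0.05 * base_amp)
                _add_burst(env[src], FS, epoch_start[ev] + BURST_OFFSET_S[ev],
                           BURST_DUR_S, amp)

    sources = np.vstack([_band_noise(rng, n, FS) for _ in range(2)]) * env
    gains = _mixing_matrix(rng)
    samples = gains @ sources + SENSOR_NOISE_UV * rng.standard_normal((8, n))

    return ElectrodeRecording(
        samples=samples.astype(np.float32),
        fs=FS,
        calibration_marks=marks,
        trial_marks=[int(round(tr.t_stimulus_s * FS)) for tr in trials],
        source_envelopes=env.astype(np.float32) if keep_sources else None,
    )


def generate_participant(
    profile: ParticipantProfile,
    n_trials_per_stage: int = 80,
    iti_s: float = 1.5,
    keep_sources: bool = False,
) -> tuple[ElectrodeRecording, list[TrialEvents]]:
    """Generate one participant's recording and event log.

    Deterministic: the same (profile, n_trials_per_stage) yields
    bit-identical output, all randomness flowing from ``profile.seed``.
    """
    profile.validate()
    if n_trials_per_stage < 2:
        raise ProfileError("n_trials_per_stage must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(profile.seed)]))
    trials = simulate_trials(profile, n_trials_per_stage, rng, iti_s=iti_s)
    rec = synthesize_recording(profile, trials, rng, keep_sources=keep_sources)
    return rec, trials


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """A set of participant profiles with lazy signal generation.

    Recordings are rendered on demand (`participant(i)`) so that cohorts of
    study scale do not have to be held in memory at once.
    """

    profiles: list[ParticipantProfile]
    n_trials_per_stage: int = 80
    iti_s: float = 1.5

    def __len__(self) -> int:
        return len(self.profiles)

    def participant(self, i: int, keep_sources: bool = False):
        return generate_participant(
            self.profiles[i], self.n_trials_per_stage, iti_s=self.iti_s,
            keep_sources=keep_sources,
        )

    @property
    def manifest(self) -> dict:
        return {
            "n_participants": len(self.profiles),
            "n_trials_per_stage": self.n_trials_per_stage,
            "profiles": [
                {**dataclasses.asdict(p), "effect_events": sorted(p.effect_events)}
                for p in self.profiles
            ],
        }


def participant_seed(base_seed: int, i: int) -> int:
    """Deterministic per-participant seed derived from the cohort seed."""
    return int(np.random.SeedSequence([int(base_seed), int(i)]).generate_state(1)[0] % (2**31))


def _allocate_counts(n: int, mix: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of n participants to liar types."""
    types = [t for t in LIAR_TYPES if mix.get(t, 0) > 0]
    fracs = np.array([mix[t] for t in types], float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("group_mix proportions must sum to 1")
    raw = fracs * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))  # stable: ties by LIAR_TYPES order
    for k in range(n - counts.sum()):
        counts[order[k]] += 1
    out: list[str] = []
    for t, c in zip(types, counts):
        out.extend([t] * c)
    return out


def generate_cohort(
    n_participants: int,
    group_mix: dict[str, float] | None = None,
    base_seed: int = 0,
    n_trials_per_stage: int = 80,
    effect_size: float = 1.0,
    effect_events: Iterable[str] = ("speech",),
    couple_receiver: bool = False,
    receiver_coupling: float = 0.1,
    iti_s: float = 1.5,
    **profile_kwargs,
) -> Cohort:
    """Build a deterministic cohort manifest.

    ``group_mix`` gives the proportion of each liar type (default half ZM,
    half CS).  When ``couple_receiver`` is set, a participant's receiver is
    given hit probability 0.5 + receiver_coupling * effect_size — stronger
    telltale leakage makes the human counterpart slightly better too, the
    structure behind the negative machine-human correlation.
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    group_mix = group_mix or {"ZM": 0.5, "CS": 0.5}
    types = _allocate_counts(n_participants, group_mix)
    profiles = []
    for i, t in enumerate(types):
        e = 0.0 if t == "NULL" else float(effect_size)
        hit = 0.5 + receiver_coupling * e if couple_receiver else 0.485
        profiles.append(
            ParticipantProfile(
                id=f"sim_{i:02d}",
                liar_type=t,
                effect_size=e,
                effect_events=frozenset(effect_events),
                receiver_hit_rate=float(np.clip(hit, 0.0, 1.0)),
                seed=participant_seed(base_seed, i),
                **profile_kwargs,
            )
        )
    return Cohort(profiles=profiles, n_trials_per_stage=n_trials_per_stage, iti_s=iti_s)


# ---------------------------------------------------------------------------
# plain-text I/O

EVENT_COLUMNS = [
    "trial_idx", "stage", "word_heard", "word_said", "is_lie",
    "receiver_said_lie", "t_stimulus_s", "t_speech_s", "t_response_s",
]


def write_events_tsv(trials: Sequence[TrialEvents], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame([dataclasses.asdict(t) for t in trials])[EVENT_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[TrialEvents]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        TrialEvents(
            trial_idx=int(r.trial_idx), stage=int(r.stage),
            word_heard=str(r.word_heard), word_said=str(r.word_said),
            is_lie=bool(r.is_lie), receiver_said_lie=bool(r.receiver_said_lie),
            t_stimulus_s=float(r.t_stimulus_s), t_speech_s=float(r.t_speech_s),
            t_response_s=float(r.t_response_s),
        )
        for r in df.itertuples()
    ]


def write_recording_csv(rec: ElectrodeRecording, path: str | Path) -> None:
    """Signals as plain CSV (sample, e0..e7) plus a JSON sidecar of marks."""
    import pandas as pd

    cols = {f"e{i}": rec.samples[i] for i in range(8)}
    pd.DataFrame({"sample": np.arange(rec.samples.shape[1]), **cols}).to_csv(
        path, index=False)
    sidecar = {
        "fs": rec.fs,
        "calibration_marks": [[g, s, e] for g, s, e in rec.calibration_marks],
        "trial_marks": list(map(int, rec.trial_marks)),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_recording_csv(path: str | Path) -> ElectrodeRecording:
    import pandas as pd

    df = pd.read_csv(path)
    samples = np.vstack([df[f"e{i}"].to_numpy(np.float32) for i in range(8)])
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ElectrodeRecording(
        samples=samples, fs=int(meta["fs"]),
        calibration_marks=[(g, float(s), float(e)) for g, s, e in meta["calibration_marks"]],
        trial_marks=list(map(int, meta["trial_marks"])),
    )
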