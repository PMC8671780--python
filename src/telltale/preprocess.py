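"""Raw 8-channel sEMG to event-locked 1-s envelope epochs.

Pipeline: differential montage (all 28 electrode pairs), zero-phase
filtering (50 Hz notch + 5-500 Hz 4th-order Butterworth band-pass), peak
envelope (cubic spline through local maxima of the rectified signal in
50-ms windows), calibration-driven selection of one ZM and one CS
differential channel, and epoching into three 1-s windows per trial
(stimulus onset, speech onset, and the second leading up to the receiver's
response).  The envelope is computed on the continuous recording and only
then segmented, so epoch edges carry no filter or spline artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .synth import EVENTS, ElectrodeRecording, TrialEvents

ZM_ELECTRODES = (0, 1, 2, 3, 4)
CS_PAIRS = ((5, 6), (6, 7))
ALL_PAIRS = tuple(combinations(range(8), 2))  # 28 unordered pairs, i < j
ZM_PAIRS = tuple(p for p in ALL_PAIRS if p[0] in ZM_ELECTRODES and p[1] in ZM_ELECTRODES)

LOW_CONFIDENCE_RATIO = 1.5


@dataclass
class DifferentialSet:
    """All 28 differential channels of an 8-electrode recording."""

    channels: np.ndarray  # [28 x T]
    pair_labels: tuple = ALL_PAIRS

    def __post_init__(self):
        if self.channels.shape[0] != len(self.pair_labels):
            raise ValueError("channel count must match pair labels")

    def pair(self, pair: tuple[int, int]) -> np.ndarray:
        return self.channels[self.pair_labels.index(tuple(pair))]


@dataclass
class SelectedChannels:
    """The two analysis channels chosen from the calibration block."""

    zm_pair: tuple[int, int]
    cs_pair: tuple[int, int]
    selection_scores: dict = field(default_factory=dict)
    low_confidence: bool = False


@dataclass
class EpochSet:
    """Trials x samples envelope matrix for one (muscle, event, stage)."""

    data: np.ndarray  # [n_trials x fs] envelope, non-negative
    labels: np.ndarray  # boolean lie indicator per trial
    muscle: str  # "ZM" | "CS"
    event: str  # "stimulus" | "speech" | "response"
    stage: int
    fs: int = 2000
    trial_idx: np.ndarray | None = None

    def __post_init__(self):
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels length must equal number of trials")
        if self.data.shape[1] != self.fs:
            raise ValueError("each epoch must be exactly 1 s of samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def compute_differentials(rec: ElectrodeRecording | np.ndarray) -> DifferentialSet:
    """All C(8,2)=28 differential channels, channel (i, j) = e_i - e_j.

    Only the i < j orientation is kept; the discarded orientation is its
    negation (antisymmetry d(i,j) = -d(j,i)).
    """
    samples = rec.samples if isinstance(rec, ElectrodeRecording) else np.asarray(rec)
    if samples.ndim != 2 or samples.shape[0] != 8:
        raise ValueError("expected an 8-channel array")
    i_idx = np.array([p[0] for p in ALL_PAIRS])
    j_idx = np.array([p[1] for p in ALL_PAIRS])
    return DifferentialSet(channels=samples[i_idx] - samples[j_idx])


def differential_pair(rec: ElectrodeRecording, pair: tuple[int, int]) -> np.ndarray:
    """Single differential channel without materializing all 28."""
    i, j = pair
    return rec.samples[i].astype(np.float64) - rec.samples[j].astype(np.float64)


def _design_filters(fs: float):
    sos_band = sps.butter(4, [5, 500], btype="bandpass", fs=fs, output="sos")
    b_notch, a_notch = sps.iirnotch(50.0, Q=30.0, fs=fs)
    return sos_band, (b_notch, a_notch)


def apply_filters(x: np.ndarray, fs: float) -> np.ndarray:
    """50 Hz notch (Q=30) then 5-500 Hz band-pass, both zero-phase.

    Forward-backward application keeps the filtering linear and
    time-invariant with zero group delay, so epoch timing is unaffected;
    the effective magnitude response is the squared design response.
    """
    if fs <= 1000:
        raise ValueError("fs must exceed 1000 so the 500 Hz band edge is below Nyquist")
    x = np.asarray(x, dtype=np.float64)
    sos_band, (b_notch, a_notch) = _design_filters(fs)
    y = sps.filtfilt(b_notch, a_notch, x, axis=-1)
    return sps.sosfiltfilt(sos_band, y, axis=-1)


def filter_response(fs: float, freqs) -> np.ndarray:
    """|H(f)| of the zero-phase filter cascade at the given frequencies.

    The design-equation oracle for `apply_filters`: squared magnitude of
    notch times band-pass, as realized by forward-backward filtering.
    """
    freqs = np.atleast_1d(freqs).astype(float)
    sos_band, (b_notch, a_notch) = _design_filters(fs)
    w = 2 * np.pi * freqs / fs
    _, h_band = sps.sosfreqz(sos_band, worN=w)
    _, h_notch = sps.freqz(b_notch, a_notch, worN=w)
    return np.abs(h_band * h_notch) ** 2


def peak_envelope(x: np.ndarray, fs: float = 2000, window_ms: float = 50) -> np.ndarray:
    """Peak envelope: cubic spline through per-window maxima of |x|.

    The rectified signal is split into consecutive ``window_ms`` windows;
    a not-a-knot cubic spline is interpolated through the (position, value)
    of each window's maximum and evaluated at every sample, then clipped at
    zero from below.  At every interpolation node the envelope equals the
    rectified signal exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D signal")
    w = max(int(round(window_ms * fs / 1000.0)), 1)
    if x.size < 2 * w:
        raise ValueError("signal must span at least two envelope windows")
    r = np.abs(x)
    n_win = x.size // w
    trimmed = r[: n_win * w].reshape(n_win, w)
    offs = trimmed.argmax(axis=1)
    pos = np.arange(n_win) * w + offs
    vals = trimmed[np.arange(n_win), offs]
    # the ragged tail (< one window) contributes one extra node if present
    if x.size > n_win * w:
        tail = r[n_win * w:]
        pos = np.append(pos, n_win * w + tail.argmax())
        vals = np.append(vals, tail.max())
    env = CubicSpline(pos, vals)(np.arange(x.size))
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# channel selection


def _segment_rms(env: np.ndarray, fs: float, intervals) -> float:
    chunks = [env[int(round(s * fs)):int(round(e * fs))] for s, e in intervals]
    cat = np.concatenate([c for c in chunks if c.size]) if chunks else np.array([])
    if cat.size == 0:
        raise ValueError("empty segment for RMS")
    return float(np.sqrt(np.mean(cat**2)))


def _rest_intervals(calibration_marks) -> list[tuple[float, float]]:
    """Gaps between consecutive gestures (the neutral-expression rests)."""
    rests = []
    for (_, _, e0), (_, s1, _) in zip(calibration_marks, calibration_marks[1:]):
        if s1 > e0:
            rests.append((e0, s1))
    return rests


def select_channels(
    envelopes: DifferentialSet,
    calibration_marks,
    fs: float = 2000,
) -> SelectedChannels:
    """Pick the ZM and CS analysis pairs from calibration envelopes.

    ``envelopes`` holds the envelope of each differential channel over the
    calibration block (time aligned with the marks).  The ZM pair is the
    cheek pair (both electrodes in 0-4) with the largest smile-vs-rest RMS
    ratio; the CS pair is whichever of (5,6), (6,7) has the largest
    frown-vs-rest ratio.  All candidate ratios are reported for audit, and
    the result is flagged low-confidence when the best ratio is below 1.5
    (no clear gesture modulation).
    """
    smiles = [(s, e) for g, s, e in calibration_marks if g == "smile"]
    frowns = [(s, e) for g, s, e in calibration_marks if g == "frown"]
    if not smiles or not frowns:
        raise ValueError("calibration must contain at least one smile and one frown")
    rests = _rest_intervals(calibration_marks) or [(0.0, calibration_marks[0][1])]

    scores: dict = {"smile": {}, "frown": {}}

    def ratio(pair, intervals):
        env = envelopes.pair(pair)
        return _segment_rms(env, fs, intervals) / max(_segment_rms(env, fs, rests), 1e-12)

    for pair in ZM_PAIRS:
        scores["smile"][pair] = ratio(pair, smiles)
    for pair in CS_PAIRS:
        scores["frown"][pair] = ratio(pair, frowns)

    zm_pair = max(ZM_PAIRS, key=lambda p: scores["smile"][p])
    cs_pair = max(CS_PAIRS, key=lambda p: scores["frown"][p])
    best = max(scores["smile"][zm_pair], scores["frown"][cs_pair])
    return SelectedChannels(
        zm_pair=zm_pair, cs_pair=cs_pair, selection_scores=scores,
        low_confidence=bool(best < LOW_CONFIDENCE_RATIO),
    )


def select_channels_from_recording(rec: ElectrodeRecording) -> SelectedChannels:
    """Convenience: filter + envelope the calibration block of every
    candidate pair, then run `select_channels`."""
    if not rec.calibration_marks:
        raise ValueError("recording has no calibration marks")
    t_end = rec.calibration_marks[-1][2] + 1.0
    n = min(int(round(t_end * rec.fs)), rec.samples.shape[1])
    seg = rec.samples[:, :n].astype(np.float64)
    diffs = compute_differentials(seg)
    envs = np.empty_like(diffs.channels)
    candidates = set(ZM_PAIRS) | set(CS_PAIRS)
    for k, pair in enumerate(diffs.pair_labels):
        if pair in candidates:
            envs[k] = peak_envelope(apply_filters(diffs.channels[k], rec.fs), rec.fs)
        else:
            envs[k] = 0.0
    return select_channels(DifferentialSet(envs), rec.calibration_marks, rec.fs)


def continuous_envelope(rec: ElectrodeRecording, pair: tuple[int, int]) -> np.ndarray:
    """Filtered peak envelope of one differential pair over the full recording."""
    return peak_envelope(apply_filters(differential_pair(rec, pair), rec.fs), rec.fs)


# ---------------------------------------------------------------------------
# epoching


def epoch_trials(
    envelope: np.ndarray,
    events: list[TrialEvents],
    muscle: str,
    fs: int = 2000,
    calibration_end_s: float = 0.0,
) -> tuple[dict, list]:
    """Cut the continuous envelope into 1-s event-locked epochs.

    Per trial: stimulus epoch [t_stimulus, t_stimulus+1), speech epoch
    [t_speech, t_speech+1), response epoch [t_response-1, t_response).
    Epochs may overlap.  Trials with any epoch out of bounds (or reaching
    into the calibration block) are dropped and logged, never fatal.

    Returns ``(epoch_sets, exclusions)`` where ``epoch_sets`` maps
    (event, stage) -> EpochSet and ``exclusions`` lists (trial_idx, reason).
    """
    envelope = np.asarray(envelope)
    T = envelope.size
    exclusions: list[tuple[int, str]] = []
    kept: dict[int, list[TrialEvents]] = {}
    for tr in events:
        starts = {
            "stimulus": tr.t_stimulus_s,
            "speech": tr.t_speech_s,
            "response": tr.t_response_s - 1.0,
        }
        reason = None
        if tr.t_response_s < 1.0:
            reason = "response earlier than 1 s"
        else:
            for ev, s in starts.items():
                i0 = int(round(s * fs))
                if i0 < 0 or i0 + fs > T:
                    reason = f"{ev} epoch outside recording"
                    break
                if s < calibration_end_s:
                    reason = f"{ev} epoch overlaps calibration"
                    break
        if reason is None:
            kept.setdefault(tr.stage, []).append(tr)
        else:
            exclusions.append((tr.trial_idx, reason))

    out: dict = {}
    for stage, trs in kept.items():
        labels = np.array([t.is_lie for t in trs], dtype=bool)
        idx = np.array([t.trial_idx for t in trs])
        for ev in EVENTS:
            rows = np.empty((len(trs), fs))
            for r, tr in enumerate(trs):
                s = {"stimulus": tr.t_stimulus_s, "speech": tr.t_speech_s,
                     "response": tr.t_response_s - 1.0}[ev]
                i0 = int(round(s * fs))
                rows[r] = envelope[i0:i0 + fs]
            out[(ev, stage)] = EpochSet(
                data=rows, labels=labels.copy(), muscle=muscle, event=ev,
                stage=stage, fs=fs, trial_idx=idx.copy(),
            )
    return out, exclusions


def standardized_epoch_difference(epochs: EpochSet) -> float:
    """Cohen's d of the per-trial mean envelope, lie minus truth."""
    m = epochs.data.mean(axis=1)
    lie, truth = m[epochs.labels], m[~epochs.labels]
    if lie.size < 2 or truth.size < 2:
        return float("nan")
    n1, n0 = lie.size, truth.size
    sp = np.sqrt(((n1 - 1) * lie.var(ddof=1) + (n0 - 1) * truth.var(ddof=1)) / (n1 + n0 - 2))
    return float((lie.mean() - truth.mean()) / max(sp, 1e-12))
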