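import numpy as np
import pytest

import telltale
from telltale import preprocess as pp

#: shorter reaction times than the study means, used where only epoch
#: structure matters — keeps generated recordings small
FAST_RT = dict(rt_sender_mean_s=1.2, rt_receiver_mean_s=1.6)


def make_epochset(n_trials=40, fs=2000, seed=0, labels=None, muscle="ZM",
                  event="speech", stage=2, scale=5.0):
    """Random non-negative envelope epochs with balanced-ish labels."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = np.arange(n_trials) % 2 == 0
    return pp.EpochSet(
        data=np.abs(rng.normal(scale, 1.0, (n_trials, fs))),
        labels=np.asarray(labels, dtype=bool),
        muscle=muscle, event=event, stage=stage, fs=fs,
    )


@pytest.fixture(scope="session")
def planted_zm_participant():
    """One ZM-type participant with a planted speech effect (d = 1)."""
    profile = telltale.ParticipantProfile(
        id="fix_zm", liar_type="ZM", effect_size=1.0,
        effect_events=frozenset({"speech"}), seed=424242, **FAST_RT)
    rec, trials = telltale.generate_participant(profile, n_trials_per_stage=40)
    return profile, rec, trials


@pytest.fixture(scope="session")
def planted_zm_epochs(planted_zm_participant):
    """Preprocessed epoch sets of the planted participant, both muscles."""
    _, rec, trials = planted_zm_participant
    sel = pp.select_channels_from_recording(rec)
    calib_end = rec.calibration_marks[-1][2]
    out = {}
    excl = {}
    for muscle, pair in (("ZM", sel.zm_pair), ("CS", sel.cs_pair)):
        env = pp.continuous_envelope(rec, pair)
        out[muscle], excl[muscle] = pp.epoch_trials(
            env, trials, muscle, rec.fs, calibration_end_s=calib_end)
    return {"selection": sel, "epochs": out, "exclusions": excl, "trials": trials}
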