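import numpy as np
import pytest

from spikesight.core import Session, Trial, TrialTable, Unit
from spikesight.synth import SimConfig, generate_session


def make_trials(n_stim=20, n_nostim=10, spacing=10.0, start=5.0,
                group="Expert", rng=None):
    """Simple alternating trial table: stimulus (hit) and no-stimulus (CR)."""
    trials = []
    kinds = ["hit"] * n_stim + ["CR"] * n_nostim
    for i, outcome in enumerate(kinds):
        visual = start + i * spacing
        whisker = visual + 1.0 if outcome in ("hit", "miss") else None
        trials.append(Trial(trial_id=i, visual_onset_s=visual,
                            whisker_onset_s=whisker,
                            auditory_onset_s=visual + 2.0, outcome=outcome))
    return TrialTable(trials=trials, session_id="fixture", group=group)


def poisson_unit(rate_hz, span, rng, unit_id="u0", area="wS1",
                 cell_class="RS"):
    """Homogeneous Poisson unit over [0, span] seconds."""
    n = rng.poisson(rate_hz * span)
    times = np.sort(rng.uniform(0.0, span, n))
    times = times[np.concatenate([[True], np.diff(times) > 1e-6])]
    return Unit(unit_id=unit_id, area=area, spike_times=times,
                cell_class=cell_class,
                spike_width_ms=0.5 if cell_class == "RS" else 0.2)


@pytest.fixture(scope="session")
def small_session():
    """A small but complete synthetic session shared by read-only tests."""
    cfg = SimConfig(
        seed=101,
        n_units={("wS1", "RS"): 5, ("wS1", "FS"): 4,
                 ("wM1", "RS"): 5, ("wM1", "FS"): 3,
                 ("ALM", "RS"): 4, ("tjM1", "RS"): 4},
        trial_counts={"hit": 25, "miss": 5, "CR": 25, "FA": 5})
    session, truth = generate_session(cfg)
    return session, truth
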