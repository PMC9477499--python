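import numpy as np
import pytest

import nremtools as nt

FS = 128.0


@pytest.fixture(scope="session")
def n2_hypnogram():
    def make(n_epochs: int) -> nt.Hypnogram:
        return nt.Hypnogram(["N2"] * n_epochs)
    return make


@pytest.fixture(scope="session")
def quiet_sim(n2_hypnogram):
    """Event-free 1/f recording (beta=1.5) on 10 min of N2."""
    p = nt.SimParams(duration_s=600, seed=42, sw_density_per_min=0,
                     sp_density_per_min=0,
                     stage_sequence=n2_hypnogram(20))
    rec, h, truth = nt.simulate_recording(p)
    return rec, h, truth


@pytest.fixture(scope="session")
def standard_sim(n2_hypnogram):
    """Default-parameter recording with events on 10 min of N2."""
    p = nt.SimParams(duration_s=600, seed=7, stage_sequence=n2_hypnogram(20))
    rec, h, truth = nt.simulate_recording(p)
    return rec, h, truth


def match_events(detected_times, truth_times, tol_s):
    """(n_matched_truth, n_unmatched_detected) under a time tolerance."""
    tp = sum(any(abs(d - t) <= tol_s for d in detected_times)
             for t in truth_times)
    fp = sum(not any(abs(d - t) <= tol_s for t in truth_times)
             for d in detected_times)
    return tp, fp


@pytest.fixture(scope="session")
def event_matcher():
    return match_events
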