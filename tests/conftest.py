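import numpy as np
import pytest

import anklemech as am


@pytest.fixture(scope="session")
def small_cohort():
    return am.sample_cohort(5, seed=11)


@pytest.fixture(scope="session")
def subject(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def noiseless_trial(subject):
    """One noiseless trial plus its generative truth and landmarks."""
    truth = am.ground_truth(subject, 1.4, seed=42)
    trial = am.render_trial(subject, 1.4, truth, noise_sd=0.0, seed=0)
    lm = am.locate_landmarks(trial)
    return trial, truth, lm


@pytest.fixture(scope="session")
def noisy_study():
    """Default-calibration 26-subject, 216-trial synthetic study."""
    cohort, truths, trials = am.simulate_study(seed=1)
    summaries = am.summarize_trials(trials)
    return cohort, truths, trials, summaries
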