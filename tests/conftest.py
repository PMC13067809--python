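import numpy as np
import pytest

from epibench import synthetic as syn
from epibench.experiments import cohort_beats


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants, 3 leads, 30 s each, hydrogel electrode, default noise."""
    templates = syn.sample_cohort_templates(6, seed=11)
    return [
        syn.synthesize_ecg(tpl, leads=3, duration=30.0,
                           electrode=syn.ElectrodeModel.pphg(),
                           seed=500 + i, participant_id=f"p{i + 1}")
        for i, tpl in enumerate(templates)
    ]


@pytest.fixture(scope="session")
def small_cohort_beats(small_cohort):
    return cohort_beats(small_cohort)


@pytest.fixture()
def clean_recording():
    """Single-lead noiseless recording through an ideal electrode."""
    tpl = syn.sample_cohort_templates(1, seed=3)[0]
    return syn.synthesize_ecg(tpl, leads=1, duration=30.0,
                              noise=syn.NoiseSpec.none(),
                              electrode=syn.ElectrodeModel.ideal(), seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
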