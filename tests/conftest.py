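import numpy as np
import pytest

from rumina.kinetics import DigestionTimeCourse, UnitKey
from rumina.synth import SimConfig

STUDY_TIMES = (24.0, 36.0, 48.0, 72.0, 96.0, 120.0)


@pytest.fixture
def study_times():
    return np.array(STUDY_TIMES)


@pytest.fixture
def small_config():
    """Tiny design for fast structural tests."""
    return SimConfig(
        n_animals=3,
        n_phyla=2,
        n_classes=3,
        n_orders=4,
        n_families=6,
        n_genera=8,
        n_planted=1,
        effect_sizes=(0.005,),
        n_rare_taxa=1,
        rare_prevalence=1,
        seed=11,
    )


@pytest.fixture
def paper_like_config():
    """Full-scale design mirroring the study layout."""
    return SimConfig(seed=42)


def make_course(times, digested, fraction="NDF", animal="ox1",
                season="spring", diet="hay", substrate="hay"):
    return DigestionTimeCourse(
        UnitKey(animal, season, diet, substrate, fraction),
        np.asarray(times, float),
        np.asarray(digested, float),
    )


def curve(times, a, b, c):
    times = np.asarray(times, float)
    return a + b * (1.0 - np.exp(-c * times))
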