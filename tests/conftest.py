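import numpy as np
import pytest

from nirsmvpa import (
    Dataset,
    Event,
    Recording,
    SyntheticSpec,
    TimeWindow,
    generate_dataset,
)


@pytest.fixture
def small_window():
    return TimeWindow(0.0, 1.0)


@pytest.fixture
def tiny_dataset():
    """3 subjects, 3 channels, hand-built recordings with clean structure.

    Condition 'A' activates channel 1, 'B' activates channel 3; signals are
    constant within each 1 s trial epoch so windowed extraction is exact.
    """
    fs = 10.0
    recordings = []
    pattern = {"A": np.array([1.0, 0.1, 0.0]), "B": np.array([0.0, 0.1, 1.0])}
    for s, bump in enumerate([0.0, 0.05, -0.05]):
        n_samp = 100
        hbo = np.zeros((3, n_samp))
        events = []
        for j, cond in enumerate(["A", "B", "A", "B"]):
            i0 = 10 + j * 20
            # step response: baseline sample 0, then the pattern value
            hbo[:, i0 + 1 : i0 + 10] += (pattern[cond] + bump)[:, None]
            events.append(Event(onset_s=i0 / fs, condition=cond))
        recordings.append(
            Recording(
                subject_id=f"s{s + 1}",
                hbo=hbo,
                channel_ids=["c1", "c2", "c3"],
                sample_rate_hz=fs,
                events=events,
            )
        )
    return Dataset(
        recordings=recordings,
        conditions=["A", "B"],
        included_channels=["c1", "c2", "c3"],
        analysis_window=TimeWindow(0.0, 1.0),
    )


@pytest.fixture
def small_spec():
    """Reduced synthetic regime for fast end-to-end tests."""
    return SyntheticSpec(
        n_subjects=6,
        n_channels=6,
        trials_per_condition=4,
        seed=7,
    )


@pytest.fixture
def small_synthetic(small_spec):
    return generate_dataset(small_spec)
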