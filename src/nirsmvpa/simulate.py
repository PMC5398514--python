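"""Synthetic infant-fNIRS dataset generator.

Emulates the regime of a typical infant event-related fNIRS study: ~10
channels sampled at 10 Hz, two stimulus conditions, a handful of trials per
condition per subject, and jittered inter-trial baselines.  Each condition
has a group-shared spatial amplitude pattern; subjects perturb it with
between-subject noise, trials with within-subject noise, and every sample
carries measurement noise.  A trial's per-channel time course is its
amplitude times a gamma-family hemodynamic response function (HRF) convolved
with the stimulus boxcar.

Each trial's evoked response is confined to its own analysis epoch:
consecutive onsets are separated by max(trial_duration + baseline jitter,
analysis-window length), and a trial's response is truncated at the next
onset.  Real hemodynamic responses under short baselines superpose across
trials; the generator trades that bleed-over for an exact contract, namely
that the windowed baseline-corrected extraction of a noise-free trial
recovers the planted pattern times the *window scaling constant* reported
by :func:`window_scale` - which is what makes every pipeline stage testable
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import Dataset, Event, Recording, TimeWindow
from .patterns import window_sample_slice


def default_group_patterns(n_channels: int) -> dict[str, np.ndarray]:
    """Two spatially distinct amplitude topographies (arbitrary HbO units).

    Gaussian bumps centred over different channel neighbourhoods, echoing
    e.g. an occipital-dominant vs a temporal-dominant response.
    """
    k = np.arange(n_channels)
    width = max(n_channels * 0.15, 1.0)
    a = 0.1 + 0.8 * np.exp(-0.5 * ((k - 0.25 * n_channels) / width) ** 2)
    b = 0.1 + 0.8 * np.exp(-0.5 * ((k - 0.70 * n_channels) / width) ** 2)
    return {"A": a, "B": b}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated experiment.

    Defaults mirror a typical infant study: 19 subjects, 10 channels, two
    conditions with 6 trials each, 10 Hz sampling, 1 s stimuli separated by
    jittered 4-9 s baselines, and a 0-10 s analysis window.
    """

    n_subjects: int = 19
    n_channels: int = 10
    conditions: tuple[str, str] = ("A", "B")
    trials_per_condition: int | tuple[int, int] = 6
    sample_rate_hz: float = 10.0
    trial_duration_s: float = 1.0
    isi_range_s: tuple[float, float] = (4.0, 9.0)
    group_patterns: dict[str, np.ndarray] | None = None
    subject_sd: float = 0.2
    trial_sd: float = 0.3
    noise_sd: float = 0.3
    hrf_peak_time_s: float = 5.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    hrf_duration_s: float = 25.0
    window: tuple[float, float] = (0.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("exactly 2 distinct conditions required")
        for name in ("subject_sd", "trial_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.isi_range_s[0] > self.isi_range_s[1] or self.isi_range_s[0] < 0:
            raise ValueError("isi_range_s must be (min, max) with 0 <= min <= max")
        if self.group_patterns is not None:
            for cond in self.conditions:
                if cond not in self.group_patterns:
                    raise ValueError(f"group_patterns missing condition {cond!r}")
                if len(np.ravel(self.group_patterns[cond])) != self.n_channels:
                    raise ValueError(
                        f"group_patterns[{cond!r}] must have {self.n_channels} "
                        "entries"
                    )

    def resolved_patterns(self) -> dict[str, np.ndarray]:
        if self.group_patterns is None:
            pats = default_group_patterns(self.n_channels)
            return {
                self.conditions[0]: pats["A"],
                self.conditions[1]: pats["B"],
            }
        return {
            c: np.asarray(self.group_patterns[c], dtype=float).ravel()
            for c in self.conditions
        }

    @property
    def channel_ids(self) -> list[str]:
        return [f"ch{j + 1:02d}" for j in range(self.n_channels)]

    @property
    def analysis_window(self) -> TimeWindow:
        return TimeWindow(*self.window)


def hrf_kernel(spec: SyntheticSpec) -> np.ndarray:
    """Stimulus response kernel: boxcar * gamma HRF, peak normalised to 1.

    The HRF is gamma(shape 6, scale peak/5) minus an undershoot gamma
    (shape 16, same scale), truncated at hrf_duration_s; the stimulus boxcar
    of trial_duration_s is convolved in and the result rescaled so its
    maximum is 1, making the planted amplitudes peak HbO changes.
    """
    from scipy.stats import gamma as gamma_dist

    dt = 1.0 / spec.sample_rate_hz
    t = np.arange(0.0, spec.hrf_duration_s, dt)
    scale = spec.hrf_peak_time_s / 5.0  # mode of gamma(6, scale) = 5*scale
    h = gamma_dist.pdf(t, a=6, scale=scale) - spec.hrf_undershoot_ratio * (
        gamma_dist.pdf(t, a=16, scale=scale)
    )
    box = np.ones(max(int(round(spec.trial_duration_s * spec.sample_rate_hz)), 1))
    k = np.convolve(h, box) * dt
    return k / k.max()


def window_scale(spec: SyntheticSpec) -> float:
    """Extraction constant: windowed baseline-corrected mean of the kernel.

    A noise-free, non-overlapping trial of planted amplitude a yields the
    pattern value a * window_scale(spec).
    """
    k = hrf_kernel(spec)
    sl = window_sample_slice(0.0, spec.analysis_window, spec.sample_rate_hz)
    padded = np.zeros(max(sl.stop, k.size))
    padded[: k.size] = k
    seg = padded[sl]
    return float((seg - seg[0]).mean())


def make_null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Replace both conditions' group patterns by their common mean.

    The resulting data are label-exchangeable: any decoding accuracy above
    chance is Monte-Carlo noise.  Idempotent.
    """
    pats = spec.resolved_patterns()
    mean = np.mean([pats[c] for c in spec.conditions], axis=0)
    return replace(
        spec, group_patterns={c: mean.copy() for c in spec.conditions}
    )


def _trial_counts(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, int]:
    if isinstance(spec.trials_per_condition, (tuple, list)):
        lo, hi = spec.trials_per_condition
        return {c: int(rng.integers(lo, hi + 1)) for c in spec.conditions}
    return {c: int(spec.trials_per_condition) for c in spec.conditions}


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Simulate a full two-condition dataset under the spec.

    Deterministic in spec.seed: the same spec yields the same dataset sample
    for sample.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    kernel = hrf_kernel(spec)
    patterns = spec.resolved_patterns()
    win = spec.analysis_window
    recordings = []
    for s in range(spec.n_subjects):
        sid = f"sub{s + 1:02d}"
        subj_pattern = {
            c: patterns[c] + rng.normal(0.0, spec.subject_sd, spec.n_channels)
            for c in spec.conditions
        }
        counts = _trial_counts(spec, rng)
        label_seq = rng.permutation(
            [c for c in spec.conditions for _ in range(counts[c])]
        )
        onsets = []
        t_cursor = rng.uniform(*spec.isi_range_s)  # leading baseline
        for _ in label_seq:
            onsets.append(t_cursor)
            # epochs never shorter than the analysis window, so no trial's
            # window reaches the next trial's response
            t_cursor += max(
                spec.trial_duration_s + rng.uniform(*spec.isi_range_s),
                win.end_s,
            )
        # pad so the analysis window and the HRF tail of the last trial fit
        duration = onsets[-1] + max(win.end_s, spec.hrf_duration_s) + 1.0
        n_samp = int(np.ceil(duration * fs))
        hbo = np.zeros((spec.n_channels, n_samp))
        events = []
        onset_idx = [int(round(o * fs)) for o in onsets]
        for j, (i0, cond) in enumerate(zip(onset_idx, label_seq)):
            amp = subj_pattern[cond] + rng.normal(
                0.0, spec.trial_sd, spec.n_channels
            )
            i1 = min(i0 + kernel.size, n_samp)
            if j + 1 < len(onset_idx):  # truncate at the next epoch
                i1 = min(i1, onset_idx[j + 1])
            hbo[:, i0:i1] += amp[:, None] * kernel[: i1 - i0]
            events.append(Event(onset_s=i0 / fs, condition=str(cond)))
        if spec.noise_sd > 0:
            hbo += rng.normal(0.0, spec.noise_sd, hbo.shape)
        recordings.append(
            Recording(
                subject_id=sid,
                hbo=hbo,
                channel_ids=spec.channel_ids,
                sample_rate_hz=fs,
                events=events,
            )
        )
    return Dataset(
        recordings=recordings,
        conditions=list(spec.conditions),
        included_channels=spec.channel_ids,
        analysis_window=win,
    )
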