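"""Synthetic fixtures with known ground truth.

Three generators mirror the three input kinds of the pipeline: labeled
tabular datasets with planted informative features, multichannel EEG with
planted ocular (blink) artifacts, and a two-arm clinical cohort with a
planted intervention effect on scale scores. All generators are pure
functions of their spec (seed included), so fixtures never need to be
shipped: they are regenerated bit-identically at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EEGRecording, LabeledDataset

__all__ = [
    "TabularSpec",
    "EEGSpec",
    "CohortSpec",
    "make_classification_dataset",
    "make_synthetic_eeg",
    "make_clinical_cohort",
    "INSTRUMENT_RANGES",
]

# Admissible score ranges per instrument. SAS/SDS: 20 items scored 1-4
# (index-style scores up to 100 after the conventional x1.25 conversion);
# HAMD scored here on its 0-68 scale; GQOLI-74 subscales on 0-100.
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "SAS": (25.0, 100.0),
    "SDS": (25.0, 100.0),
    "HAMD": (0.0, 68.0),
    "GQOLI74_physical": (0.0, 100.0),
    "GQOLI74_psychological": (0.0, 100.0),
    "GQOLI74_social": (0.0, 100.0),
    "GQOLI74_substance": (0.0, 100.0),
}


@dataclass(frozen=True)
class TabularSpec:
    """Shape and signal strength of a planted classification dataset.

    ``effect_size`` is the standardized mean shift (in units of the
    feature's noise SD) applied to informative features in class 1.
    """

    n_samples: int
    n_features: int
    n_informative: int
    effect_size: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")


@dataclass(frozen=True)
class EEGSpec:
    """Composition of a synthetic EEG record: sines + noise + blinks."""

    n_channels: int = 3
    duration: float = 10.0
    fs: float = 1000.0
    sine_components: tuple[tuple[float, float], ...] = ((10.0, 1.0),)
    n_blinks: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_blinks < 0:
            raise ValueError("n_blinks must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm pre/post cohort with a planted intervention effect.

    ``intervention_effect`` is the extra mean post-score reduction of the
    intervention arm relative to control, in scale points.
    """

    n_per_group: int = 27
    pre_mean: float = 24.0
    pre_sd: float = 4.0
    intervention_effect: float = 6.0
    control_reduction: float = 8.0
    reduction_sd: float = 3.0
    instrument: str = "HAMD"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.pre_sd < 0 or self.reduction_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.instrument not in INSTRUMENT_RANGES:
            raise ValueError(f"unknown instrument {self.instrument!r}")


def make_classification_dataset(spec: TabularSpec) -> LabeledDataset:
    """Generate a two-class dataset with planted informative features.

    Exactly ``spec.n_informative`` features carry a class-conditional mean
    shift of ``effect_size`` noise SDs (applied to class 1); the remaining
    features are class-independent standard Gaussian noise. Ground-truth
    informative indices are returned on the dataset, never embedded in X.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_samples * (1.0 - spec.class_balance)))
    n1 = min(max(n1, 1), spec.n_samples - 1)
    y = np.zeros(spec.n_samples, dtype=int)
    y[rng.choice(spec.n_samples, size=n1, replace=False)] = 1
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    informative = rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    informative = np.sort(informative)
    X[np.ix_(y == 1, informative)] += spec.effect_size
    return LabeledDataset(X, y, informative_idx=informative)


def _blink_template(fs: float, width_s: float, amplitude: float) -> np.ndarray:
    """Raised-cosine pulse emulating an ocular artifact: a slow,
    high-amplitude transient typical of frontal-channel blinks."""
    n = max(int(round(width_s * fs)), 2)
    t = np.arange(n) / (n - 1)
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def make_synthetic_eeg(spec: EEGSpec) -> tuple[EEGRecording, EEGRecording, list[int]]:
    """Generate a contaminated EEG recording plus its blink-free reference.

    Returns ``(contaminated, clean, blink_onsets)`` where ``blink_onsets``
    are the sample indices where blink pulses were planted (shared across
    channels, as real blinks are on frontal electrodes). Blink pulses are
    300 ms raised cosines with amplitude 5x the clean-signal SD, placed
    uniformly at random without overlap.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    base = np.zeros(n)
    for freq, amp in spec.sine_components:
        base += amp * np.sin(2.0 * np.pi * freq * t)
    clean = np.tile(base, (spec.n_channels, 1))
    if spec.noise_sd > 0:
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)

    contaminated = clean.copy()
    onsets: list[int] = []
    if spec.n_blinks > 0:
        sd = float(np.std(clean))
        if sd == 0.0:
            sd = 1.0
        pulse = _blink_template(spec.fs, 0.3, 5.0 * sd)
        width = pulse.size
        if width >= n:
            raise ValueError("blink template longer than the recording")
        free = np.ones(n - width, dtype=bool)
        for _ in range(spec.n_blinks):
            candidates = np.flatnonzero(free)
            if candidates.size == 0:
                raise ValueError("cannot place blinks without overlap")
            start = int(rng.choice(candidates))
            onsets.append(start)
            contaminated[:, start : start + width] += pulse
            lo = max(start - width, 0)
            free[lo : start + width] = False
        onsets.sort()

    labels = [f"ch{i}" for i in range(spec.n_channels)]
    if spec.n_channels == 3:
        labels = ["Fp1", "Fp2", "Fpz"]
    return (
        EEGRecording(contaminated, spec.fs, labels),
        EEGRecording(clean, spec.fs, list(labels)),
        onsets,
    )


def make_clinical_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate per-patient pre/post scale scores for two equal groups.

    Post scores are pre scores minus a Gaussian reduction; the intervention
    arm's mean reduction exceeds control's by ``intervention_effect`` scale
    points. Scores are clipped to the instrument's admissible range. Output
    is long-format: columns group, patient_id, instrument, timepoint, score.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = INSTRUMENT_RANGES[spec.instrument]
    rows = []
    for group, extra in (("control", 0.0), ("intervention", spec.intervention_effect)):
        pre = rng.normal(spec.pre_mean, spec.pre_sd, size=spec.n_per_group)
        reduction = rng.normal(
            spec.control_reduction + extra, spec.reduction_sd, size=spec.n_per_group
        )
        pre = np.clip(pre, lo, hi)
        post = np.clip(pre - reduction, lo, hi)
        for i in range(spec.n_per_group):
            pid = f"{group[:3]}-{i:03d}"
            rows.append((group, pid, spec.instrument, "pre", round(float(pre[i]), 1)))
            rows.append((group, pid, spec.instrument, "post", round(float(post[i]), 1)))
    return pd.DataFrame(
        rows, columns=["group", "patient_id", "instrument", "timepoint", "score"]
    )
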