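"""Core in-memory containers shared across the pipeline.

These are deliberately thin dataclasses around numpy arrays: a labeled
tabular dataset (the object both filter and wrapper selection operate on),
a multichannel EEG recording, and the boolean feature mask that serves as
the decision variable of the wrapper search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "EEGRecording", "FeatureMask"]

# A feature mask is simply a boolean vector over feature columns.
FeatureMask = np.ndarray


@dataclass
class LabeledDataset:
    """Samples x features matrix with binary class labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix.
    y : ndarray of shape (n_samples,)
        Integer class labels.
    feature_names : list of str
        Column names, one per feature.
    informative_idx : ndarray or None
        Ground-truth indices of planted informative features, when the
        dataset was synthesized; ``None`` for real data.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    informative_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must equal the number of rows of X")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)

    def to_frame(self, label_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_col] = self.y
        return df

    def to_csv(self, path, label_col: str = "label") -> None:
        self.to_frame(label_col).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label_col: str = "label") -> "LabeledDataset":
        df = pd.read_csv(path)
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not found")
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col])
        return cls(X.to_numpy(dtype=float), y, list(X.columns))


@dataclass
class EEGRecording:
    """Multichannel EEG time series in microvolts.

    ``data`` is channels x samples; ``fs`` the sampling rate in Hz;
    ``channel_labels`` one label per channel (e.g. Fp1, Fp2, Fpz).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.fs, list(self.channel_labels))


def mask_from_indices(indices, n_features: int) -> FeatureMask:
    """Boolean mask with the given feature indices set."""
    mask = np.zeros(n_features, dtype=bool)
    mask[np.asarray(list(indices), dtype=int)] = True
    return mask
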