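"""Filter stage: ANOVA F and mutual-information ranking, then their union.

Each feature is scored twice — by the one-way ANOVA F statistic of its
values grouped by class, and by the mutual information (bits) between its
binned values and the class label. The top-k features under each score
are unioned to form the reduced feature space handed to the wrapper
stage. The union keeps any feature that either criterion considers
strong: ANOVA captures mean shifts, MI captures arbitrary (including
non-monotone) dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMask, LabeledDataset

__all__ = [
    "AnovaDecomposition",
    "FilterConfig",
    "anova_decompose",
    "mutual_information_discrete",
    "mutual_information_continuous",
    "filter_union",
    "score_table",
]


@dataclass(frozen=True)
class AnovaDecomposition:
    """One-way variance decomposition of a feature grouped by class.

    tv is the total sum of squares about the grand mean, bgv the
    between-group and wgv the within-group component (tv = bgv + wgv);
    msg = bgv/(k-1), msw = wgv/(N-k), f_score = msg/msw (infinite when
    the groups are perfectly separated, i.e. wgv = 0 < bgv).
    """

    tv: float
    bgv: float
    wgv: float
    msg: float
    msw: float
    f_score: float


def anova_decompose(feature_values, labels) -> AnovaDecomposition:
    """Decompose one feature's variance by class and form the F score."""
    values = np.asarray(feature_values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("feature_values and labels must be equal-length 1-D")
    groups = [values[labels == g] for g in np.unique(labels)]
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA requires at least two groups")
    n_total = values.size
    if n_total <= k:
        raise ValueError("need more observations than groups for msw")
    grand = values.mean()
    tv = float(np.sum((values - grand) ** 2))
    bgv = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    wgv = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    msg = bgv / (k - 1)
    msw = wgv / (n_total - k)
    if msw == 0.0:
        f = np.inf if msg > 0 else 0.0
    else:
        f = msg / msw
    return AnovaDecomposition(tv, bgv, wgv, msg, msw, float(f))


def mutual_information_discrete(x, y) -> float:
    """Plug-in mutual information (bits) of two category sequences."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length and non-empty")
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def mutual_information_continuous(x, y, mi_bins: int = 10) -> float:
    """Mutual information (bits) of two real sequences via equal-width
    2-D binning followed by the discrete plug-in estimator.

    A constant margin occupies a single bin and contributes zero
    information, so constant inputs return 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length and non-empty")
    if mi_bins < 2:
        raise ValueError("mi_bins must be >= 2")

    def bin_indices(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros(v.size, dtype=int)
        edges = np.linspace(lo, hi, mi_bins + 1)
        return np.clip(np.digitize(v, edges[1:-1]), 0, mi_bins - 1)

    return mutual_information_discrete(bin_indices(x), bin_indices(y))


@dataclass(frozen=True)
class FilterConfig:
    """How many features each criterion passes, and the MI binning.

    ``k_anova``/``k_mi`` default to ceil(n_features/2) when None.
    """

    k_anova: int | None = None
    k_mi: int | None = None
    mi_bins: int = 10

    def resolve(self, n_features: int) -> tuple[int, int]:
        k_a = self.k_anova if self.k_anova is not None else -(-n_features // 2)
        k_m = self.k_mi if self.k_mi is not None else -(-n_features // 2)
        for name, k in (("k_anova", k_a), ("k_mi", k_m)):
            if not 1 <= k <= n_features:
                raise ValueError(f"{name}={k} must lie in [1, n_features]")
        return k_a, k_m


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by lower index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:k]


def score_table(dataset: LabeledDataset, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-feature ANOVA F and MI scores plus selection flags."""
    if cfg is None:
        cfg = FilterConfig()
    if dataset.n_classes < 2:
        raise ValueError("filter selection requires at least two classes")
    k_a, k_m = cfg.resolve(dataset.n_features)
    f_scores = np.array(
        [anova_decompose(dataset.X[:, j], dataset.y).f_score
         for j in range(dataset.n_features)]
    )
    mi_scores = np.array(
        [mutual_information_continuous(dataset.X[:, j], dataset.y, cfg.mi_bins)
         for j in range(dataset.n_features)]
    )
    sel_a = np.zeros(dataset.n_features, dtype=bool)
    sel_a[_top_k(f_scores, k_a)] = True
    sel_m = np.zeros(dataset.n_features, dtype=bool)
    sel_m[_top_k(mi_scores, k_m)] = True
    return pd.DataFrame(
        {
            "feature": dataset.feature_names,
            "f_score": f_scores,
            "mi_bits": mi_scores,
            "selected_anova": sel_a,
            "selected_mi": sel_m,
            "selected": sel_a | sel_m,
        }
    )


def filter_union(dataset: LabeledDataset, cfg: FilterConfig | None = None) -> FeatureMask:
    """Union of the top-k_anova F-ranked and top-k_mi MI-ranked features."""
    table = score_table(dataset, cfg)
    return table["selected"].to_numpy()
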