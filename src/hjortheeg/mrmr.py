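"""Maximum-relevance minimum-redundancy greedy feature selection.

Mutual information is estimated by the discrete plug-in estimator on
equal-frequency-binned features (5 bins by default). Greedy forward
selection: the first pick maximizes relevance MI(f; label); each later
pick maximizes either relevance − mean-redundancy (MID) or
relevance / mean-redundancy (MIQ, redundancy floored at a small ε)
against the already-selected set. Ties break toward the earlier column
in canonical table order. Everything is deterministic.

``class_prior='empirical'`` uses observed class frequencies as the
label marginal (the ordinary plug-in); ``'uniform'`` reweights rows so
every class carries equal total weight. With a balanced cohort the two
coincide.
"""

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError
from .io import feature_columns_of

REDUNDANCY_EPS = 1e-12


@dataclass(frozen=True)
class SelectionConfig:
    k: int = 12
    scheme: str = "MIQ"  # {"MIQ", "MID"}
    n_bins: int = 5
    class_prior: str = "empirical"  # {"empirical", "uniform"}

    def __post_init__(self):
        if self.scheme not in ("MIQ", "MID"):
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.class_prior not in ("empirical", "uniform"):
            raise ConfigurationError(f"unknown class_prior {self.class_prior!r}")
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")


@dataclass
class SelectionResult:
    ordered: List[str]
    relevance: List[float]  # MI(f; label) in nats, aligned with `ordered`
    redundancy_at_pick: List[float]  # mean MI with previously selected at pick time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ordered) + 1),
                "feature": self.ordered,
                "relevance_nats": self.relevance,
                "redundancy_at_pick_nats": self.redundancy_at_pick,
            }
        )


def discretize(values, n_bins: int) -> np.ndarray:
    """Equal-frequency integer codes; ties on a bin edge go to the lower bin."""
    v = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ConfigurationError("cannot discretize non-finite values")
    edges = np.quantile(v, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, v, side="left").astype(np.int64)


def mutual_information(a, b, weights=None) -> float:
    """Plug-in MI (nats) between two integer code vectors.

    With ``weights`` the joint distribution is the normalized weighted
    cell mass (used for the label-prior option).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise AlignmentError(f"length mismatch: {a.shape} vs {b.shape}")
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * kb + b, weights=weights, minlength=ka * kb).astype(
        np.float64
    ).reshape(ka, kb)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    terms = joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])
    # summing in sorted order makes MI(a, b) == MI(b, a) float-exact
    return float(np.sort(terms).sum())


def _label_codes_and_weights(labels, class_prior: str):
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    if len(uniques) < 2:
        raise ConfigurationError("mRMR needs at least 2 classes present")
    weights = None
    if class_prior == "uniform":
        counts = np.bincount(codes).astype(np.float64)
        weights = (1.0 / (len(uniques) * counts))[codes]
    return codes, weights


def mrmr(
    table: pd.DataFrame, labels, config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Greedy mRMR over the feature columns of ``table``."""
    features = feature_columns_of(table)
    if config.k > len(features):
        raise ConfigurationError(
            f"k={config.k} exceeds feature count {len(features)}"
        )
    y, w = _label_codes_and_weights(labels, config.class_prior)
    codes = {f: discretize(table[f].to_numpy(), config.n_bins) for f in features}
    relevance = np.array([mutual_information(codes[f], y, weights=w) for f in features])

    n = len(features)
    selected: List[int] = []
    red_sum = np.zeros(n)  # running Σ MI(f, s) over selected s
    available = np.ones(n, dtype=bool)
    rel_out, red_out = [], []
    for pick in range(config.k):
        if pick == 0:
            score = np.where(available, relevance, -np.inf)
            mean_red = np.zeros(n)
        else:
            mean_red = red_sum / pick
            if config.scheme == "MIQ":
                score = relevance / np.maximum(mean_red, REDUNDANCY_EPS)
            else:
                score = relevance - mean_red
            score = np.where(available, score, -np.inf)
        j = int(np.argmax(score))  # argmax keeps the first (canonical-order) max
        selected.append(j)
        available[j] = False
        rel_out.append(float(relevance[j]))
        red_out.append(float(mean_red[j]) if pick else 0.0)
        if pick + 1 < config.k:
            cj = codes[features[j]]
            for i in np.flatnonzero(available):
                red_sum[i] += mutual_information(codes[features[i]], cj)
    return SelectionResult(
        ordered=[features[j] for j in selected],
        relevance=rel_out,
        redundancy_at_pick=red_out,
    )
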