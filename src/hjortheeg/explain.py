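"""Model explanation and channel-wise statistics.

LIME (tabular): around one instance, draw Gaussian perturbations with
per-feature SDs taken from the training fold, weight them by an RBF
proximity kernel on the standardized Euclidean distance, and fit a
weighted ridge regression of the model's continuous decision scores on
the standardized perturbed features (optionally restricted to the
``top_k`` features with the largest weighted univariate association).
The signed ridge coefficients are the explanation; aggregating their
absolute values over explained instances, grouped by (band, channel),
yields a per-channel importance map normalized to max 1.

Channel statistics: per channel, a two-sample Wilcoxon rank-sum test
between patients and controls on the chosen analysis unit (subject
means by default, avoiding pseudo-replication over correlated epochs;
an epoch-level mode is available). The z field is the tie-corrected
normal approximation, signed positive when patients are stochastically
larger; the p-value is exact for small untied samples and asymptotic
otherwise.
"""

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.linear_model import Ridge

from .errors import ConfigurationError
from .io import parse_feature_name
from .montage import MONTAGE_19

ALPHA = 0.05


@dataclass(frozen=True)
class LimeConfig:
    n_samples: int = 1000
    kernel_width: Optional[float] = None  # default 0.75 * sqrt(d)
    top_k: Optional[int] = None  # default: all features of the instance
    ridge_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 100:
            raise ConfigurationError("LIME needs n_samples >= 100")
        if self.kernel_width is not None and self.kernel_width <= 0:
            raise ConfigurationError("kernel_width must be > 0")


@dataclass
class Explanation:
    instance_id: str
    feature_names: List[str]
    weights: np.ndarray  # signed, aligned with feature_names
    r2: float
    degenerate: bool = False  # constant predict_fn


def lime_explain(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    instance: np.ndarray,
    train_mean: np.ndarray,
    train_sd: np.ndarray,
    feature_names: Sequence[str],
    cfg: LimeConfig = LimeConfig(),
    instance_id: str = "",
) -> Explanation:
    """Local linear surrogate of ``predict_fn`` around ``instance``."""
    instance = np.asarray(instance, dtype=np.float64)
    train_mean = np.asarray(train_mean, dtype=np.float64)
    train_sd = np.asarray(train_sd, dtype=np.float64)
    d = instance.size
    if np.any(train_sd <= 0):
        raise ConfigurationError("train SDs must be > 0 for perturbed features")
    kw = cfg.kernel_width if cfg.kernel_width is not None else 0.75 * np.sqrt(d)
    top_k = min(cfg.top_k or d, d)
    rng = np.random.default_rng(cfg.seed)

    Z = instance + train_sd * rng.standard_normal((cfg.n_samples, d))
    Z[0] = instance  # the instance itself anchors the fit
    y = np.asarray(predict_fn(Z), dtype=np.float64).ravel()
    weights_full = np.zeros(d)
    if np.ptp(y) < 1e-12:
        warnings.warn("constant predict_fn: LIME weights set to zero")
        return Explanation(instance_id, list(feature_names), weights_full, 0.0, True)

    dist2 = np.sum(((Z - instance) / train_sd) ** 2, axis=1)
    w = np.exp(-dist2 / kw**2)
    Zs = (Z - train_mean) / train_sd

    if top_k < d:
        # weighted univariate association |cov_w(z_j, y)|
        wm = w / w.sum()
        zc = Zs - (wm @ Zs)
        yc = y - wm @ y
        assoc = np.abs((wm * yc) @ zc)
        support = np.sort(np.argsort(assoc)[::-1][:top_k])
    else:
        support = np.arange(d)

    model = Ridge(alpha=cfg.ridge_alpha)
    model.fit(Zs[:, support], y, sample_weight=w)
    pred = model.predict(Zs[:, support])
    ybar = np.average(y, weights=w)
    ss_res = np.average((y - pred) ** 2, weights=w)
    ss_tot = np.average((y - ybar) ** 2, weights=w)
    r2 = float(1 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    weights_full[support] = model.coef_
    return Explanation(instance_id, list(feature_names), weights_full, r2)


def aggregate_channel_importance(
    explanations: Sequence[Explanation],
    band: str,
    channels: Sequence[str] = MONTAGE_19.channels,
) -> Dict[str, float]:
    """Mean |weight| per channel over all explanations, rescaled to max 1.

    Only features of ``band`` contribute; channels never selected in
    any explanation score 0. Invariant to permuting the explanations.
    """
    if not explanations:
        raise ConfigurationError("need at least one explanation")
    sums = {ch: 0.0 for ch in channels}
    counts = {ch: 0 for ch in channels}
    for exp in explanations:
        for name, weight in zip(exp.feature_names, exp.weights):
            b, _p, ch = parse_feature_name(name)
            if b == band and ch in sums:
                sums[ch] += abs(float(weight))
                counts[ch] += 1
    importance = {
        ch: (sums[ch] / counts[ch] if counts[ch] else 0.0) for ch in channels
    }
    peak = max(importance.values())
    if peak > 0:
        importance = {ch: v / peak for ch, v in importance.items()}
    return importance


@dataclass
class ChannelStat:
    channel: str
    z: float
    p: float
    significant: bool = field(default=False)


def _ranksum_z(patient: np.ndarray, control: np.ndarray) -> float:
    """Tie-corrected normal-approximation z; positive when patients larger."""
    n1, n2 = len(patient), len(control)
    pooled = np.concatenate([patient, control])
    ranks = spstats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var_u == 0:
        return 0.0
    return float((u - n1 * n2 / 2) / np.sqrt(var_u))


def wilcoxon_map(
    table: pd.DataFrame,
    parameter: str,
    band: str,
    unit: str = "subject_mean",
    alpha: float = ALPHA,
    channels: Sequence[str] = MONTAGE_19.channels,
) -> List[ChannelStat]:
    """Per-channel rank-sum comparison of patients vs controls."""
    if unit not in ("subject_mean", "epoch"):
        raise ConfigurationError(f"unknown analysis unit {unit!r}")
    is_patient = table["group"] == "patient"
    if is_patient.all() or (~is_patient).all():
        raise ConfigurationError("both groups must be present")
    out = []
    for ch in channels:
        col = f"{band}.{parameter}.{ch}"
        values = table[[col, "subject_id"]].copy()
        if unit == "subject_mean":
            per = table.groupby("subject_id", sort=False).agg(
                value=(col, "mean"), patient=("group", lambda g: g.iloc[0] == "patient")
            )
            x_pat = per.loc[per["patient"], "value"].to_numpy()
            x_ctl = per.loc[~per["patient"], "value"].to_numpy()
        else:
            x_pat = table.loc[is_patient, col].to_numpy()
            x_ctl = table.loc[~is_patient, col].to_numpy()
        p = float(
            spstats.mannwhitneyu(
                x_pat, x_ctl, alternative="two-sided", method="auto"
            ).pvalue
        )
        z = _ranksum_z(x_pat, x_ctl)
        out.append(ChannelStat(channel=ch, z=z, p=p, significant=p < alpha))
    return out


def channel_stats_frame(stats: Sequence[ChannelStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": [s.channel for s in stats],
            "z": [s.z for s in stats],
            "p": [s.p for s in stats],
            "significant": [s.significant for s in stats],
        }
    )
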