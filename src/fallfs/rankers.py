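"""The four filter feature-ranking methods: chi-square, information gain,
minimum-redundancy-maximum-relevance (MRMR), and ReliefF.

Each ranker consumes an imputed feature table (or a plain DataFrame) and a
binary label vector and returns a :class:`RankedList` — a full ordering of
the features, best first. Chi-square, information gain and MRMR operate on
discretized data: ordinal features at their native codes, metric features cut
into (at most) 10 equal-frequency bins. ReliefF is distance-based and works
on range-normalized raw values.

Score ties are broken by feature-name lexicographic order everywhere and
logged, so rankings are fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fallfs.cohort import FeatureTable

logger = logging.getLogger(__name__)

N_BINS = 10
_TIE_TOL = 1e-12


@dataclass
class RankedList:
    """A filter method's full ordering of features, best first.

    ``scores`` align with ``features``. For chi-square/info-gain/ReliefF the
    scores are non-increasing; for MRMR the order is the greedy selection
    order and each score is the greedy objective at selection time.
    """

    features: list[str]
    scores: np.ndarray
    method: str
    discretization: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.features) != len(self.scores):
            raise ValueError("features and scores length mismatch")

    def top(self, m: int) -> list[str]:
        return self.features[:m]


def _as_frame(X) -> tuple[pd.DataFrame, pd.Series | None]:
    """Accept a FeatureTable (preferred) or a plain all-metric DataFrame."""
    if isinstance(X, FeatureTable):
        if X.mask.to_numpy().any():
            raise ValueError("rankers require an imputed table (no missing cells)")
        return X.values, X.meta["scale"]
    df = pd.DataFrame(X)
    if df.isna().to_numpy().any():
        raise ValueError("rankers require no missing cells")
    return df, None


def discretize_column(x: np.ndarray, scale: str = "metric", n_bins: int = N_BINS) -> np.ndarray:
    """0-based integer codes: native codes for ordinals, equal-frequency bins
    (fewer if ties collapse bins) for metric features."""
    if scale == "ordinal":
        _, codes = np.unique(x, return_inverse=True)
        return codes
    edges = np.unique(np.quantile(x, np.arange(1, n_bins) / n_bins))
    codes = np.searchsorted(edges, x, side="left")
    _, codes = np.unique(codes, return_inverse=True)
    return codes


def _discretize(X) -> tuple[list[str], np.ndarray, str]:
    df, scales = _as_frame(X)
    names = list(df.columns)
    codes = np.empty((len(df), len(names)), dtype=np.int64)
    for j, f in enumerate(names):
        scale = "metric" if scales is None else str(scales[f])
        codes[:, j] = discretize_column(df[f].to_numpy(dtype=float), scale)
    return names, codes, f"equal-frequency {N_BINS} bins (ordinals native)"


def _order(names: list[str], scores: np.ndarray) -> list[int]:
    """Descending score with lexicographic tie-break, logged."""
    idx = sorted(range(len(names)), key=lambda j: (-scores[j], names[j]))
    for a, b in zip(idx, idx[1:]):
        if abs(scores[a] - scores[b]) <= _TIE_TOL:
            logger.debug("score tie between %r and %r broken lexicographically", names[a], names[b])
            break
    return idx


def _contingency(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    k = codes.max() + 1
    return np.bincount(codes * 2 + y, minlength=2 * k).reshape(k, 2).astype(float)


def chi_square_statistic(codes: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-square of the feature-level x label table, no correction.

    A degenerate table (single feature level or single class) scores 0.
    """
    obs = _contingency(codes, y)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information_bits(a: np.ndarray, b: np.ndarray) -> float:
    """I(A;B) in bits over 0-based integer codes: H(A) + H(B) - H(A,B)."""
    ka, kb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    return _entropy_bits(joint.reshape(ka, kb).sum(1)) + _entropy_bits(
        joint.reshape(ka, kb).sum(0)
    ) - _entropy_bits(joint)


def info_gain_bits(codes: np.ndarray, y: np.ndarray) -> float:
    """H(y) - H(y | X) in bits."""
    return mutual_information_bits(codes, np.asarray(y, dtype=np.int64))


def rank_chi_square(X, y) -> RankedList:
    names, codes, desc = _discretize(X)
    y = np.asarray(y, dtype=np.int64)
    scores = np.array([chi_square_statistic(codes[:, j], y) for j in range(len(names))])
    idx = _order(names, scores)
    return RankedList([names[j] for j in idx], scores[idx], "chi_square", desc)


def rank_info_gain(X, y) -> RankedList:
    names, codes, desc = _discretize(X)
    y = np.asarray(y, dtype=np.int64)
    scores = np.array([info_gain_bits(codes[:, j], y) for j in range(len(names))])
    idx = _order(names, scores)
    return RankedList([names[j] for j in idx], scores[idx], "info_gain", desc)


def rank_mrmr(X, y, form: str = "difference") -> RankedList:
    """Greedy MRMR ordering.

    The first feature maximizes I(X_j; y); each next feature maximizes
    relevance minus mean redundancy, ``I(X_j;y) - mean_{s in S} I(X_j;X_s)``
    over the already-selected set S (the MID form; ``form='quotient'`` uses
    relevance / mean redundancy instead). The recorded score is the greedy
    objective at selection time.
    """
    if form not in ("difference", "quotient"):
        raise ValueError(f"unknown MRMR form {form!r}")
    names, codes, desc = _discretize(X)
    p = len(names)
    if p < 2:
        raise ValueError("MRMR needs at least 2 features")
    y = np.asarray(y, dtype=np.int64)
    relevance = np.array([mutual_information_bits(codes[:, j], y) for j in range(p)])

    remaining = list(range(p))
    red_sum = np.zeros(p)
    order: list[int] = []
    scores: list[float] = []
    while remaining:
        if not order:
            obj = {j: relevance[j] for j in remaining}
        else:
            k = len(order)
            if form == "difference":
                obj = {j: relevance[j] - red_sum[j] / k for j in remaining}
            else:
                obj = {j: relevance[j] / max(red_sum[j] / k, 1e-300) for j in remaining}
        best = min(remaining, key=lambda j: (-obj[j], names[j]))
        near = [j for j in remaining if j != best and abs(obj[j] - obj[best]) <= _TIE_TOL]
        if near:
            logger.debug("MRMR tie at step %d broken lexicographically (%r)", len(order), names[best])
        order.append(best)
        scores.append(obj[best])
        remaining.remove(best)
        for j in remaining:
            red_sum[j] += mutual_information_bits(codes[:, j], codes[:, best])
    return RankedList([names[j] for j in order], np.array(scores), "mrmr", desc)


def rank_relieff(X, y, k_neighbors: int = 10, n_probes: int | None = None, seed: int | None = None) -> RankedList:
    """ReliefF weights under Manhattan distance on range-normalized features.

    For each probe instance the k nearest hits (same class) and k nearest
    misses (other class) are found; each feature's weight accumulates the mean
    per-feature miss difference minus the mean hit difference, divided by the
    probe count. ``n_probes=None`` uses every instance (exhaustive,
    deterministic); otherwise probes are sampled without replacement using
    ``seed``. A class with fewer than k+1 members reduces k for that class
    with a warning.
    """
    import warnings

    df, _ = _as_frame(X)
    names = list(df.columns)
    Xv = df.to_numpy(dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n, p = Xv.shape

    rng_range = Xv.max(axis=0) - Xv.min(axis=0)
    rng_range[rng_range == 0] = 1.0  # constant feature: all diffs 0, weight 0
    Xn = (Xv - Xv.min(axis=0)) / rng_range

    if n_probes is None or n_probes >= n:
        probes = np.arange(n)
    else:
        probes = np.sort(np.random.default_rng(seed).choice(n, size=n_probes, replace=False))

    class_idx = {c: np.flatnonzero(y == c) for c in np.unique(y)}
    k_eff = {}
    for c, idx in class_idx.items():
        k_c = min(k_neighbors, len(idx) - 1)
        if k_c < k_neighbors:
            warnings.warn(f"class {c} has {len(idx)} members; using k={k_c}", stacklevel=2)
        k_eff[c] = max(k_c, 0)

    W = np.zeros(p)
    for i in probes:
        d = np.abs(Xn - Xn[i]).sum(axis=1)
        for c, idx in class_idx.items():
            cand = idx[idx != i] if c == y[i] else idx
            k_c = k_eff[c] if c == y[i] else min(k_neighbors, len(idx))
            if k_c == 0 or len(cand) == 0:
                continue
            # stable neighbor choice: distance then index
            nearest = cand[np.lexsort((cand, d[cand]))[:k_c]]
            mean_diff = np.abs(Xn[nearest] - Xn[i]).mean(axis=0)
            W += mean_diff if c != y[i] else -mean_diff
    W /= len(probes)

    idx = _order(names, W)
    return RankedList([names[j] for j in idx], W[idx], "relieff", "range-normalized, Manhattan")


RANKERS = {
    "chi_square": rank_chi_square,
    "info_gain": rank_info_gain,
    "mrmr": rank_mrmr,
    "relieff": rank_relieff,
}
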