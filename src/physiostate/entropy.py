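"""Sample entropy, multiscale entropy (MSE) and refined composite multiscale
entropy (RCMSE) of a one-dimensional time series.

Sample entropy (SampEn) measures the irregularity of a series as the negative
logarithm of the conditional probability that two sequences similar for ``m``
points remain similar at ``m + 1`` points, within a tolerance ``r`` and
excluding self-matches.  Multiscale variants apply SampEn to coarse-grained
versions of the series: at scale factor ``tau`` the series is averaged over
non-overlapping windows of length ``tau``, which can start at any of the
``tau`` possible offsets ``k``.

MSE uses only the ``k = 1`` coarse-grained series per scale.  RCMSE computes
template-match counts on *every* offset series ``k = 1..tau``, sums the counts
across offsets and takes a single logarithm of the pooled ratio.  Pooling
makes the estimate defined more often and less variable on short series,
which is the point of the "refined composite" construction.

Conventions (standard for SampEn):

* template distance is the Chebyshev (max-norm) distance;
* matching is inclusive (``distance <= r``), self-pairs excluded;
* both match counts use the compatible template range ``i = 1..N-m`` so that
  a constant series yields entropy exactly 0;
* the tolerance ``r`` is fixed once from the standard deviation of the
  *original* series and reused unchanged at every scale;
* an entropy value is undefined (reported as NaN, never infinity) when either
  pooled match count is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist

from .exceptions import ConfigError, InvalidOffsetError, ScaleTooLargeError, TooShortError

__all__ = [
    "EntropyParams",
    "ScaleEntry",
    "EntropyProfile",
    "coarse_grain",
    "match_counts",
    "sample_entropy",
    "mse_profile",
    "rcmse_profile",
]


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ConfigError("empty time series")
    if not np.all(np.isfinite(x)):
        raise ConfigError("time series contains non-finite values")
    return x


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the entropy estimators.

    Parameters
    ----------
    m : int
        Embedding (template) dimension, default 2.
    r_coef : float
        Tolerance coefficient; the absolute tolerance is
        ``r = r_coef * std(original series)`` computed once and reused at
        every scale.  Default 0.2.
    tau_list : tuple of int
        Strictly increasing scale factors, default ``(1, 2, 3, 5)``.
    log_base : float
        Base of the logarithm.  Default 2 so entropies are in bits; use
        ``math.e`` for nats.
    r : float, optional
        Absolute tolerance override.  When set, ``r_coef`` is ignored.
    """

    m: int = 2
    r_coef: float = 0.2
    tau_list: tuple[int, ...] = (1, 2, 3, 5)
    log_base: float = 2.0
    r: float | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ConfigError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r is None and self.r_coef <= 0:
            raise ConfigError(f"tolerance coefficient must be > 0, got {self.r_coef}")
        if self.r is not None and self.r <= 0:
            raise ConfigError(f"absolute tolerance must be > 0, got {self.r}")
        if self.log_base <= 1:
            raise ConfigError(f"log base must be > 1, got {self.log_base}")
        taus = tuple(int(t) for t in self.tau_list)
        if not taus or any(t < 1 for t in taus):
            raise ConfigError("tau_list must hold positive integers")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ConfigError("tau_list must be strictly increasing")
        object.__setattr__(self, "tau_list", taus)

    def tolerance(self, x) -> float:
        """Absolute tolerance for series ``x`` (frozen from its std)."""
        if self.r is not None:
            return float(self.r)
        sigma = float(np.std(_as_series(x)))
        if sigma == 0.0:
            # constant series: any positive tolerance matches everything
            return float(self.r_coef)
        return self.r_coef * sigma


@dataclass(frozen=True)
class ScaleEntry:
    """Entropy at one scale: value is NaN when no templates matched."""

    tau: int
    value: float
    n_m: int
    n_m1: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass
class EntropyProfile:
    """Per-scale entropy values with the parameters that produced them."""

    entries: list[ScaleEntry]
    m: int
    r: float
    log_base: float
    method: str = "rcmse"
    taus: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        self.taus = tuple(e.tau for e in self.entries)

    def value(self, tau: int) -> float:
        for e in self.entries:
            if e.tau == tau:
                return e.value
        raise KeyError(f"no entry for tau={tau}")

    def values(self) -> np.ndarray:
        return np.array([e.value for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": [e.tau for e in self.entries],
                "value": [e.value for e in self.entries],
                "n_m": [e.n_m for e in self.entries],
                "n_m1": [e.n_m1 for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def coarse_grain(x, tau: int, k: int = 1) -> np.ndarray:
    """Coarse-grain ``x`` at scale ``tau`` with offset ``k``.

    Element ``j`` (1-based) of the output is the mean of ``x`` over the
    window ``[(j-1)*tau + k, j*tau + k - 1]`` (1-based inclusive), so the
    output length is ``floor((N - k + 1) / tau)``.
    """
    x = _as_series(x)
    tau = int(tau)
    k = int(k)
    n = x.size
    if tau < 1 or tau > n:
        raise ScaleTooLargeError(f"scale tau={tau} invalid for series of length {n}")
    if not 1 <= k <= tau:
        raise InvalidOffsetError(f"offset k={k} outside 1..{tau}")
    if tau == 1:
        return x.copy()
    n_out = (n - k + 1) // tau
    if n_out == 0:
        return np.empty(0)
    start = k - 1
    return x[start : start + n_out * tau].reshape(n_out, tau).mean(axis=1)


def match_counts(y, m: int, r: float) -> tuple[int, int]:
    """Count matched template pairs of length ``m`` and ``m + 1``.

    Both counts run over the compatible template range ``i = 1..N-m``:
    unordered pairs ``(i, j)``, ``i < j``, whose Chebyshev distance is
    ``<= r``.  Self-pairs are excluded.
    """
    y = _as_series(y)
    m = int(m)
    if m < 1:
        raise ConfigError(f"embedding dimension m must be >= 1, got {m}")
    if y.size < m + 1:
        raise TooShortError(f"series of length {y.size} too short for m={m} (need >= {m + 1})")
    templates = sliding_window_view(y, m + 1)  # (N - m) rows
    if templates.shape[0] < 2:
        return 0, 0
    d_m = pdist(templates[:, :m], metric="chebyshev")
    d_m1 = np.maximum(d_m, pdist(templates[:, [m]], metric="chebyshev"))
    return int(np.count_nonzero(d_m <= r)), int(np.count_nonzero(d_m1 <= r))


def _neg_log_ratio(n_m1: int, n_m: int, log_base: float) -> float:
    if n_m == 0 or n_m1 == 0:
        return math.nan
    return -math.log(n_m1 / n_m) / math.log(log_base)


def sample_entropy(x, params: EntropyParams | None = None, *, r: float | None = None) -> float:
    """SampEn of ``x``; NaN when either match count is zero.

    ``r`` overrides the tolerance (used internally when the tolerance was
    frozen from a parent series before coarse-graining).
    """
    params = params or EntropyParams()
    x = _as_series(x)
    r_abs = params.tolerance(x) if r is None else float(r)
    n_m, n_m1 = match_counts(x, params.m, r_abs)
    return _neg_log_ratio(n_m1, n_m, params.log_base)


def _profile(x, params: EntropyParams, refined: bool) -> EntropyProfile:
    x = _as_series(x)
    r_abs = params.tolerance(x)
    entries = []
    for tau in params.tau_list:
        min_len = (params.m + 1) * tau
        if x.size < min_len:
            entries.append(ScaleEntry(tau, math.nan, 0, 0))
            continue
        offsets = range(1, tau + 1) if refined else (1,)
        tot_m = tot_m1 = 0
        for k in offsets:
            y = coarse_grain(x, tau, k)
            if y.size < params.m + 1:
                continue
            n_m, n_m1 = match_counts(y, params.m, r_abs)
            tot_m += n_m
            tot_m1 += n_m1
        entries.append(ScaleEntry(tau, _neg_log_ratio(tot_m1, tot_m, params.log_base), tot_m, tot_m1))
    return EntropyProfile(entries, params.m, r_abs, params.log_base, "rcmse" if refined else "mse")


def mse_profile(x, params: EntropyParams | None = None) -> EntropyProfile:
    """Multiscale entropy: SampEn of the single k=1 coarse series per scale."""
    return _profile(x, params or EntropyParams(), refined=False)


def rcmse_profile(x, params: EntropyParams | None = None) -> EntropyProfile:
    """Refined composite multiscale entropy.

    Per scale ``tau``, match counts are computed on every offset series
    ``k = 1..tau`` and pooled before the logarithm:
    ``-log(sum_k n_{k}^{m+1} / sum_k n_{k}^{m})``.
    """
    return _profile(x, params or EntropyParams(), refined=True)
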