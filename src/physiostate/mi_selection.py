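"""Discrete information-theoretic estimators and greedy mutual-information
feature ranking.

Features are discretized once per selection run into equal-frequency bins;
probabilities are maximum-likelihood plug-in estimates from the bin
occupancies (no smoothing), and all entropies are in bits.  The ranking
criteria share a greedy forward structure — step 1 always picks the feature
with the largest marginal relevance I(f;C), later steps maximise a
criterion-specific trade-off between relevance and redundancy with the
already-selected set S:

===========  ==============================================================
IG           I(f;C)                      (pure ranking, no redundancy)
MIFS         I(f;C) − β Σ_{s∈S} I(f;s)
MIFS-U       I(f;C) − β Σ_{s∈S} [I(s;C)/H(s)] I(f;s)
mRMR         I(f;C) − (1/|S|) Σ_{s∈S} I(f;s)
NMIFS        I(f;C) − (1/|S|) Σ_{s∈S} I(f;s)/min(H(f),H(s))
CR-MIFS      (1/|S|) Σ_{s∈S} I(f;C|s) − (1/|S|) Σ_{s∈S} I(f;s)
===========  ==============================================================

CR-MIFS replaces the static marginal relevance by the *conditional*
relevance I(f;C|s), averaged over the selected features: the worth of a
candidate is re-assessed given what is already known.  This is what lets it
pick up a feature that is useless alone but informative jointly (the XOR
case), which the static criteria structurally cannot.

Ties are broken by the lowest feature index throughout, so a selection run
is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigError
from .features import FeatureTable

__all__ = [
    "CRITERIA",
    "DiscretizedFeature",
    "SelectionTrace",
    "discretize",
    "entropy_d",
    "joint_entropy_d",
    "conditional_entropy_d",
    "mutual_information_d",
    "conditional_mi_d",
    "rank_features",
]

CRITERIA = ("IG", "MIFS", "MIFS-U", "mRMR", "NMIFS", "CR-MIFS")

_EPS = 1e-12  # floating-point cancellation guard for MI >= 0


@dataclass(frozen=True)
class DiscretizedFeature:
    """Integer bin codes for one feature; codes lie in [0, n_bins)."""

    codes: np.ndarray
    n_bins: int
    strategy: str = "equal-frequency"
    bin_edges: np.ndarray | None = None

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.size == 0:
            raise ConfigError("empty discretized feature")
        if codes.min() < 0 or codes.max() >= self.n_bins:
            raise ConfigError("codes outside [0, n_bins)")
        object.__setattr__(self, "codes", codes)

    @property
    def n(self) -> int:
        return self.codes.size


def discretize(values, n_bins: int, strategy: str = "equal-frequency") -> DiscretizedFeature:
    """Equal-frequency binning; tied values always share a bin, so a
    constant feature occupies a single bin."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ConfigError("cannot discretize an empty vector")
    if not np.all(np.isfinite(values)):
        raise ConfigError("values must be finite")
    if n_bins < 2:
        raise ConfigError(f"need at least 2 bins, got {n_bins}")
    if n_bins > values.size:
        raise ConfigError(f"{n_bins} bins for only {values.size} cases")
    if strategy != "equal-frequency":
        raise ConfigError(f"unknown discretization strategy {strategy!r}")
    # rank-based split: ties get the rank of their first occurrence, hence
    # identical values always map to the same code
    ranks = rankdata(values, method="min") - 1
    codes = (ranks.astype(np.int64) * n_bins) // values.size
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    return DiscretizedFeature(codes, n_bins, strategy, edges)


def _codes(f) -> np.ndarray:
    if isinstance(f, DiscretizedFeature):
        return f.codes
    arr = np.asarray(f)
    if arr.dtype.kind not in "iu":
        raise ConfigError("expected integer codes or a DiscretizedFeature")
    return arr.astype(np.int64).ravel()


def _check_lengths(*arrays):
    n = {a.size for a in arrays}
    if len(n) != 1:
        raise ConfigError(f"length mismatch: {sorted(n)}")


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_codes(*features) -> np.ndarray:
    """Fuse several code vectors into one (mixed-radix pairing)."""
    out = np.zeros(features[0].size, dtype=np.int64)
    for f in features:
        out = out * (int(f.max()) + 1) + f
    return out


def entropy_d(f) -> float:
    """Shannon entropy H(f) in bits from the occupancy counts."""
    c = _codes(f)
    return _entropy_from_counts(np.bincount(c))


def joint_entropy_d(f, g) -> float:
    """H(f, g) from the joint occupancy table."""
    cf, cg = _codes(f), _codes(g)
    _check_lengths(cf, cg)
    return _entropy_from_counts(np.bincount(_joint_codes(cf, cg)))


def conditional_entropy_d(f, g) -> float:
    """H(f | g) = H(f, g) − H(g) (chain rule)."""
    cf, cg = _codes(f), _codes(g)
    _check_lengths(cf, cg)
    return joint_entropy_d(cf, cg) - entropy_d(cg)


def mutual_information_d(f, g) -> float:
    """I(f; g) = H(f) + H(g) − H(f, g), clipped to 0 at −1e-12."""
    cf, cg = _codes(f), _codes(g)
    _check_lengths(cf, cg)
    mi = entropy_d(cf) + entropy_d(cg) - joint_entropy_d(cf, cg)
    return 0.0 if mi < _EPS else mi


def conditional_mi_d(f, c, g) -> float:
    """I(f; c | g) = H(f|g) + H(c|g) − H(f,c|g), clipped to 0."""
    cf, cc, cg = _codes(f), _codes(c), _codes(g)
    _check_lengths(cf, cc, cg)
    cmi = (
        joint_entropy_d(cf, cg)
        + joint_entropy_d(cc, cg)
        - entropy_d(cg)
        - _entropy_from_counts(np.bincount(_joint_codes(cf, cc, cg)))
    )
    return 0.0 if cmi < _EPS else cmi


# ---------------------------------------------------------------------------
# Greedy forward ranking


@dataclass
class StepScores:
    """Scores of every candidate at one greedy step."""

    step: int
    chosen: str
    candidates: list[str]
    relevance: dict[str, float]
    redundancy: dict[str, float]
    total: dict[str, float]


@dataclass
class SelectionTrace:
    """Ordered ranking with per-step criterion scores."""

    criterion: str
    order: list[str]
    steps: list[StepScores]
    beta: float
    n_bins: int
    params: dict = field(default_factory=dict)

    def ranking_string(self) -> str:
        return ", ".join(self.order)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for f in s.candidates:
                rows.append(
                    {
                        "step": s.step,
                        "feature": f,
                        "relevance": s.relevance[f],
                        "redundancy": s.redundancy[f],
                        "total": s.total[f],
                        "chosen": int(f == s.chosen),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# criterion={self.criterion} beta={self.beta} n_bins={self.n_bins}\n")
            fh.write(f"# ranking: {self.ranking_string()}\n")
            df.to_csv(fh, index=False, float_format="%.12g")


def _f_sort_key(name: str):
    """Lowest f-index first; non-f names fall back to lexicographic."""
    s = str(name)
    if s.startswith("f") and s[1:].isdigit():
        return (0, int(s[1:]))
    return (1, s)


def default_n_bins(n_cases: int) -> int:
    return min(math.ceil(math.sqrt(n_cases)), 10)


def rank_features(
    table: FeatureTable,
    criterion: str = "CR-MIFS",
    k: int | None = None,
    *,
    beta: float = 0.5,
    n_bins: int | None = None,
) -> SelectionTrace:
    """Greedy forward feature ranking of ``table`` under ``criterion``.

    ``k`` features are selected (default: all).  ``beta`` is the MIFS /
    MIFS-U redundancy weight; ``n_bins`` the equal-frequency bin count
    (default min(ceil(sqrt(n_cases)), 10)).  Bin edges are computed once
    and reused for every pairwise quantity in the run.
    """
    if criterion not in CRITERIA:
        raise ConfigError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    names = list(table.feature_names)
    if k is None:
        k = len(names)
    if not 1 <= k <= len(names):
        raise ConfigError(f"k={k} outside 1..{len(names)}")
    if n_bins is None:
        n_bins = default_n_bins(table.n_cases)

    disc = {
        name: discretize(table.features[name].to_numpy(), n_bins).codes
        for name in names
    }
    y = np.asarray(pd.factorize(table.labels, sort=True)[0], dtype=np.int64)

    h = {name: entropy_d(disc[name]) for name in names}
    rel0 = {name: mutual_information_d(disc[name], y) for name in names}
    pair_mi: dict[tuple[str, str], float] = {}

    def mi_pair(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = mutual_information_d(disc[a], disc[b])
        return pair_mi[key]

    selected: list[str] = []
    candidates = sorted(names, key=_f_sort_key)
    steps: list[StepScores] = []

    for step in range(1, k + 1):
        relevance, redundancy, total = {}, {}, {}
        for f in candidates:
            if not selected:
                relevance[f] = rel0[f]
                redundancy[f] = 0.0
            elif criterion == "IG":
                relevance[f] = rel0[f]
                redundancy[f] = 0.0
            elif criterion == "MIFS":
                relevance[f] = rel0[f]
                redundancy[f] = beta * sum(mi_pair(f, s) for s in selected)
            elif criterion == "MIFS-U":
                relevance[f] = rel0[f]
                redundancy[f] = beta * sum(
                    (rel0[s] / h[s]) * mi_pair(f, s) if h[s] > 0 else 0.0
                    for s in selected
                )
            elif criterion == "mRMR":
                relevance[f] = rel0[f]
                redundancy[f] = sum(mi_pair(f, s) for s in selected) / len(selected)
            elif criterion == "NMIFS":
                relevance[f] = rel0[f]
                redundancy[f] = (
                    sum(
                        mi_pair(f, s) / m if (m := min(h[f], h[s])) > 0 else 0.0
                        for s in selected
                    )
                    / len(selected)
                )
            else:  # CR-MIFS
                relevance[f] = sum(
                    conditional_mi_d(disc[f], y, disc[s]) for s in selected
                ) / len(selected)
                redundancy[f] = sum(mi_pair(f, s) for s in selected) / len(selected)
            total[f] = relevance[f] - redundancy[f]
        # deterministic tie-break: highest total, then lowest f-index
        best = max(total.values())
        chosen = min((f for f in candidates if total[f] == best), key=_f_sort_key)
        steps.append(StepScores(step, chosen, list(candidates), relevance, redundancy, total))
        selected.append(chosen)
        candidates.remove(chosen)

    return SelectionTrace(criterion, selected, steps, beta, n_bins, {"k": k})
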