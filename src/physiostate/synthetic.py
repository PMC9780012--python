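"""Seeded generators for the synthetic test bed.

Two families of objects stand in for an access-controlled polysomnography
cohort:

* **records** — two-class multichannel "physiological" signals whose classes
  differ in temporal *irregularity*, not in mean level.  In the default
  scenario the EEG-like channel of awake epochs (C1) is white Gaussian
  noise while that of sleeping epochs (C2) is strongly autocorrelated AR(1)
  noise (phi = 0.9); the oximetry- and pulse-like channels are
  class-neutral.  Because sample entropy of white noise exceeds that of
  smooth correlated noise, the class signal is carried by the entropy
  features — exercising the premise that complexity measures, not levels,
  separate the statuses.

* **feature tables** — decision tables with planted structure for
  selection tests: a class-informative feature (mean shift of effect size
  d), a jittered duplicate of it, an XOR pair that is jointly but not
  marginally informative, and pure-noise distractors.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .features import FeatureTable, MultichannelRecord

__all__ = [
    "ChannelSpec",
    "SignalGenConfig",
    "TableGenConfig",
    "gen_colored_series",
    "gen_record",
    "gen_feature_table",
    "make_xor_table",
]

_AR_BURN_IN = 100


@dataclass(frozen=True)
class ChannelSpec:
    """One channel: name, rate, and a per-class generating process.

    ``process_c1`` / ``process_c2`` are ``(kind, params)`` pairs with kind
    in {'white', 'ar1', 'sine'}:

    * ``white``: standard Gaussian noise, params ignored;
    * ``ar1``: x_t = phi x_{t-1} + eps_t, params = {'phi': float};
    * ``sine``: unit-amplitude sinusoid plus noise, params =
      {'freq_hz': float, 'snr': float} (snr = amplitude/noise-sd ratio).
    """

    name: str
    rate_hz: float
    process_c1: tuple[str, dict]
    process_c2: tuple[str, dict]

    def __post_init__(self):
        if self.rate_hz < 1:
            raise ConfigError(f"rate for {self.name!r} must be >= 1 Hz")
        for kind, params in (self.process_c1, self.process_c2):
            if kind not in ("white", "ar1", "sine"):
                raise ConfigError(f"unknown process kind {kind!r}")
            if kind == "ar1" and not -1 < params.get("phi", 0.0) < 1:
                raise ConfigError("AR(1) coefficient phi must lie in (-1, 1)")


def _default_channels() -> list[ChannelSpec]:
    # rates are desk-scale stand-ins for clinical PSG channels
    return [
        ChannelSpec("SaO2", 4.0, ("white", {}), ("white", {})),
        ChannelSpec("PR", 4.0, ("sine", {"freq_hz": 0.02, "snr": 1.0}),
                    ("sine", {"freq_hz": 0.02, "snr": 1.0})),
        ChannelSpec("EEG", 16.0, ("white", {}), ("ar1", {"phi": 0.9})),
    ]


@dataclass(frozen=True)
class SignalGenConfig:
    """Default scenario: 200 epochs per class, 30 s (0.5 min) epochs,
    class signal carried by the EEG channel's autocorrelation."""

    n_epochs_per_class: int = 200
    epoch_len_s: float = 30.0
    channels: list[ChannelSpec] = field(default_factory=_default_channels)
    seed: int = 0

    def __post_init__(self):
        if self.n_epochs_per_class < 1:
            raise ConfigError("need at least one epoch per class")
        if self.epoch_len_s <= 0:
            raise ConfigError("epoch length must be positive")
        if not self.channels:
            raise ConfigError("need at least one channel")


def gen_colored_series(n: int, process: str, params: dict | None = None,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """One seeded realization of length ``n``.

    ``white``: N(0,1) i.i.d.; ``ar1``: x_t = phi x_{t-1} + eps_t with a
    100-sample burn-in; ``sine``: sin(2 pi f t) + noise with sd 1/snr
    (``params`` needs 'freq_hz', 'snr' and optionally 'rate_hz').
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = params or {}
    if n < 1:
        raise ConfigError("series length must be >= 1")
    if process == "white":
        return rng.standard_normal(n)
    if process == "ar1":
        phi = float(params.get("phi", 0.9))
        if not -1 < phi < 1:
            raise ConfigError("phi must lie in (-1, 1)")
        eps = rng.standard_normal(n + _AR_BURN_IN)
        x = np.empty(n + _AR_BURN_IN)
        x[0] = eps[0]
        for t in range(1, n + _AR_BURN_IN):
            x[t] = phi * x[t - 1] + eps[t]
        return x[_AR_BURN_IN:]
    if process == "sine":
        rate = float(params.get("rate_hz", 1.0))
        freq = float(params.get("freq_hz", 0.02))
        snr = float(params.get("snr", 1.0))
        if snr <= 0:
            raise ConfigError("snr must be positive")
        t = np.arange(n) / rate
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * freq * t + phase) + rng.standard_normal(n) / snr
    raise ConfigError(f"unknown process kind {process!r}")


def gen_record(config: SignalGenConfig | None = None) -> MultichannelRecord:
    """Two-class multichannel record with label order shuffled by seed.

    Epochs are generated independently (no continuity across epoch
    boundaries); each epoch of each channel is one realization of the
    class-conditional process of that channel.
    """
    config = config or SignalGenConfig()
    rng = np.random.default_rng(config.seed)
    n_total = 2 * config.n_epochs_per_class
    labels = np.array(["C1"] * config.n_epochs_per_class + ["C2"] * config.n_epochs_per_class,
                      dtype=object)
    rng.shuffle(labels)
    samples: dict[str, np.ndarray] = {}
    for spec in config.channels:
        n_per_epoch = round(config.epoch_len_s * spec.rate_hz)
        chunks = []
        for lab in labels:
            kind, params = spec.process_c1 if lab == "C1" else spec.process_c2
            params = dict(params)
            params.setdefault("rate_hz", spec.rate_hz)
            chunks.append(gen_colored_series(n_per_epoch, kind, params, rng))
        samples[spec.name] = np.concatenate(chunks)
    return MultichannelRecord(
        channel_names=[s.name for s in config.channels],
        samples=samples,
        rates={s.name: s.rate_hz for s in config.channels},
        epoch_len_s=config.epoch_len_s,
        labels=labels,
    )


@dataclass(frozen=True)
class TableGenConfig:
    """Planted-structure decision table.

    Column layout (in order): one relevant feature (class means +/- d/2),
    one redundant jittered copy of it, an XOR pair (two +/-1 cluster
    features whose sign product encodes the class), then ``n_noise``
    standard-normal distractors.
    """

    n_cases: int = 400
    effect_size: float = 1.5
    jitter_sd: float = 0.1
    include_xor: bool = True
    n_noise: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 4 or self.n_cases % 2:
            raise ConfigError("n_cases must be even and >= 4")
        if self.effect_size < 0:
            raise ConfigError("effect size must be >= 0")
        if self.jitter_sd < 0:
            raise ConfigError("jitter sd must be >= 0")


def gen_feature_table(config: TableGenConfig | None = None) -> tuple[FeatureTable, dict]:
    """Feature table with known ground truth.

    Returns ``(table, roles)`` where ``roles`` maps column name to one of
    'relevant', 'redundant', 'xor_a', 'xor_b', 'noise'.
    """
    config = config or TableGenConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    half = n // 2
    labels = np.array(["C1"] * half + ["C2"] * half, dtype=object)
    rng.shuffle(labels)
    is_c1 = labels == "C1"

    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    shift = np.where(is_c1, config.effect_size / 2, -config.effect_size / 2)
    relevant = rng.standard_normal(n) + shift
    cols["relevant"] = relevant
    roles["relevant"] = "relevant"
    cols["redundant"] = relevant + config.jitter_sd * rng.standard_normal(n)
    roles["redundant"] = "redundant"
    if config.include_xor:
        # sign of xor_a * xor_b encodes the class: marginally uninformative
        sign_a = rng.choice([-1.0, 1.0], size=n)
        sign_b = np.where(is_c1, sign_a, -sign_a)
        cols["xor_a"] = sign_a + 0.2 * rng.standard_normal(n)
        cols["xor_b"] = sign_b + 0.2 * rng.standard_normal(n)
        roles["xor_a"] = "xor_a"
        roles["xor_b"] = "xor_b"
    for i in range(config.n_noise):
        name = f"noise{i + 1}"
        cols[name] = rng.standard_normal(n)
        roles[name] = "noise"

    index = pd.Index([f"X{i + 1}" for i in range(n)], name="case")
    renamed = {old: f"f{i + 1}" for i, old in enumerate(cols)}
    df = pd.DataFrame(cols, index=index).rename(columns=renamed)
    roles = {renamed[old]: role for old, role in roles.items()}
    table = FeatureTable(df, pd.Series(labels, index=index, name="label"))
    return table, roles


def make_xor_table() -> tuple[FeatureTable, dict]:
    """Small exact-count table contrasting conditional and static relevance.

    40 cases, binary features with exact cell counts:

    * f1: uniform 0/1 (20/20); f2: 1 with probability 0.3 within each f1
      group (6/20 each); the class is C1 iff f1 XOR f2 — so f1 carries
      moderate marginal information (f2's imbalance leaks through the XOR),
      f2 carries none at all but determines the class jointly with f1;
    * f3: agrees with the class in 26/40 cases (weakly informative alone);
    * f4: balanced within each class (exactly zero marginal information).

    After f1 is selected, a conditional-relevance criterion sees f2's full
    worth I(f2;C|f1) = H(C|f1) while any static criterion still scores it
    I(f2;C) = 0 and prefers f3.  Returns ``(table, roles)``.
    """
    rows = []
    # cells: (f1, f2, count); class = f1 XOR f2
    for f1v, f2v, count in [(0, 0, 14), (0, 1, 6), (1, 0, 14), (1, 1, 6)]:
        for _ in range(count):
            rows.append([f1v, f2v, f1v ^ f2v])
    arr = np.array(rows)
    c = arr[:, 2]
    # f3: 13 ones among the 20 class-1 cases, 7 among the 20 class-0 cases,
    # spread across f1 groups to keep I(f3;f1) small
    f3 = np.zeros(40, dtype=int)
    quota = {(0, 1): 4, (1, 1): 9, (0, 0): 5, (1, 0): 2}  # (f1, class) -> ones
    for key, q in quota.items():
        idx = np.flatnonzero((arr[:, 0] == key[0]) & (c == key[1]))[:q]
        f3[idx] = 1
    # f4: exactly half ones within each (f1, class) cell where possible
    f4 = np.zeros(40, dtype=int)
    for f1v in (0, 1):
        for cv in (0, 1):
            idx = np.flatnonzero((arr[:, 0] == f1v) & (c == cv))
            f4[idx[: len(idx) // 2]] = 1
    index = pd.Index([f"X{i + 1}" for i in range(40)], name="case")
    df = pd.DataFrame(
        {"f1": arr[:, 0], "f2": arr[:, 1], "f3": f3, "f4": f4},
        index=index,
        dtype=float,
    )
    labels = pd.Series(np.where(c == 1, "C1", "C2"), index=index, name="label")
    roles = {"f1": "xor_a", "f2": "xor_b", "f3": "marginal", "f4": "noise"}
    return FeatureTable(df, labels), roles
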