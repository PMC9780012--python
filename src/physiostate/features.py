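"""Signal ingestion, epoch slicing and construction of the reconstructed
(channel x scale) entropy feature space.

A recording holds several physiological channels (e.g. SaO2, pulse rate,
EEG) sampled at possibly different rates but spanning the same wall-clock
duration, plus one binary status label per fixed-length epoch (C1 = awake /
waiting to sleep, C2 = sleeping).  Each epoch of each channel is summarised
by its RCMSE value at every requested scale factor, giving a decision table
of ``n_epochs`` rows by ``n_channels * n_scales`` columns.  Features are
indexed column-major by channel: channel rank ``c`` at scale rank ``s`` maps
to ``f_{(c-1)*Ms + s}``, so with 3 channels and scales (1, 2, 3, 5) the
first channel owns f1..f4, the second f5..f8 and the third f9..f12.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import EntropyParams, rcmse_profile
from .exceptions import ConfigError, DataFormatError

__all__ = [
    "VALID_LABELS",
    "MultichannelRecord",
    "FeatureTable",
    "read_record",
    "write_record",
    "read_edf",
    "slice_epochs",
    "feature_index",
    "feature_channel_scale",
    "build_feature_table",
    "count_feature_subsets",
    "read_feature_table",
    "write_feature_table",
]

log = logging.getLogger(__name__)

VALID_LABELS = ("C1", "C2")


@dataclass
class MultichannelRecord:
    """Raw per-channel sample sequences with rates and per-epoch labels."""

    channel_names: list[str]
    samples: dict[str, np.ndarray]
    rates: dict[str, float]  # Hz
    epoch_len_s: float
    labels: np.ndarray  # one 'C1'/'C2' per whole epoch

    def __post_init__(self):
        if not self.channel_names:
            raise DataFormatError("record has no channels")
        for name in self.channel_names:
            if name not in self.samples or name not in self.rates:
                raise DataFormatError(f"missing samples or rate for channel {name!r}")
            self.samples[name] = np.asarray(self.samples[name], dtype=float).ravel()
            if self.rates[name] <= 0:
                raise ConfigError(f"non-positive sampling rate for channel {name!r}")
        if self.epoch_len_s <= 0:
            raise ConfigError("epoch length must be positive")
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise DataFormatError(f"labels outside {VALID_LABELS}: {sorted(map(str, bad))}")
        durations = {n: self.samples[n].size / self.rates[n] for n in self.channel_names}
        ref = durations[self.channel_names[0]]
        for n, d in durations.items():
            if not math.isclose(d, ref, rel_tol=0, abs_tol=0.5 / self.rates[n]):
                raise DataFormatError(
                    f"channel {n!r} spans {d:.3f}s but {self.channel_names[0]!r} spans {ref:.3f}s"
                )
        if self.labels.size != self.n_epochs:
            raise DataFormatError(
                f"{self.labels.size} labels for {self.n_epochs} whole epochs"
            )

    @property
    def n_epochs(self) -> int:
        name = self.channel_names[0]
        return int(self.samples[name].size // round(self.epoch_len_s * self.rates[name]))


def _epoch_samples(record: MultichannelRecord, name: str) -> int:
    raw = record.epoch_len_s * record.rates[name]
    n = round(raw)
    if not math.isclose(raw, n, rel_tol=0, abs_tol=1e-9) or n < 1:
        raise ConfigError(
            f"epoch length {record.epoch_len_s}s x rate {record.rates[name]}Hz "
            f"for channel {name!r} is not a whole number of samples"
        )
    return int(n)


def slice_epochs(record: MultichannelRecord) -> list[dict[str, np.ndarray]]:
    """Split each channel into whole epochs; epoch i holds samples
    ``[i*L, (i+1)*L)`` (0-based half-open); a trailing partial epoch is
    dropped.  Returns one ``{channel: samples}`` dict per epoch."""
    per_channel = {}
    n_epochs = None
    for name in record.channel_names:
        L = _epoch_samples(record, name)
        x = record.samples[name]
        k = x.size // L
        per_channel[name] = [x[i * L : (i + 1) * L] for i in range(k)]
        n_epochs = k if n_epochs is None else min(n_epochs, k)
    return [
        {name: per_channel[name][i] for name in record.channel_names}
        for i in range(n_epochs)
    ]


def feature_index(channel_rank: int, scale_rank: int, n_scales: int) -> int:
    """1-based reconstructed feature index: ``(c-1)*Ms + s``."""
    if channel_rank < 1:
        raise ConfigError(f"channel rank must be >= 1, got {channel_rank}")
    if not 1 <= scale_rank <= n_scales:
        raise ConfigError(f"scale rank {scale_rank} outside 1..{n_scales}")
    return (channel_rank - 1) * n_scales + scale_rank


def feature_channel_scale(f_index: int, n_scales: int) -> tuple[int, int]:
    """Inverse of :func:`feature_index`."""
    if f_index < 1:
        raise ConfigError(f"feature index must be >= 1, got {f_index}")
    c, s = divmod(f_index - 1, n_scales)
    return c + 1, s + 1


@dataclass
class FeatureTable:
    """Decision table: epochs (cases) x reconstructed features, plus labels.

    ``features`` is indexed by case id (X1, X2, ...) with columns f1..fK;
    ``labels`` is aligned on the same index.  ``tau_list`` and
    ``channel_names`` record the (channel, scale) meaning of each column.
    """

    features: pd.DataFrame
    labels: pd.Series
    channel_names: list[str] = field(default_factory=list)
    tau_list: tuple[int, ...] = ()

    def __post_init__(self):
        if self.features.shape[0] == 0:
            raise DataFormatError("feature table has no rows")
        if not self.features.index.equals(self.labels.index):
            raise DataFormatError("feature rows and labels are misaligned")
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise DataFormatError(f"labels outside {VALID_LABELS}: {sorted(map(str, bad))}")
        if self.channel_names and self.tau_list:
            expected = len(self.channel_names) * len(self.tau_list)
            if self.features.shape[1] != expected:
                raise DataFormatError(
                    f"{self.features.shape[1]} columns but "
                    f"{len(self.channel_names)} channels x {len(self.tau_list)} scales"
                )

    @property
    def n_cases(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def column_of(self, channel: str, tau: int) -> str:
        c = self.channel_names.index(channel) + 1
        s = self.tau_list.index(tau) + 1
        return f"f{feature_index(c, s, len(self.tau_list))}"

    def channel_of(self, feature_name: str) -> str:
        if not self.channel_names or not self.tau_list:
            raise ConfigError("table carries no channel/scale metadata")
        f = int(str(feature_name).lstrip("f"))
        c, _ = feature_channel_scale(f, len(self.tau_list))
        return self.channel_names[c - 1]

    def x_y(self) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and labels as arrays (labels stay 'C1'/'C2')."""
        return self.features.to_numpy(dtype=float), self.labels.to_numpy(dtype=object)


def build_feature_table(
    record: MultichannelRecord, params: EntropyParams | None = None
) -> FeatureTable:
    """RCMSE of every (epoch, channel, scale): the decision table.

    The tolerance is frozen per epoch-channel series.  Undefined entropy
    cells (no template matches) are imputed with the column median of the
    defined values; a column with no defined value at all is retained,
    filled with 0, and flagged in the log.
    """
    params = params or EntropyParams()
    epochs = slice_epochs(record)
    if not epochs:
        raise DataFormatError("record holds no whole epoch")
    ms = len(params.tau_list)
    columns = [
        f"f{feature_index(c + 1, s + 1, ms)}"
        for c in range(len(record.channel_names))
        for s in range(ms)
    ]
    rows = np.full((len(epochs), len(columns)), np.nan)
    for i, epoch in enumerate(epochs):
        for c, name in enumerate(record.channel_names):
            prof = rcmse_profile(epoch[name], params)
            rows[i, c * ms : (c + 1) * ms] = prof.values()
    index = pd.Index([f"X{i + 1}" for i in range(len(epochs))], name="case")
    df = pd.DataFrame(rows, index=index, columns=columns)
    for col in df.columns:
        n_nan = int(df[col].isna().sum())
        if n_nan == 0:
            continue
        if n_nan == len(df):
            log.warning("feature %s undefined for every epoch; filled with 0", col)
            df[col] = 0.0
        else:
            med = float(df[col].median())
            log.info("feature %s: %d undefined cells imputed with median %.6g", col, n_nan, med)
            df[col] = df[col].fillna(med)
    labels = pd.Series(record.labels[: len(epochs)], index=index, name="label")
    return FeatureTable(df, labels, list(record.channel_names), params.tau_list)


def count_feature_subsets(n_features: int) -> int:
    """Number of non-empty subsets of ``n_features`` features: 2^n - 1."""
    n = int(n_features)
    if n < 1:
        raise ConfigError(f"need at least one feature, got {n}")
    return 2**n - 1


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_record(record: MultichannelRecord, path, schema_path=None) -> None:
    """Write a record as delimited text: one column per channel (columns of
    different rates have different lengths; shorter ones are left blank at
    the tail) plus a ``label`` column holding one label per epoch.  The
    schema (rates, epoch length) goes to ``schema_path`` (default:
    ``path`` + '.schema') as ``key=value`` lines."""
    sep = _sep_for(path)
    cols = {n: pd.Series(record.samples[n]) for n in record.channel_names}
    cols["label"] = pd.Series(record.labels)
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.12g")
    schema_path = schema_path or f"{path}.schema"
    with open(schema_path, "w") as fh:
        fh.write(f"epoch_len_s={record.epoch_len_s:.12g}\n")
        for n in record.channel_names:
            fh.write(f"rate.{n}={record.rates[n]:.12g}\n")


def _read_schema(schema_path) -> dict:
    schema: dict = {"rates": {}}
    with open(schema_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise DataFormatError(f"malformed schema line: {line!r}")
            key, val = line.split("=", 1)
            if key == "epoch_len_s":
                schema["epoch_len_s"] = float(val)
            elif key.startswith("rate."):
                schema["rates"][key[5:]] = float(val)
            else:
                raise DataFormatError(f"unknown schema key: {key!r}")
    if "epoch_len_s" not in schema or not schema["rates"]:
        raise DataFormatError("schema must give epoch_len_s and at least one rate.<channel>")
    return schema


def read_record(path, schema=None) -> MultichannelRecord:
    """Read a record written by :func:`write_record`.

    ``schema`` is either a dict ``{'epoch_len_s': float, 'rates': {ch: Hz}}``
    or a path to a ``key=value`` schema file; default ``path`` + '.schema'.
    Channels shorter than the longest column are blank-padded at the tail;
    blanks anywhere else are rejected.
    """
    if schema is None:
        schema = f"{path}.schema"
    if not isinstance(schema, dict):
        schema = _read_schema(schema)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "label" not in df.columns:
        raise DataFormatError("record file lacks a 'label' column")
    names = [c for c in df.columns if c != "label"]
    missing = set(schema["rates"]) - set(names)
    if missing:
        raise DataFormatError(f"channels in schema but not in file: {sorted(missing)}")
    samples = {}
    for n in names:
        if n not in schema["rates"]:
            raise DataFormatError(f"channel {n!r} has no rate in the schema")
        col = df[n].to_numpy(dtype=float)
        valid = ~np.isnan(col)
        k = int(valid.sum())
        if not valid[:k].all():
            row = int(np.flatnonzero(~valid)[0]) + 2  # +2: header + 1-based
            raise DataFormatError(f"channel {n!r}: blank cell inside the data at line {row}")
        samples[n] = col[:k]
    raw_labels = df["label"].dropna().astype(str).to_numpy()
    return MultichannelRecord(
        channel_names=names,
        samples=samples,
        rates=dict(schema["rates"]),
        epoch_len_s=float(schema["epoch_len_s"]),
        labels=raw_labels,
    )


def read_edf(path):
    """EDF ingestion is not built in; convert to delimited text first."""
    raise NotImplementedError(
        "EDF reading is unsupported here; export the channels to delimited "
        "text (see read_record) or install an EDF reader such as pyedflib "
        "and convert externally."
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write ``case,f1..fN,label`` delimited text, 12 significant digits."""
    df = table.features.copy()
    df["label"] = table.labels
    df.to_csv(path, sep=_sep_for(path), float_format="%.12g")


def read_feature_table(path) -> FeatureTable:
    """Read a ``case,f1..fN,label`` table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[0] == 0:
        raise DataFormatError("empty feature table")
    if "case" not in df.columns or "label" not in df.columns:
        raise DataFormatError("feature table needs 'case' and 'label' columns")
    if df["case"].duplicated().any():
        dup = df.loc[df["case"].duplicated(), "case"].iloc[0]
        raise DataFormatError(f"duplicate case id: {dup!r}")
    if df["label"].isna().any():
        row = int(df.index[df["label"].isna()][0]) + 2
        raise DataFormatError(f"missing label at line {row}")
    df = df.set_index("case")
    labels = df.pop("label").astype(str)
    feats = df.astype(float)
    if feats.isna().any().any():
        raise DataFormatError("feature table contains blank feature cells")
    return FeatureTable(feats, labels.rename("label"))
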