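"""Windowed time-domain feature extraction for multichannel sEMG.

Eleven features are computed per channel per analysis window: seven scalar
descriptors (waveform length, integrated absolute value, root mean square,
simple square integral, kurtosis, skewness, thresholded zero crossings) and
the four coefficients of an order-4 autoregressive model.  Stacking all
channels gives the channel-feature variable matrix that the selection
stages (MTSR, mRMR) screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical feature order; every row index in a feature matrix follows it.
FEATURE_NAMES: tuple[str, ...] = (
    "WL", "IAV", "RMS", "SSI", "Kurtosis", "Skewness", "ZC",
    "AR1", "AR2", "AR3", "AR4",
)

N_FEATURES = len(FEATURE_NAMES)


class DegenerateWindowError(ValueError):
    """Raised when a window has zero variance so SD-normalised moments
    (kurtosis, skewness) are undefined."""


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window configuration.

    Parameters
    ----------
    length : int
        Window length L in samples.  Must allow an AR fit: L >= ar_order + 2.
    step : int
        Stride between consecutive window starts, in samples.  ``step <
        length`` gives overlapping windows (the default is 50% overlap).
    zc_threshold : float
        Amplitude-gap threshold T of the zero-crossing count, in signal
        units.  A crossing is counted only when the two samples straddle
        zero AND differ by more than T.
    ar_order : int
        Order p of the autoregressive model (p coefficients are emitted).
    """

    length: int = 200
    step: int = 100
    zc_threshold: float = 10.0
    ar_order: int = 4

    def __post_init__(self) -> None:
        if self.length < self.ar_order + 2:
            raise ValueError(
                f"window length {self.length} too short for AR order "
                f"{self.ar_order} (need >= {self.ar_order + 2})")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.zc_threshold < 0:
            raise ValueError("zc_threshold must be >= 0")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")


@dataclass
class Recording:
    """A multichannel recording with per-sample gesture labels.

    ``samples`` is time x channels.  ``segments`` optionally marks trial
    boundaries (per-sample integer id); analysis windows never straddle a
    segment boundary, which prevents windows from mixing two trials.
    """

    samples: np.ndarray
    sampling_rate: float
    labels: np.ndarray
    channel_ids: tuple = ()
    segments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a 2-D time x channels array "
                             "with at least one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.n_samples:
            raise ValueError("labels must be per-sample "
                             f"({len(self.labels)} != {self.n_samples})")
        if not self.channel_ids:
            self.channel_ids = tuple(range(1, self.samples.shape[1] + 1))
        elif len(self.channel_ids) != self.samples.shape[1]:
            raise ValueError("channel_ids length must match channel count")
        if self.segments is not None:
            self.segments = np.asarray(self.segments)
            if len(self.segments) != self.n_samples:
                raise ValueError("segments must be per-sample")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class FeatureMatrix:
    """The d x n channel-feature variable matrix.

    Rows are (channel, feature) pairs in channel-major order; columns are
    analysis windows.  ``standardization`` records per-row mean/scale when
    the matrix has been z-scored.
    """

    values: np.ndarray
    row_index: tuple[tuple[object, str], ...]
    col_labels: np.ndarray
    standardization: dict | None = None
    window_spec: WindowSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.row_index):
            raise ValueError("row_index length must match value rows")
        if len(set(self.row_index)) != len(self.row_index):
            raise ValueError("duplicate (channel, feature) rows")
        self.col_labels = np.asarray(self.col_labels)
        if self.values.shape[1] != len(self.col_labels):
            raise ValueError("col_labels length must match value columns")

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> tuple:
        seen: dict = {}
        for ch, _ in self.row_index:
            seen.setdefault(ch, None)
        return tuple(seen)

    def row_position(self, channel, feature: str) -> int:
        return self.row_index.index((channel, feature))

    def subset(self, channels=None, features=None) -> "FeatureMatrix":
        """Restrict to rows whose channel and feature are both retained."""
        channels = None if channels is None else set(channels)
        features = None if features is None else set(features)
        keep = [i for i, (ch, ft) in enumerate(self.row_index)
                if (channels is None or ch in channels)
                and (features is None or ft in features)]
        if not keep:
            raise ValueError("subset selects no rows")
        return FeatureMatrix(
            values=self.values[keep],
            row_index=tuple(self.row_index[i] for i in keep),
            col_labels=self.col_labels,
            standardization=self.standardization,
            window_spec=self.window_spec,
        )

    def standardize(self, train_mask: np.ndarray | None = None) -> "FeatureMatrix":
        """Return a per-row z-scored copy.

        Statistics come from ``train_mask`` columns when given, otherwise
        from all windows.  Zero-variance rows keep scale 1 (logged).
        """
        cols = self.values if train_mask is None else self.values[:, train_mask]
        mean = cols.mean(axis=1)
        sd = cols.std(axis=1, ddof=1) if cols.shape[1] > 1 else np.ones(self.d)
        flat = sd == 0
        if flat.any():
            logger.warning("standardize: %d zero-variance rows left unscaled",
                           int(flat.sum()))
            sd = np.where(flat, 1.0, sd)
        vals = (self.values - mean[:, None]) / sd[:, None]
        return FeatureMatrix(
            values=vals,
            row_index=self.row_index,
            col_labels=self.col_labels,
            standardization={"mean": mean.tolist(), "scale": sd.tolist()},
            window_spec=self.window_spec,
        )

    def to_dataframe(self):
        import pandas as pd

        idx = [f"{ch}:{ft}" for ch, ft in self.row_index]
        return pd.DataFrame(self.values, index=idx)


# ---------------------------------------------------------------------------
# feature computation


def _ar_design(window: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    L = len(window)
    Z = np.column_stack([window[p - k:L - k] for k in range(1, p + 1)])
    y = window[p:]
    return Z, y


def ar_coefficients(window: np.ndarray, order: int) -> np.ndarray:
    """Least-squares fit of x_i = sum_p a_p x_{i-p} + eps_i (covariance
    method).  Returns a_1..a_p."""
    Z, y = _ar_design(np.asarray(window, dtype=float), order)
    G = Z.T @ Z
    b = Z.T @ y
    try:
        return np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(Z, y, rcond=None)[0]


def zero_crossings(window: np.ndarray, threshold: float) -> int:
    """Count adjacent pairs with x_i * x_{i+1} < 0 and |x_i - x_{i+1}| > T."""
    x0, x1 = window[:-1], window[1:]
    return int(np.count_nonzero((x0 * x1 < 0)
                                & (np.abs(x0 - x1) > threshold)))


def extract_window_features(window: Sequence[float],
                            spec: WindowSpec) -> np.ndarray:
    """Compute the 11 features of one analysis window, in FEATURE_NAMES order.

    Raises
    ------
    DegenerateWindowError
        If the window has zero variance (kurtosis/skewness undefined).
    """
    x = np.asarray(window, dtype=float)
    if len(x) != spec.length:
        raise ValueError(f"window length {len(x)} != spec.length {spec.length}")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    L = len(x)
    wl = float(np.sum(np.abs(np.diff(x))))
    iav = float(np.sum(np.abs(x)))
    ssi = float(np.sum(x * x))
    rms = float(np.sqrt(ssi / L))
    mean = x.mean()
    dev = x - mean
    sd = float(np.sqrt(np.sum(dev * dev) / (L - 1)))
    if sd == 0.0:
        raise DegenerateWindowError("zero-variance window: kurtosis and "
                                    "skewness are undefined")
    kurt = float(np.sum(dev ** 4) / (L - 1) / sd ** 4 - 3.0)
    skew = float(np.sum(dev ** 3) / (L - 1) / sd ** 3)
    zc = zero_crossings(x, spec.zc_threshold)
    ar = ar_coefficients(x, spec.ar_order)
    return np.concatenate(([wl, iav, rms, ssi, kurt, skew, zc], ar))


# ---------------------------------------------------------------------------
# windowing


def _majority_label(labels: np.ndarray):
    """Majority vote; ties go to the first-occurring class in the window."""
    uniq, first_pos, counts = np.unique(labels, return_index=True,
                                        return_counts=True)
    best = counts.max()
    tied = counts == best
    return uniq[tied][np.argmin(first_pos[tied])]


def window_starts(n_samples: int, spec: WindowSpec,
                  segments: np.ndarray | None = None) -> np.ndarray:
    """Start indices of all analysis windows; windows never cross a
    segment boundary."""
    if segments is None:
        if n_samples < spec.length:
            return np.empty(0, dtype=int)
        return np.arange(0, n_samples - spec.length + 1, spec.step)
    starts: list[int] = []
    boundaries = np.flatnonzero(np.diff(segments)) + 1
    seg_edges = np.concatenate(([0], boundaries, [n_samples]))
    for lo, hi in zip(seg_edges[:-1], seg_edges[1:]):
        if hi - lo >= spec.length:
            starts.extend(range(lo, hi - spec.length + 1, spec.step))
    return np.asarray(starts, dtype=int)


def windowize(rec: Recording, spec: WindowSpec,
              drop_transition: bool = False):
    """Slice the recording into labelled windows.

    Returns a list of ``(windows, label)`` where ``windows`` is a
    channels x length array.  The label is the majority per-sample label
    inside the window; with ``drop_transition`` windows containing more
    than one label are discarded.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    starts = window_starts(rec.n_samples, spec, rec.segments)
    if len(starts) == 0:
        raise ValueError("recording shorter than one window")
    out = []
    for s in starts:
        lab_slice = rec.labels[s:s + spec.length]
        if drop_transition and len(np.unique(lab_slice)) > 1:
            continue
        out.append((rec.samples[s:s + spec.length].T,
                    _majority_label(lab_slice)))
    if not out:
        raise ValueError("all windows dropped as transition windows")
    return out


# ---------------------------------------------------------------------------
# vectorised matrix construction


def _batch_features(wins: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Features for a (n_win, L) stack of windows; rows with zero variance
    get NaN kurtosis/skewness (policy applied by the caller)."""
    L = wins.shape[1]
    wl = np.abs(np.diff(wins, axis=1)).sum(axis=1)
    iav = np.abs(wins).sum(axis=1)
    ssi = (wins * wins).sum(axis=1)
    rms = np.sqrt(ssi / L)
    dev = wins - wins.mean(axis=1, keepdims=True)
    var = (dev * dev).sum(axis=1) / (L - 1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = (dev ** 4).sum(axis=1) / (L - 1) / sd ** 4 - 3.0
        skew = (dev ** 3).sum(axis=1) / (L - 1) / sd ** 3
    x0, x1 = wins[:, :-1], wins[:, 1:]
    zc = ((x0 * x1 < 0) & (np.abs(x0 - x1) > spec.zc_threshold)).sum(axis=1)

    p = spec.ar_order
    Z = np.stack([wins[:, p - k:L - k] for k in range(1, p + 1)], axis=2)
    y = wins[:, p:]
    G = np.einsum("wip,wiq->wpq", Z, Z)
    b = np.einsum("wip,wi->wp", Z, y)
    try:
        ar = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        ar = np.stack([np.linalg.lstsq(Z[i], y[i], rcond=None)[0]
                       for i in range(len(wins))])
    return np.column_stack([wl, iav, rms, ssi, kurt, skew, zc, ar])


def build_feature_matrix(rec: Recording, spec: WindowSpec,
                         standardize: bool = False,
                         degenerate: str = "drop",
                         drop_transition: bool = False) -> FeatureMatrix:
    """Build the d x n channel-feature matrix (d = C * 11).

    ``degenerate`` controls windows where any channel has zero variance:
    "drop" removes the window (logged), "error" raises, "nan" keeps NaN
    sentinels.
    """
    if degenerate not in ("drop", "error", "nan"):
        raise ValueError("degenerate must be drop|error|nan")
    pairs = windowize(rec, spec, drop_transition=drop_transition)
    labels = np.asarray([lab for _, lab in pairs])
    stack = np.asarray([w for w, _ in pairs])        # (n_win, C, L)
    n_win, n_ch, _ = stack.shape
    feats = np.empty((n_win, n_ch, N_FEATURES))
    for c in range(n_ch):
        feats[:, c, :] = _batch_features(stack[:, c, :], spec)
    bad = np.isnan(feats).any(axis=(1, 2))
    if bad.any():
        if degenerate == "error":
            raise DegenerateWindowError(
                f"{int(bad.sum())} windows have a zero-variance channel")
        if degenerate == "drop":
            logger.warning("dropping %d degenerate windows", int(bad.sum()))
            feats, labels = feats[~bad], labels[~bad]
            if len(feats) == 0:
                raise DegenerateWindowError("all windows degenerate")
    # channel-major rows: (ch1, WL) ... (ch1, AR4), (ch2, WL) ...
    values = feats.transpose(1, 2, 0).reshape(n_ch * N_FEATURES, -1)
    row_index = tuple((ch, ft) for ch in rec.channel_ids
                      for ft in FEATURE_NAMES)
    fm = FeatureMatrix(values=values, row_index=row_index,
                       col_labels=labels, window_spec=spec)
    return fm.standardize() if standardize else fm
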