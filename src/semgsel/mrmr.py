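"""Minimum-redundancy maximum-relevance (mRMR) variable ranking.

Relevance of a variable is its mutual information (MI) with the gesture
class; redundancy is its mean MI with the already-selected variables.  MI
is estimated with the plug-in (empirical-frequency) estimator on
discretized features, in bits.  The greedy incremental search adds, at each
step, the variable maximizing

    I(x_j; c) - (1/|S|) * sum_{x_i in S} I(x_j; x_i)        (MID)

or the quotient form I(x_j; c) / mean-redundancy (MIQ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .varset import VariableSet

logger = logging.getLogger(__name__)


@dataclass
class DiscretizedMatrix:
    """Integer-state version of a feature matrix (small alphabet per row)."""

    states: np.ndarray
    scheme: dict
    row_index: tuple | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D")

    @property
    def alphabet_sizes(self) -> np.ndarray:
        return np.asarray([len(np.unique(r)) for r in self.states])


def discretize(values, scheme: str = "sd", n_bins: int = 3,
               sd_factor: float = 0.5, row_index=None) -> DiscretizedMatrix:
    """Discretize each row of a (d, n) matrix (or FeatureMatrix).

    scheme "sd" (default): 3-state coding by thresholds mean +/- sd_factor*SD
    (sample SD, ddof=1): -1 below, 0 inside, +1 above.  Zero-variance rows
    map entirely to state 0.
    scheme "quantile": equal-frequency binning into ``n_bins`` states.
    """
    if hasattr(values, "values") and hasattr(values, "row_index"):
        row_index = values.row_index
        values = values.values
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    d, n = X.shape
    states = np.zeros((d, n), dtype=np.int64)
    if scheme == "sd":
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1) if n > 1 else np.zeros(d)
        flat = sd == 0
        if flat.any():
            logger.warning("discretize: %d zero-variance rows -> state 0",
                           int(flat.sum()))
        lo = mean - sd_factor * sd
        hi = mean + sd_factor * sd
        states = (X > hi[:, None]).astype(np.int64) \
            - (X < lo[:, None]).astype(np.int64)
        states[flat] = 0
        desc = {"method": "sd", "sd_factor": sd_factor}
    elif scheme == "quantile":
        for i in range(d):
            qs = np.quantile(X[i], np.linspace(0, 1, n_bins + 1)[1:-1])
            states[i] = np.searchsorted(np.unique(qs), X[i], side="right")
        desc = {"method": "quantile", "n_bins": n_bins}
    else:
        raise ValueError("scheme must be 'sd' or 'quantile'")
    return DiscretizedMatrix(states=states, scheme=desc, row_index=row_index)


def _codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    _, inv = np.unique(v, return_inverse=True)
    return inv, int(inv.max()) + 1


def mutual_information(a, b) -> float:
    """Plug-in mutual information of two discrete vectors, in bits.

    I = sum p(x,y) log2[ p(x,y) / (p(x) p(y)) ] over observed cells;
    empty cells (0 log 0) contribute nothing.  Symmetric, non-negative up
    to rounding.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(a) == 0:
        raise ValueError("empty vectors")
    ca, na = _codes(a)
    cb, nb = _codes(b)
    joint = np.bincount(ca * nb + cb, minlength=na * nb).reshape(na, nb)
    n = len(a)
    pj = joint / n
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    nz = pj > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(pj[nz] * np.log2(pj[nz] / outer[nz])))


@dataclass
class MrmrState:
    """Trace of a greedy mRMR run: selection order, scores, MI caches."""

    selected: list
    scores: list
    relevance: np.ndarray
    criterion: str


def mrmr_rank(disc: DiscretizedMatrix, labels, m: int,
              criterion: str = "mid",
              row_index=None) -> tuple[VariableSet, MrmrState]:
    """Rank the top-``m`` variables by the incremental mRMR search.

    The first pick maximizes relevance I(x_j; c); later picks maximize the
    MID difference (or MIQ quotient) against the mean redundancy with the
    current selection.  Exact score ties break to the lower variable index.
    """
    states = disc.states
    d, n = states.shape
    if not 1 <= m <= d:
        raise ValueError(f"m must be in [1, {d}]")
    criterion = criterion.lower()
    if criterion not in ("mid", "miq"):
        raise ValueError("criterion must be 'mid' or 'miq'")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    rel = np.asarray([mutual_information(states[j], labels)
                      for j in range(d)])
    selected = [int(np.argmax(rel))]          # argmax -> lowest tied index
    scores = [float(rel[selected[0]])]
    red_sum = np.zeros(d)
    pair_mi_rows: dict[int, np.ndarray] = {}
    while len(selected) < m:
        last = selected[-1]
        if last not in pair_mi_rows:
            pair_mi_rows[last] = np.asarray(
                [mutual_information(states[last], states[j])
                 for j in range(d)])
        red_sum += pair_mi_rows[last]
        mean_red = red_sum / len(selected)
        if criterion == "mid":
            crit = rel - mean_red
        else:
            crit = rel / np.maximum(mean_red, 1e-12)
        crit = crit.copy()
        crit[selected] = -np.inf
        nxt = int(np.argmax(crit))
        selected.append(nxt)
        scores.append(float(crit[nxt]))
    idx = row_index if row_index is not None else disc.row_index
    pairs = tuple(idx[i] for i in selected) if idx is not None \
        else tuple((i, "") for i in selected)
    vs = VariableSet(pairs=pairs, method="mrmr", scores=tuple(scores))
    state = MrmrState(selected=selected, scores=scores, relevance=rel,
                      criterion=criterion)
    return vs, state
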