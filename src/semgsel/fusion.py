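"""Channel co-occurrence counting, channel ranking and decision-level fusion.

Given the variable sets screened by MTSR and mRMR, each channel pair is
scored by the number of features the two channels share within a set (the
co-occurrence matrix).  Row sums rank the channels per method; the two
rankings are then fused into a final channel subset.  A separate majority
rule picks the features used by more than half of the channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FEATURE_NAMES
from .varset import VariableSet


@dataclass
class CooccurrenceMatrix:
    """Symmetric C x C shared-feature counts (diagonal stored as 0)."""

    counts: np.ndarray
    channels: tuple
    method: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.channels)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be C x C")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        names = [str(c) for c in self.channels]
        df = pd.DataFrame(self.counts, index=names, columns=names)
        df.loc["Sum"] = self.row_sums
        return df


@dataclass
class ChannelRanking:
    """Channels ordered by descending row sum, with competition ranks
    (tied channels share the best rank of their block, e.g. 1, 2, 2, 4)."""

    channels: tuple
    row_sums: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.row_sums = np.asarray(self.row_sums, dtype=int)
        if len(self.row_sums) != len(self.channels):
            raise ValueError("row_sums length mismatch")

    @property
    def order(self) -> tuple:
        key = sorted(range(len(self.channels)),
                     key=lambda i: (-self.row_sums[i], i))
        return tuple(self.channels[i] for i in key)

    @property
    def ranks(self) -> dict:
        out = {}
        for i, ch in enumerate(self.channels):
            out[ch] = 1 + int(np.sum(self.row_sums > self.row_sums[i]))
        return out

    def tie_groups(self) -> tuple:
        """Channels grouped by equal row sum, best group first."""
        groups: dict[int, list] = {}
        for ch, s in zip(self.channels, self.row_sums):
            groups.setdefault(int(s), []).append(ch)
        return tuple(tuple(groups[s]) for s in sorted(groups, reverse=True))

    def row_sum_of(self, ch) -> int:
        return int(self.row_sums[self.channels.index(ch)])


@dataclass
class FusionResult:
    selected_channels: tuple
    strategy: str
    k: int
    audit: dict


def cooccurrence(sel: VariableSet, channels) -> CooccurrenceMatrix:
    """counts[i][j] = number of features shared by channels i and j within
    the selected set (i != j)."""
    channels = tuple(channels)
    feats = {ch: sel.features_of(ch) for ch in channels}
    unknown = set(sel.channels) - set(channels)
    if unknown:
        raise ValueError(f"selection references unknown channels {unknown}")
    C = len(channels)
    counts = np.zeros((C, C), dtype=int)
    for i in range(C):
        for j in range(i + 1, C):
            c = len(feats[channels[i]] & feats[channels[j]])
            counts[i, j] = counts[j, i] = c
    return CooccurrenceMatrix(counts=counts, channels=channels,
                              method=sel.method)


def rank_channels(coocc: CooccurrenceMatrix) -> ChannelRanking:
    return ChannelRanking(channels=coocc.channels,
                          row_sums=coocc.row_sums, method=coocc.method)


def _pick(candidates, k, rank_sum, total_row_sum, channel_pos):
    """Order candidates by (rank-sum asc, total row-sum asc, index) and
    take k."""
    ordered = sorted(candidates,
                     key=lambda ch: (rank_sum[ch], total_row_sum[ch],
                                     channel_pos[ch]))
    return tuple(sorted(ordered[:k], key=lambda ch: channel_pos[ch]))


def fuse_rankings(rank_a: ChannelRanking, rank_b: ChannelRanking, k: int,
                  strategy: str = "mutual_top") -> FusionResult:
    """Fuse two channel rankings into a final k-channel subset.

    mutual_top (default): grow both top lists in lockstep until their
    intersection holds at least k channels, then keep the k intersection
    members with the smallest rank-sum (ties: smaller combined row sum,
    then lower channel position).  rank_sum: take the k smallest rank-sums
    directly (Borda-style), same tie-breaks.
    """
    if tuple(rank_a.channels) != tuple(rank_b.channels):
        raise ValueError("rankings must share one channel universe")
    channels = rank_a.channels
    C = len(channels)
    if not 1 <= k <= C:
        raise ValueError(f"k must be in [1, {C}]")
    ra, rb = rank_a.ranks, rank_b.ranks
    rank_sum = {ch: ra[ch] + rb[ch] for ch in channels}
    total = {ch: rank_a.row_sum_of(ch) + rank_b.row_sum_of(ch)
             for ch in channels}
    pos = {ch: i for i, ch in enumerate(channels)}
    audit = {"rank_sum": dict(rank_sum), "strategy": strategy}
    if strategy == "mutual_top":
        for t in range(1, C + 1):
            inter = [ch for ch in channels if ra[ch] <= t and rb[ch] <= t]
            if len(inter) >= k:
                audit["t"] = t
                sel = _pick(inter, k, rank_sum, total, pos)
                return FusionResult(selected_channels=sel,
                                    strategy=strategy, k=k, audit=audit)
        raise RuntimeError("unreachable: full lists always intersect")
    if strategy == "rank_sum":
        sel = _pick(list(channels), k, rank_sum, total, pos)
        return FusionResult(selected_channels=sel, strategy=strategy,
                            k=k, audit=audit)
    raise ValueError("strategy must be 'mutual_top' or 'rank_sum'")


def select_features_by_majority(sel_a: VariableSet, sel_b: VariableSet,
                                n_channels: int) -> dict:
    """Features used by strictly more than half of the channels, per
    method, plus their union (in canonical feature order)."""
    def majority(sel: VariableSet) -> tuple:
        users: dict[str, set] = {}
        for ch, ft in sel.pairs:
            users.setdefault(ft, set()).add(ch)
        return tuple(ft for ft in FEATURE_NAMES
                     if len(users.get(ft, ())) > n_channels / 2)

    fa, fb = majority(sel_a), majority(sel_b)
    union = tuple(ft for ft in FEATURE_NAMES if ft in set(fa) | set(fb))
    return {sel_a.method: fa, sel_b.method: fb, "union": union}
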