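"""Selected channel-feature variable sets with method provenance."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class VariableSet:
    """An (ordered) collection of selected (channel, feature) pairs.

    Order is meaningful for ranking methods (mRMR); ``scores`` optionally
    carries the per-pair score (coefficient row norm or mRMR criterion
    value) aligned with ``pairs``.
    """

    pairs: tuple
    method: str
    scores: tuple = field(default=())

    def __post_init__(self) -> None:
        pairs = tuple((ch, ft) for ch, ft in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (channel, feature) pairs")
        if self.scores and len(self.scores) != len(pairs):
            raise ValueError("scores must align with pairs")

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def channels(self) -> tuple:
        seen: dict = {}
        for ch, _ in self.pairs:
            seen.setdefault(ch, None)
        return tuple(seen)

    def features_of(self, channel) -> frozenset:
        return frozenset(ft for ch, ft in self.pairs if ch == channel)

    def as_set(self) -> frozenset:
        return frozenset(self.pairs)
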