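"""Published reference tables for the 8-channel / 7-gesture study.

Encodes, verbatim, the two 36-variable selections (MTSR and mRMR columns
of the published variable table), the expected channel co-occurrence
matrices with their Sum rows, the published channel orderings, the fused
channel subsets at k = 2, 3, 4 and the majority-rule feature lists.  These
are inputs for reproduction tests and for fixture-mode pipeline runs; the
original recordings behind them are not redistributed here.

One printed cell of the mRMR co-occurrence table (channels 4-8: printed 2)
contradicts both its mirror cell (3) and the printed Sum row; the encoding
uses the symmetric, Sum-consistent value 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import CooccurrenceMatrix
from .varset import VariableSet

CHANNELS = tuple(range(1, 9))

_TABLE2_MTSR = {
    1: ("RMS", "AR1", "AR2", "AR4"),
    2: ("WL", "Skewness", "AR1", "AR2", "AR3"),
    3: ("WL", "IAV", "AR1", "AR2", "AR3"),
    4: ("WL", "IAV", "AR1", "AR4"),
    5: ("RMS", "Kurtosis", "AR1", "AR2", "AR3", "AR4"),
    6: ("WL", "Skewness"),
    7: ("IAV", "Skewness", "AR1", "AR2"),
    8: ("WL", "SSI", "Kurtosis", "Skewness", "AR1", "AR2"),
}

_TABLE2_MRMR = {
    1: ("WL", "IAV", "Kurtosis", "SSI", "AR3"),
    2: ("WL", "IAV", "Kurtosis", "Skewness"),
    3: ("WL", "IAV", "Kurtosis", "SSI"),
    4: ("WL", "IAV", "Kurtosis"),
    5: ("WL", "IAV", "Kurtosis", "SSI", "AR3"),
    6: ("WL", "IAV", "SSI", "AR3"),
    7: ("WL", "IAV", "Kurtosis", "AR3"),
    8: ("WL", "IAV", "SSI", "Kurtosis", "Skewness", "AR1", "AR2"),
}

_TABLE3_COUNTS = np.array([
    [0, 2, 2, 2, 4, 0, 2, 2],
    [2, 0, 4, 2, 3, 2, 3, 4],
    [2, 4, 0, 3, 3, 1, 3, 3],
    [2, 2, 3, 0, 2, 1, 2, 2],
    [4, 3, 3, 2, 0, 0, 2, 3],
    [0, 2, 1, 1, 0, 0, 1, 2],
    [2, 3, 3, 2, 2, 1, 0, 3],
    [2, 4, 3, 2, 3, 2, 3, 0],
])

_TABLE4_COUNTS = np.array([
    [0, 3, 4, 3, 5, 4, 4, 4],
    [3, 0, 3, 3, 3, 2, 3, 4],
    [4, 3, 0, 3, 4, 3, 3, 4],
    [3, 3, 3, 0, 3, 2, 3, 3],   # (4,8): 3 per symmetry and the Sum row
    [5, 3, 4, 3, 0, 4, 4, 4],
    [4, 2, 3, 2, 4, 0, 3, 3],
    [4, 3, 3, 3, 4, 3, 0, 3],
    [4, 4, 4, 3, 4, 3, 3, 0],
])

TABLE3_SUMS = (14, 20, 19, 14, 17, 7, 16, 19)
TABLE4_SUMS = (27, 21, 24, 20, 27, 21, 23, 25)

#: Published channel orderings as tie groups, best first.
MTSR_ORDER_GROUPS = ((2,), (3, 8), (5,), (7,), (1, 4), (6,))
MRMR_ORDER_GROUPS = ((1, 5), (8,), (3,), (7,), (2, 6), (4,))

#: Published fused channel subsets by target size k.
FUSED_CHANNELS = {2: (5, 8), 3: (3, 5, 8), 4: (3, 5, 7, 8)}

#: Published majority-rule feature lists (> half of the 8 channels).
MTSR_MAJORITY_FEATURES = ("WL", "AR1", "AR2")
MRMR_MAJORITY_FEATURES = ("WL", "IAV", "SSI", "Kurtosis")
UNION_FEATURES = ("WL", "IAV", "SSI", "Kurtosis", "AR1", "AR2")

#: Channels listed per feature in the published feature-usage table.
TABLE5_CHANNELS = {
    "WL": {"mtsr": (2, 3, 4, 6, 8), "mrmr": (1, 2, 3, 4, 5, 6, 7, 8)},
    "IAV": {"mtsr": (3, 4, 7), "mrmr": (1, 2, 3, 4, 5, 6, 7, 8)},
    "RMS": {"mtsr": (1, 5), "mrmr": ()},
    "SSI": {"mtsr": (8,), "mrmr": (1, 3, 5, 6, 8)},
    "Kurtosis": {"mtsr": (5, 8), "mrmr": (1, 2, 3, 4, 5, 7, 8)},
    "Skewness": {"mtsr": (2, 6, 7, 8), "mrmr": (2, 8)},
    "ZC": {"mtsr": (), "mrmr": ()},
    "AR1": {"mtsr": (1, 2, 3, 4, 5, 7, 8), "mrmr": (8,)},
    "AR2": {"mtsr": (1, 2, 3, 5, 7, 8), "mrmr": (8,)},
    "AR3": {"mtsr": (2, 3, 5), "mrmr": (1, 5, 6, 7)},
    "AR4": {"mtsr": (1, 4, 5), "mrmr": ()},
}


def _as_varset(table: dict, method: str) -> VariableSet:
    pairs = tuple((ch, ft) for ch in CHANNELS for ft in table[ch])
    return VariableSet(pairs=pairs, method=method)


@dataclass(frozen=True)
class FixtureTables:
    table2_mtsr: VariableSet
    table2_mrmr: VariableSet
    expected_table3: CooccurrenceMatrix
    expected_table4: CooccurrenceMatrix
    expected_orders: dict
    expected_feature_lists: dict
    fused_channels: dict


def load_fixtures() -> FixtureTables:
    """The published reference tables as package objects."""
    return FixtureTables(
        table2_mtsr=_as_varset(_TABLE2_MTSR, "mtsr"),
        table2_mrmr=_as_varset(_TABLE2_MRMR, "mrmr"),
        expected_table3=CooccurrenceMatrix(
            counts=_TABLE3_COUNTS.copy(), channels=CHANNELS, method="mtsr"),
        expected_table4=CooccurrenceMatrix(
            counts=_TABLE4_COUNTS.copy(), channels=CHANNELS, method="mrmr"),
        expected_orders={"mtsr": MTSR_ORDER_GROUPS,
                         "mrmr": MRMR_ORDER_GROUPS},
        expected_feature_lists={"mtsr": MTSR_MAJORITY_FEATURES,
                                "mrmr": MRMR_MAJORITY_FEATURES,
                                "union": UNION_FEATURES},
        fused_channels=dict(FUSED_CHANNELS),
    )
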