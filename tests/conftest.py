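import itertools

import numpy as np
import pytest

from tricall.calls import DOWN, LEVELS, NC, UP, CallTable, Contrast

# Nine-cell reference counts for a two-treatment response-mode table
# (rows: inhibitor up/nc/down; cols: hormone up/nc/down).  Used as fixture
# inputs throughout; cells sum to 20,566.
NINE_CELL_COUNTS = np.array(
    [[89, 301, 3],
     [365, 19197, 175],
     [15, 280, 141]], dtype=np.int64)

# 27-cell reference counts for a three-treatment table, rows in product
# order over (inhibitor1, inhibitor2) with levels (up, nc, down); cells
# sum to 20,560.
TWENTY_SEVEN_CELL_COUNTS = np.array(
    [[60, 147, 1],      # up, up
     [28, 131, 2],      # up, nc
     [2, 4, 0],         # up, down
     [119, 1238, 4],    # nc, up
     [227, 16558, 89],  # nc, nc
     [14, 1401, 82],    # nc, down
     [0, 2, 0],         # down, up
     [8, 171, 30],      # down, nc
     [5, 126, 111]],    # down, down
    dtype=np.int64)


def make_call_table(patterns, contrast_names, genes=None):
    """CallTable from explicit per-gene call tuples."""
    patterns = list(patterns)
    if genes is None:
        genes = [f"g{i}" for i in range(len(patterns))]
    return CallTable(
        genes=list(genes),
        contrasts=[Contrast.canonical(c) for c in contrast_names],
        calls=np.array(patterns, dtype=np.int8),
    )


@pytest.fixture
def nine_cell_counts():
    return NINE_CELL_COUNTS.copy()


@pytest.fixture
def twenty_seven_cell_counts():
    return TWENTY_SEVEN_CELL_COUNTS.copy()


@pytest.fixture
def cluster_contrasts():
    return ["SA", "EDE", "U73", "W30B", "W30SA"]


@pytest.fixture
def all_81_patterns():
    """Every call pattern over (SA, inhibitor, W30B, W30SA)."""
    return list(itertools.product(LEVELS, repeat=4))
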