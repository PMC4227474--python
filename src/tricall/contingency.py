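"""Response-mode contingency analysis.

Cross-tabulates trinary calls over one or more *row factors* and one
*column factor* (3^k x 3 response modes), computes independence-expected
counts ``E = row_total * col_total / grand_total``, per-cell
observed/expected enrichment ratios, and a plain chi-squared statistic
(no continuity correction; cells with E = 0 are skipped and reported).

The grand total is always the sum of the observed cells, never a
user-supplied figure.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tricall.calls import DOWN, LEVELS, LEVEL_NAMES, NC, UP, CallTable


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for reported ratios)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def display_ratio(value: float) -> str:
    """Reported-ratio formatting: 1 decimal, integer when >= 10."""
    if not np.isfinite(value):
        return "undef"
    if value >= 10:
        return str(int(round_half_up(value, 0)))
    return f"{round_half_up(value, 1):.1f}"


@dataclasses.dataclass
class ContingencyResult:
    """Observed/expected/ratio grids over a response-mode cross-classification.

    ``row_levels[r]`` is the tuple of trinary codes (one per row factor) of
    row ``r``; rows enumerate the Cartesian product of (UP, NC, DOWN) over
    the row factors in that order, columns likewise for the column factor.
    ``ratio`` is NaN wherever the expected count is zero (undefined flag).
    """

    row_factors: tuple[str, ...]
    col_factor: str
    row_levels: tuple[tuple[int, ...], ...]
    col_levels: tuple[int, ...]
    observed: np.ndarray
    expected: np.ndarray = dataclasses.field(init=False)
    ratio: np.ndarray = dataclasses.field(init=False)
    row_totals: np.ndarray = dataclasses.field(init=False)
    col_totals: np.ndarray = dataclasses.field(init=False)
    grand_total: int = dataclasses.field(init=False)
    chi2: float = dataclasses.field(init=False)
    dof: int = dataclasses.field(init=False)
    p_value: float = dataclasses.field(init=False)
    skipped_cells: list[tuple[int, int]] = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=np.int64)
        if obs.ndim != 2 or obs.shape != (len(self.row_levels), len(self.col_levels)):
            raise ValueError(
                f"observed shape {obs.shape} does not match "
                f"{len(self.row_levels)} rows x {len(self.col_levels)} cols"
            )
        if (obs < 0).any():
            raise ValueError("observed counts must be non-negative")
        self.observed = obs
        self.row_totals = obs.sum(axis=1)
        self.col_totals = obs.sum(axis=0)
        self.grand_total = int(obs.sum())
        if self.grand_total == 0:
            raise ValueError("empty universe: all observed counts are zero")
        self.expected = np.outer(self.row_totals, self.col_totals) / self.grand_total
        with np.errstate(divide="ignore", invalid="ignore"):
            self.ratio = np.where(self.expected > 0, obs / self.expected, np.nan)
        nonzero = self.expected > 0
        self.skipped_cells = [tuple(ij) for ij in np.argwhere(~nonzero)]
        self.chi2 = float(
            ((obs[nonzero] - self.expected[nonzero]) ** 2 / self.expected[nonzero]).sum()
        )
        self.dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
        self.p_value = float(stats.chi2.sf(self.chi2, self.dof)) if self.dof else 1.0

    @classmethod
    def from_observed(
        cls,
        observed: np.ndarray | Sequence[Sequence[int]],
        row_factors: Sequence[str],
        col_factor: str,
    ) -> "ContingencyResult":
        """Build directly from an observed-count grid (rows in product order)."""
        row_factors = tuple(row_factors)
        row_levels = tuple(itertools.product(LEVELS, repeat=len(row_factors)))
        return cls(
            row_factors=row_factors,
            col_factor=col_factor,
            row_levels=row_levels,
            col_levels=tuple(LEVELS),
            observed=np.asarray(observed),
        )

    # -- lookups -----------------------------------------------------------

    def cell(self, row_level: tuple[int, ...] | int, col_level: int) -> dict:
        """Observed / expected / ratio for one response-mode cell."""
        if isinstance(row_level, int):
            row_level = (row_level,)
        r = self.row_levels.index(tuple(row_level))
        c = self.col_levels.index(col_level)
        return {
            "observed": int(self.observed[r, c]),
            "expected": float(self.expected[r, c]),
            "ratio": float(self.ratio[r, c]),
        }

    def collapse(self, factor: str) -> "ContingencyResult":
        """Marginalize out one row factor by summing observed counts."""
        if factor not in self.row_factors:
            raise ValueError(f"{factor!r} is not a row factor of this table")
        keep = [i for i, f in enumerate(self.row_factors) if f != factor]
        if not keep:
            raise ValueError("cannot collapse the only row factor")
        new_levels = tuple(itertools.product(LEVELS, repeat=len(keep)))
        index = {lv: i for i, lv in enumerate(new_levels)}
        obs = np.zeros((len(new_levels), len(self.col_levels)), dtype=np.int64)
        for r, lv in enumerate(self.row_levels):
            reduced = tuple(lv[i] for i in keep)
            obs[index[reduced]] += self.observed[r]
        return ContingencyResult(
            row_factors=tuple(self.row_factors[i] for i in keep),
            col_factor=self.col_factor,
            row_levels=new_levels,
            col_levels=self.col_levels,
            observed=obs,
        )

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: factor levels, observed, expected, ratio."""
        rows = []
        for r, row_level in enumerate(self.row_levels):
            for c, col_level in enumerate(self.col_levels):
                rec = {
                    f: LEVEL_NAMES[lv] for f, lv in zip(self.row_factors, row_level)
                }
                rec[self.col_factor] = LEVEL_NAMES[col_level]
                rec["observed"] = int(self.observed[r, c])
                rec["expected"] = float(self.expected[r, c])
                rec["ratio"] = float(self.ratio[r, c])
                rec["ratio_display"] = display_ratio(float(self.ratio[r, c]))
                rows.append(rec)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "row_factors": list(self.row_factors),
            "col_factor": self.col_factor,
            "grand_total": self.grand_total,
            "row_totals": [int(t) for t in self.row_totals],
            "col_totals": [int(t) for t in self.col_totals],
            "chi2": self.chi2,
            "dof": self.dof,
            "p_value": self.p_value,
            "skipped_cells": [list(map(int, ij)) for ij in self.skipped_cells],
        }


def cross_tabulate(
    table: CallTable, row_factors: Sequence[str], col_factor: str
) -> ContingencyResult:
    """Count genes per joint response mode and derive expected counts/ratios.

    The universe is the set of genes with calls for all named contrasts
    (every gene of the table, given the no-missing-value model).  Row
    factors must be disjoint from the column factor.
    """
    row_factors = tuple(row_factors)
    if not row_factors:
        raise ValueError("need at least one row factor")
    if col_factor in row_factors:
        raise ValueError(f"column factor {col_factor!r} repeats a row factor")
    if len(set(row_factors)) != len(row_factors):
        raise ValueError(f"duplicate row factors in {row_factors}")
    if table.n_genes == 0:
        raise ValueError("empty universe: call table has no genes")

    level_pos = {lv: i for i, lv in enumerate(LEVELS)}
    row_cols = [table.column(f) for f in row_factors]
    col = table.column(col_factor)

    n_rows = 3 ** len(row_factors)
    obs = np.zeros((n_rows, 3), dtype=np.int64)
    # row index: mixed-radix over the per-factor level positions, first
    # factor most significant — matches itertools.product order.
    r_idx = np.zeros(table.n_genes, dtype=np.int64)
    for rc in row_cols:
        r_idx = r_idx * 3 + np.vectorize(level_pos.get)(rc)
    c_idx = np.vectorize(level_pos.get)(col)
    np.add.at(obs, (r_idx, c_idx), 1)

    row_levels = tuple(itertools.product(LEVELS, repeat=len(row_factors)))
    return ContingencyResult(
        row_factors=row_factors,
        col_factor=col_factor,
        row_levels=row_levels,
        col_levels=tuple(LEVELS),
        observed=obs,
    )


def enrichment_ratio(
    observed: int, row_total: int, col_total: int, grand_total: int
) -> float:
    """Observed/expected ratio: ``observed * N / (row_total * col_total)``.

    Returns NaN (undefined flag) when ``row_total * col_total == 0``.
    """
    for name, v in (
        ("observed", observed),
        ("row_total", row_total),
        ("col_total", col_total),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if grand_total <= 0:
        raise ValueError(f"grand_total must be positive, got {grand_total}")
    if row_total > grand_total or col_total > grand_total:
        raise ValueError("marginal totals cannot exceed the grand total")
    denom = row_total * col_total
    if denom == 0:
        return float("nan")
    return observed * grand_total / denom


def modifier_overrepresentation(
    gene_set: Iterable[str], table: CallTable, modifier: str, level: int
) -> float:
    """Fold over-representation of a modifier response level within a gene set.

    ``fold = (members with call == level) / (|set| * marginal / |universe|)``
    where the marginal is the universe count of genes with that call on the
    modifier contrast.  Returns NaN when the universe marginal is zero.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    universe = set(table.genes)
    missing = gene_set - universe
    if missing:
        raise ValueError(f"gene set not within table universe: {sorted(missing)[:5]}")
    col = table.column(modifier)
    marginal = int((col == level).sum())
    if marginal == 0:
        return float("nan")
    index = table.gene_index()
    in_level = sum(1 for g in gene_set if col[index[g]] == level)
    expected = len(gene_set) * marginal / table.n_genes
    return in_level / expected
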