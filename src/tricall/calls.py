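"""Trinary response-call tables: the substrate of every downstream analysis.

A *call* is one of three codes describing how a gene responded in a named
treatment-versus-reference contrast: ``UP`` (+1), ``NC`` (0, no change) or
``DOWN`` (-1).  A :class:`CallTable` holds one call per (gene, contrast)
cell — there is no missing-value code; a gene either has a complete row of
calls or is not in the table at all, which keeps contingency marginals
exact downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Trinary call codes.
UP: int = 1
NC: int = 0
DOWN: int = -1

#: Display / tabulation order of the three levels (up first, mirroring the
#: usual layout of published response-mode tables).
LEVELS: tuple[int, int, int] = (UP, NC, DOWN)

LEVEL_NAMES: dict[int, str] = {UP: "up", NC: "nc", DOWN: "down"}

# Accepted input vocabulary (matched case-insensitively).  Canonical output
# tokens are "up" / "nc" / "down".
_TOKEN_TO_CODE: dict[str, int] = {
    "up": UP,
    "+1": UP,
    "1": UP,
    "nc": NC,
    "0": NC,
    "down": DOWN,
    "-1": DOWN,
}

#: Canonical contrast names used throughout the pipeline.
CANONICAL_CONTRASTS: dict[str, str] = {
    "SA": "SA vs control",
    "EDE": "edelfosine vs control",
    "U73": "U73122 vs control",
    "W30B": "W30 vs W1, basal",
    "W30SA": "SA+W30 vs SA+W1",
    "NBUT": "n-ButOH vs tert-ButOH, basal",
    "NBUTSA": "SA+n-ButOH vs SA+tert-ButOH",
    "R59": "R59022 vs control",
}


class CallTableError(ValueError):
    """Raised on malformed call-table input (bad token, duplicate gene...)."""


def parse_call(token: str) -> int:
    """Map one input token to a trinary code.  Case-insensitive."""
    code = _TOKEN_TO_CODE.get(str(token).strip().lower())
    if code is None:
        raise CallTableError(f"unknown call token {token!r}")
    return code


def format_call(code: int) -> str:
    """Canonical token for a trinary code."""
    try:
        return LEVEL_NAMES[int(code)]
    except KeyError:
        raise CallTableError(f"invalid trinary code {code!r}") from None


@dataclasses.dataclass(frozen=True)
class Contrast:
    """A named treatment-versus-reference comparison."""

    name: str
    treatment: str = ""
    reference: str = ""

    @classmethod
    def canonical(cls, name: str) -> "Contrast":
        return cls(name=name, treatment=CANONICAL_CONTRASTS.get(name, ""))


@dataclasses.dataclass
class CallTable:
    """Genes x contrasts grid of trinary calls.

    Attributes
    ----------
    genes : list of str
        Ordered unique gene identifiers.
    contrasts : list of Contrast
        Ordered contrasts; names unique.
    calls : ndarray of int8, shape (n_genes, n_contrasts)
        Values in {+1, 0, -1}.
    provenance : str
        Free-text metadata (origin, filters applied, drop counts).
    """

    genes: list[str]
    contrasts: list[Contrast]
    calls: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_g, n_c = len(self.genes), len(self.contrasts)
        if self.calls.shape != (n_g, n_c):
            raise CallTableError(
                f"calls grid shape {self.calls.shape} does not match "
                f"{n_g} genes x {n_c} contrasts"
            )
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise CallTableError(f"duplicate gene identifier {g!r}")
            seen.add(g)
        names = [c.name for c in self.contrasts]
        if len(set(names)) != len(names):
            raise CallTableError(f"duplicate contrast names in {names}")
        bad = ~np.isin(self.calls, list(LEVELS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CallTableError(
                f"invalid call code {self.calls[i, j]} at gene "
                f"{self.genes[i]!r}, contrast {names[j]!r}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def contrast_names(self) -> list[str]:
        return [c.name for c in self.contrasts]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def column(self, contrast: str) -> np.ndarray:
        """Calls of every gene for one contrast, in gene order."""
        try:
            j = self.contrast_names.index(contrast)
        except ValueError:
            raise CallTableError(
                f"unknown contrast {contrast!r}; available: {self.contrast_names}"
            ) from None
        return self.calls[:, j]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        """Integer-coded DataFrame, genes as index, contrasts as columns."""
        return pd.DataFrame(
            self.calls, index=pd.Index(self.genes, name="gene"),
            columns=self.contrast_names,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallTable):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.contrast_names == other.contrast_names
            and np.array_equal(self.calls, other.calls)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "CallTable":
        """Build from an integer-coded DataFrame (index genes, columns contrasts)."""
        contrasts = [Contrast.canonical(str(c)) for c in frame.columns]
        return cls(
            genes=[str(g) for g in frame.index],
            contrasts=contrasts,
            calls=frame.to_numpy(dtype=np.int8),
            provenance=provenance,
        )


# -- IO --------------------------------------------------------------------


def read_call_table(path) -> CallTable:
    """Read a TSV call table (header names contrasts, first column gene IDs).

    Accepted cell tokens: up/+1/1, nc/0, down/-1 (case-insensitive).
    Raises :class:`CallTableError` naming the offending gene/cell on
    duplicate gene IDs or unknown tokens.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise CallTableError(f"{path}: need a gene column plus >=1 contrast column")
    gene_col = raw.columns[0]
    genes = raw[gene_col].tolist()
    dupes = raw[gene_col][raw[gene_col].duplicated()]
    if len(dupes):
        raise CallTableError(f"{path}: duplicate gene identifier {dupes.iloc[0]!r}")
    contrast_names = [str(c) for c in raw.columns[1:]]
    calls = np.empty((len(genes), len(contrast_names)), dtype=np.int8)
    for j, cname in enumerate(contrast_names):
        for i, token in enumerate(raw[cname]):
            try:
                calls[i, j] = parse_call(token)
            except CallTableError:
                raise CallTableError(
                    f"{path}: unknown call token {token!r} at row {i + 2} "
                    f"(gene {genes[i]!r}), column {cname!r}"
                ) from None
    contrasts = [Contrast.canonical(c) for c in contrast_names]
    return CallTable(genes=genes, contrasts=contrasts, calls=calls,
                     provenance=f"read from {path}")


def write_call_table(table: CallTable, path) -> None:
    """Write a call table as TSV with canonical up/nc/down tokens."""
    frame = table.to_frame()
    out = frame.map(lambda c: LEVEL_NAMES[int(c)])
    out.to_csv(path, sep="\t")


# -- deriving calls from continuous changes --------------------------------


def derive_calls(
    changes: pd.DataFrame,
    significant: pd.DataFrame,
    up_threshold: float,
    down_threshold: float,
) -> CallTable:
    """Turn signed expression changes + significance flags into trinary calls.

    Rule (per cell): UP iff significant and change >= ``up_threshold``;
    DOWN iff significant and change <= ``down_threshold``; else NC.

    Genes with any non-finite, non-significant change value are dropped
    (logged, and counted in the table provenance); a non-finite change that
    is flagged significant is an error.
    """
    if not (down_threshold < 0 < up_threshold):
        raise ValueError(
            f"thresholds must satisfy down < 0 < up, got "
            f"({down_threshold}, {up_threshold})"
        )
    if list(changes.columns) != list(significant.columns) or not changes.index.equals(
        significant.index
    ):
        raise ValueError("changes and significant grids must be aligned")

    vals = changes.to_numpy(dtype=float)
    sig = significant.to_numpy(dtype=bool)
    finite = np.isfinite(vals)
    if (sig & ~finite).any():
        i, j = np.argwhere(sig & ~finite)[0]
        raise ValueError(
            f"non-finite change flagged significant at gene "
            f"{changes.index[i]!r}, contrast {changes.columns[j]!r}"
        )
    keep = finite.all(axis=1)
    dropped = [str(g) for g in changes.index[~keep]]
    if dropped:
        logger.info("derive_calls: dropped %d gene(s) with missing changes: %s",
                    len(dropped), ", ".join(dropped[:10]))
    vals, sig = vals[keep], sig[keep]
    calls = np.zeros(vals.shape, dtype=np.int8)
    calls[sig & (vals >= up_threshold)] = UP
    calls[sig & (vals <= down_threshold)] = DOWN

    contrasts = [Contrast.canonical(str(c)) for c in changes.columns]
    prov = (f"derived with thresholds ({down_threshold}, {up_threshold}); "
            f"dropped={len(dropped)}")
    return CallTable(
        genes=[str(g) for g in changes.index[keep]],
        contrasts=contrasts,
        calls=calls,
        provenance=prov,
    )


def universe_for(table: CallTable, contrast_names: Sequence[str]) -> list[str]:
    """Genes eligible for an operation over the named contrasts.

    With the no-missing-values model every gene in the table qualifies; the
    call validates contrast existence and preserves gene order.
    """
    for name in contrast_names:
        table.column(name)
    return list(table.genes)
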