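"""Expression-change signatures and Euclidean similarity ranking.

A signature is the n most up-regulated plus n most down-regulated genes of
a query experiment, with their signed change values.  Each experiment of a
panel is scored by the Euclidean distance between its change values and
the signature's over their shared genes, normalized by sqrt(n_shared) so
panels with unequal gene overlap stay comparable.  The *relative score*
r = mean(d) / d equals 1 exactly when an experiment's distance matches the
panel average — the scoring contract of signature-search tools.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd


@dataclasses.dataclass
class Signature:
    """Gene -> signed change value entries, sorted by change descending."""

    entries: pd.Series
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if self.entries.index.duplicated().any():
            dup = self.entries.index[self.entries.index.duplicated()][0]
            raise ValueError(f"duplicate gene {dup!r} in signature")
        if len(self.entries) != self.n_up + self.n_down:
            raise ValueError("n_up + n_down must equal the number of entries")
        # deterministic order: change descending, gene ID ascending on ties
        frame = self.entries.rename("value").rename_axis("gene").reset_index()
        frame = frame.sort_values(["value", "gene"], ascending=[False, True])
        self.entries = frame.set_index("gene")["value"]

    @property
    def genes(self) -> list[str]:
        return list(self.entries.index)

    def as_signs(self) -> pd.Series:
        """Direction-only view (+1 for the up half, -1 for the down half)."""
        return pd.Series(np.sign(self.entries.to_numpy()), index=self.entries.index)


def build_signature(
    changes: Mapping[str, float] | pd.Series, n_top: int = 200
) -> Signature:
    """Select the ``n_top`` largest and ``n_top`` most negative changes.

    Ties at either cutoff are broken by gene ID lexicographic order
    (deterministic) and reported with a warning; an all-tied input is
    degenerate and warned about as a full tie.
    """
    series = pd.Series(dict(changes)) if not isinstance(changes, pd.Series) else changes
    series = series.astype(float)
    series = series[np.isfinite(series)]
    if len(series) < 2 * n_top:
        raise ValueError(
            f"need at least {2 * n_top} finite changes, got {len(series)}"
        )
    if series.nunique() == 1:
        warnings.warn("all change values identical: signature is a full tie",
                      stacklevel=2)
    frame = series.rename("value").rename_axis("gene").reset_index()
    desc = frame.sort_values(["value", "gene"], ascending=[False, True])
    top = desc.head(n_top)
    # the down half is drawn from the remaining genes so halves never overlap
    rest = frame[~frame["gene"].isin(top["gene"])]
    bottom = rest.sort_values(["value", "gene"], ascending=[True, True]).head(n_top)
    if len(frame) > 2 * n_top:
        cut_hi = top["value"].iloc[-1]
        cut_lo = bottom["value"].iloc[-1]
        n_tied = ((series == cut_hi).sum() - (top["value"] == cut_hi).sum()) + (
            (series == cut_lo).sum() - (bottom["value"] == cut_lo).sum()
        )
        if n_tied > 0:
            warnings.warn(
                f"{n_tied} gene(s) tied at a selection cutoff; "
                "ties broken by gene ID", stacklevel=2,
            )
    entries = pd.concat(
        [top.set_index("gene")["value"], bottom.set_index("gene")["value"]]
    )
    return Signature(entries=entries, n_up=n_top, n_down=n_top)


def rank_panel(
    sig: Signature,
    panel: pd.DataFrame,
    mode: str = "values",
    normalize: bool = True,
) -> pd.DataFrame:
    """Score every panel experiment against the signature.

    Parameters
    ----------
    panel:
        Genes x experiments matrix of signed change values; NaN cells mean
        the gene was not measured in that experiment.
    mode:
        "values" compares against the signature's change values, "signs"
        against their directions only (+1/-1).
    normalize:
        Divide each Euclidean distance by sqrt(n_shared) (default), making
        experiments with unequal overlap comparable.

    Returns a DataFrame (experiment, n_shared, distance, relative_score,
    rank) sorted by relative score descending.  Experiments sharing no
    gene with the signature are dropped with a warning.  The relative
    score is ``mean(d) / max(d, eps)`` with ``eps = 1e-12 * mean(d)``, so
    a score of 1 marks panel-average similarity.
    """
    if mode not in ("values", "signs"):
        raise ValueError(f"mode must be 'values' or 'signs', got {mode!r}")
    if panel.shape[1] == 0:
        raise ValueError("empty panel")
    ref = sig.as_signs() if mode == "signs" else sig.entries

    rows = []
    for exp in panel.columns:
        col = panel[exp]
        shared = ref.index.intersection(col.dropna().index)
        if len(shared) == 0:
            warnings.warn(f"experiment {exp!r} shares no gene with the signature; "
                          "dropped", stacklevel=2)
            continue
        diff = ref.loc[shared].to_numpy(float) - col.loc[shared].to_numpy(float)
        d = float(np.linalg.norm(diff))
        if normalize:
            d /= np.sqrt(len(shared))
        rows.append({"experiment": exp, "n_shared": len(shared), "distance": d})
    if not rows:
        raise ValueError("no experiment shares any gene with the signature")

    frame = pd.DataFrame(rows)
    d_bar = float(frame["distance"].mean())
    eps = 1e-12 * d_bar if d_bar > 0 else 1e-12
    frame["relative_score"] = d_bar / np.maximum(frame["distance"], eps)
    frame = frame.sort_values(
        ["relative_score", "experiment"], ascending=[False, True]
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
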