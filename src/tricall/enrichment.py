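"""Functional-category enrichment of a gene set against a genome background.

Per category the *set frequency* (fraction of set genes annotated to it) is
divided by the *background frequency* over the universe, giving a
normalized ratio; bootstrap replicates (resampling genes of the input set
with replacement) provide a mean and sample SD per category.

No DAG propagation or p-values here — this is frequency normalization in
the flat GO-slim style, where a gene may carry several categories and bars
can sum to more than 100%.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclasses.dataclass
class AnnotationMap:
    """gene -> set of category identifiers, plus the background universe."""

    annotations: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        stray = set(self.annotations) - set(self.universe)
        if stray:
            raise ValueError(
                f"annotated genes outside the universe: {sorted(stray)[:5]}"
            )
        for gene, cats in self.annotations.items():
            if any(not c for c in cats):
                raise ValueError(f"empty category identifier on gene {gene!r}")

    @property
    def categories(self) -> list[str]:
        out: set[str] = set()
        for cats in self.annotations.values():
            out |= cats
        return sorted(out)

    def restricted_to_annotated(self) -> "AnnotationMap":
        """Shrink the universe to annotated genes (config option)."""
        annotated = frozenset(g for g, c in self.annotations.items() if c)
        return AnnotationMap(
            annotations={g: c for g, c in self.annotations.items() if c},
            universe=annotated,
        )

    @classmethod
    def from_tsv(cls, path, universe: Iterable[str] | None = None) -> "AnnotationMap":
        """Two-column TSV (gene, category), repeated rows for multi-annotation.

        Without an explicit universe the annotated genes themselves form it.
        """
        frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"],
                            dtype=str, comment="#")
        ann: dict[str, set[str]] = {}
        for gene, cat in zip(frame["gene"], frame["category"]):
            ann.setdefault(str(gene), set()).add(str(cat))
        genes = frozenset(universe) if universe is not None else frozenset(ann)
        return cls(annotations={g: frozenset(c) for g, c in ann.items()},
                   universe=genes)

    def to_tsv(self, path) -> None:
        rows = [
            {"gene": g, "category": c}
            for g in sorted(self.annotations)
            for c in sorted(self.annotations[g])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _frequencies(genes: Iterable[str], ann: AnnotationMap,
                 categories: list[str]) -> np.ndarray:
    genes = list(genes)
    counts = dict.fromkeys(categories, 0)
    for g in genes:
        for c in ann.annotations.get(g, ()):  # unannotated genes dilute
            counts[c] += 1
    return np.array([counts[c] for c in categories], dtype=float) / len(genes)


def enrichment(gene_set: Iterable[str], ann: AnnotationMap) -> pd.DataFrame:
    """Point-estimate profile: set/background frequencies and their ratio.

    Returns a DataFrame indexed by category with columns ``set_frequency``,
    ``background_frequency`` and ``ratio`` (NaN where the background
    frequency is zero).
    """
    gene_set = sorted(set(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    stray = set(gene_set) - set(ann.universe)
    if stray:
        raise ValueError(f"gene set not within universe: {sorted(stray)[:5]}")
    cats = ann.categories
    set_freq = _frequencies(gene_set, ann, cats)
    bg_freq = _frequencies(ann.universe, ann, cats)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bg_freq > 0, set_freq / bg_freq, np.nan)
    return pd.DataFrame(
        {
            "set_frequency": set_freq,
            "background_frequency": bg_freq,
            "ratio": ratio,
        },
        index=pd.Index(cats, name="category"),
    )


def bootstrap_enrichment(
    gene_set: Iterable[str],
    ann: AnnotationMap,
    n_boot: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Enrichment profile with bootstrap mean and sample SD per category.

    Each replicate resamples ``|set|`` genes *from the set* with
    replacement and recomputes the normalized ratios; deterministic under
    a fixed seed.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    profile = enrichment(gene_set, ann)
    genes = np.array(sorted(set(gene_set)))
    cats = list(profile.index)
    bg_freq = profile["background_frequency"].to_numpy()
    rng = np.random.default_rng(seed)
    ratios = np.empty((n_boot, len(cats)))
    for b in range(n_boot):
        resample = rng.choice(genes, size=len(genes), replace=True)
        set_freq = _frequencies(resample, ann, cats)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios[b] = np.where(bg_freq > 0, set_freq / bg_freq, np.nan)
    profile = profile.copy()
    profile["boot_mean"] = ratios.mean(axis=0)
    profile["boot_sd"] = ratios.std(axis=0, ddof=1)
    profile["n_boot"] = n_boot
    return profile
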