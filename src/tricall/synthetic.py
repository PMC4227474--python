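"""Seeded generators for every input the pipeline consumes.

Each generator returns both the data object and a *truth* dict recording
the planted structure (cell probabilities, cluster labels, motif carriers,
enrichment multipliers, panel order) so recovery can be asserted by tests
and end-to-end runs need no external download.  All randomness flows
through one ``numpy.random.default_rng(seed)`` per call.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tricall.calls import DOWN, LEVELS, NC, UP, CallTable, Contrast
from tricall.clustering import CLUSTERS, assign_clusters
from tricall.enrichment import AnnotationMap
from tricall.motifs import PromoterSet, revcomp
from tricall.similarity import Signature


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


# -- call tables -----------------------------------------------------------


def call_table_from_counts(
    counts: np.ndarray | Sequence[Sequence[int]],
    row_factors: Sequence[str],
    col_factor: str,
) -> CallTable:
    """Deterministic call table whose cross-tabulation equals ``counts`` exactly.

    ``counts`` has one row per joint level of the row factors (product
    order, UP first) and one column per column-factor level.
    """
    counts = np.asarray(counts, dtype=np.int64)
    row_factors = list(row_factors)
    row_levels = list(itertools.product(LEVELS, repeat=len(row_factors)))
    if counts.shape != (len(row_levels), 3):
        raise ValueError(
            f"counts shape {counts.shape} != ({len(row_levels)}, 3)"
        )
    rows: list[tuple[int, ...]] = []
    for r, row_level in enumerate(row_levels):
        for c, col_level in enumerate(LEVELS):
            rows.extend([(*row_level, col_level)] * int(counts[r, c]))
    calls = np.array(rows, dtype=np.int8)
    contrasts = [Contrast.canonical(f) for f in row_factors + [col_factor]]
    return CallTable(
        genes=_gene_names(len(rows)),
        contrasts=contrasts,
        calls=calls,
        provenance="synthetic: exact cell counts",
    )


def simulate_call_table(
    n_genes: int,
    cell_probs: np.ndarray | Sequence[Sequence[float]],
    row_factors: Sequence[str],
    col_factor: str,
    seed: int,
) -> tuple[CallTable, dict]:
    """Multinomial draw of genes over response-mode cells.

    ``cell_probs`` is a (3^k, 3) grid of cell probabilities (renormalized
    if needed).  The truth dict records the planted probabilities and the
    implied independence ratios ``p / (p_row * p_col)``.
    """
    probs = np.asarray(cell_probs, dtype=float)
    row_factors = list(row_factors)
    n_rows = 3 ** len(row_factors)
    if probs.shape != (n_rows, 3):
        raise ValueError(f"cell_probs shape {probs.shape} != ({n_rows}, 3)")
    if (probs < 0).any():
        raise ValueError("cell probabilities must be non-negative")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_genes, probs.ravel()).reshape(probs.shape)
    table = call_table_from_counts(counts, row_factors, col_factor)
    table.provenance = f"synthetic: multinomial draw, seed={seed}"

    p_row = probs.sum(axis=1, keepdims=True)
    p_col = probs.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        planted_ratio = np.where(p_row * p_col > 0, probs / (p_row * p_col), np.nan)
    truth = {
        "seed": seed,
        "cell_probs": probs.tolist(),
        "planted_ratio": planted_ratio.tolist(),
        "counts": counts.tolist(),
    }
    return table, truth


# -- planted clusters ------------------------------------------------------


def _pattern_labels(
    inhibitors: Sequence[str], **assign_kwargs
) -> tuple[list[tuple[int, ...]], list[str], dict[str, list[str]]]:
    """Classify every joint call pattern under each inhibitor's rule set.

    Returns (patterns, contrast names, labels-per-inhibitor), where each
    pattern is a tuple of calls over (SA, *inhibitors, W30B, W30SA).
    """
    names = ["SA", *inhibitors, "W30B", "W30SA"]
    patterns = list(itertools.product(LEVELS, repeat=len(names)))
    table = CallTable(
        genes=[f"p{i}" for i in range(len(patterns))],
        contrasts=[Contrast.canonical(n) for n in names],
        calls=np.array(patterns, dtype=np.int8),
    )
    labels = {
        inh: [
            assign_clusters(table, inh, **assign_kwargs).labels[g]
            for g in table.genes
        ]
        for inh in inhibitors
    }
    return patterns, names, labels


def plant_clusters(
    cluster_sizes: Mapping[str, int],
    n_background: int,
    seed: int,
    inhibitors: Sequence[str] = ("EDE", "U73"),
    single_sizes: Mapping[str, int] | None = None,
    **assign_kwargs,
) -> tuple[CallTable, dict]:
    """Generate a call table with genes planted into cluster predicates.

    ``cluster_sizes[X]`` genes get patterns satisfying cluster X under
    *every* inhibitor (stringent members); ``single_sizes[X]`` genes
    satisfy X under exactly one inhibitor, alternating which (loose-only
    members); background genes are rejection-free draws from patterns that
    satisfy no cluster under any inhibitor.  Patterns are sampled
    uniformly over each satisfying set, exercising every predicate
    branch.  Truth maps gene -> (cluster or None, mode).
    """
    single_sizes = dict(single_sizes or {})
    patterns, names, labels = _pattern_labels(inhibitors, **assign_kwargs)
    rng = np.random.default_rng(seed)

    pools: dict[tuple[str, str], list[int]] = {}
    for cluster in CLUSTERS:
        pools[(cluster, "both")] = [
            i for i in range(len(patterns))
            if all(labels[inh][i] == cluster for inh in inhibitors)
        ]
        for inh in inhibitors:
            pools[(cluster, f"single:{inh}")] = [
                i for i in range(len(patterns))
                if labels[inh][i] == cluster
                and all(labels[o][i] == "none" for o in inhibitors if o != inh)
            ]
    background_pool = [
        i for i in range(len(patterns))
        if all(labels[inh][i] == "none" for inh in inhibitors)
    ]

    rows: list[int] = []
    truth_entries: list[tuple[str | None, str]] = []
    for cluster in CLUSTERS:
        k = int(cluster_sizes.get(cluster, 0))
        pool = pools[(cluster, "both")]
        if k > 0 and not pool:
            raise ValueError(f"no pattern satisfies cluster {cluster} under "
                             f"all inhibitors")
        rows.extend(rng.choice(pool, size=k).tolist() if k else [])
        truth_entries.extend([(cluster, "both")] * k)
        k_single = int(single_sizes.get(cluster, 0))
        for j in range(k_single):
            inh = inhibitors[j % len(inhibitors)]
            pool = pools[(cluster, f"single:{inh}")]
            if not pool:
                raise ValueError(
                    f"no pattern satisfies cluster {cluster} under {inh} only"
                )
            rows.append(int(rng.choice(pool)))
            truth_entries.append((cluster, f"single:{inh}"))
    if n_background:
        rows.extend(rng.choice(background_pool, size=n_background).tolist())
        truth_entries.extend([(None, "background")] * n_background)

    order = rng.permutation(len(rows))
    genes = _gene_names(len(rows))
    calls = np.array([patterns[rows[i]] for i in order], dtype=np.int8)
    truth = {
        genes[pos]: {"cluster": truth_entries[i][0], "mode": truth_entries[i][1]}
        for pos, i in enumerate(order)
    }
    table = CallTable(
        genes=genes,
        contrasts=[Contrast.canonical(n) for n in names],
        calls=calls,
        provenance=f"synthetic: planted clusters, seed={seed}",
    )
    return table, {"seed": seed, "genes": truth}


# -- promoters -------------------------------------------------------------


def _random_sequences(
    rng: np.random.Generator, n: int, length: int, gc: float
) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return [
        "".join(bases[rng.choice(4, size=length, p=p)]) for _ in range(n)
    ]


def simulate_promoters(
    n_fg: int,
    n_bg: int,
    length: int,
    motif: str,
    p_fg: float,
    p_bg: float,
    seed: int,
    gc: float = 0.5,
) -> tuple[PromoterSet, PromoterSet, dict]:
    """Foreground/background promoter sets with a planted motif.

    Sequences are i.i.d. at the stated GC fraction; with the stated
    per-set probability a promoter receives one motif insertion
    (overwriting the background bases) at a uniform position on a uniform
    strand.  Truth records carrier IDs per set.
    """
    motif = motif.upper()
    if not 4 <= len(motif) <= 10:
        raise ValueError(f"planted motif length {len(motif)} outside [4, 10]")
    if len(motif) > length:
        raise ValueError("motif longer than promoter")
    for name, p in (("p_fg", p_fg), ("p_bg", p_bg)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {p}")

    rng = np.random.default_rng(seed)

    def build(n: int, p: float, prefix: str) -> tuple[dict[str, str], list[str]]:
        seqs = _random_sequences(rng, n, length, gc)
        carriers: list[str] = []
        out: dict[str, str] = {}
        for i, seq in enumerate(seqs):
            gene = f"{prefix}{i:05d}"
            if rng.random() < p:
                pos = int(rng.integers(0, length - len(motif) + 1))
                ins = motif if rng.random() < 0.5 else revcomp(motif)
                seq = seq[:pos] + ins + seq[pos + len(motif):]
                carriers.append(gene)
            out[gene] = seq
        return out, carriers

    fg_seqs, fg_carriers = build(n_fg, p_fg, "FG")
    bg_seqs, bg_carriers = build(n_bg, p_bg, "BG")
    truth = {
        "seed": seed,
        "motif": motif,
        "fg_carriers": fg_carriers,
        "bg_carriers": bg_carriers,
    }
    return PromoterSet(fg_seqs), PromoterSet(bg_seqs), truth


# -- annotations -----------------------------------------------------------


def simulate_annotations(
    n_universe: int,
    background_freqs: Sequence[float] | Mapping[str, float],
    set_size: int,
    set_multipliers: Sequence[float] | Mapping[str, float],
    seed: int,
) -> tuple[AnnotationMap, list[str], dict]:
    """Annotation map with planted per-category set enrichment.

    Background genes carry category c with probability ``bg_freq[c]``;
    the first ``set_size`` genes (the designated gene set) with
    probability ``min(1, bg_freq[c] * multiplier[c])``.
    """
    if isinstance(background_freqs, Mapping):
        cats = sorted(background_freqs)
        bg = np.array([background_freqs[c] for c in cats], dtype=float)
    else:
        bg = np.asarray(background_freqs, dtype=float)
        cats = [f"cat{i:02d}" for i in range(len(bg))]
    if isinstance(set_multipliers, Mapping):
        mult = np.array([set_multipliers.get(c, 1.0) for c in cats], dtype=float)
    else:
        mult = np.asarray(set_multipliers, dtype=float)
    if len(mult) != len(bg):
        raise ValueError("one multiplier per category required")
    if ((bg < 0) | (bg > 1)).any() or (mult < 0).any():
        raise ValueError("invalid probabilities or multipliers")
    if set_size > n_universe:
        raise ValueError("set larger than universe")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_universe)
    set_genes = genes[:set_size]
    p_set = np.minimum(1.0, bg * mult)
    ann: dict[str, frozenset[str]] = {}
    for i, gene in enumerate(genes):
        p = p_set if i < set_size else bg
        mask = rng.random(len(cats)) < p
        if mask.any():
            ann[gene] = frozenset(c for c, m in zip(cats, mask) if m)
    amap = AnnotationMap(annotations=ann, universe=frozenset(genes))
    truth = {
        "seed": seed,
        "categories": cats,
        "background_freqs": bg.tolist(),
        "set_multipliers": mult.tolist(),
        "set_genes": set_genes,
    }
    return amap, set_genes, truth


# -- similarity panels -----------------------------------------------------


def simulate_panel(
    sig: Signature,
    n_experiments: int,
    noise_step: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Experiments = signature + Gaussian noise growing along a gradient.

    Experiment ``E00`` is an exact copy; experiment i adds noise with SD
    ``noise_step * i * sd(signature)``, so the planted similarity order is
    the experiment order.
    """
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    if noise_step < 0:
        raise ValueError("noise_step must be non-negative")
    rng = np.random.default_rng(seed)
    base = sig.entries.to_numpy(dtype=float)
    scale = float(np.std(base)) or 1.0
    data = {}
    names = [f"E{i:02d}" for i in range(n_experiments)]
    for i, name in enumerate(names):
        data[name] = base + rng.normal(0.0, noise_step * i * scale, size=len(base))
    panel = pd.DataFrame(data, index=sig.entries.index)
    truth = {"seed": seed, "planted_order": names, "noise_step": noise_step}
    return panel, truth
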