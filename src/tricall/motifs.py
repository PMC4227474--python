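"""Promoter extraction and exhaustive short-motif over-representation scanning.

Every 4–10 bp word present in the foreground promoter set is tested for
over-representation against a background set with a 2x2 chi-squared on
per-promoter *presence* counts (a promoter either contains the word on
either strand or it does not), no continuity correction.  A word and its
reverse complement are one motif, reported under the lexicographically
smaller spelling.  Hits can be annotated against a catalog of IUPAC
cis-element patterns.
"""

from __future__ import annotations

import dataclasses
import itertools
import re
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"), "R": frozenset("AG"), "W": frozenset("AT"),
    "S": frozenset("CG"), "Y": frozenset("CT"), "K": frozenset("GT"),
    "V": frozenset("ACG"), "H": frozenset("ACT"), "D": frozenset("AGT"),
    "B": frozenset("CGT"), "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(motif: str) -> str:
    """Lexicographically smaller of a word and its reverse complement."""
    rc = revcomp(motif)
    return motif if motif <= rc else rc


@dataclasses.dataclass
class PromoterSet:
    """Uppercase A/C/G/T/N promoter sequences keyed by unique gene ID.

    Records shorter than the minimum motif length (4) are kept but flagged
    unusable and never counted in presence tables.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for gene, seq in self.sequences.items():
            s = str(seq).upper()
            if set(s) - set("ACGTN"):
                bad = sorted(set(s) - set("ACGTN"))
                raise ValueError(f"promoter {gene!r}: invalid characters {bad}")
            clean[str(gene)] = s
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def usable(self, min_len: int = 4) -> dict[str, str]:
        return {g: s for g, s in self.sequences.items() if len(s) >= min_len}

    @classmethod
    def from_fasta(cls, path) -> "PromoterSet":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate promoter ID {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        return cls(sequences=seqs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=g, description="") for g, s in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclasses.dataclass
class MotifHit:
    """One over-represented motif with its 2x2 presence table and statistic."""

    motif: str
    fg_present: int
    fg_absent: int
    bg_present: int
    bg_absent: int
    chi2: float
    p_value: float
    strand_note: str = "both"
    catalog_matches: list[tuple[str, str, str]] = dataclasses.field(
        default_factory=list
    )  # (element name, IUPAC pattern, strand)

    def __post_init__(self) -> None:
        if not 4 <= len(self.motif) <= 10:
            raise ValueError(f"motif length {len(self.motif)} outside [4, 10]")

    @property
    def fg_rate(self) -> float:
        return self.fg_present / (self.fg_present + self.fg_absent)

    @property
    def bg_rate(self) -> float:
        return self.bg_present / (self.bg_present + self.bg_absent)


# -- promoter extraction ---------------------------------------------------


def extract_promoters(
    gene_coords: pd.DataFrame,
    genome: Mapping[str, str],
    max_len: int = 1000,
) -> PromoterSet:
    """Cut the up-to-``max_len`` bp window immediately upstream of each TSS.

    ``gene_coords`` needs columns gene, chrom, strand, tss, gene_end
    (1-based inclusive; an optional utr5_end column is accepted for
    interface completeness — the 5'UTR lies downstream of the TSS and is
    excluded by construction since the window ends at the TSS, exclusive).
    The window is truncated where it would overlap any other gene's
    annotated span (min(tss, gene_end)..max(tss, gene_end)); minus-strand
    windows are reverse-complemented so sequences read toward the TSS.
    """
    required = {"gene", "chrom", "strand", "tss", "gene_end"}
    missing = required - set(gene_coords.columns)
    if missing:
        raise ValueError(f"gene_coords lacks columns: {sorted(missing)}")

    spans: dict[str, list[tuple[str, int, int]]] = {}
    for rec in gene_coords.itertuples(index=False):
        chrom = str(rec.chrom)
        if chrom not in genome:
            raise ValueError(f"unknown chromosome {chrom!r} for gene {rec.gene!r}")
        lo, hi = sorted((int(rec.tss), int(rec.gene_end)))
        if not 1 <= int(rec.tss) <= len(genome[chrom]):
            raise ValueError(f"TSS {rec.tss} of gene {rec.gene!r} outside {chrom!r}")
        spans.setdefault(chrom, []).append((str(rec.gene), lo, hi))

    out: dict[str, str] = {}
    for rec in gene_coords.itertuples(index=False):
        gene, chrom = str(rec.gene), str(rec.chrom)
        tss, strand = int(rec.tss), str(rec.strand)
        chrom_seq = genome[chrom]
        if strand == "+":
            start, end = max(1, tss - max_len), tss - 1  # 1-based inclusive
            for other, lo, hi in spans[chrom]:
                if other == gene:
                    continue
                if hi >= start and lo <= end:  # overlap: keep TSS-proximal part
                    start = max(start, hi + 1)
            window = chrom_seq[start - 1:end] if start <= end else ""
        elif strand == "-":
            start, end = tss + 1, min(len(chrom_seq), tss + max_len)
            for other, lo, hi in spans[chrom]:
                if other == gene:
                    continue
                if hi >= start and lo <= end:
                    end = min(end, lo - 1)
            window = revcomp(chrom_seq[start - 1:end]) if start <= end else ""
        else:
            raise ValueError(f"invalid strand {strand!r} for gene {gene!r}")
        out[gene] = window.upper()
    return PromoterSet(sequences=out)


# -- scanning --------------------------------------------------------------


def _presence_counter(
    seqs: Iterable[str], kmin: int, kmax: int, cache: dict[str, str]
) -> Counter:
    """Count, per canonical k-mer, the number of promoters containing it.

    Scanning the forward strand with reverse-complement canonicalization
    covers both strands.  Words containing N never match.
    """
    counter: Counter = Counter()
    for seq in seqs:
        present: set[str] = set()
        n = len(seq)
        for k in range(kmin, min(kmax, n) + 1):
            for i in range(n - k + 1):
                word = seq[i:i + k]
                if "N" in word:
                    continue
                canon = cache.get(word)
                if canon is None:
                    canon = canonical(word)
                    cache[word] = canon
                present.add(canon)
        counter.update(present)
    return counter


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Plain chi-squared (1 dof, no continuity correction) for [[a,b],[c,d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(stats.chi2.sf(stat, 1))


def scan_motifs(
    fg: PromoterSet,
    bg: PromoterSet,
    kmin: int = 4,
    kmax: int = 10,
    alpha: float = 1e-5,
) -> list[MotifHit]:
    """Exhaustive over-representation scan of fg against bg promoters.

    Tests every canonical k-mer (k in [kmin, kmax]) present in at least
    one foreground promoter; keeps hits with chi-squared p < ``alpha``
    and a foreground presence rate exceeding the background rate, sorted
    by p ascending (ties by motif string).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if kmin > kmax:
        raise ValueError(f"kmin {kmin} > kmax {kmax}")
    if not (4 <= kmin and kmax <= 10):
        raise ValueError(f"motif lengths must stay within [4, 10]")
    fg_seqs = fg.usable(kmin)
    bg_seqs = bg.usable(kmin)
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background sets must be non-empty")

    cache: dict[str, str] = {}
    fg_counts = _presence_counter(fg_seqs.values(), kmin, kmax, cache)
    bg_counts = _presence_counter(bg_seqs.values(), kmin, kmax, cache)
    n_fg, n_bg = len(fg_seqs), len(bg_seqs)

    motifs = sorted(fg_counts)
    a = np.array([fg_counts[m] for m in motifs], dtype=np.int64)
    c = np.array([bg_counts.get(m, 0) for m in motifs], dtype=np.int64)
    b, d = n_fg - a, n_bg - c
    n = n_fg + n_bg
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    pvals = stats.chi2.sf(stat, 1)
    over = a / n_fg > c / n_bg
    keep = (pvals < alpha) & over

    hits = [
        MotifHit(
            motif=motifs[i],
            fg_present=int(a[i]),
            fg_absent=int(b[i]),
            bg_present=int(c[i]),
            bg_absent=int(d[i]),
            chi2=float(stat[i]),
            p_value=float(pvals[i]),
        )
        for i in np.flatnonzero(keep)
    ]
    hits.sort(key=lambda h: (h.p_value, h.motif))
    return hits


def prune_nested(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Keep, per containment chain, the hit with the smallest p-value.

    A hit is dropped when a better-ranked kept hit contains it or is
    contained in it (on either strand).
    """
    kept: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (h.p_value, h.motif)):
        forms = (hit.motif, revcomp(hit.motif))
        nested = any(
            f in k.motif or k.motif in f for k in kept for f in forms
        )
        if not nested:
            kept.append(hit)
    return kept


# -- IUPAC catalog matching ------------------------------------------------


def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    bad = sorted(set(pattern) - set(IUPAC_CODES))
    if bad:
        raise ValueError(f"invalid IUPAC character(s) {bad} in pattern {pattern!r}")
    return pattern


def _compatible(word: str, pattern: str) -> bool:
    """True when the word and IUPAC pattern (equal length) are compatible."""
    return all(base in IUPAC_CODES[code] for base, code in zip(word, pattern))


def _matches_pattern(motif: str, pattern: str) -> bool:
    """Motif contains a pattern match, or is contained in one.

    Shorter-than-pattern motifs match when they align compatibly against
    some window of the pattern (i.e. some literal expansion of the pattern
    contains the motif).
    """
    lm, lp = len(motif), len(pattern)
    if lm >= lp:
        return any(_compatible(motif[i:i + lp], pattern) for i in range(lm - lp + 1))
    return any(_compatible(motif, pattern[i:i + lm]) for i in range(lp - lm + 1))


def match_catalog(
    hits: Sequence[MotifHit], catalog: Sequence[tuple[str, str]]
) -> list[MotifHit]:
    """Annotate hits with matching catalog cis-elements (both strands).

    A hit matches an element when the motif — or its reverse complement,
    recorded with strand "reverse" — contains or is contained in a string
    matching the element's IUPAC pattern.  Returns the same hit objects
    with ``catalog_matches`` and ``strand_note`` filled in.
    """
    validated = [(name, _validate_pattern(pat)) for name, pat in catalog]
    for hit in hits:
        matches: list[tuple[str, str, str]] = []
        for name, pattern in validated:
            fwd = _matches_pattern(hit.motif, pattern)
            rev = _matches_pattern(revcomp(hit.motif), pattern)
            if fwd:
                matches.append((name, pattern, "forward"))
            elif rev:
                matches.append((name, pattern, "reverse"))
        hit.catalog_matches = matches
        strands = {s for _, _, s in matches}
        if strands == {"forward"}:
            hit.strand_note = "forward"
        elif strands == {"reverse"}:
            hit.strand_note = "reverse"
        elif strands:
            hit.strand_note = "both"
    return list(hits)


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    rows = [
        {
            "motif": h.motif,
            "fg_present": h.fg_present,
            "fg_absent": h.fg_absent,
            "bg_present": h.bg_present,
            "bg_absent": h.bg_absent,
            "chi2": h.chi2,
            "p_value": h.p_value,
            "strand_note": h.strand_note,
            "catalog_matches": ";".join(
                f"{name}|{pat}|{strand}" for name, pat, strand in h.catalog_matches
            ),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["motif", "fg_present", "fg_absent", "bg_present", "bg_absent",
                 "chi2", "p_value", "strand_note", "catalog_matches"],
    )


def read_catalog(path) -> list[tuple[str, str]]:
    """Two-column TSV (element name, IUPAC pattern)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["name", "pattern"],
                        dtype=str, comment="#")
    return [(str(n), _validate_pattern(str(p))) for n, p in
            zip(frame["name"], frame["pattern"])]
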