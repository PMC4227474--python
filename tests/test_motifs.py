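import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tricall.motifs import (
    MotifHit,
    PromoterSet,
    canonical,
    chi2_2x2,
    extract_promoters,
    hits_to_frame,
    match_catalog,
    prune_nested,
    revcomp,
    scan_motifs,
)
from tricall.synthetic import simulate_promoters


def naive_presence_count(motif, promoters):
    """Oracle: double-strand substring search over every promoter."""
    rc = revcomp(motif)
    return sum(1 for seq in promoters.sequences.values()
               if motif in seq or rc in seq)


class TestPromoterSet:
    def test_uppercases_and_validates(self):
        ps = PromoterSet({"g1": "acgt" * 3})
        assert ps.sequences["g1"] == "ACGT" * 3

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="g1"):
            PromoterSet({"g1": "ACGU"})

    def test_short_records_flagged_unusable(self):
        ps = PromoterSet({"short": "ACG", "ok": "ACGTACGT"})
        assert set(ps.usable(4)) == {"ok"}

    def test_fasta_round_trip(self, tmp_path):
        ps = PromoterSet({"g1": "ACGTACGTAC", "g2": "TTTTNACGTA"})
        path = tmp_path / "p.fasta"
        ps.to_fasta(path)
        assert PromoterSet.from_fasta(path).sequences == ps.sequences


class TestExtractPromoters:
    @staticmethod
    def coords(rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss",
                                           "utr5_end", "gene_end"])

    def test_plain_upstream_window(self):
        genome = {"chr1": "A" * 1000 + "C" * 1000 + "G" * 1000}
        coords = self.coords([("g1", "chr1", "+", 2001, 2100, 2500)])
        ps = extract_promoters(coords, genome, max_len=1000)
        # positions 1001..2000 -> all C
        assert ps.sequences["g1"] == "C" * 1000

    def test_truncation_at_upstream_neighbor(self):
        genome = {"chr1": "A" * 3000}
        coords = self.coords([
            ("g1", "chr1", "+", 2001, 2100, 2500),
            ("up", "chr1", "+", 1001, 1100, 1500),
        ])
        ps = extract_promoters(coords, genome, max_len=1000)
        assert len(ps.sequences["g1"]) == 500  # 1501..2000

    def test_minus_strand_reverse_complemented(self):
        genome = {"chr1": "A" * 10 + "ACGTT" + "G" * 10}
        coords = self.coords([("g1", "chr1", "-", 10, 8, 5)])
        ps = extract_promoters(coords, genome, max_len=5)
        # upstream of a minus-strand TSS at 10 is 11..15 = "ACGTT"
        assert ps.sequences["g1"] == revcomp("ACGTT")

    def test_chromosome_start_clips_window(self):
        genome = {"chr1": "ACGTACGTAC"}
        coords = self.coords([("g1", "chr1", "+", 5, 6, 8)])
        ps = extract_promoters(coords, genome, max_len=1000)
        assert ps.sequences["g1"] == "ACGT"

    def test_tss_outside_chromosome_rejected(self):
        coords = self.coords([("g1", "chr1", "+", 50, 51, 60)])
        with pytest.raises(ValueError, match="TSS"):
            extract_promoters(coords, {"chr1": "ACGT"})

    def test_unknown_chromosome_rejected(self):
        coords = self.coords([("g1", "chrX", "+", 2, 3, 4)])
        with pytest.raises(ValueError, match="chrX"):
            extract_promoters(coords, {"chr1": "ACGT"})

    def test_random_annotation_matches_slicing_oracle(self):
        rng = np.random.default_rng(17)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=5000))}
        rows = []
        positions = rng.choice(np.arange(200, 4800, 250), size=12,
                               replace=False)
        for i, tss in enumerate(positions):
            strand = "+" if i % 2 == 0 else "-"
            end = tss + 100 if strand == "+" else tss - 100
            rows.append((f"g{i}", "c", strand, int(tss), int(tss), int(end)))
        coords = self.coords(rows)
        ps = extract_promoters(coords, genome, max_len=300)

        spans = [(g, min(t, e), max(t, e)) for g, _, _, t, _, e in rows]
        for g, _, strand, tss, _, _ in rows:
            seq = genome["c"]
            if strand == "+":
                window = [p for p in range(max(1, tss - 300), tss)]
            else:
                window = [p for p in range(tss + 1,
                                           min(len(seq), tss + 300) + 1)]
            blocked = set()
            for og, lo, hi in spans:
                if og != g:
                    blocked |= set(range(lo, hi + 1))
            keep = [p for p in window if p not in blocked]
            # maximal contiguous run adjacent to the TSS
            if strand == "+":
                keep_run = []
                for p in reversed(keep):
                    if not keep_run or p == keep_run[-1] - 1:
                        keep_run.append(p)
                keep = sorted(keep_run)
                expected = "".join(seq[p - 1] for p in keep)
            else:
                keep_run = []
                for p in keep:
                    if not keep_run or p == keep_run[-1] + 1:
                        keep_run.append(p)
                expected = revcomp("".join(seq[p - 1] for p in keep_run))
            assert ps.sequences[g] == expected, (g, strand)


class TestScanMotifs:
    def test_fg_equals_bg_gives_no_hits(self):
        rng = np.random.default_rng(0)
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=200))
                for i in range(50)}
        ps = PromoterSet(seqs)
        assert scan_motifs(ps, ps) == []

    def test_planted_motif_detected(self):
        fg, bg, truth = simulate_promoters(
            n_fg=100, n_bg=100, length=300, motif="GTCAAC",
            p_fg=0.5, p_bg=0.01, seed=4)
        hits = scan_motifs(fg, bg, kmin=4, kmax=10)
        motifs = {h.motif for h in hits}
        assert canonical("GTCAAC") in motifs
        planted = next(h for h in hits if h.motif == canonical("GTCAAC"))
        assert planted.p_value < 1e-8

    def test_planted_2x2_statistic_matches_brute_force(self):
        # presence table (50, 50, 1, 99): chi2 ~ 63, p ~ 1e-15
        stat, p = chi2_2x2(50, 50, 1, 99)
        n = 200
        e = np.outer([100, 100], [51, 149]) / n
        o = np.array([[50, 50], [1, 99]])
        brute = ((o - e) ** 2 / e).sum()
        assert stat == pytest.approx(brute, rel=1e-12)
        assert stat == pytest.approx(63.15, abs=0.5)
        assert p < 1e-14
        assert p == pytest.approx(stats.chi2.sf(brute, 1), rel=1e-9)

    def test_presence_counts_match_naive_search(self):
        fg, bg, _ = simulate_promoters(
            n_fg=30, n_bg=30, length=150, motif="TTGACC",
            p_fg=0.6, p_bg=0.05, seed=9)
        hits = scan_motifs(fg, bg, kmin=4, kmax=6, alpha=0.5)
        assert hits, "expected at least one hit at a loose threshold"
        for h in hits[:20]:
            assert h.fg_present == naive_presence_count(h.motif, fg)
            assert h.bg_present == naive_presence_count(h.motif, bg)
            assert h.fg_present + h.fg_absent == len(fg)
            assert h.bg_present + h.bg_absent == len(bg)

    def test_canonicalization_under_revcomp_of_input(self):
        fg, bg, _ = simulate_promoters(
            n_fg=40, n_bg=40, length=120, motif="GGATCC",
            p_fg=0.7, p_bg=0.02, seed=3)
        hits_fwd = scan_motifs(fg, bg, kmin=4, kmax=6, alpha=1e-3)
        fg_rc = PromoterSet({g: revcomp(s) for g, s in fg.sequences.items()})
        bg_rc = PromoterSet({g: revcomp(s) for g, s in bg.sequences.items()})
        hits_rc = scan_motifs(fg_rc, bg_rc, kmin=4, kmax=6, alpha=1e-3)
        assert [(h.motif, h.fg_present) for h in hits_fwd] == \
               [(h.motif, h.fg_present) for h in hits_rc]

    def test_lowering_alpha_never_adds_hits(self):
        fg, bg, _ = simulate_promoters(
            n_fg=50, n_bg=50, length=200, motif="ACGTAC",
            p_fg=0.6, p_bg=0.05, seed=6)
        loose = {h.motif for h in scan_motifs(fg, bg, kmin=4, kmax=6,
                                              alpha=1e-3)}
        strict = {h.motif for h in scan_motifs(fg, bg, kmin=4, kmax=6,
                                               alpha=1e-6)}
        assert strict <= loose

    def test_n_bases_never_match(self):
        fg = PromoterSet({"g1": "NNNNNNNNNN", "g2": "ACGTACGTAC"})
        bg = PromoterSet({"b1": "TTTTTTTTTT"})
        hits = scan_motifs(fg, bg, kmin=4, kmax=4, alpha=0.999)
        assert all("N" not in h.motif for h in hits)

    def test_invalid_parameters(self):
        ps = PromoterSet({"g": "ACGTACGT"})
        with pytest.raises(ValueError):
            scan_motifs(ps, ps, alpha=0.0)
        with pytest.raises(ValueError):
            scan_motifs(ps, ps, kmin=8, kmax=5)

    def test_null_calibration(self):
        # no planted signal: total hit count over seeded runs stays within
        # 10x the family-wise expectation n_tested * alpha
        alpha = 1e-5
        total_hits, total_expected = 0, 0.0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            seqs = ["".join(rng.choice(list("ACGT"), size=500))
                    for _ in range(200)]
            order = rng.permutation(200)
            fg = PromoterSet({f"f{i}": seqs[j] for i, j in
                              enumerate(order[:100])})
            bg = PromoterSet({f"b{i}": seqs[j] for i, j in
                              enumerate(order[100:])})
            hits = scan_motifs(fg, bg, kmin=4, kmax=10, alpha=alpha)
            n_tested = len(_count_tested(fg))
            total_hits += len(hits)
            total_expected += n_tested * alpha
        assert total_hits <= max(10 * total_expected, 5)


def _count_tested(fg):
    from tricall.motifs import _presence_counter
    return _presence_counter(fg.sequences.values(), 4, 10, {})


class TestPruneNested:
    def make_hit(self, motif, p):
        return MotifHit(motif=motif, fg_present=10, fg_absent=10,
                        bg_present=1, bg_absent=19, chi2=10.0, p_value=p)

    def test_keeps_best_of_containment_chain(self):
        h_long = self.make_hit("ACGTACG", 1e-10)
        h_short = self.make_hit("CGTAC", 1e-7)
        h_other = self.make_hit("TTTTGG", 1e-6)
        kept = prune_nested([h_short, h_long, h_other])
        assert {h.motif for h in kept} == {"ACGTACG", "TTTTGG"}

    def test_revcomp_containment_also_pruned(self):
        h_long = self.make_hit("ACGTACG", 1e-10)
        nested_rc = self.make_hit(revcomp("CGTAC"), 1e-7)
        kept = prune_nested([h_long, nested_rc])
        assert {h.motif for h in kept} == {"ACGTACG"}


class TestCatalogMatching:
    def make_hit(self, motif):
        return MotifHit(motif=motif, fg_present=5, fg_absent=5,
                        bg_present=1, bg_absent=9, chi2=5.0, p_value=1e-6)

    def test_degenerate_code_matches(self):
        hit = self.make_hit("TTGACC")
        (annotated,) = match_catalog([hit], [("wbox", "TTGACY")])
        assert annotated.catalog_matches == [("wbox", "TTGACY", "forward")]
        assert annotated.strand_note == "forward"

    def test_mismatch(self):
        hit = self.make_hit("GGTACA")
        (annotated,) = match_catalog([hit], [("wbox", "TTGACY")])
        assert annotated.catalog_matches == []

    def test_reverse_strand_match_recorded(self):
        hit = self.make_hit(canonical("GGTCAA"))  # revcomp of TTGACC
        assert revcomp(hit.motif) == "TTGACC" or hit.motif == "TTGACC"
        (annotated,) = match_catalog([self.make_hit("GGTCAA")],
                                     [("wbox", "TTGACY")])
        assert annotated.catalog_matches == [("wbox", "TTGACY", "reverse")]
        assert annotated.strand_note == "reverse"

    def test_motif_containing_pattern_matches(self):
        hit = self.make_hit("ATTGACCA")  # contains TTGACC
        (annotated,) = match_catalog([hit], [("wbox", "TTGACY")])
        assert annotated.catalog_matches

    def test_motif_contained_in_pattern_matches(self):
        hit = self.make_hit("TGAC")  # window of TTGACY expansion
        (annotated,) = match_catalog([hit], [("wbox", "TTGACY")])
        assert annotated.catalog_matches

    def test_invalid_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="invalid IUPAC"):
            match_catalog([self.make_hit("ACGTAC")], [("bad", "ACGTX")])

    def test_matching_agrees_with_expansion_oracle(self):
        rng = np.random.default_rng(12)
        codes = list("ACGTMRWSYKN")
        bases = {"A": "A", "C": "C", "G": "G", "T": "T", "M": "AC",
                 "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
                 "N": "ACGT"}
        for _ in range(40):
            motif = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 8))))
            pattern = "".join(rng.choice(codes, size=int(rng.integers(4, 7))))
            expansions = ["".join(t) for t in
                          itertools.product(*[bases[c] for c in pattern])]
            def contains_either_way(word):
                return any(e in word for e in expansions) or any(
                    word in e for e in expansions)
            want = contains_either_way(motif) or contains_either_way(
                revcomp(motif))
            hit = self.make_hit(motif)
            (annotated,) = match_catalog([hit], [("el", pattern)])
            assert bool(annotated.catalog_matches) == want, (motif, pattern)


class TestHitsFrame:
    def test_frame_columns(self):
        fg, bg, _ = simulate_promoters(
            n_fg=30, n_bg=30, length=100, motif="TTGACC",
            p_fg=0.8, p_bg=0.0, seed=2)
        hits = scan_motifs(fg, bg, kmin=6, kmax=6, alpha=1e-3)
        frame = hits_to_frame(hits)
        assert list(frame.columns)[:2] == ["motif", "fg_present"]
        assert (frame["p_value"] < 1e-3).all()
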