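"""Novel miRNA discovery: filtering, flanks, hairpin screening, calling."""

import numpy as np
import pandas as pd
import pytest

from soymir.fold import fold
from soymir.novel import (
    HairpinCandidate,
    NovelMirna,
    call_novel,
    duplex_mismatches,
    evaluate_hairpin,
    extract_flanks,
    filter_annotated,
    group_families,
    locate_in_genes,
    run_novel_analysis,
)
from soymir.seqs import random_seq, revcomp
from soymir.simulate import GeneModel, build_precursor


def tag_table(seqs, count=10):
    df = pd.DataFrame({"L1": [count] * len(seqs)}, index=pd.Index(seqs, name="sequence"))
    df["total"] = df["L1"]
    return df


class TestFilterAnnotated:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.genome = {"chr1": random_seq(rng, 5000)}
        self.tag_rrna = self.genome["chr1"][999:1020]
        self.tag_exon = self.genome["chr1"][1999:2020]
        self.tag_intron = self.genome["chr1"][2499:2520]
        self.tag_anti_exon = revcomp(self.tag_exon)
        self.ncrna = [("chr1", 950, 1100, "+")]
        self.exons = [("chr1", 1900, 2100, "+")]
        self.known = [("chr1", 4000, 4100, "+")]

    def run(self, seqs):
        tags = tag_table(seqs)
        hits = {
            s: [h for h in [
                ("chr1", self.genome["chr1"].find(s) + 1,
                 self.genome["chr1"].find(s) + len(s), "+")
            ] if h[1] > 0] or [
                ("chr1", self.genome["chr1"].find(revcomp(s)) + 1,
                 self.genome["chr1"].find(revcomp(s)) + len(s), "-")
            ]
            for s in seqs
        }
        return filter_annotated(tags, hits, self.genome, self.known, self.ncrna, self.exons)

    def test_tag_in_ncrna_removed(self):
        assert self.run([self.tag_rrna]) == []

    def test_sense_exon_tag_removed_antisense_retained(self):
        kept = self.run([self.tag_exon, self.tag_anti_exon])
        assert self.tag_exon not in kept
        assert self.tag_anti_exon in kept

    def test_intron_tag_retained(self):
        assert self.run([self.tag_intron]) == [self.tag_intron]

    def test_known_precursor_overlap_removed_either_strand(self):
        t = self.genome["chr1"][4019:4040]
        assert self.run([t]) == []
        assert self.run([revcomp(t)]) == []

    def test_malformed_interval_rejected(self):
        tags = tag_table([self.tag_intron])
        with pytest.raises(ValueError):
            filter_annotated(tags, {}, self.genome, [("chr1", 100, 50)], [], [])


class TestExtractFlanks:
    def test_window_size_mid_chromosome(self):
        genome = {"chr1": random_seq(np.random.default_rng(1), 1000)}
        win, locus, pos = extract_flanks(("chr1", 400, 420, "+"), genome)
        assert len(win) == 221 and pos == 100
        assert win[pos : pos + 21] == genome["chr1"][399:420]

    def test_left_flank_clipped_at_chromosome_start(self):
        genome = {"chr1": random_seq(np.random.default_rng(2), 1000)}
        win, locus, pos = extract_flanks(("chr1", 30, 50, "+"), genome)
        assert locus[1] == 1 and pos == 29

    def test_minus_strand_window_contains_tag_verbatim(self):
        genome = {"chr1": random_seq(np.random.default_rng(3), 1000)}
        tag = revcomp(genome["chr1"][499:520])
        win, locus, pos = extract_flanks(("chr1", 500, 520, "-"), genome)
        assert win[pos : pos + 21] == tag


class TestEvaluateHairpin:
    def make_candidate(self, stem_len=35, loop_len=15, flank=100, seed=4):
        rng = np.random.default_rng(seed)
        pre = build_precursor(random_seq(rng, stem_len), random_seq(rng, loop_len))
        window = random_seq(rng, flank) + pre + random_seq(rng, flank)
        mature_pos = flank + 2
        c = HairpinCandidate(
            locus=("chr1", 1, len(window), "+"),
            sequence=window,
            mature_seq=window[mature_pos : mature_pos + 21],
            mature_pos=mature_pos,
            window_counts={"L1": 200},
        )
        c.structure, c.mfe = fold(c.sequence)
        return c

    def test_planted_perfect_stem_passes(self):
        c = self.make_candidate()
        assert evaluate_hairpin(c)
        assert c.reasons == []
        assert c.star_seq is not None

    def test_weak_stem_fails_on_mfe(self):
        # an 8-bp stem folds to about -12 kcal/mol under the internal model
        rng = np.random.default_rng(5)
        stem = "GCGCGCGC"
        pre = stem + "AAAA" + revcomp(stem)
        c = HairpinCandidate(
            locus=("chr1", 1, len(pre), "+"), sequence=pre,
            mature_seq=pre[:18], mature_pos=0,
        )
        c.structure, c.mfe = fold(c.sequence)
        assert c.mfe > -20
        assert not evaluate_hairpin(c)
        assert "MFE" in c.reasons

    def test_mature_straddling_loop_fails(self):
        c = self.make_candidate()
        mid = 100 + 35 + 2  # spans the stem/loop boundary
        c.mature_pos = mid
        c.mature_seq = c.sequence[mid : mid + 21]
        assert not evaluate_hairpin(c)
        assert any("straddles" in r or "unpaired" in r for r in c.reasons)

    def test_hairpin_length_window_enforced(self):
        # a 25-bp stem in a 72-nt window cannot reach the 80 nt minimum
        c = self.make_candidate(stem_len=25, loop_len=12, flank=5, seed=6)
        assert not evaluate_hairpin(c)
        assert "hairpin-length" in c.reasons


class TestDuplexMismatches:
    def test_perfect_duplex_with_overhang(self):
        m = "ACGTACGTACGTACGTACGTA"
        assert duplex_mismatches(m, revcomp(m)) == 0

    def test_shifted_duplex_within_tolerance(self):
        m = "ACGTACGTACGTACGTACGTA"
        star = revcomp("GG" + m[:-2])
        assert duplex_mismatches(m, star) <= 2

    def test_unrelated_sequences_heavily_mismatched(self):
        assert duplex_mismatches("A" * 21, "C" * 21) > 4


class TestCallNovel:
    def passing(self, total, star, locus=("chr1", 100, 320, "+")):
        c = HairpinCandidate(
            locus=locus, sequence="N", mature_seq="A" * 21, mature_pos=0,
            window_counts={"L1": total}, star_counts={"L1": star},
        )
        c.passed = True
        return c

    def test_star_once_and_total_over_100_called(self):
        assert len(call_novel([self.passing(150, 1)])) == 1

    def test_total_exactly_100_rejected(self):
        assert call_novel([self.passing(100, 5)]) == []

    def test_no_star_rejected(self):
        assert call_novel([self.passing(500, 0)]) == []

    def test_star_not_required_mode(self):
        assert len(call_novel([self.passing(500, 0)], star_required=False)) == 1

    def test_overlapping_loci_keep_higher_count(self):
        a = self.passing(500, 2, ("chr1", 100, 320, "+"))
        b = self.passing(300, 2, ("chr1", 150, 370, "-"))
        kept = call_novel([a, b])
        assert kept == [a]

    def test_min_total_monotonicity(self):
        cands = [self.passing(t, 1, ("chr1", 1000 * t, 1000 * t + 200, "+"))
                 for t in (120, 300, 800)]
        prev = None
        for mt in (100, 250, 500, 1000):
            n = len(call_novel(cands, min_total=mt))
            if prev is not None:
                assert n <= prev
            prev = n


class TestFamilies:
    def cand(self, mature, total):
        c = HairpinCandidate(
            locus=("chr1", total, total + 200, "+"), sequence=mature,
            mature_seq=mature, mature_pos=0, window_counts={"L1": total},
        )
        c.structure = "." * len(mature)
        return c

    def test_identical_matures_share_family_with_letters(self):
        m = "ACGTACGTACGTACGTACGTA"
        out = group_families([self.cand(m, 500), self.cand(m, 300)])
        names = sorted(x.name for x in out)
        assert names[0].startswith("novel-soy0001a")
        assert names[1].startswith("novel-soy0001b")

    def test_three_mismatches_split_families(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = "TCGTTCGTACGTACGTACGTT"  # 3 substitutions
        out = group_families([self.cand(a, 500), self.cand(b, 300)])
        assert len({x.family_id for x in out}) == 2

    def test_nine_paralogs_lettered_a_through_i(self):
        m = "ACGTACGTACGTACGTACGTA"
        out = group_families([self.cand(m, 1000 - i) for i in range(9)])
        letters = sorted(x.name.split("-")[2][4:-0] or x.name for x in out)
        suffixes = sorted(x.name.replace("novel-soy0001", "").split("-")[0] for x in out)
        assert suffixes == list("abcdefghi")


class TestHostGenes:
    def make_novel(self, chrom, start, strand="+"):
        c = HairpinCandidate(
            locus=(chrom, start, start + 220, strand),
            sequence="N" * 221, mature_seq="A" * 21, mature_pos=100,
        )
        c.structure = "." * 221
        return NovelMirna("novel-soy0001-5p", "novel-soy0001", "5p", c)

    def test_intron_label(self):
        g = GeneModel("GeneX", "chr1", 1000, 4000,
                      "+", [(1000, 1400), (1900, 2400), (3000, 4000)])
        m = self.make_novel("chr1", 1500)
        hosts = locate_in_genes([m], [g])
        assert hosts.iloc[0]["host"] == "GeneX_intr1"

    def test_intergenic(self):
        g = GeneModel("GeneX", "chr1", 1000, 4000, "+", [(1000, 4000)])
        m = self.make_novel("chr1", 8000)
        hosts = locate_in_genes([m], [g])
        assert hosts.iloc[0]["host"] == "intergenic"

    def test_antisense_exon_flagged(self):
        g = GeneModel("GeneX", "chr1", 1000, 4000, "-", [(1000, 1800), (2500, 4000)])
        m = self.make_novel("chr1", 1100, "+")
        hosts = locate_in_genes([m], [g])
        assert hosts.iloc[0]["host"].startswith("GeneX_exon")
        assert hosts.iloc[0]["antisense"]


class TestTruthRecovery:
    def test_perfect_precision_and_recall_on_simulation(
        self, small_sim, small_processed, libs
    ):
        truth = small_sim["truth"]
        tags, hits = small_processed["tags"], small_processed["hits"]
        known_loci = [(p.chrom, p.start, p.end, p.strand) for p in truth.known()]
        ncrna = [(r["chrom"], r["start"], r["end"], r["strand"])
                 for r in truth.ncrna_intervals]
        exons = [(g.chrom, s, e, g.strand) for g in truth.genes for s, e in g.exons]
        novel, cands, hosts = run_novel_analysis(
            tags, hits, truth.genome, known_loci, ncrna, exons, libs, truth.genes
        )
        tm = {p.mature_seq for p in truth.novel()}
        cm = {m.candidate.mature_seq for m in novel}
        assert cm == tm  # precision = recall = 1
        assert (hosts["host"] == "Gene01_intr2").sum() == 1

    def test_decoy_tags_absent_from_candidates(self, small_sim, small_processed, libs):
        truth = small_sim["truth"]
        tags, hits = small_processed["tags"], small_processed["hits"]
        known_loci = [(p.chrom, p.start, p.end, p.strand) for p in truth.known()]
        ncrna = [(r["chrom"], r["start"], r["end"], r["strand"])
                 for r in truth.ncrna_intervals]
        exons = [(g.chrom, s, e, g.strand) for g in truth.genes for s, e in g.exons]
        eligible = filter_annotated(tags, hits, truth.genome, known_loci, ncrna, exons)
        decoy_seqs = {t.sequence for t in truth.decoy_tags}
        assert not (decoy_seqs & set(eligible))
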