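"""Synthetic small RNA-seq study generator with full ground truth.

The generator emulates the structure of a 16-library soybean low-nitrogen
study: a toy genome carrying planted pre-miRNA hairpins (perfect stems, so
any folding backend recovers the hairpin), decoy loci for the novel-miRNA
caller, ncRNA/exon annotations, transcripts with planted target sites, and
one FASTQ library per cell of the 2 genotype x 2 tissue x 2 term x 2
treatment crossing.  Every quantity a downstream stage is expected to
recover is recorded in :class:`SimTruth`.

Read composition per library
----------------------------
Planted mature/star tags and their positionally jittered isoforms receive
expected counts equal to their configured per-library means (stress
libraries scale planted differential-expression effects by ``2**effect``);
the remainder of the sequencing depth is filled with genome-derived noise
reads, a small unmappable-read class, and injected contaminants (low
quality, poly-A, N-containing, too-short) so that cleaning and mapping are
exercised with known expectations.  Counts are multinomial draws at fixed
depth, deterministic per seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soymir import design as design_mod
from soymir.design import comparison_id, library_ids, stress_control_pairs
from soymir.io import write_bed, write_fasta, write_gff
from soymir.seqs import random_seq, revcomp

# read-length distribution of the background (non-miRNA) small RNA pool;
# peaked at 24 nt with a secondary 21 nt mode so that unique tags peak at 24
# while total reads (which include the 21-nt matures) peak at 21.
NOISE_LENGTH_DIST: dict[int, float] = {
    18: 0.03, 19: 0.04, 20: 0.07, 21: 0.20, 22: 0.09, 23: 0.07,
    24: 0.30, 25: 0.07, 26: 0.04, 27: 0.03, 28: 0.03, 29: 0.02, 30: 0.01,
}

JITTER_SHIFTS = [(-2, 0), (-1, 0), (1, 0), (2, 0), (0, -2), (0, -1), (0, 1), (0, 2)]

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimConfig:
    """Study conditions of the bundled simulation.

    Defaults describe the test-scale design: 30 known precursors, 5 planted
    novel hairpins plus decoy loci, 10 planted differential-expression
    effects of |log2 effect| = 2, and 1e5 reads per library.
    """

    seed: int = 42
    n_chrom: int = 2
    chrom_len: int = 200_000
    # loci
    n_known: int = 30
    n_novel: int = 5
    n_decoy_no_star: int = 2
    n_decoy_low_count: int = 2
    n_decoy_non_hairpin: int = 2
    stem_len: int = 35
    loop_len: int = 15
    mature_len: int = 21
    # per-library read composition; expression means are expected counts at
    # reference_depth and scale linearly with the simulated depth
    depth: int = 100_000
    reference_depth: int = 100_000
    jitter_prob: float = 0.1
    star_fraction: float = 0.1
    lowqual_fraction: float = 0.02
    polya_fraction: float = 0.01
    ncontam_fraction: float = 0.005
    short_fraction: float = 0.015
    unmapped_noise_fraction: float = 0.02
    background: bool = True  # False: only planted reads, no noise/contaminants
    adapter3: str = DEFAULT_ADAPTER3
    # expression model (expected reads per library at the configured depth)
    mean_expression: float = 300.0
    expression_sigma: float = 0.6
    de_mean: float = 800.0
    n_de_effects: int = 10
    de_effect: float = 2.0
    n_low_expression: int = 3
    low_expression_mean: float = 8.0
    n_rare: int = 2
    rare_mean: float = 0.15
    novel_mean: float = 300.0
    decoy_low_count_mean: float = 4.0
    decoy_tag_mean: float = 100.0
    # annotation refinement fixtures
    annotated_offset_fraction: float = 0.5
    include_opposite_arm_annotation: bool = True
    include_multi_duplex: bool = False
    include_arm_switch: bool = False
    include_non_unifiable: bool = False
    include_variety_specific: bool = False
    # targets
    n_transcripts: int = 20
    transcript_len: int = 800


@dataclass
class PrecursorTruth:
    precursor_id: str
    family: str
    chrom: str
    start: int  # 1-based inclusive genomic coordinates of the precursor
    end: int
    strand: str
    sequence: str  # 5'->3' precursor sequence (reverse-complemented for '-')
    mature_offset: int  # 0-based start of the mature tag on the precursor
    mature_seq: str
    star_offset: int
    star_seq: str
    kind: str  # known | novel | decoy_no_star | decoy_low_count
    mean: float
    star_fraction: float
    annotated_seq: str | None = None
    annotated_offset: int | None = None
    annotation_class: str | None = None
    arm_switch: bool = False
    non_unifiable: bool = False
    variety_specific: bool = False
    mature2_offset: int | None = None
    mature2_seq: str | None = None
    star2_offset: int | None = None
    star2_seq: str | None = None
    mean2: float = 0.0
    host_gene: str | None = None
    host_feature: str | None = None

    @property
    def mature_id(self) -> str:
        return f"{self.precursor_id}-5p"


@dataclass
class DEEffect:
    mirna_id: str
    comparison: str  # "<stress>_vs_<control>" id
    log2_effect: float


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    position: int  # 1-based start of the site on the transcript
    expected_score: float


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, ascending

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class DecoyTag:
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # ncrna | exon_sense
    mean: float


@dataclass
class SimTruth:
    """Everything a downstream stage is expected to recover."""

    config: SimConfig
    genome: dict[str, str]
    precursors: list[PrecursorTruth]
    de_effects: list[DEEffect]
    target_sites: list[PlantedTarget]
    transcripts: dict[str, str]
    ncrna_intervals: list[dict]
    genes: list[GeneModel]
    decoy_tags: list[DecoyTag]
    library_ids: list[str] = field(default_factory=library_ids)

    def known(self) -> list[PrecursorTruth]:
        return [p for p in self.precursors if p.kind == "known"]

    def novel(self) -> list[PrecursorTruth]:
        return [p for p in self.precursors if p.kind == "novel"]

    def decoys(self) -> list[PrecursorTruth]:
        return [p for p in self.precursors if p.kind.startswith("decoy")]

    def precursor(self, pid: str) -> PrecursorTruth:
        for p in self.precursors:
            if p.precursor_id == pid:
                return p
        raise KeyError(pid)


def generate_genome(seed: int, n_chrom: int = 2, chrom_len: int = 200_000) -> dict[str, str]:
    """Uniform-random toy genome, deterministic per seed."""
    if n_chrom < 1 or chrom_len < 1000:
        raise ValueError("need n_chrom >= 1 and chrom_len >= 1000")
    rng = np.random.default_rng(seed)
    return {f"chr{i + 1}": random_seq(rng, chrom_len) for i in range(n_chrom)}


def build_precursor(stem: str, loop: str) -> str:
    """Perfect-stem hairpin: stem + loop + reverse complement of the stem."""
    return stem + loop + revcomp(stem)


def duplex_positions(stem_len: int, loop_len: int, mature_offset: int, mature_len: int) -> int:
    """0-based star start for a mature at ``mature_offset`` on the 5' arm,
    using the canonical 2-nt 3' overhang of a DCL1 duplex."""
    return 2 * stem_len + loop_len - mature_offset - mature_len + 2


class _Planter:
    """Places loci on the genome without overlap (bounded retries)."""

    def __init__(self, genome: dict[str, bytearray], rng: np.random.Generator, margin: int = 350):
        self.genome = genome
        self.rng = rng
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def place(self, length: int, flank: int = 150) -> tuple[str, int]:
        """Return (chrom, 0-based start) for a free slot, honouring margins."""
        chroms = list(self.genome)
        for _ in range(2000):
            chrom = chroms[int(self.rng.integers(len(chroms)))]
            limit = len(self.genome[chrom]) - length - flank
            start = int(self.rng.integers(flank, limit))
            lo, hi = start - self.margin, start + length + self.margin
            if all(e < lo or s > hi for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((start, start + length))
                return chrom, start
        raise RuntimeError("could not place locus without overlap")

    def write(self, chrom: str, start: int, seq: str) -> None:
        self.genome[chrom][start : start + len(seq)] = seq.encode()


def plant_precursors(
    genome: dict[str, bytearray],
    planter: _Planter,
    n: int,
    stem_len: int,
    loop_len: int,
    mature_len: int,
    rng: np.random.Generator,
    kind: str,
    id_prefix: str,
    families: list[str] | None = None,
) -> list[PrecursorTruth]:
    """Plant ``n`` perfect-stem hairpins; paralogous family members share a
    mature sequence up to one substitution."""
    if stem_len < mature_len - 2:
        raise ValueError("stem too short for the mature duplex")
    out: list[PrecursorTruth] = []
    family_stems: dict[str, tuple[str, int]] = {}
    for i in range(n):
        fam = families[i] if families else f"{id_prefix}{i + 1:03d}"
        if fam in family_stems:
            stem0, a = family_stems[fam]
            stem = list(stem0)
            # one substitution inside the mature region distinguishes paralogs
            pos = a + int(rng.integers(mature_len))
            stem[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[stem[pos]]
            stem = "".join(stem)
        else:
            stem = random_seq(rng, stem_len)
            a = int(rng.integers(2, stem_len - mature_len + 1))
            family_stems[fam] = (stem, a)
        loop = random_seq(rng, loop_len)
        seq = build_precursor(stem, loop)
        b = duplex_positions(stem_len, loop_len, a, mature_len)
        chrom, start0 = planter.place(len(seq))
        strand = "+" if i % 2 == 0 else "-"
        planter.write(chrom, start0, seq if strand == "+" else revcomp(seq))
        letters = "abcdefghij"
        idx = sum(1 for p in out if p.family == fam)
        suffix = letters[idx] if families else ""
        pid = f"{fam}{suffix}" if families else fam
        out.append(
            PrecursorTruth(
                precursor_id=pid,
                family=fam,
                chrom=chrom,
                start=start0 + 1,
                end=start0 + len(seq),
                strand=strand,
                sequence=seq,
                mature_offset=a,
                mature_seq=seq[a : a + mature_len],
                star_offset=b,
                star_seq=seq[b : b + mature_len],
                kind=kind,
                mean=0.0,
                star_fraction=0.1,
            )
        )
    return out


class Simulator:
    """Builds the full synthetic study from a :class:`SimConfig`."""

    def __init__(self, config: SimConfig | None = None):
        self.config = config or SimConfig()
        self.truth: SimTruth | None = None

    # ------------------------------------------------------------------
    def build_truth(self) -> SimTruth:
        cfg = self.config
        # a stream distinct from the genome's, or planted stems would
        # duplicate genome stretches drawn from the same generator state
        rng = np.random.default_rng([cfg.seed, 1])
        genome = {
            k: bytearray(v.encode())
            for k, v in generate_genome(cfg.seed, cfg.n_chrom, cfg.chrom_len).items()
        }
        planter = _Planter(genome, rng)

        # gene models first so an intron can host a novel hairpin
        genes = self._make_genes(planter, rng)

        # known precursor families: a few paralog groups plus singletons
        fams = []
        group_sizes = [3, 2, 2]
        gi = 0
        for size in group_sizes:
            gi += 1
            fams.extend([f"soymir{gi:03d}"] * size)
        while len(fams) < cfg.n_known:
            gi += 1
            fams.append(f"soymir{gi:03d}")
        fams = fams[: cfg.n_known]
        known = plant_precursors(
            genome, planter, cfg.n_known, cfg.stem_len, cfg.loop_len,
            cfg.mature_len, rng, "known", "soymir", families=fams,
        )

        # novel hairpins: the last one is planted inside an intron of gene 1
        novel = self._plant_novel(genome, planter, rng, genes)
        decoys = self._plant_decoys(genome, planter, rng)

        precursors = known + novel + decoys
        self._assign_expression(precursors, rng)
        self._assign_annotations(known, rng)
        self._apply_fixture_flags(known)

        de_effects = self._plant_de_effects(known, rng)
        ncrna, decoy_tags = self._make_ncrna_and_decoy_tags(genome, planter, rng, genes)
        transcripts, target_sites = self._make_transcripts(known, de_effects, rng)

        genome_str = {k: v.decode() for k, v in genome.items()}
        # noise reads are drawn from unplanted genome only: planted loci emit
        # hairpin-derived reads, background degradation comes from elsewhere
        self._occupied = {c: sorted(iv) for c, iv in planter.occupied.items()}
        self.truth = SimTruth(
            config=cfg,
            genome=genome_str,
            precursors=precursors,
            de_effects=de_effects,
            target_sites=target_sites,
            transcripts=transcripts,
            ncrna_intervals=ncrna,
            genes=genes,
            decoy_tags=decoy_tags,
        )
        return self.truth

    # ------------------------------------------------------------------
    def _make_genes(self, planter: _Planter, rng: np.random.Generator) -> list[GeneModel]:
        genes = []
        for gidx in range(3):
            length = 3000
            chrom, start0 = planter.place(length, flank=200)
            s = start0 + 1
            exon_spans = [(0, 400), (900, 1400), (2000, 2400), (2800, 2999)]
            exons = [(s + a, s + b) for a, b in exon_spans]
            genes.append(
                GeneModel(
                    gene_id=f"Gene{gidx + 1:02d}",
                    chrom=chrom,
                    start=s,
                    end=s + length - 1,
                    strand="+" if gidx % 2 == 0 else "-",
                    exons=exons,
                )
            )
        return genes

    def _plant_novel(
        self,
        genome: dict[str, bytearray],
        planter: _Planter,
        rng: np.random.Generator,
        genes: list[GeneModel],
    ) -> list[PrecursorTruth]:
        cfg = self.config
        out = plant_precursors(
            genome, planter, max(cfg.n_novel - 1, 0), cfg.stem_len, cfg.loop_len,
            cfg.mature_len, rng, "novel", "novelpre",
        )
        for i, p in enumerate(out):
            p.precursor_id = f"novelpre{i + 1:03d}"
            p.family = p.precursor_id
        if cfg.n_novel >= 1 and genes:
            # host the last novel hairpin inside intron 2 of gene 1
            g = genes[0]
            intron_s, intron_e = g.introns()[1]
            stem = random_seq(rng, cfg.stem_len)
            loop = random_seq(rng, cfg.loop_len)
            seq = build_precursor(stem, loop)
            a = 2
            b = duplex_positions(cfg.stem_len, cfg.loop_len, a, cfg.mature_len)
            start0 = intron_s - 1 + 120
            planter.write(g.chrom, start0, seq)
            out.append(
                PrecursorTruth(
                    precursor_id=f"novelpre{cfg.n_novel:03d}",
                    family=f"novelpre{cfg.n_novel:03d}",
                    chrom=g.chrom,
                    start=start0 + 1,
                    end=start0 + len(seq),
                    strand="+",
                    sequence=seq,
                    mature_offset=a,
                    mature_seq=seq[a : a + cfg.mature_len],
                    star_offset=b,
                    star_seq=seq[b : b + cfg.mature_len],
                    kind="novel",
                    mean=0.0,
                    star_fraction=cfg.star_fraction,
                    host_gene=g.gene_id,
                    host_feature="intr2",
                )
            )
        return out

    def _plant_decoys(
        self, genome: dict[str, bytearray], planter: _Planter, rng: np.random.Generator
    ) -> list[PrecursorTruth]:
        cfg = self.config
        out: list[PrecursorTruth] = []
        no_star = plant_precursors(
            genome, planter, cfg.n_decoy_no_star, cfg.stem_len, cfg.loop_len,
            cfg.mature_len, rng, "decoy_no_star", "decoyns",
        )
        low = plant_precursors(
            genome, planter, cfg.n_decoy_low_count, cfg.stem_len, cfg.loop_len,
            cfg.mature_len, rng, "decoy_low_count", "decoylc",
        )
        out.extend(no_star + low)
        # expressed non-hairpin loci: a tag with flanks left as random genome
        for i in range(cfg.n_decoy_non_hairpin):
            chrom, start0 = planter.place(cfg.mature_len)
            seq = genome[chrom][start0 : start0 + cfg.mature_len].decode()
            out.append(
                PrecursorTruth(
                    precursor_id=f"decoynh{i + 1:03d}",
                    family=f"decoynh{i + 1:03d}",
                    chrom=chrom,
                    start=start0 + 1,
                    end=start0 + cfg.mature_len,
                    strand="+",
                    sequence=seq,
                    mature_offset=0,
                    mature_seq=seq,
                    star_offset=0,
                    star_seq="",
                    kind="decoy_non_hairpin",
                    mean=0.0,
                    star_fraction=0.0,
                )
            )
        return out

    def _assign_expression(self, precursors: list[PrecursorTruth], rng: np.random.Generator) -> None:
        cfg = self.config
        known = [p for p in precursors if p.kind == "known"]
        for p in known:
            p.mean = float(
                np.exp(rng.normal(np.log(cfg.mean_expression), cfg.expression_sigma))
            )
            p.star_fraction = cfg.star_fraction
        # low-expression and rare fixtures exercise the DE count filters
        n_low, n_rare = cfg.n_low_expression, cfg.n_rare
        if n_low:
            for p in known[len(known) - n_low - n_rare : len(known) - n_rare]:
                p.mean = cfg.low_expression_mean
        if n_rare:
            for p in known[len(known) - n_rare :]:
                p.mean = cfg.rare_mean
        for p in precursors:
            if p.kind == "novel":
                p.mean = cfg.novel_mean
                p.star_fraction = cfg.star_fraction
            elif p.kind == "decoy_no_star":
                p.mean = cfg.novel_mean
                p.star_fraction = 0.0
            elif p.kind == "decoy_low_count":
                p.mean = cfg.decoy_low_count_mean
                p.star_fraction = cfg.star_fraction
            elif p.kind == "decoy_non_hairpin":
                p.mean = cfg.novel_mean
                p.star_fraction = 0.0

    def _assign_annotations(self, known: list[PrecursorTruth], rng: np.random.Generator) -> None:
        """Annotated matures: a configurable fraction shifted by 1 nt, plus one
        opposite-arm annotation, mirroring miRBase disagreement patterns."""
        cfg = self.config
        for i, p in enumerate(known):
            if cfg.include_opposite_arm_annotation and i == 1:
                p.annotated_seq = p.star_seq
                p.annotated_offset = p.star_offset
                p.annotation_class = "opposite-arm"
            elif rng.random() < cfg.annotated_offset_fraction:
                off = p.mature_offset + 1
                p.annotated_seq = p.sequence[off : off + cfg.mature_len]
                p.annotated_offset = off
                p.annotation_class = "shifted-same-arm"
            else:
                p.annotated_seq = p.mature_seq
                p.annotated_offset = p.mature_offset
                p.annotation_class = "identical"

    def _apply_fixture_flags(self, known: list[PrecursorTruth]) -> None:
        cfg = self.config
        idx = 2  # skip the opposite-arm-annotated precursor
        if cfg.include_multi_duplex and len(known) > idx:
            p = known[idx]
            # rebuild with a longer stem carrying a second non-overlapping duplex
            stem_len = 60
            rng = np.random.default_rng(cfg.seed + 17)
            stem = random_seq(rng, stem_len)
            loop = random_seq(rng, cfg.loop_len)
            seq = build_precursor(stem, loop)
            a1, a2 = 2, 30
            p.sequence = seq
            p.end = p.start + len(seq) - 1
            p.mature_offset = a1
            p.mature_seq = seq[a1 : a1 + cfg.mature_len]
            p.star_offset = duplex_positions(stem_len, cfg.loop_len, a1, cfg.mature_len)
            p.star_seq = seq[p.star_offset : p.star_offset + cfg.mature_len]
            p.mature2_offset = a2
            p.mature2_seq = seq[a2 : a2 + cfg.mature_len]
            p.star2_offset = duplex_positions(stem_len, cfg.loop_len, a2, cfg.mature_len)
            p.star2_seq = seq[p.star2_offset : p.star2_offset + cfg.mature_len]
            p.mean2 = 200.0
            p.annotated_seq = p.mature_seq
            p.annotated_offset = a1
            p.annotation_class = "identical"
            idx += 1
        if cfg.include_arm_switch and len(known) > idx:
            known[idx].arm_switch = True
            idx += 1
        if cfg.include_non_unifiable and len(known) > idx:
            known[idx].non_unifiable = True
            idx += 1
        if cfg.include_variety_specific and len(known) > idx:
            known[idx].variety_specific = True

    def _plant_de_effects(self, known: list[PrecursorTruth], rng: np.random.Generator) -> list[DEEffect]:
        cfg = self.config
        pairs = stress_control_pairs()
        eligible = [
            p for p in known
            if not (p.arm_switch or p.non_unifiable or p.variety_specific)
            and p.mean > cfg.low_expression_mean
        ]
        effects = []
        for i in range(min(cfg.n_de_effects, len(eligible))):
            p = eligible[i]
            p.mean = cfg.de_mean
            stress, control = pairs[i % len(pairs)]
            sign = 1.0 if i % 2 == 0 else -1.0
            effects.append(
                DEEffect(
                    mirna_id=p.mature_id,
                    comparison=comparison_id(stress, control),
                    log2_effect=sign * cfg.de_effect,
                )
            )
        return effects

    def _make_ncrna_and_decoy_tags(
        self,
        genome: dict[str, bytearray],
        planter: _Planter,
        rng: np.random.Generator,
        genes: list[GeneModel],
    ) -> tuple[list[dict], list[DecoyTag]]:
        cfg = self.config
        ncrna = []
        tags = []
        # five ncRNA intervals; the first hosts an expressed decoy tag
        for i in range(5):
            chrom, start0 = planter.place(120)
            ncrna.append(
                {"chrom": chrom, "start": start0 + 1, "end": start0 + 120,
                 "name": f"rRNA{i + 1}", "strand": "+"}
            )
        r = ncrna[0]
        s0 = r["start"] - 1 + 40
        seq = genome[r["chrom"]][s0 : s0 + cfg.mature_len].decode()
        tags.append(
            DecoyTag(seq, r["chrom"], s0 + 1, s0 + cfg.mature_len, "+", "ncrna", cfg.decoy_tag_mean)
        )
        # an expressed tag on the sense strand of an exon of gene 2
        g = genes[1]
        ex_s, _ = g.exons[1]
        s0 = ex_s - 1 + 50
        seq = genome[g.chrom][s0 : s0 + cfg.mature_len].decode()
        if g.strand == "-":
            seq = revcomp(seq)
        tags.append(
            DecoyTag(seq, g.chrom, s0 + 1, s0 + cfg.mature_len, g.strand, "exon_sense", cfg.decoy_tag_mean)
        )
        return ncrna, tags

    def _make_transcripts(
        self,
        known: list[PrecursorTruth],
        de_effects: list[DEEffect],
        rng: np.random.Generator,
    ) -> tuple[dict[str, str], list[PlantedTarget]]:
        cfg = self.config
        transcripts = {
            f"Trans{i + 1:03d}": random_seq(rng, cfg.transcript_len)
            for i in range(cfg.n_transcripts)
        }
        sites: list[PlantedTarget] = []
        de_mirnas = []
        seen = set()
        for e in de_effects:
            if e.mirna_id not in seen:
                seen.add(e.mirna_id)
                de_mirnas.append(e.mirna_id)
        by_id = {p.mature_id: p for p in known}
        tids = list(transcripts)
        for i, mid in enumerate(de_mirnas[:6]):
            mat = by_id[mid].mature_seq
            site = revcomp(mat)
            tid = tids[i]
            pos0 = 100 + 37 * i
            score = 0.0
            if i == 1:
                # introduce a single G:U wobble outside miRNA positions 10-11:
                # at a miRNA G, replace the paired target C with T
                gpos = next(
                    j for j in range(len(mat)) if mat[j] == "G" and not 9 <= j <= 10
                )
                sitelist = list(site)
                sitelist[len(mat) - 1 - gpos] = "T"
                site = "".join(sitelist)
                score = 0.5
            seq = transcripts[tid]
            transcripts[tid] = seq[:pos0] + site + seq[pos0 + len(site):]
            sites.append(PlantedTarget(mid, tid, pos0 + 1, score))
        # one transcript hit by two distinct miRNAs
        if len(de_mirnas) >= 2:
            tid = tids[len(de_mirnas[:6])]
            seq = transcripts[tid]
            for j, mid in enumerate(de_mirnas[:2]):
                site = revcomp(by_id[mid].mature_seq)
                pos0 = 120 + j * 200
                seq = seq[:pos0] + site + seq[pos0 + len(site):]
                sites.append(PlantedTarget(mid, tid, pos0 + 1, 0.0))
            transcripts[tid] = seq
        return transcripts, sites

    # ------------------------------------------------------------------
    # library simulation
    # ------------------------------------------------------------------
    def species_weights(self) -> tuple[list[tuple[str, str, str]], np.ndarray]:
        """Planted read species and their expected per-library counts.

        Returns (species, weights) where species is a list of
        (sequence, class, precursor_or_tag_id) and weights has shape
        (n_species, 16) in library order.
        """
        truth = self.truth
        assert truth is not None, "call build_truth() first"
        cfg = self.config
        libs = truth.library_ids
        effects = {(e.mirna_id, e.comparison): e.log2_effect for e in truth.de_effects}
        stress_of = {comparison_id(s, c): s for s, c in stress_control_pairs()}

        species: list[tuple[str, str, str]] = []
        rows: list[np.ndarray] = []

        def lib_scales(p: PrecursorTruth) -> np.ndarray:
            scale = np.ones(len(libs))
            for (mid, comp), eff in effects.items():
                if mid == p.mature_id:
                    stress = stress_of[comp]
                    scale[libs.index(stress)] *= 2.0 ** eff
            return scale

        # arm-switch fixture: the shoot libraries carry the switched arm
        switch_mask = np.array(
            [design_mod.make_design()[i].tissue == "shoot" for i in range(len(libs))]
        )

        for p in truth.precursors:
            if p.kind == "decoy_non_hairpin":
                species.append((p.mature_seq, "decoy_non_hairpin", p.precursor_id))
                rows.append(np.full(len(libs), p.mean))
                continue
            scale = lib_scales(p)
            w_m = p.mean * scale
            w_s = p.mean * p.star_fraction * scale
            if p.arm_switch:
                w_m, w_s = np.where(switch_mask, w_s, w_m), np.where(switch_mask, w_m, w_s)
            if p.non_unifiable or p.variety_specific:
                # two competing 5'-arm variants with large count swings
                alt_off = p.mature_offset + 4
                alt_seq = p.sequence[alt_off : alt_off + len(p.mature_seq)]
                if p.non_unifiable:
                    top_a = np.arange(len(libs)) % 2 == 0
                else:
                    top_a = np.array(
                        [design_mod.make_design()[i].genotype == "tolerant" for i in range(len(libs))]
                    )
                w_a = np.where(top_a, p.mean, p.mean / 50.0)
                w_b = np.where(top_a, p.mean / 50.0, p.mean)
                species.append((p.mature_seq, "mature", p.precursor_id))
                rows.append(w_a)
                species.append((alt_seq, "variant", p.precursor_id))
                rows.append(w_b)
                species.append((p.star_seq, "star", p.precursor_id))
                rows.append(p.mean * p.star_fraction * np.ones(len(libs)))
                continue
            jp = cfg.jitter_prob
            species.append((p.mature_seq, "mature", p.precursor_id))
            rows.append(w_m * (1.0 - jp))
            if jp > 0:
                for ds, de in JITTER_SHIFTS:
                    s = p.mature_offset + ds
                    e = p.mature_offset + len(p.mature_seq) + de
                    if s < 0 or e > len(p.sequence):
                        continue
                    species.append((p.sequence[s:e], "isoform", p.precursor_id))
                    rows.append(w_m * jp / len(JITTER_SHIFTS))
            if p.star_fraction > 0:
                species.append((p.star_seq, "star", p.precursor_id))
                rows.append(w_s)
            if p.mature2_seq:
                w2 = np.full(len(libs), p.mean2)
                species.append((p.mature2_seq, "mature2", p.precursor_id))
                rows.append(w2)
                species.append((p.star2_seq, "star2", p.precursor_id))
                rows.append(w2 * p.star_fraction)
        for t in truth.decoy_tags:
            species.append((t.sequence, f"decoytag_{t.kind}", t.kind))
            rows.append(np.full(len(libs), t.mean))
        scale = cfg.depth / cfg.reference_depth
        return species, np.vstack(rows) * scale

    def expected_mature_count(self, pid: str, lib: str) -> float:
        """Expected +/-2-window mature count (mature + jittered isoforms)."""
        truth = self.truth
        p = truth.precursor(pid)
        scale = 1.0
        stress_of = {s: comparison_id(s, c) for s, c in stress_control_pairs()}
        for e in truth.de_effects:
            if e.mirna_id == p.mature_id and stress_of.get(lib) == e.comparison:
                scale *= 2.0 ** e.log2_effect
        return p.mean * scale * self.config.depth / self.config.reference_depth

    def simulate_libraries(self, outdir: str | os.PathLike, seed: int | None = None) -> dict[str, str]:
        """Write one FASTQ per library; returns {library_id: path}.

        The multinomial draw per library is deterministic for a seed.
        """
        truth = self.truth or self.build_truth()
        cfg = self.config
        if len(set(truth.library_ids)) != 16:
            raise ValueError("design must contain exactly 16 unique library ids")
        base_seed = cfg.seed if seed is None else seed
        os.makedirs(outdir, exist_ok=True)
        species, weights = self.species_weights()
        libs = truth.library_ids
        chroms = list(truth.genome)
        chrom_seqs = [truth.genome[c] for c in chroms]
        # prefix sums of planted coverage for O(1) rejection of noise draws
        margin = 30
        forbidden = []
        for c in chroms:
            mask = np.zeros(len(truth.genome[c]) + 1, dtype=np.int32)
            for s, e in getattr(self, "_occupied", {}).get(c, ()):
                mask[max(s - margin, 0)] += 1
                mask[min(e + margin, len(truth.genome[c]))] -= 1
            forbidden.append(np.cumsum(mask) > 0)
        noise_lens = np.array(list(NOISE_LENGTH_DIST))
        noise_p = np.array(list(NOISE_LENGTH_DIST.values()))
        noise_p = noise_p / noise_p.sum()
        adapter = cfg.adapter3
        paths = {}
        for li, lib in enumerate(libs):
            rng = np.random.default_rng([base_seed, li])
            w = weights[:, li]
            depth = cfg.depth
            if cfg.background:
                n_lowq = int(round(cfg.lowqual_fraction * depth))
                n_polya = int(round(cfg.polya_fraction * depth))
                n_ncont = int(round(cfg.ncontam_fraction * depth))
                n_short = int(round(cfg.short_fraction * depth))
                n_unmap = int(round(cfg.unmapped_noise_fraction * depth))
            else:
                n_lowq = n_polya = n_ncont = n_short = n_unmap = 0
            budget = depth - n_lowq - n_polya - n_ncont - n_short - n_unmap
            planted_total = w.sum()
            if cfg.background and planted_total > budget:
                raise ValueError(
                    "planted expression exceeds the library depth; "
                    "raise depth or lower expression means"
                )
            n_noise = int(round(budget - planted_total)) if cfg.background else 0
            # planted counts: multinomial over species at their exact expected
            # proportions within the planted+noise budget
            probs = np.concatenate([w, [n_noise]]) / (planted_total + n_noise)
            counts = rng.multinomial(budget, probs)
            planted_counts, noise_count = counts[:-1], counts[-1]

            lines: list[str] = []
            serial = 0

            def emit(seq: str, qual_char: str = "I", n: int = 1) -> None:
                nonlocal serial
                read = seq + adapter
                q = qual_char * len(read)
                for _ in range(n):
                    serial += 1
                    lines.append(f"@{lib}_{serial}\n{read}\n+\n{q}\n")

            for (seq, _cls, _pid), c in zip(species, planted_counts):
                if c:
                    emit(seq, n=int(c))
            # genome-derived noise reads
            emitted = 0
            while emitted < noise_count:
                batch = noise_count - emitted
                ci = rng.integers(0, len(chroms), size=batch)
                ls = noise_lens[rng.choice(len(noise_lens), size=batch, p=noise_p)]
                st = rng.random(batch)
                rev = rng.random(batch) < 0.5
                for k in range(batch):
                    cs = chrom_seqs[ci[k]]
                    L = int(ls[k])
                    pos = int(st[k] * (len(cs) - L))
                    if forbidden[ci[k]][pos : pos + L].any():
                        continue  # re-drawn in the next batch
                    frag = cs[pos : pos + L]
                    emit(revcomp(frag) if rev[k] else frag)
                    emitted += 1
            for _ in range(n_unmap):
                emit(random_seq(rng, 21))
            for _ in range(n_lowq):
                emit(random_seq(rng, 21), qual_char="#")
            for _ in range(n_polya):
                emit("A" * 24)
            for _ in range(n_ncont):
                s = list(random_seq(rng, 21))
                s[10] = "N"
                emit("".join(s))
            for _ in range(n_short):
                emit(random_seq(rng, int(rng.integers(15, 18))))
            path = os.path.join(outdir, f"{lib}.fastq")
            with open(path, "w") as fh:
                fh.writelines(lines)
            paths[lib] = path
        return paths

    # ------------------------------------------------------------------
    def simulate_ct_table(
        self,
        seed: int | None = None,
        reference_sds: tuple[float, ...] = (0.05, 0.08, 0.5, 0.9, 1.3),
        target_sd: float = 0.1,
        n_replicates: int = 3,
    ) -> tuple[pd.DataFrame, list[str]]:
        """Tidy qPCR Ct table over the 16 libraries with triplicates.

        Candidate reference genes ref1..refN carry flat expression with the
        given per-gene Ct noise (the first two are the stable pair);
        target genes are the planted differential-expression miRNAs, whose
        expression follows the planted per-library means so that qPCR
        ratios and sequencing fold changes derive from the same truth.
        Returns (table, reference gene names).
        """
        truth = self.truth or self.build_truth()
        rng = np.random.default_rng(
            [self.config.seed if seed is None else seed, 7]
        )
        libs = truth.library_ids
        rows = []
        refs = [f"ref{i + 1}" for i in range(len(reference_sds))]
        for gene, sd in zip(refs, reference_sds):
            base = rng.uniform(20, 24)
            for lib in libs:
                for rep in range(n_replicates):
                    rows.append(
                        {"gene": gene, "sample": lib, "replicate": rep,
                         "ct": base + rng.normal(0, sd)}
                    )
        target_ids = []
        for e in truth.de_effects:
            if e.mirna_id not in target_ids:
                target_ids.append(e.mirna_id)
        for mid in target_ids:
            pid = mid.rsplit("-", 1)[0]
            base = rng.uniform(20, 26)
            for lib in libs:
                q = self.expected_mature_count(pid, lib)
                ct = base - np.log2(max(q, 1e-6))
                for rep in range(n_replicates):
                    rows.append(
                        {"gene": mid, "sample": lib, "replicate": rep,
                         "ct": ct + rng.normal(0, target_sd)}
                    )
        return pd.DataFrame(rows), refs

    # ------------------------------------------------------------------
    # file export of the reference inputs and truth tables
    # ------------------------------------------------------------------
    def write_reference(self, outdir: str | os.PathLike) -> dict[str, str]:
        truth = self.truth or self.build_truth()
        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def p(name: str) -> str:
            paths[name] = os.path.join(outdir, name)
            return paths[name]

        write_fasta(p("genome.fa"), truth.genome.items())
        known = truth.known()
        write_fasta(p("known_precursors.fa"), [(k.precursor_id, k.sequence) for k in known])
        write_fasta(
            p("annotated_matures.fa"),
            [(k.mature_id, k.annotated_seq) for k in known if k.annotated_seq],
        )
        write_gff(
            p("known_precursors.gff3"),
            [
                {
                    "seqid": k.chrom, "source": "soymir_sim", "type": "miRNA_primary_transcript",
                    "start": k.start, "end": k.end, "score": ".", "strand": k.strand,
                    "phase": ".", "attributes": f"ID={k.precursor_id}",
                }
                for k in known
            ],
        )
        write_bed(p("ncrna.bed"), truth.ncrna_intervals)
        gene_rows = []
        for g in truth.genes:
            gene_rows.append(
                {"seqid": g.chrom, "source": "soymir_sim", "type": "gene", "start": g.start,
                 "end": g.end, "score": ".", "strand": g.strand, "phase": ".",
                 "attributes": f"ID={g.gene_id}"}
            )
            for i, (s, e) in enumerate(g.exons):
                gene_rows.append(
                    {"seqid": g.chrom, "source": "soymir_sim", "type": "exon", "start": s,
                     "end": e, "score": ".", "strand": g.strand, "phase": ".",
                     "attributes": f"ID={g.gene_id}.exon{i + 1};Parent={g.gene_id}"}
                )
        write_gff(p("genes.gff3"), gene_rows)
        write_fasta(p("transcripts.fa"), truth.transcripts.items())

        pd.DataFrame(
            [
                {
                    "precursor_id": x.precursor_id, "family": x.family, "kind": x.kind,
                    "chrom": x.chrom, "start": x.start, "end": x.end, "strand": x.strand,
                    "mature_seq": x.mature_seq, "mature_offset": x.mature_offset,
                    "star_seq": x.star_seq, "star_offset": x.star_offset,
                    "mean": x.mean, "star_fraction": x.star_fraction,
                    "annotation_class": x.annotation_class,
                }
                for x in truth.precursors
            ]
        ).to_csv(p("truth_precursors.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [{"mirna_id": e.mirna_id, "comparison": e.comparison, "log2_effect": e.log2_effect}
             for e in truth.de_effects]
        ).to_csv(p("truth_de_effects.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [{"mirna_id": t.mirna_id, "transcript_id": t.transcript_id,
              "position": t.position, "expected_score": t.expected_score}
             for t in truth.target_sites]
        ).to_csv(p("truth_targets.tsv"), sep="\t", index=False)
        return paths
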