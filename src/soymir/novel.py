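"""Novel miRNA prediction from unannotated genome-mapped tags.

Candidate loci are built from mapped tags that survive annotation filtering
(known precursors and ncRNA on either strand, exons on the sense strand
only, so intronic and antisense loci remain discoverable).  Tag hits within
a merge distance are clustered into loci, +/-100 nt flanks are extracted,
the window is folded, and the hairpin is screened against plant miRNA
annotation criteria.  A surviving candidate is called a novel miRNA iff its
miRNA* was detected in at least one library and its total mature window
count across the 16 libraries exceeds 100 reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soymir.fold import dotbracket_to_pairs, fold
from soymir.seqs import gc_pairable, revcomp

DEFAULT_FLANK = 100
DEFAULT_MERGE_DIST = 200
DEFAULT_MFE_CUTOFF = -20.0
DEFAULT_MIN_TOTAL = 100
DEFAULT_MIN_CANDIDATE_COUNT = 20  # minimum total count of a seed tag for a locus
HAIRPIN_LEN_RANGE = (80, 376)
MATURE_LEN_RANGE = (18, 25)
MAX_DUPLEX_MISMATCH = 4
MAX_DUPLEX_SHIFT = 2
FAMILY_MAX_MISMATCH = 2
FAMILY_MAX_SHIFT = 2


@dataclass
class HairpinCandidate:
    locus: tuple[str, int, int, str]  # chrom, start, end (1-based incl), strand
    sequence: str  # extracted window, tag reads 5'->3'
    structure: str = ""
    mfe: float = 0.0
    mature_seq: str = ""
    mature_pos: int = 0  # 0-based start of the mature tag in the window
    star_seq: str | None = None
    window_counts: dict = field(default_factory=dict)
    star_counts: dict = field(default_factory=dict)
    passed: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(sum(self.window_counts.values()))

    @property
    def star_total(self) -> int:
        return int(sum(self.star_counts.values()))


@dataclass
class NovelMirna:
    name: str
    family_id: str
    arm: str
    candidate: HairpinCandidate


def _prefix_masks(genome: dict[str, str], intervals) -> dict[str, np.ndarray]:
    """Per-chromosome prefix-sum arrays for O(1) interval-overlap queries.

    ``intervals`` yields (chrom, start, end) in 1-based inclusive coords.
    """
    masks = {c: np.zeros(len(s) + 1, dtype=bool) for c, s in genome.items()}
    tmp = {c: np.zeros(len(s) + 1, dtype=bool) for c, s in genome.items()}
    for chrom, start, end in intervals:
        tmp[chrom][start : end + 1] = True
    return {c: np.concatenate([[0], np.cumsum(tmp[c][1:])]) for c in tmp}


def _overlaps(pref: np.ndarray, start: int, end: int) -> bool:
    return bool(pref[min(end, len(pref) - 1)] - pref[max(start - 1, 0)] > 0)


def filter_annotated(
    tags: pd.DataFrame,
    hits: dict[str, list[tuple[str, int, int, str]]],
    genome: dict[str, str],
    known_loci,
    ncrna,
    exons,
) -> list[str]:
    """Tags eligible for novel-miRNA discovery.

    A tag is removed iff any genome hit overlaps a known precursor locus
    (either strand), an ncRNA feature (either strand), or an exon on the
    sense strand only.  Unmapped tags are dropped.  Interval arguments yield
    (chrom, start, end[, strand]) tuples, 1-based inclusive.
    """
    for iv in list(known_loci) + list(ncrna) + list(exons):
        if iv[2] < iv[1]:
            raise ValueError(f"malformed interval {iv}")
    any_strand = _prefix_masks(
        genome, [(c, s, e) for c, s, e, *_ in list(known_loci) + list(ncrna)]
    )
    exon_by_strand = {
        st: _prefix_masks(genome, [(c, s, e) for c, s, e, stt in exons if stt == st])
        for st in ("+", "-")
    }
    keep = []
    for seq in tags.index:
        hs = hits.get(seq) or []
        if not hs:
            continue
        removed = False
        for chrom, s, e, strand in hs:
            if _overlaps(any_strand[chrom], s, e) or _overlaps(
                exon_by_strand[strand][chrom], s, e
            ):
                removed = True
                break
        if not removed:
            keep.append(seq)
    return keep


def extract_flanks(
    hit: tuple[str, int, int, str], genome: dict[str, str], flank: int = DEFAULT_FLANK
) -> tuple[str, tuple[str, int, int, str], int]:
    """Window of +/-``flank`` nt around a tag hit, clipped at chromosome ends.

    Minus-strand hits are reverse-complemented so the tag reads 5'->3' in
    the returned window.  Returns (window sequence, window locus, 0-based
    tag position within the window).
    """
    chrom, s, e, strand = hit
    seq = genome[chrom]
    ws = max(s - flank, 1)
    we = min(e + flank, len(seq))
    window = seq[ws - 1 : we]
    if strand == "-":
        window = revcomp(window)
        tag_pos = we - e
    else:
        tag_pos = s - ws
    return window, (chrom, ws, we, strand), tag_pos


def _partners(structure: str) -> dict[int, int]:
    out = {}
    for i, j in dotbracket_to_pairs(structure):
        out[i] = j
        out[j] = i
    return out


def duplex_mismatches(mature: str, star: str) -> int:
    """Ungapped duplex mismatch count between a mature and a star tag.

    The star is aligned antiparallel to the mature at shifts up to +/-2 nt
    (the 3' overhang tolerance); WC and G:U pairs count as matched, anything
    else as a mismatch, and unaligned overhang positions are ignored.
    Returns the minimum over shifts.
    """
    rc = revcomp(star)
    best = len(mature)
    for shift in range(-MAX_DUPLEX_SHIFT, MAX_DUPLEX_SHIFT + 1):
        mm = 0
        n = 0
        for i, c in enumerate(mature):
            k = i + shift
            if 0 <= k < len(rc):
                n += 1
                # rc aligns the star antiparallel; equality means WC pairing
                if c != rc[k] and not gc_pairable(c, revcomp(rc[k])):
                    mm += 1
        if n >= min(len(mature), len(star)) - MAX_DUPLEX_SHIFT:
            best = min(best, mm)
    return best


def evaluate_hairpin(
    cand: HairpinCandidate,
    mfe_cutoff: float = DEFAULT_MFE_CUTOFF,
    hairpin_range: tuple[int, int] = HAIRPIN_LEN_RANGE,
    mature_range: tuple[int, int] = MATURE_LEN_RANGE,
) -> bool:
    """Screen a folded candidate against plant miRNA hairpin criteria.

    Pass requires: MFE <= cutoff; mature length 18-25 nt lying entirely on
    one arm (its paired partners all on one side, no self-pairing inside
    the footprint); a mature/star duplex with <= 4 mismatches; and the
    enclosing hairpin trimmed from the window within the accepted length
    range.  Failure reasons accumulate on the candidate.
    """
    reasons = []
    if cand.mfe > mfe_cutoff:
        reasons.append("MFE")
    m_lo, m_hi = cand.mature_pos, cand.mature_pos + len(cand.mature_seq)
    if not mature_range[0] <= len(cand.mature_seq) <= mature_range[1]:
        reasons.append("mature-length")
    partners = _partners(cand.structure)
    part = [partners[i] for i in range(m_lo, m_hi) if i in partners]
    if not part:
        reasons.append("mature-unpaired")
    else:
        if any(m_lo <= p < m_hi for p in part):
            reasons.append("mature-straddles-loop")
        elif not (all(p >= m_hi for p in part) or all(p < m_lo for p in part)):
            reasons.append("mature-straddles-loop")
        else:
            star_lo, star_hi = min(part), max(part) + 1
            star_seq = cand.sequence[star_lo:star_hi]
            cand.star_seq = star_seq
            if duplex_mismatches(cand.mature_seq, star_seq) > MAX_DUPLEX_MISMATCH:
                reasons.append("duplex-mismatches")
            # enclosing hairpin: outermost pair bracketing the mature footprint
            enclosing = [
                (i, partners[i])
                for i in partners
                if i < partners[i] and i <= m_lo and partners[i] >= m_hi - 1
            ]
            if not enclosing:
                reasons.append("no-enclosing-stem")
            else:
                i0 = min(e[0] for e in enclosing)
                j0 = max(e[1] for e in enclosing)
                span = j0 - i0 + 1
                if not hairpin_range[0] <= span <= hairpin_range[1]:
                    reasons.append("hairpin-length")
    cand.reasons = reasons
    cand.passed = not reasons
    return cand.passed


def build_candidates(
    tags: pd.DataFrame,
    hits: dict[str, list],
    eligible: list[str],
    genome: dict[str, str],
    libs: list[str],
    flank: int = DEFAULT_FLANK,
    merge_dist: int = DEFAULT_MERGE_DIST,
    min_candidate_count: int = DEFAULT_MIN_CANDIDATE_COUNT,
    window: int = 2,
) -> tuple[list[HairpinCandidate], pd.DataFrame]:
    """Cluster eligible tag hits into loci and fold candidate windows.

    Seeds are tags whose total count reaches ``min_candidate_count``
    (a Mireap-style minimum locus depth); hits within ``merge_dist`` are
    merged so isoform stacks yield one locus.  The most abundant tag of a
    locus becomes the mature candidate; window counts aggregate same-strand
    tags starting within +/-``window`` nt of it.
    """
    seeds = [s for s in eligible if tags.loc[s, "total"] >= min_candidate_count]
    entries = []
    for seq in eligible:
        for chrom, s, e, strand in hits[seq]:
            entries.append((chrom, strand, s, e, seq))
    frame = pd.DataFrame(entries, columns=["chrom", "strand", "start", "end", "sequence"])
    seed_rows = frame[frame["sequence"].isin(set(seeds))].sort_values(["chrom", "strand", "start"])
    cands: list[HairpinCandidate] = []
    for (chrom, strand), grp in seed_rows.groupby(["chrom", "strand"]):
        cluster: list[pd.Series] = []
        last_end = None
        for _, row in grp.iterrows():
            if last_end is not None and row["start"] - last_end > merge_dist:
                cands.append(
                    _locus_candidate(cluster, frame, tags, genome, libs, flank, window)
                )
                cluster = []
            cluster.append(row)
            last_end = max(last_end or 0, row["end"])
        if cluster:
            cands.append(_locus_candidate(cluster, frame, tags, genome, libs, flank, window))
    for c in cands:
        c.structure, c.mfe = fold(c.sequence)
    return cands, frame


def _locus_candidate(cluster, frame, tags, genome, libs, flank, window) -> HairpinCandidate:
    best = max(cluster, key=lambda r: tags.loc[r["sequence"], "total"])
    hit = (best["chrom"], int(best["start"]), int(best["end"]), best["strand"])
    win_seq, locus, tag_pos = extract_flanks(hit, genome, flank)
    # same-strand tags starting within the aggregation window of the mature
    near = frame[
        (frame["chrom"] == hit[0])
        & (frame["strand"] == hit[3])
        & ((frame["start"] - hit[1]).abs() <= window)
    ].drop_duplicates("sequence")
    counts = {l: int(tags.loc[near["sequence"], l].sum()) for l in libs}
    return HairpinCandidate(
        locus=locus,
        sequence=win_seq,
        mature_seq=best["sequence"],
        mature_pos=tag_pos,
        window_counts=counts,
    )


def attach_star_counts(
    cand: HairpinCandidate,
    hit_frame: pd.DataFrame,
    tags: pd.DataFrame,
    libs: list[str],
    tol: int = 2,
) -> None:
    """Per-library counts of sequenced tags matching the predicted star.

    A star observation is any mapped tag on the candidate strand whose
    footprint lies within ``tol`` nt of the predicted star segment.
    ``hit_frame`` holds the eligible tag hits (chrom, strand, start, end,
    sequence).
    """
    if cand.star_seq is None:
        cand.star_counts = {l: 0 for l in libs}
        return
    chrom, ws, we, strand = cand.locus
    star_off = cand.sequence.find(cand.star_seq)
    if strand == "+":
        g_start = ws + star_off
    else:
        g_start = we - star_off - len(cand.star_seq) + 1
    g_end = g_start + len(cand.star_seq) - 1
    sel = hit_frame[
        (hit_frame["chrom"] == chrom)
        & (hit_frame["strand"] == strand)
        & ((hit_frame["start"] - g_start).abs() <= tol)
        & ((hit_frame["end"] - g_end).abs() <= tol + MAX_DUPLEX_SHIFT)
    ].drop_duplicates("sequence")
    cand.star_counts = {l: int(tags.loc[sel["sequence"], l].sum()) for l in libs}


def call_novel(
    candidates: list[HairpinCandidate],
    min_total: int = DEFAULT_MIN_TOTAL,
    star_required: bool = True,
) -> list[HairpinCandidate]:
    """Apply the two critical novel-miRNA criteria and deduplicate loci.

    Kept iff the star was sequenced in at least one library (when required)
    and the 16-library total of mature window counts is strictly over
    ``min_total``.  Overlapping loci keep the higher-count candidate.
    """
    passing = []
    for c in candidates:
        if not c.passed:
            continue
        if star_required and c.star_total < 1:
            continue
        if c.total <= min_total:
            continue
        passing.append(c)
    passing.sort(key=lambda c: (-c.total, c.locus))
    kept: list[HairpinCandidate] = []
    for c in passing:
        chrom, s, e, strand = c.locus
        clash = any(
            k.locus[0] == chrom and not (e < k.locus[1] or s > k.locus[2])
            for k in kept
        )
        if not clash:
            kept.append(c)
    return kept


def _family_related(a: str, b: str) -> bool:
    """Matures within 2 mismatches allowing end shifts up to 2 nt."""
    for shift in range(-FAMILY_MAX_SHIFT, FAMILY_MAX_SHIFT + 1):
        mm = 0
        overlap = 0
        for i in range(len(a)):
            k = i + shift
            if 0 <= k < len(b):
                overlap += 1
                if a[i] != b[k]:
                    mm += 1
        if overlap >= max(len(a), len(b)) - FAMILY_MAX_SHIFT and mm <= FAMILY_MAX_MISMATCH:
            return True
    return False


def group_families(called: list[HairpinCandidate]) -> list[NovelMirna]:
    """Name called candidates and group paralogs into lettered families.

    Candidates are numbered in descending total-count order
    (novel-soy0001, ...); single-linkage clustering of mature sequences
    (<= 2 mismatches, end shifts <= 2 nt) defines families, and families of
    two or more loci carry letters a, b, ... ordered by descending count.
    """
    n = len(called)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _family_related(called[i].mature_seq, called[j].mature_seq):
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    order = sorted(range(n), key=lambda i: -called[i].total)
    family_num: dict[int, int] = {}
    num = 0
    for i in order:
        root = find(i)
        if root not in family_num:
            num += 1
            family_num[root] = num
    out: list[NovelMirna] = []
    for root, members in clusters.items():
        fam = family_num[root]
        members = sorted(members, key=lambda i: -called[i].total)
        letters = "abcdefghijklmnopqrstuvwxyz"
        for li, i in enumerate(members):
            c = called[i]
            letter = letters[li] if len(members) > 1 else ""
            arm = _mature_arm(c)
            out.append(
                NovelMirna(
                    name=f"novel-soy{fam:04d}{letter}-{arm}",
                    family_id=f"novel-soy{fam:04d}",
                    arm=arm,
                    candidate=c,
                )
            )
    out.sort(key=lambda m: (m.family_id, m.name))
    return out


def _mature_arm(cand: HairpinCandidate) -> str:
    partners = _partners(cand.structure)
    part = [
        partners[i]
        for i in range(cand.mature_pos, cand.mature_pos + len(cand.mature_seq))
        if i in partners
    ]
    if part and all(p >= cand.mature_pos + len(cand.mature_seq) for p in part):
        return "5p"
    return "3p"


def locate_in_genes(novel: list[NovelMirna], genes) -> pd.DataFrame:
    """Host-gene table: intergenic, or intr<k>/exon<k> of the host gene.

    Exon/intron numbering follows the gene's strand; loci antisense to
    their host gene carry an ``antisense`` flag.
    """
    rows = []
    for m in novel:
        chrom, s, e, strand = m.candidate.locus
        # the mature tag, not the flanked window, defines the locus position
        off = m.candidate.mature_pos
        if strand == "+":
            ms, me = s + off, s + off + len(m.candidate.mature_seq) - 1
        else:
            me = e - off
            ms = me - len(m.candidate.mature_seq) + 1
        label, anti = "intergenic", False
        for g in genes:
            if g.chrom != chrom or not (g.start <= ms and me <= g.end):
                continue
            anti = strand != g.strand
            exons = g.exons if g.strand == "+" else g.exons[::-1]
            label = None
            for k, (xs, xe) in enumerate(exons, start=1):
                if ms <= xe and me >= xs:
                    label = f"{g.gene_id}_exon{k}"
                    break
            if label is None:
                introns = g.introns() if g.strand == "+" else g.introns()[::-1]
                for k, (is_, ie) in enumerate(introns, start=1):
                    if ms <= ie and me >= is_:
                        label = f"{g.gene_id}_intr{k}"
                        break
            label = label or "intergenic"
            break
        rows.append(
            {"name": m.name, "chrom": chrom, "start": ms, "end": me,
             "strand": strand, "host": label, "antisense": anti}
        )
    return pd.DataFrame(rows)


def run_novel_analysis(
    tags: pd.DataFrame,
    hits: dict[str, list],
    genome: dict[str, str],
    known_loci,
    ncrna,
    exons,
    libs: list[str],
    genes=(),
    flank: int = DEFAULT_FLANK,
    merge_dist: int = DEFAULT_MERGE_DIST,
    mfe_cutoff: float = DEFAULT_MFE_CUTOFF,
    min_total: int = DEFAULT_MIN_TOTAL,
    min_candidate_count: int = DEFAULT_MIN_CANDIDATE_COUNT,
    star_required: bool = True,
) -> tuple[list[NovelMirna], list[HairpinCandidate], pd.DataFrame]:
    """Full novel stage; returns (called miRNAs, all candidates, host table)."""
    eligible = filter_annotated(tags, hits, genome, known_loci, ncrna, exons)
    candidates, hit_frame = build_candidates(
        tags, hits, eligible, genome, libs, flank, merge_dist, min_candidate_count
    )
    for c in candidates:
        evaluate_hairpin(c, mfe_cutoff=mfe_cutoff)
        if c.passed:
            attach_star_counts(c, hit_frame, tags, libs)
    called = call_novel(candidates, min_total=min_total, star_required=star_required)
    novel = group_families(called)
    hosts = locate_in_genes(novel, genes)
    return novel, candidates, hosts


def novel_table(novel: list[NovelMirna], libs: list[str]) -> pd.DataFrame:
    rows = []
    for m in novel:
        c = m.candidate
        row = {
            "name": m.name,
            "family": m.family_id,
            "chrom": c.locus[0],
            "start": c.locus[1],
            "end": c.locus[2],
            "strand": c.locus[3],
            "sequence": c.mature_seq,
            "structure": c.structure,
            "mfe": c.mfe,
        }
        for l in libs:
            row[l] = c.window_counts.get(l, 0)
        row["total"] = c.total
        rows.append(row)
    return pd.DataFrame(rows)
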