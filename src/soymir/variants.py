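"""Cross-library unification of the most abundant precursor-arm variants.

Sequenced small RNAs rarely coincide exactly with the annotated mature
miRNA: positional isoforms (isomiRs) on the same precursor arm often
dominate.  With many libraries available, the dominant variant can be
compared across libraries and, when one sequence is the most abundant
variant in a majority of them and the competing per-library winners have
comparable frequencies, that sequence becomes the "unified most abundant
variant" representing the arm in every library.  Arms whose winners swing
wildly between libraries are reported as non-unifiable; winners that
partition cleanly by genotype are additionally flagged variety-specific.

Roles follow duplex logic: the more abundant arm variant of a precursor is
the miRNA, the opposite-arm variant is the miRNA* (reported even when
sequenced only once in a single library).  Counts are aggregated over a
+/-2 nt start-offset window around the unified variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MAJORITY_FRAC = 0.5
DEFAULT_CLOSENESS_RATIO = 2.0
DEFAULT_WINDOW = 2
DEFAULT_MIN_SECONDARY = 100
DUPLEX_OFFSET_TOL = 3  # tolerance (nt) when matching a star partner position

ARMS = ("5p", "3p")


@dataclass
class ArmAlignment:
    """Exact placement of a tag on a precursor arm."""

    sequence: str
    precursor_id: str
    offset: int  # 0-based start on the precursor
    arm: str  # 5p | 3p | loop-spanning


@dataclass
class UnifiedVariant:
    precursor_id: str
    arm: str
    sequence: str | None
    offset: int | None
    role: str | None = None  # miRNA | miRNA*
    unifiable: bool = True
    variety_specific: bool = False
    arm_switch: bool = False
    window_counts: dict = field(default_factory=dict)
    agrees_with_annotation: bool | None = None
    annotation_class: str | None = None
    name: str | None = None

    @property
    def total(self) -> int:
        return int(sum(self.window_counts.values()))


def arm_of(offset: int, length: int, midpoint: int) -> str:
    """Arm by hairpin midpoint: fully left = 5p, fully right = 3p."""
    if offset + length <= midpoint:
        return "5p"
    if offset >= midpoint:
        return "3p"
    return "loop-spanning"


def align_to_precursors(
    tag_sequences,
    precursors: dict[str, str],
    midpoints: dict[str, int] | None = None,
    seed_len: int = 18,
) -> list[ArmAlignment]:
    """Report every exact substring occurrence of each tag on each precursor.

    ``midpoints`` maps precursor id to the hairpin midpoint used for arm
    assignment; by default the middle of the sequence, which is adequate for
    the roughly symmetric stem-loops deposited in miRBase.
    """
    midpoints = midpoints or {p: len(s) // 2 for p, s in precursors.items()}
    index: dict[str, list[tuple[str, int]]] = {}
    for pid, seq in precursors.items():
        for i in range(max(len(seq) - seed_len + 1, 0)):
            index.setdefault(seq[i : i + seed_len], []).append((pid, i))
    out: list[ArmAlignment] = []
    for tag in tag_sequences:
        if len(tag) < seed_len:
            continue
        for pid, i in index.get(tag[:seed_len], ()):
            if precursors[pid].startswith(tag, i):
                out.append(
                    ArmAlignment(tag, pid, i, arm_of(i, len(tag), midpoints[pid]))
                )
    return out


def _alignment_frame(alignments: list[ArmAlignment], counts: pd.DataFrame, libs: list[str]) -> pd.DataFrame:
    rows = [
        {"sequence": a.sequence, "precursor_id": a.precursor_id, "offset": a.offset, "arm": a.arm}
        for a in alignments
        if a.arm in ARMS
    ]
    if not rows:
        return pd.DataFrame(columns=["sequence", "precursor_id", "offset", "arm", *libs])
    df = pd.DataFrame(rows)
    df = df.join(counts.loc[df["sequence"], libs].reset_index(drop=True))
    return df


def most_abundant_per_arm(
    alignments: list[ArmAlignment] | pd.DataFrame,
    counts: pd.DataFrame,
    library: str,
) -> pd.DataFrame:
    """Top tag per (precursor, arm) in one library.

    Ties break toward the smaller offset, then the lexicographically smaller
    sequence; arms with zero aligned reads in the library are omitted.
    """
    libs = [library]
    df = alignments if isinstance(alignments, pd.DataFrame) else _alignment_frame(alignments, counts, libs)
    df = df[df[library] > 0]
    if df.empty:
        return pd.DataFrame(columns=["precursor_id", "arm", "sequence", "offset", "count"])
    df = df.sort_values(
        by=[library, "offset", "sequence"], ascending=[False, True, True], kind="mergesort"
    )
    top = df.groupby(["precursor_id", "arm"], sort=True).first().reset_index()
    top = top.rename(columns={library: "count"})
    return top[["precursor_id", "arm", "sequence", "offset", "count"]]


def unify_variants(
    arm_frame: pd.DataFrame,
    libs: list[str],
    majority_frac: float = DEFAULT_MAJORITY_FRAC,
    closeness_ratio: float = DEFAULT_CLOSENESS_RATIO,
    genotype_of: dict[str, str] | None = None,
) -> UnifiedVariant:
    """Unify one precursor arm across libraries.

    ``arm_frame`` holds all tags aligned to the arm with per-library counts
    plus 'sequence' and 'offset' columns.  Let T be the tag that is the
    per-library winner in the largest number of supporting libraries (ties
    resolved toward the higher total count).  T is the unified variant iff
    it wins in more than ``majority_frac`` of the supporting libraries and,
    in every library won by another tag U, count(T)/count(U) >=
    1/closeness_ratio.  Otherwise the arm is non-unifiable.
    """
    if not 0 < majority_frac <= 1:
        raise ValueError("majority_frac must lie in (0, 1]")
    pid = arm_frame["precursor_id"].iloc[0]
    arm = arm_frame["arm"].iloc[0]
    g = arm_frame.groupby("sequence")
    seq_counts = g[libs].sum()
    offsets = g["offset"].min()
    present = seq_counts.sum(axis=0) > 0
    supporting = [l for l in libs if present[l]]
    if not supporting:
        raise ValueError("arm has no supporting library")
    winners: dict[str, str] = {}
    for lib in supporting:
        sub = seq_counts[seq_counts[lib] > 0]
        order = sub.sort_values(lib, ascending=False)
        best = order[order[lib] == order[lib].iloc[0]]
        cand = sorted(best.index, key=lambda s: (offsets[s], s))
        winners[lib] = cand[0]
    tally = pd.Series(winners).value_counts()
    top_n = tally.iloc[0]
    tied = [s for s in tally.index if tally[s] == top_n]
    T = max(tied, key=lambda s: (seq_counts.loc[s, libs].sum(), s))
    n_win = tally[T]
    unifiable = n_win > majority_frac * len(supporting)
    if unifiable:
        for lib, w in winners.items():
            if w != T:
                c_t = seq_counts.loc[T, lib] if T in seq_counts.index else 0
                c_u = seq_counts.loc[w, lib]
                if c_u > 0 and c_t / c_u < 1.0 / closeness_ratio:
                    unifiable = False
                    break
    variety_specific = False
    if not unifiable and genotype_of:
        by_geno: dict[str, set[str]] = {}
        for lib, w in winners.items():
            by_geno.setdefault(genotype_of[lib], set()).add(w)
        winner_sets = list(by_geno.values())
        if len(winner_sets) > 1 and all(len(s) == 1 for s in winner_sets) and len(
            set.union(*winner_sets)
        ) > 1:
            variety_specific = True
    return UnifiedVariant(
        precursor_id=pid,
        arm=arm,
        sequence=T if unifiable else None,
        offset=int(offsets[T]) if unifiable else None,
        unifiable=unifiable,
        variety_specific=variety_specific,
    )


def aggregate_window_counts(
    variant_offset: int,
    arm_frame: pd.DataFrame,
    libs: list[str],
    window: int = DEFAULT_WINDOW,
) -> dict[str, int]:
    """Sum per-library counts of same-arm tags whose start offset lies within
    ``window`` nt of the variant's; window=0 recovers the exact count."""
    sel = arm_frame[(arm_frame["offset"] - variant_offset).abs() <= window]
    dedup = sel.drop_duplicates("sequence")
    return {l: int(dedup[l].sum()) for l in libs}


def assign_roles(variants: list[UnifiedVariant], per_lib_tops: pd.DataFrame | None = None) -> None:
    """Assign miRNA / miRNA* per precursor by arm totals (in place).

    The arm with the larger total window count is the miRNA; the opposite
    arm variant is the miRNA* even if sequenced once in one library.  When
    per-library winners are provided, precursors whose winning arm differs
    between libraries are flagged arm-switching.
    """
    with_counts = [v for v in variants if v.window_counts]
    if not with_counts:
        return
    best = max(with_counts, key=lambda v: v.total)
    for v in variants:
        v.role = "miRNA" if v is best else ("miRNA*" if v.total > 0 else None)
    if per_lib_tops is not None and not per_lib_tops.empty:
        arms = set()
        for lib, grp in per_lib_tops.groupby("library"):
            if grp.empty:
                continue
            arms.add(grp.loc[grp["count"].idxmax(), "arm"])
        if len(arms) > 1:
            for v in variants:
                v.arm_switch = True


def detect_multiple_mirnas(
    precursor_seq: str,
    primary: dict[str, UnifiedVariant],
    arm_frames: dict[str, pd.DataFrame],
    libs: list[str],
    min_secondary: int = DEFAULT_MIN_SECONDARY,
    window: int = DEFAULT_WINDOW,
) -> list[UnifiedVariant]:
    """Secondary miRNA variants from long precursors hosting two duplexes.

    A second variant on an arm is emitted iff its footprint does not overlap
    the primary variant's on that arm, its total count reaches
    ``min_secondary``, and a duplex-compatible partner tag exists on the
    opposite arm.
    """
    out: list[UnifiedVariant] = []
    L = len(precursor_seq)
    for arm, frame in arm_frames.items():
        prim = primary.get(arm)
        if prim is None or prim.sequence is None:
            continue
        p_lo, p_hi = prim.offset, prim.offset + len(prim.sequence)
        g = frame.groupby("sequence")
        totals = g[libs].sum().sum(axis=1)
        offsets = g["offset"].min()
        lens = g["sequence"].first().str.len()
        cands = totals.sort_values(ascending=False)
        for seq in cands.index:
            o = int(offsets[seq])
            if not (o + len(seq) <= p_lo or o >= p_hi):
                continue  # overlaps the primary footprint
            if totals[seq] < min_secondary:
                break
            # star-compatible partner: a tag on the opposite arm starting near
            # the mirror position of this candidate's duplex
            other_arm = "3p" if arm == "5p" else "5p"
            other = arm_frames.get(other_arm)
            if other is None or other.empty:
                continue
            mirror = L - (o + len(seq)) + 2
            partners = other[(other["offset"] - mirror).abs() <= DUPLEX_OFFSET_TOL]
            if partners[libs].to_numpy().sum() < 1:
                continue
            counts = aggregate_window_counts(o, frame, libs, window)
            out.append(
                UnifiedVariant(
                    precursor_id=prim.precursor_id,
                    arm=arm,
                    sequence=seq,
                    offset=o,
                    role="miRNA",
                    window_counts=counts,
                )
            )
            break  # at most one secondary per arm
    return out


def compare_to_annotation(
    variant: UnifiedVariant,
    precursor_seq: str,
    annotated_seq: str | None,
    midpoint: int | None = None,
) -> str:
    """Classify a unified variant against the annotated mature miRNA.

    Classes: identical, shifted-same-arm (overlapping footprint, different
    boundaries), opposite-arm, novel-arm (annotation absent from the
    precursor, or footprints disjoint on the same arm).
    """
    if variant.sequence is None:
        return "non-unifiable"
    if annotated_seq is None:
        return "novel-arm"
    mid = midpoint if midpoint is not None else len(precursor_seq) // 2
    ann_off = precursor_seq.find(annotated_seq)
    if ann_off < 0:
        warnings.warn("annotated mature not found on its precursor")
        return "novel-arm"
    if variant.sequence == annotated_seq:
        cls = "identical"
    else:
        ann_arm = arm_of(ann_off, len(annotated_seq), mid)
        if ann_arm != variant.arm:
            cls = "opposite-arm"
        elif (
            variant.offset < ann_off + len(annotated_seq)
            and ann_off < variant.offset + len(variant.sequence)
        ):
            cls = "shifted-same-arm"
        else:
            cls = "novel-arm"
    variant.annotation_class = cls
    variant.agrees_with_annotation = cls == "identical"
    return cls


def run_known_analysis(
    tags: pd.DataFrame,
    precursors: dict[str, str],
    libs: list[str],
    annotated: dict[str, str] | None = None,
    genotype_of: dict[str, str] | None = None,
    majority_frac: float = DEFAULT_MAJORITY_FRAC,
    closeness_ratio: float = DEFAULT_CLOSENESS_RATIO,
    window: int = DEFAULT_WINDOW,
    min_secondary: int = DEFAULT_MIN_SECONDARY,
    detect_secondary: bool = True,
) -> list[UnifiedVariant]:
    """Full known-miRNA stage: align, unify per arm, assign roles, aggregate
    window counts, detect secondary duplexes and compare to annotation.

    ``annotated`` maps mature names of the form ``<precursor_id>-5p`` (or any
    name whose precursor can be matched by prefix) to mature sequences.
    """
    alignments = align_to_precursors(tags.index, precursors)
    frame = _alignment_frame(alignments, tags, libs)
    ann_by_pid: dict[str, str] = {}
    for name, seq in (annotated or {}).items():
        for pid in precursors:
            if name.startswith(pid):
                ann_by_pid[pid] = seq
                break
    results: list[UnifiedVariant] = []
    for pid, pframe in frame.groupby("precursor_id"):
        per_arm: dict[str, UnifiedVariant] = {}
        arm_frames: dict[str, pd.DataFrame] = {}
        tops = []
        for arm, aframe in pframe.groupby("arm"):
            if aframe[libs].to_numpy().sum() == 0:
                continue
            arm_frames[arm] = aframe
            v = unify_variants(
                aframe, libs, majority_frac, closeness_ratio, genotype_of
            )
            if v.sequence is not None:
                v.window_counts = aggregate_window_counts(v.offset, aframe, libs, window)
            per_arm[arm] = v
            for lib in libs:
                t = most_abundant_per_arm(aframe, tags, lib)
                if not t.empty:
                    t = t.assign(library=lib)
                    tops.append(t)
        if not per_arm:
            continue
        top_frame = pd.concat(tops, ignore_index=True) if tops else pd.DataFrame()
        assign_roles(list(per_arm.values()), top_frame)
        secondaries = (
            detect_multiple_mirnas(
                precursors[pid], per_arm, arm_frames, libs, min_secondary, window
            )
            if detect_secondary
            else []
        )
        multi = bool(secondaries)
        for arm, v in per_arm.items():
            if v.role == "miRNA" and annotated is not None:
                compare_to_annotation(v, precursors[pid], ann_by_pid.get(pid))
            v.name = f"{pid}-{arm}" + ("-1" if multi and v.role == "miRNA" else "")
            results.append(v)
        for i, s in enumerate(secondaries):
            s.name = f"{s.precursor_id}-{s.arm}-{i + 2}"
            results.append(s)
    return results


def variants_table(variants: list[UnifiedVariant], libs: list[str]) -> pd.DataFrame:
    """One row per (precursor, arm, role) with 16 window-count columns."""
    rows = []
    for v in variants:
        row = {
            "name": v.name,
            "precursor_id": v.precursor_id,
            "arm": v.arm,
            "role": v.role,
            "sequence": v.sequence,
            "unifiable": v.unifiable,
            "variety_specific": v.variety_specific,
            "arm_switch": v.arm_switch,
            "annotation_class": v.annotation_class,
        }
        for l in libs:
            row[l] = v.window_counts.get(l, 0)
        row["total"] = v.total
        rows.append(row)
    return pd.DataFrame(rows)
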