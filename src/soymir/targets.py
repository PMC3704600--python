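"""Complementarity-based miRNA target prediction.

Plant miRNAs pair their targets near-perfectly, so candidate sites are
scored by ungapped antiparallel alignment of the miRNA to a transcript
window of the same length: a Watson-Crick pair scores 0, a G:U wobble 0.5
and any other combination 1 mismatch unit.  A site is reported when the
score does not exceed ``max_score`` (default 2.0) and miRNA positions 10-11
(5' counting) are perfectly Watson-Crick paired; by default a wobble at
10-11 also rejects the site, the permissive reading being available through
``allow_wobble_central``.
"""

from __future__ import annotations

from dataclasses import dataclass

from soymir.seqs import is_watson_crick, is_wobble, revcomp, to_dna

DEFAULT_MAX_SCORE = 2.0
CENTRAL_POSITIONS = (10, 11)  # 1-based positions from the miRNA 5' end
WOBBLE_SCORE = 0.5


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based position on the transcript
    score: float
    central_ok: bool


def score_duplex(mirna: str, site: str) -> tuple[float, list[str]]:
    """Mismatch score of a miRNA against an equal-length target window.

    Both sequences are given 5'->3'; the miRNA is aligned antiparallel, so
    miRNA position i (1-based from the 5' end) faces site position
    len-1-i (0-based).  Returns (score, per-position states) where states
    are 'WC', 'GU' or 'MM' ordered from the miRNA 5' end.
    """
    m = to_dna(mirna)
    s = to_dna(site)
    if len(m) != len(s):
        raise ValueError("miRNA and site must have equal length")
    states = []
    score = 0.0
    for i, base in enumerate(m):
        t = s[len(s) - 1 - i]
        if is_watson_crick(base, t):
            states.append("WC")
        elif is_wobble(base, t):
            states.append("GU")
            score += WOBBLE_SCORE
        else:
            states.append("MM")
            score += 1.0
    return score, states


def central_region_ok(states: list[str], allow_wobble: bool = False) -> bool:
    """No mismatch at miRNA positions 10-11 of the duplex."""
    forbidden = {"MM"} if allow_wobble else {"MM", "GU"}
    return all(states[p - 1] not in forbidden for p in CENTRAL_POSITIONS)


def find_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
    allow_wobble_central: bool = False,
) -> list[TargetSite]:
    """All complementary sites of one miRNA across a transcript set.

    A window of miRNA length slides over each transcript; one miRNA may hit
    many transcripts and one transcript may be hit by several miRNAs.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    m = to_dna(mirna_seq)
    n = len(m)
    out: list[TargetSite] = []
    for tid, seq in transcripts.items():
        s = to_dna(seq)
        for start in range(len(s) - n + 1):
            window = s[start : start + n]
            score, states = score_duplex(m, window)
            if score > max_score:
                continue
            if not central_region_ok(states, allow_wobble_central):
                continue
            out.append(TargetSite(mirna_id, tid, start + 1, score, True))
    return out


def predict_all(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
    allow_wobble_central: bool = False,
):
    """Target table over a set of miRNAs; returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for mid, seq in mirnas.items():
        for site in find_targets(mid, seq, transcripts, max_score, allow_wobble_central):
            rows.append(
                {
                    "mirna_id": site.mirna_id,
                    "transcript_id": site.transcript_id,
                    "position": site.site_start,
                    "score": site.score,
                }
            )
    return pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "position", "score"])
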