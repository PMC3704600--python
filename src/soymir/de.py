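"""Poisson-model differential expression of miRNA counts between libraries.

The design has one sequenced library per condition, so significance is
assessed with the Audic-Claverie conditional-Poisson test standard in
digital-tag pipelines: given a count x in a library of size N1, the
probability of observing y in a library of size N2 is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y) )

which is the negative-binomial mass nbinom(y; x+1, N1/(N1+N2)).  The
reported p-value doubles the smaller tail (capped at 1); a single-tail mode
is available.  Expression is normalized as transcripts per million (TPM)
over the library's genome-mapped clean reads, fold change is
log2(stress/control) with zeros replaced by 0.01, miRNAs below 1 TPM in
both libraries are excluded, and calls additionally require a raw count
over ``min_reads`` in at least one of the compared libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from soymir.design import comparison_id, stress_control_pairs

ZERO_SUBSTITUTE = 0.01
DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 1.0
DEFAULT_MIN_READS = 100


@dataclass
class DEResult:
    mirna_id: str
    comparison: str
    count_stress: int
    count_control: int
    tpm_stress: float
    tpm_control: float
    log2fc: float | None
    pvalue: float | None
    status: str  # up | down | not_significant | excluded_low | excluded_minreads


def tpm_normalize(raw_count: float, library_size: float) -> float:
    """Transcripts per million: count * 1e6 / library size."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return raw_count * 1e6 / library_size


def fold_change(tpm_stress: float, tpm_control: float) -> float | None:
    """log2(stress/control) with the 0.01 zero substitution.

    Returns None when both TPMs are below 1 (the miRNA is excluded from
    differential-expression analysis).
    """
    if tpm_stress < 0 or tpm_control < 0:
        raise ValueError("TPM values must be non-negative")
    if tpm_stress < 1 and tpm_control < 1:
        return None
    s = tpm_stress if tpm_stress > 0 else ZERO_SUBSTITUTE
    c = tpm_control if tpm_control > 0 else ZERO_SUBSTITUTE
    return float(np.log2(s / c))


def _nb_cdf(y, n, p):
    """P(Y <= y) for Y ~ nbinom(n, p), via the regularized incomplete beta."""
    return special.betainc(n, y + 1.0, p)


def poisson_pvalue(x, y, n1, n2, tail: str = "two-sided"):
    """Audic-Claverie p-value for counts (x, y) in libraries of sizes (n1, n2).

    Vectorized over x and y.  The conditional distribution of y given x is
    negative binomial with size x+1 and success probability n1/(n1+n2); both
    tails are evaluated through the regularized incomplete beta function,
    which is accurate in log space for large counts.  ``tail`` is
    'two-sided' (doubled smaller tail, capped at 1) or 'single' (smaller
    tail alone).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p = n1 / (n1 + n2)
    lower = _nb_cdf(y, x + 1.0, p)
    upper = np.where(y > 0, 1.0 - _nb_cdf(y - 1.0, x + 1.0, p), 1.0)
    smaller = np.minimum(lower, upper)
    if tail == "single":
        out = smaller
    elif tail == "two-sided":
        out = np.minimum(2.0 * smaller, 1.0)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return out if out.shape else float(out)


def classify(
    count_stress: int,
    count_control: int,
    tpm_stress: float,
    tpm_control: float,
    pvalue: float | None,
    log2fc: float | None,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    min_reads: int = DEFAULT_MIN_READS,
) -> str:
    """Status of one miRNA in one comparison.

    A miRNA enters the comparison only if its raw count is strictly over
    ``min_reads`` in at least one of the two libraries; with both TPMs
    below 1 it is excluded; otherwise up/down requires p <= alpha and
    |log2fc| >= lfc.
    """
    if log2fc is None:
        return "excluded_low"
    if max(count_stress, count_control) <= min_reads:
        return "excluded_minreads"
    if pvalue is not None and pvalue <= alpha:
        if log2fc >= lfc:
            return "up"
        if log2fc <= -lfc:
            return "down"
    return "not_significant"


def run_de(
    counts: pd.DataFrame,
    library_sizes: dict[str, int] | pd.Series,
    comparisons: list[tuple[str, str]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    min_reads: int = DEFAULT_MIN_READS,
    tail: str = "two-sided",
) -> pd.DataFrame:
    """Differential expression over the stress-vs-control comparisons.

    ``counts`` is a miRNA x library matrix of window counts.  Returns one
    row per (miRNA, comparison) with TPMs, log2 fold change, p-value,
    Benjamini-Hochberg q-value (reported for reference; classification uses
    the raw p-value) and status.
    """
    comparisons = comparisons or stress_control_pairs()
    sizes = pd.Series(library_sizes)
    rows = []
    for stress, control in comparisons:
        comp = comparison_id(stress, control)
        n1, n2 = float(sizes[control]), float(sizes[stress])
        for mirna, row in counts.iterrows():
            x, y = int(row[control]), int(row[stress])
            tpm_c = tpm_normalize(x, n1)
            tpm_s = tpm_normalize(y, n2)
            l2fc = fold_change(tpm_s, tpm_c)
            pval = float(poisson_pvalue(x, y, n1, n2, tail=tail)) if l2fc is not None else None
            status = classify(y, x, tpm_s, tpm_c, pval, l2fc, alpha, lfc, min_reads)
            rows.append(
                {
                    "mirna_id": mirna,
                    "comparison": comp,
                    "count_stress": y,
                    "count_control": x,
                    "tpm_stress": tpm_s,
                    "tpm_control": tpm_c,
                    "log2fc": l2fc,
                    "pvalue": pval,
                    "status": status,
                }
            )
    df = pd.DataFrame(rows)
    df["qvalue"] = np.nan
    mask = df["pvalue"].notna()
    if mask.any():
        df.loc[mask, "qvalue"] = _bh_adjust(df.loc[mask, "pvalue"].to_numpy())
    return df


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    q = np.empty(n)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        prev = min(prev, p[idx] * n / rank)
        q[idx] = prev
    return q


def de_summary(de: pd.DataFrame) -> pd.DataFrame:
    """Up/down counts per comparison (the bar-plot summary shape)."""
    sub = de[de["status"].isin(["up", "down"])]
    out = sub.groupby(["comparison", "status"]).size().unstack(fill_value=0)
    return out.reindex(columns=["up", "down"], fill_value=0)


def family_of(name: str) -> str:
    """Family identifier: the name stripped of arm suffix, variant number and
    paralog letter (e.g. soymir001a-5p-1 and soymir001b-5p -> soymir001)."""
    parts = name.split("-")
    while parts and (parts[-1] in ("5p", "3p") or parts[-1].isdigit()):
        parts.pop()
    base = "-".join(parts)
    return base.rstrip("abcdefghijklmnopqrstuvwxyz") if base else name


def compare_sets(
    de_lists: dict[str, list[str]], granularity: str = "variant"
) -> dict[str, object]:
    """Common and per-comparison exclusive DE sets.

    ``de_lists`` maps comparison ids to lists of DE miRNA names.  At
    ``granularity='family'`` names roll up through :func:`family_of`.
    Returns {'common': set, 'specific': {comparison: set}}.
    """
    if len(de_lists) < 2:
        raise ValueError("need at least two comparisons")
    if granularity == "family":
        sets = {c: {family_of(n) for n in names} for c, names in de_lists.items()}
    elif granularity == "variant":
        sets = {c: set(names) for c, names in de_lists.items()}
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    common = set.intersection(*sets.values())
    others = {
        c: set.union(*(s for k, s in sets.items() if k != c)) if len(sets) > 1 else set()
        for c in sets
    }
    specific = {c: sets[c] - others[c] for c in sets}
    return {"common": common, "specific": specific}
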