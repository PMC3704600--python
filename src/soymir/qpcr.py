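"""geNorm reference-gene stability and delta-Ct relative quantification.

Candidate reference genes are ranked by the geNorm average expression
stability M: for gene j, M_j is the mean over all other genes k of the
standard deviation across samples of log2(q_j / q_k); stable genes have low
M.  The pairwise variation V_{n/n+1} between normalization factors built
from the n and n+1 most stable genes decides how many references suffice
(first n with V < 0.15).  Quantities derive from Ct values by the delta-Ct
transform q = E^(Ct_min - Ct) with amplification efficiency E (default 2 =
perfect doubling per cycle), and target expression is normalized by the
geometric mean of the chosen reference quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EFFICIENCY = 2.0
V_CUTOFF = 0.15
STEM_LOOP_BACKBONE = "GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC"
UNIVERSAL_REVERSE_PRIMER = "GTGCAGGGTCCGAGGT"
STEM_LOOP_TAIL_LEN = 6


def ct_to_quantity(
    ct: pd.Series | np.ndarray | float,
    reference_ct: float | None = None,
    efficiency: float = DEFAULT_EFFICIENCY,
):
    """Relative quantity from a Ct value: E^(Ct_ref - Ct).

    ``reference_ct`` defaults to the minimum Ct of the input (the most
    abundant sample has quantity 1).
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    arr = np.asarray(ct, dtype=float)
    ref = float(np.min(arr)) if reference_ct is None else reference_ct
    q = efficiency ** (ref - arr)
    if isinstance(ct, pd.Series):
        return pd.Series(q, index=ct.index)
    return q if q.shape else float(q)


def quantities_from_ct_table(
    table: pd.DataFrame, efficiency: float = DEFAULT_EFFICIENCY
) -> pd.DataFrame:
    """Genes x samples quantity matrix from a tidy Ct table.

    ``table`` columns: gene, sample, [replicate,] ct.  Triplicates are
    summarized by their mean Ct before the delta-Ct transform; each gene is
    referenced to its own minimum mean Ct.
    """
    mean_ct = table.groupby(["gene", "sample"])["ct"].mean().unstack("sample")
    return mean_ct.apply(lambda row: ct_to_quantity(row, efficiency=efficiency), axis=1)


def genorm_m(quantities: pd.DataFrame) -> pd.Series:
    """Average expression stability M per gene (genes x samples input)."""
    if quantities.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    logq = np.log2(quantities)
    genes = quantities.index
    m = {}
    for j in genes:
        sds = [
            float((logq.loc[j] - logq.loc[k]).std(ddof=1))
            for k in genes
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m).sort_values()


def genorm_ranking(quantities: pd.DataFrame) -> list[str]:
    """Stability ranking by iterative exclusion of the least stable gene.

    The final two genes cannot be separated by the procedure and are
    reported jointly at the head of the ranking, ordered by their M in the
    final pair.
    """
    remaining = quantities.copy()
    excluded: list[str] = []
    while remaining.shape[0] > 2:
        m = genorm_m(remaining)
        worst = m.index[-1]
        excluded.append(worst)
        remaining = remaining.drop(index=worst)
    final = genorm_m(remaining)
    return list(final.index) + excluded[::-1]


def pairwise_variation(quantities: pd.DataFrame, ranking: list[str] | None = None) -> pd.Series:
    """V_{n/n+1} sequence for n = 2 .. n_genes-1.

    NF_n is the per-sample geometric mean of the n most stable genes;
    V_{n/n+1} is the standard deviation across samples of
    log2(NF_n / NF_{n+1}).
    """
    ranking = ranking or genorm_ranking(quantities)
    if len(ranking) > quantities.shape[0]:
        raise ValueError("ranking longer than the gene count")
    logq = np.log2(quantities.loc[ranking])
    vs = {}
    for n in range(2, len(ranking)):
        nf_n = logq.iloc[:n].mean(axis=0)
        nf_n1 = logq.iloc[: n + 1].mean(axis=0)
        vs[f"V{n}/{n + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    return pd.Series(vs)


def recommended_reference_count(v: pd.Series, cutoff: float = V_CUTOFF) -> int:
    """Smallest n with V_{n/n+1} below the cutoff (all-fail returns n_max)."""
    for name, val in v.items():
        if val < cutoff:
            return int(name[1:].split("/")[0])
    return len(v) + 2


def relative_expression(
    target_q: pd.Series, reference_q: pd.DataFrame
) -> pd.Series:
    """Target quantity normalized by the geometric mean of reference genes.

    ``target_q`` is indexed by sample; ``reference_q`` is references x
    samples.  Raises on zero reference quantities.
    """
    if reference_q.shape[0] < 1:
        raise ValueError("need at least one reference gene")
    if (reference_q <= 0).to_numpy().any():
        raise ValueError("zero or negative reference quantity")
    geomean = np.exp(np.log(reference_q).mean(axis=0))
    return target_q / geomean[target_q.index]


def stress_control_log2_ratio(
    normalized: pd.Series, stress_sample: str, control_sample: str
) -> float:
    return float(np.log2(normalized[stress_sample] / normalized[control_sample]))


def replicate_ttest(
    table: pd.DataFrame, gene: str, stress_sample: str, control_sample: str,
    references: list[str], efficiency: float = DEFAULT_EFFICIENCY,
) -> tuple[float, float]:
    """Two-sample t-test on per-replicate normalized quantities.

    Replicate Ct values of the target are converted to quantities and
    normalized by the geometric mean of the replicate-mean reference
    quantities of the same sample; returns (log2 ratio, p-value).
    """
    q = quantities_from_ct_table(table, efficiency)
    ref_geo = np.exp(np.log(q.loc[references]).mean(axis=0))
    sub = table[table["gene"] == gene]
    groups = {}
    for samp in (stress_sample, control_sample):
        cts = sub[sub["sample"] == samp]["ct"].to_numpy()
        ref_all = table[(table["gene"] == gene)]["ct"]
        qs = efficiency ** (float(ref_all.mean()) - cts)
        groups[samp] = qs / ref_geo[samp]
    t, p = stats.ttest_ind(groups[stress_sample], groups[control_sample])
    ratio = float(
        np.log2(np.mean(groups[stress_sample]) / np.mean(groups[control_sample]))
    )
    return ratio, float(p)


def validate_stem_loop_primer(primer: str, mirna: str | None = None) -> bool:
    """Check the stem-loop RT primer convention: a 44-nt self-looped backbone
    followed by a 6-nt tail reverse-complementary to the miRNA 3' end."""
    if len(STEM_LOOP_BACKBONE) != 44:
        raise AssertionError("backbone constant corrupted")
    if not primer.upper().startswith(STEM_LOOP_BACKBONE):
        return False
    tail = primer.upper()[len(STEM_LOOP_BACKBONE):]
    if len(tail) != STEM_LOOP_TAIL_LEN:
        return False
    if mirna is not None:
        from soymir.seqs import revcomp, to_dna

        return tail == revcomp(to_dna(mirna)[-STEM_LOOP_TAIL_LEN:])
    return True
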