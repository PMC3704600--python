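"""Read cleaning, unique-tag collapsing, exact genome mapping and summaries.

The stage mirrors the standard small RNA-seq preprocessing chain: 3' adapter
clipping, removal of contaminant reads (low quality, N-containing, poly-A,
out-of-range lengths), collapsing identical clean reads into unique tags
with per-library counts, and exact (mismatch-free) mapping of tags to both
genome strands.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soymir.io import iter_fastq
from soymir.seqs import revcomp

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_QUAL = 20.0
POLY_A_FRACTION = 0.8  # reads >= 80% A after trimming are treated as poly-A contaminants


@dataclass
class LibraryStats:
    """Per-library read accounting in the shape of a sequencing stats table."""

    library_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    unique_reads: int = 0
    mapped_reads: int = 0
    mapped_unique: int = 0
    discarded: dict = field(default_factory=dict)

    @property
    def mapped_pct(self) -> float:
        return percent(self.mapped_reads, self.clean_reads)

    @property
    def mapped_unique_pct(self) -> float:
        return percent(self.mapped_unique, self.unique_reads)

    @property
    def mean_frequency(self) -> float:
        """Average sequenced frequency of a unique tag (clean / unique)."""
        return round(self.clean_reads / self.unique_reads, 1) if self.unique_reads else 0.0


def percent(num: int, den: int) -> float:
    """Percentage rounded to two decimals, the convention of stats tables."""
    return round(100.0 * num / den, 2) if den else 0.0


class FastqFormatError(ValueError):
    pass


def _find_adapter(read: str, adapter3: str) -> int:
    """Return the trim position (insert length), or -1 if no adapter found.

    The adapter is located by the longest prefix of ``adapter3`` of length
    >= 8 occurring inside the read; failing that, a 3'-anchored partial
    overlap of >= 6 nt is accepted.
    """
    max_l = min(len(adapter3), len(read))
    for l in range(max_l, 7, -1):
        pos = read.find(adapter3[:l])
        if pos >= 0:
            return pos
    for l in range(min(7, max_l), 5, -1):
        if read.endswith(adapter3[:l]):
            return len(read) - l
    return -1


def trim_and_filter(
    fastq_path: str | os.PathLike,
    adapter3: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_qual: float = DEFAULT_MIN_QUAL,
    library_id: str | None = None,
) -> tuple[list[str], LibraryStats]:
    """Clip the 3' adapter and drop contaminant reads.

    A read is retained iff, after trimming, its length lies in
    [min_len, max_len], its mean Phred quality is >= min_qual, it contains
    no N, and it is not a poly-A artefact (>= 80% A).
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    lib = library_id or os.path.splitext(os.path.basename(os.fspath(fastq_path)))[0]
    stats = LibraryStats(library_id=lib)
    discard = {"no_adapter": 0, "length": 0, "quality": 0, "n_base": 0, "poly_a": 0}
    clean: list[str] = []
    qual_cache: dict[str, float] = {}
    records = iter_fastq(fastq_path)
    idx = -1
    while True:
        idx += 1
        try:
            title, seq, qual = next(records)
        except StopIteration:
            break
        except ValueError as exc:
            raise FastqFormatError(f"record {idx}: {exc}") from exc
        if len(seq) != len(qual):
            raise FastqFormatError(f"record {idx}: sequence/quality length mismatch")
        stats.raw_reads += 1
        pos = _find_adapter(seq, adapter3)
        if pos < 0:
            discard["no_adapter"] += 1
            continue
        insert = seq[:pos]
        q = qual[:pos]
        if not min_len <= len(insert) <= max_len:
            discard["length"] += 1
            continue
        mq = qual_cache.get(q)
        if mq is None:
            mq = float(np.mean([ord(c) - 33 for c in q])) if q else 0.0
            if len(qual_cache) < 4096:
                qual_cache[q] = mq
        if mq < min_qual:
            discard["quality"] += 1
            continue
        if "N" in insert:
            discard["n_base"] += 1
            continue
        if insert.count("A") >= POLY_A_FRACTION * len(insert):
            discard["poly_a"] += 1
            continue
        clean.append(insert)
    stats.clean_reads = len(clean)
    stats.discarded = discard
    return clean, stats


def collapse_unique(clean_by_library: dict[str, list[str]]) -> pd.DataFrame:
    """Collapse identical clean reads into unique tags with per-library counts.

    Returns a DataFrame indexed by tag sequence with one integer column per
    library plus a ``total`` column, sorted by descending total count with
    lexicographic sequence as the tie-break.  Column sums equal the clean
    read counts (count conservation).
    """
    from collections import Counter

    counters = {lib: Counter(reads) for lib, reads in clean_by_library.items()}
    all_tags = set()
    for c in counters.values():
        all_tags.update(c)
    index = sorted(all_tags)
    data = {
        lib: np.array([counters[lib].get(t, 0) for t in index], dtype=np.int64)
        for lib in clean_by_library
    }
    df = pd.DataFrame(data, index=pd.Index(index, name="sequence"))
    df["total"] = df.sum(axis=1)
    # descending total, lexicographic sequence as tie-break
    df = df.iloc[np.lexsort((df.index.values, -df["total"].values))]
    return df


class GenomeIndex:
    """Exact-match index over both genome strands.

    A k-mer (k = min tag length) dictionary maps seeds to candidate
    positions; each candidate is verified by direct string comparison, so
    the contract is "all exact occurrences" of the tag on either strand.
    """

    def __init__(self, genome: dict[str, str], k: int = DEFAULT_MIN_LEN):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))

    def hits(self, tag: str) -> list[tuple[str, int, int, str]]:
        """All exact occurrences as (chrom, start, end, strand), 1-based inclusive."""
        out = []
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            for chrom, i in self.index.get(query[: self.k], ()):
                if self.genome[chrom].startswith(query, i):
                    out.append((chrom, i + 1, i + len(query), strand))
        return sorted(out)


def map_to_genome(tags: pd.DataFrame, index: GenomeIndex) -> dict[str, list[tuple[str, int, int, str]]]:
    """Map every tag exactly to the genome; returns {sequence: hits}.

    Tags without hits map to an empty list and are excluded from miRNA
    analysis downstream.
    """
    return {seq: index.hits(seq) for seq in tags.index}


def finish_stats(
    stats: dict[str, LibraryStats],
    tags: pd.DataFrame,
    hits: dict[str, list],
) -> pd.DataFrame:
    """Fill unique/mapped columns and return the summary table."""
    mapped_mask = np.array([bool(hits.get(s)) for s in tags.index])
    for lib in stats:
        col = tags[lib].values
        st = stats[lib]
        st.unique_reads = int((col > 0).sum())
        st.mapped_reads = int(col[mapped_mask].sum())
        st.mapped_unique = int((col[mapped_mask] > 0).sum())
    rows = []
    for lib, st in stats.items():
        rows.append(
            {
                "library": lib,
                "raw_reads": st.raw_reads,
                "clean_reads": st.clean_reads,
                "unique_reads": st.unique_reads,
                "mapped_reads": st.mapped_reads,
                "mapped_pct": st.mapped_pct,
                "mapped_unique": st.mapped_unique,
                "mapped_unique_pct": st.mapped_unique_pct,
            }
        )
    return pd.DataFrame(rows).set_index("library")


def length_distribution(tags: pd.DataFrame, weighting: str = "total") -> pd.DataFrame:
    """Fraction of reads (or tags) per length 18-30, per library.

    ``weighting='total'`` weights each tag by its read count;
    ``weighting='unique'`` counts each tag once.  Fractions sum to 1 per
    library.
    """
    if tags.empty:
        raise ValueError("no tags")
    if weighting not in ("total", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    lengths = tags.index.str.len()
    libs = [c for c in tags.columns if c != "total"]
    out = {}
    for lib in libs:
        w = tags[lib].values if weighting == "total" else (tags[lib].values > 0).astype(float)
        tot = w.sum()
        frac = (
            pd.Series(w, index=lengths).groupby(level=0).sum() / tot
            if tot
            else pd.Series(dtype=float)
        )
        out[lib] = frac
    df = pd.DataFrame(out).fillna(0.0)
    df.index.name = "length"
    return df.sort_index()


def process_libraries(
    fastq_paths: dict[str, str],
    genome: dict[str, str],
    adapter3: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_qual: float = DEFAULT_MIN_QUAL,
) -> tuple[pd.DataFrame, dict[str, list], pd.DataFrame]:
    """Run the full stage: trim, collapse, map, summarize.

    Returns (tag table, {sequence: genome hits}, stats table).
    """
    clean = {}
    stats = {}
    for lib, path in fastq_paths.items():
        clean[lib], stats[lib] = trim_and_filter(
            path, adapter3, min_len, max_len, min_qual, library_id=lib
        )
    tags = collapse_unique(clean)
    index = GenomeIndex(genome, k=min_len)
    hits = map_to_genome(tags, index)
    table = finish_stats(stats, tags, hits)
    return tags, hits, table


def write_tag_fasta(path: str | os.PathLike, tags: pd.DataFrame) -> None:
    """Collapsed tag FASTA in the ``tag_<rank>_x<count>`` dialect."""
    with open(path, "w") as fh:
        for rank, (seq, row) in enumerate(tags.iterrows(), start=1):
            fh.write(f">tag_{rank}_x{int(row['total'])}\n{seq}\n")
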