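"""PolyA-site calling and internal-priming filtering.

A polyA site (PAS) is the exact nucleotide of the last templated base
before the untemplated-A tail. Sites are called from end-read records:
only reads whose tail length passes the minimum contribute, and a site
is emitted only when its pooled count across all samples reaches the
minimum read support. Sites whose immediate 3' genomic context is
A-rich are discarded as internal-priming artifacts (the oligo-dT primer
annealing to templated adenines rather than a real tail).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def call_polya_sites(
    records: pd.DataFrame,
    config: PipelineConfig,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Call polyA sites from end-read records.

    Parameters
    ----------
    records:
        End-read records (``formats_io.read_end_records`` layout),
        possibly concatenated over samples.
    config:
        Supplies ``min_tail`` (per-read filter) and ``min_reads``
        (pooled per-site filter).
    samples:
        Column order for the per-sample count columns; defaults to the
        sorted sample ids present in ``records``.

    Returns
    -------
    DataFrame with columns chrom, pos, strand, one count column per
    sample, and ``total`` (pooled count), sorted by (chrom, strand, pos).
    """
    if samples is None:
        samples = sorted(records["sample_id"].unique()) if len(records) else []
    samples = list(samples)
    base_cols = ["chrom", "pos", "strand", *samples, "total"]
    if records.empty:
        return pd.DataFrame(columns=base_cols)

    passing = records.loc[records["tail_length"] >= config.min_tail]
    if passing.empty:
        return pd.DataFrame(columns=base_cols)
    counts = (
        passing.groupby(["chrom", "strand", "cleavage_pos", "sample_id"])
        .size()
        .unstack("sample_id", fill_value=0)
        .reindex(columns=samples, fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    counts = counts.loc[counts["total"] >= config.min_reads]
    out = counts.reset_index().rename(columns={"cleavage_pos": "pos"})
    out = out.sort_values(["chrom", "strand", "pos"], kind="stable")
    return out[base_cols].reset_index(drop=True)


def downstream_context(
    genome: Mapping[str, str], chrom: str, strand: str, pos: int, width: int
) -> str:
    """Sense-strand sequence immediately 3' of a cleavage position.

    Truncated at the chromosome boundary; a position outside the
    chromosome raises ``IndexError``.
    """
    seq = genome[chrom]
    ref = seq if isinstance(seq, str) else str(seq[:])  # pyfaidx record or str
    if not 0 <= pos < len(ref):
        raise IndexError(f"site {chrom}:{pos} outside chromosome (len {len(ref)})")
    if strand == "+":
        return ref[pos + 1 : pos + 1 + width].upper()
    return reverse_complement(ref[max(0, pos - width) : pos]).upper()


def is_internal_priming(context: str, config: PipelineConfig) -> bool:
    """A-count / A-run rule on the downstream sense-strand context."""
    if context.count("A") >= config.ip_max_a:
        return True
    return "A" * config.ip_max_run in context


def filter_internal_priming(
    sites: pd.DataFrame,
    genome: Mapping[str, str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Remove sites whose downstream genomic context is A-rich.

    A site is removed iff the ``ip_window`` nucleotides immediately 3'
    of the cleavage position (sense strand) contain >= ``ip_max_a``
    adenines in total or a run of >= ``ip_max_run`` consecutive
    adenines.
    """
    if sites.empty:
        return sites.copy()
    # materialize chromosomes once; pyfaidx slicing per site is slower
    chrom_seq = {c: str(genome[c][:]).upper() for c in sites["chrom"].unique()}
    keep = []
    for row in sites.itertuples():
        context = downstream_context(
            chrom_seq, row.chrom, row.strand, row.pos, config.ip_window
        )
        keep.append(not is_internal_priming(context, config))
    return sites.loc[keep].reset_index(drop=True)
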