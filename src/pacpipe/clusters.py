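"""PolyA-cluster (PAC) construction and gene annotation.

Nearby polyA sites on the same chromosome and strand are merged into
polyA clusters by single-linkage chaining: any two sites within the
clustering gap are linked, and the clusters are the connected
components. Each PAC is then assigned to the same-strand gene whose
span contains its representative position and classified by region
(3'-UTR of the last exon, internal exon, intron, or intergenic), with
its exonic (transcript-coordinate) distance from the stop codon.
"""

from __future__ import annotations

import bisect
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .formats_io import GeneModel

log = logging.getLogger(__name__)

REGION_UTR3 = "UTR3_last_exon"
REGION_INTERNAL_EXON = "internal_exon"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"


def cluster_sites(sites: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Merge called sites into PACs by single-linkage chaining.

    Sites sorted by position form one cluster as long as each step to
    the next site is <= ``cluster_gap``; a larger step starts a new
    cluster. The representative position is the member site with the
    largest pooled count, ties broken toward the 3' end in
    transcription direction.

    Returns one row per PAC: pac_id, chrom, start, end (half-open span
    covering member sites), strand, representative_pos, per-sample
    counts (summed over members), total.
    """
    samples = [
        c for c in sites.columns
        if c not in ("chrom", "pos", "strand", "total")
    ]
    out_cols = ["pac_id", "chrom", "start", "end", "strand",
                "representative_pos", *samples, "total"]
    if sites.empty:
        return pd.DataFrame(columns=out_cols)

    rows = []
    for (chrom, strand), group in sites.groupby(["chrom", "strand"], sort=True):
        group = group.sort_values("pos", kind="stable")
        pos = group["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > config.cluster_gap) + 1
        for member in np.split(np.arange(len(pos)), breaks):
            sub = group.iloc[member]
            totals = sub["total"].to_numpy()
            best = totals.max()
            tied = sub.loc[sub["total"] == best, "pos"]
            rep = tied.max() if strand == "+" else tied.min()
            row = {
                "chrom": chrom,
                "start": int(pos[member[0]]),
                "end": int(pos[member[-1]]) + 1,
                "strand": strand,
                "representative_pos": int(rep),
                "total": int(totals.sum()),
            }
            for s in samples:
                row[s] = int(sub[s].sum())
            rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["chrom", "strand", "start"], kind="stable"
    ).reset_index(drop=True)
    out.insert(0, "pac_id", [f"PAC{i:05d}" for i in range(len(out))])
    return out[out_cols]


def _locate_in_gene(model: GeneModel, pos: int) -> tuple[str, int | None]:
    """Region and transcription-order exon index of a genomic position."""
    for genomic_idx, (e0, e1) in enumerate(model.exons):
        if e0 <= pos < e1:
            n = len(model.exons)
            tx_idx = genomic_idx if model.strand == "+" else n - 1 - genomic_idx
            if tx_idx == n - 1 and _downstream_of(model, pos):
                return REGION_UTR3, tx_idx
            return REGION_INTERNAL_EXON, tx_idx
    return REGION_INTRON, None


def _downstream_of(model: GeneModel, pos: int) -> bool:
    """Is pos strictly 3' of the stop codon in transcription direction?"""
    if model.strand == "+":
        return pos > model.stop_codon_pos
    return pos < model.stop_codon_pos


def transcript_distance(model: GeneModel, pos: int) -> float:
    """Exonic distance (nt) from the stop codon to ``pos``, 3'-ward.

    Measured in transcript coordinates: intronic sequence between the
    stop codon and the position does not count. NaN when the position is
    intronic or not 3' of the stop codon.
    """
    if not _downstream_of(model, pos):
        return float("nan")
    region, _ = _locate_in_gene(model, pos)
    if region == REGION_INTRON:
        return float("nan")
    stop, strand = model.stop_codon_pos, model.strand
    dist = 0
    for e0, e1 in model.exons:
        lo, hi = (stop, pos) if strand == "+" else (pos, stop)
        # overlap of the exon with the open genomic interval (lo, hi]
        a, b = max(e0, lo + 1), min(e1, hi + 1)
        if strand == "-":
            a, b = max(e0, lo), min(e1, hi)
        if b > a:
            dist += b - a
    return float(dist)


def annotate_pacs(
    pacs: pd.DataFrame, gene_models: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Assign each PAC to a gene and genomic region.

    A PAC is assigned to the same-strand gene whose span contains its
    representative position; antisense or unassigned PACs are
    intergenic. When several same-strand genes overlap the position, the
    gene whose stop codon is nearest 5' of the PAC wins and the
    ambiguity is logged.
    """
    models = sorted(gene_models.values(), key=lambda m: (m.chrom, m.span[0]))
    by_key: dict[tuple[str, str], tuple[list[int], list[GeneModel]]] = {}
    for m in models:
        starts, ms = by_key.setdefault((m.chrom, m.strand), ([], []))
        starts.append(m.span[0])
        ms.append(m)

    gene_ids, regions, exon_idx, dists = [], [], [], []
    for row in pacs.itertuples():
        pos = row.representative_pos
        hits: list[GeneModel] = []
        starts, ms = by_key.get((row.chrom, row.strand), ([], []))
        for i in range(bisect.bisect_right(starts, pos)):
            if ms[i].span[0] <= pos < ms[i].span[1]:
                hits.append(ms[i])
        if len(hits) > 1:
            def stop_gap(m: GeneModel) -> float:
                d = (pos - m.stop_codon_pos if m.strand == "+"
                     else m.stop_codon_pos - pos)
                return d if d >= 0 else float("inf")
            hits.sort(key=stop_gap)
            log.warning(
                "PAC %s at %s:%d overlaps %d same-strand genes; assigned %s",
                row.pac_id, row.chrom, pos, len(hits), hits[0].gene_id,
            )
        if not hits:
            gene_ids.append(None)
            regions.append(REGION_INTERGENIC)
            exon_idx.append(None)
            dists.append(float("nan"))
            continue
        model = hits[0]
        region, idx = _locate_in_gene(model, pos)
        gene_ids.append(model.gene_id)
        regions.append(region)
        exon_idx.append(idx)
        dists.append(transcript_distance(model, pos))

    out = pacs.copy()
    out["gene_id"] = gene_ids
    out["region"] = regions
    out["exon_index"] = pd.array(exon_idx, dtype="Int64")
    out["dist_from_stop"] = dists
    return out
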