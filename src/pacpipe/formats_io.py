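"""Readers and writers for the standard formats the pipeline touches.

Internal convention: 0-based half-open genomic intervals, strand stored
explicitly. GTF (1-based closed) is converted at the boundary, in both
directions, so the conversions are mutual inverses.

End reads travel as a 6-column BED dialect::

    chrom  start  end  read_id  tail_length  strand

with a single-nucleotide interval at the cleavage position (the last
templated base) and the untemplated-A tail length in the score slot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

END_READ_COLUMNS = ["chrom", "start", "end", "read_id", "tail_length", "strand"]

#: Stable column orders for the tabular outputs.
SITE_COLUMNS = ["chrom", "pos", "strand"]
PAC_COLUMNS = [
    "pac_id", "chrom", "start", "end", "strand", "representative_pos",
    "gene_id", "region", "exon_index", "dist_from_stop",
]
EVENT_COLUMNS = [
    "gene_id", "category", "pdu_control", "pdu_treated", "delta_pdu",
    "n_pacs_retained", "n_significant",
]
CANDIDATE_COLUMNS = [
    "gene_id", "category", "delta_pdu", "n_positive_windows",
    "cgcc_only_windows", "filters_passed", "flags",
]


class ParseError(ValueError):
    """Raised on malformed input, naming the offending location."""


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model in internal coordinates.

    ``exons`` are 0-based half-open genomic spans in ascending genomic
    order regardless of strand; transcription order is derived from
    ``strand``. ``stop_codon_pos`` is the genomic coordinate of the
    3'-most base of the stop codon in transcription direction: on the
    plus strand the rightmost stop-codon base, on the minus strand the
    leftmost.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    stop_codon_pos: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        spans = sorted(self.exons)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        object.__setattr__(self, "exons", tuple(spans))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def last_exon(self) -> tuple[int, int]:
        """The 3'-most exon in transcription direction."""
        return self.exons_transcription_order[-1]


def read_gene_models(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF into :class:`GeneModel` objects keyed by gene id.

    Requires ``exon`` and ``stop_codon`` features. When a gene carries
    several transcripts, the longest (summed exon length) is kept — the
    analysis concerns last-exon/3'-UTR events, where 5' isoform
    structure is irrelevant.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_transcript: dict[str, dict] = {}
    for feature in db.all_features():
        if feature.featuretype not in ("exon", "stop_codon"):
            continue
        try:
            gene_id = feature.attributes["gene_id"][0]
            tx_id = feature.attributes.get("transcript_id", [gene_id])[0]
        except KeyError as exc:
            raise ParseError(
                f"{gtf_path}: feature at {feature.seqid}:{feature.start} "
                f"missing {exc}"
            ) from exc
        if feature.strand not in "+-":
            raise ParseError(
                f"{gtf_path}: missing strand for {gene_id} at "
                f"{feature.seqid}:{feature.start}"
            )
        rec = per_transcript.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": feature.seqid,
             "strand": feature.strand, "exons": [], "stop": None},
        )
        span = (feature.start - 1, feature.end)  # 1-based closed -> half-open
        if feature.featuretype == "exon":
            rec["exons"].append(span)
        else:
            rec["stop"] = span if rec["stop"] is None else (
                min(rec["stop"][0], span[0]), max(rec["stop"][1], span[1])
            )

    best: dict[str, tuple[int, GeneModel]] = {}
    for tx_id, rec in per_transcript.items():
        if not rec["exons"] or rec["stop"] is None:
            raise ParseError(
                f"{gtf_path}: transcript {tx_id} lacks exon or stop_codon"
            )
        stop_pos = rec["stop"][1] - 1 if rec["strand"] == "+" else rec["stop"][0]
        model = GeneModel(
            gene_id=rec["gene_id"], chrom=rec["chrom"], strand=rec["strand"],
            exons=tuple(rec["exons"]), stop_codon_pos=stop_pos,
        )
        length = sum(e1 - e0 for e0, e1 in model.exons)
        prev = best.get(model.gene_id)
        if prev is None or length > prev[0]:
            best[model.gene_id] = (length, model)
    return {gid: model for gid, (_, model) in sorted(best.items())}


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (gene/transcript/exon/stop_codon rows)."""
    lines = []
    for m in models:
        g0, g1 = m.span
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
        def row(feat: str, s: int, e: int) -> str:
            # internal half-open -> GTF 1-based closed
            return "\t".join(
                [m.chrom, "pacpipe", feat, str(s + 1), str(e), ".",
                 m.strand, ".", attrs]
            )
        lines.append(row("gene", g0, g1))
        lines.append(row("transcript", g0, g1))
        for e0, e1 in m.exons:
            lines.append(row("exon", e0, e1))
        if m.strand == "+":
            stop_span = (m.stop_codon_pos - 2, m.stop_codon_pos + 1)
        else:
            stop_span = (m.stop_codon_pos, m.stop_codon_pos + 3)
        lines.append(row("stop_codon", *stop_span))
    Path(path).write_text("\n".join(lines) + "\n")


def read_end_records(bed_path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read per-read 3'-end records from the BED dialect.

    Returns a DataFrame with columns chrom, strand, cleavage_pos,
    tail_length, sample_id, read_id. The cleavage position is the start
    column on the plus strand and end-1 on the minus strand (identical
    for the single-nucleotide intervals the pipeline emits, but the rule
    is applied regardless).
    """
    path = Path(bed_path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=END_READ_COLUMNS,
            dtype={"chrom": str, "start": int, "end": int, "read_id": str,
                   "tail_length": int, "strand": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=END_READ_COLUMNS)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "strand": df["strand"].astype(str),
            "cleavage_pos": df["start"].where(df["strand"] == "+", df["end"] - 1),
            "tail_length": df["tail_length"],
            "sample_id": sample_id,
            "read_id": df["read_id"].astype(str),
        }
    )
    bad = ~out["strand"].isin(["+", "-"])
    if bad.any():
        raise ParseError(f"{path}: bad strand on line {int(bad.idxmax()) + 1}")
    return out


def write_end_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write end-read records (columns as returned by read_end_records)."""
    df = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["cleavage_pos"],
            "end": records["cleavage_pos"] + 1,
            "read_id": records["read_id"],
            "tail_length": records["tail_length"],
            "strand": records["strand"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table (sample_id, condition, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing = {"sample_id", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: design table missing columns {sorted(missing)}")
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write a TSV with a stable column order (extra columns appended)."""
    if columns is not None:
        ordered = [c for c in columns if c in df.columns]
        ordered += [c for c in df.columns if c not in ordered]
        df = df[ordered]
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph_tracks(pacs: pd.DataFrame, samples: Sequence[str],
                          out_dir: str | Path) -> list[Path]:
    """Write one bedGraph of per-PAC counts per sample.

    Each PAC contributes one line covering its span with the sample's
    count as the value.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    body = pacs.sort_values(["chrom", "start"], kind="stable")
    for sample in samples:
        path = out_dir / f"pac_counts_{sample}.bedGraph"
        with open(path, "w") as handle:
            handle.write(f'track type=bedGraph name="PAC counts {sample}"\n')
            for row in body.itertuples():
                handle.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t"
                    f"{int(getattr(row, sample))}\n"
                )
        paths.append(path)
    return paths


def write_tracks_and_tables(
    pacs: pd.DataFrame,
    events: pd.DataFrame,
    candidates: pd.DataFrame,
    samples: Sequence[str],
    out_dir: str | Path,
) -> dict[str, object]:
    """Persist the finalized pipeline objects under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table(pacs, out_dir / "pacs.tsv", PAC_COLUMNS)
    write_table(events, out_dir / "events.tsv", EVENT_COLUMNS)
    write_table(candidates, out_dir / "candidates.tsv", CANDIDATE_COLUMNS)
    tracks = write_bedgraph_tracks(pacs, samples, out_dir)
    return {
        "pacs": out_dir / "pacs.tsv",
        "events": out_dir / "events.tsv",
        "candidates": out_dir / "candidates.tsv",
        "tracks": tracks,
    }
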