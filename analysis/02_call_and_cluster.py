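#!/usr/bin/env python
"""Call polyA sites and build annotated polyA clusters (PACs).

Reads with an untemplated-A tail of >=25 nt vote for their cleavage
nucleotide; positions with >=5 pooled reads become sites; A-rich
downstream contexts are removed as internal-priming artifacts; the
survivors are chained into PACs (gap <= 10 nt) and annotated against
the gene models. Writes sites.tsv and pacs.tsv under results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from pacpipe import clusters, sites
from pacpipe.config import PipelineConfig
from pacpipe.formats_io import (
    read_design,
    read_end_records,
    read_gene_models,
    write_table,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig()

    design = read_design(args.data / "design.tsv")
    samples = design["sample_id"].tolist()
    records = pd.concat(
        [read_end_records(args.data / f"reads_{s}.bed", s) for s in samples],
        ignore_index=True,
    )
    print(f"{len(records)} end reads across {len(samples)} samples")

    called = sites.call_polya_sites(records, config, samples)
    n_raw = len(called)
    called = sites.filter_internal_priming(
        called, Fasta(str(args.data / "genome.fa")), config
    )
    print(f"{n_raw} sites called; {n_raw - len(called)} removed as "
          f"internal priming; {len(called)} kept")

    pacs = clusters.cluster_sites(called, config)
    pacs = clusters.annotate_pacs(
        pacs, read_gene_models(args.data / "annotation.gtf")
    )
    by_region = pacs["region"].value_counts().to_dict()
    print(f"{len(pacs)} PACs; by region: {by_region}")

    write_table(called, args.out / "sites.tsv")
    write_table(pacs, args.out / "pacs.tsv")
    print(f"tables under {args.out}")


if __name__ == "__main__":
    main()
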