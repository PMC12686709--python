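#!/usr/bin/env python
"""Differential expression, differential PAC usage and APA events.

Gene counts (sum of PAC counts) get a negative-binomial Wald test
(called at fold change > 1.5, BH padj < 0.1); per-PAC usage gets a
Welch t-test on arcsine-root usages (significant at |change| >= 10
points, padj < 0.1); genes with >=2 occupancy-passing PACs and >=1
significant shift are classified as lengthening / shortening / both /
splicing with their delta PDUI. Writes de.tsv, usage.tsv,
pac_tests.tsv and events.tsv under results/tables/.
"""

import argparse
from pathlib import Path

from pacpipe import apastats
from pacpipe.config import PipelineConfig
from pacpipe.formats_io import read_design, read_table, write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--tables", type=Path,
                        default=ROOT / "results" / "tables")
    args = parser.parse_args()
    config = PipelineConfig()

    design = read_design(args.data / "design.tsv")
    samples = design["sample_id"].tolist()
    pacs = read_table(args.tables / "pacs.tsv")

    counts = apastats.gene_counts(pacs, samples)
    de = apastats.test_gene_de(counts, design, config)
    print(f"{len(counts)} genes counted; {int(de.called.sum())} DE calls "
          f"(fold > {config.fc_min}, padj < {config.padj_max})")

    usage = apastats.usage_table(pacs, samples)
    tests = apastats.test_pac_usage(usage, design, config)
    print(f"{len(tests)} PACs tested for usage shifts; "
          f"{int(tests.significant.sum())} significant")

    events, _ = apastats.classify_events(usage, tests, design, config)
    print(f"{len(events)} APA events: "
          + ", ".join(f"{k}={v}" for k, v in
                      sorted(events.category.value_counts().items())))
    with_delta = events.dropna(subset=["delta_pdu"])
    if len(with_delta):
        print("delta PDUI range: "
              f"[{with_delta.delta_pdu.min():+.3f}, "
              f"{with_delta.delta_pdu.max():+.3f}]")

    write_table(de.reset_index(), args.tables / "de.tsv")
    write_table(usage, args.tables / "usage.tsv")
    write_table(tests, args.tables / "pac_tests.tsv")
    write_table(events, args.tables / "events.tsv")


if __name__ == "__main__":
    main()
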