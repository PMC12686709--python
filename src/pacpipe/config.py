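"""Pipeline-wide configuration.

All thresholds of the analysis chain live in a single :class:`PipelineConfig`
so that every stage (site calling, clustering, differential usage, G4
scanning, candidate selection) reads from one validated source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


@dataclass
class PipelineConfig:
    """Thresholds and windows applied along the pipeline.

    Attributes
    ----------
    min_reads:
        Minimum pooled (all samples) read count for a polyA site to be
        called.
    min_tail:
        Minimum untemplated-A tail length (nt) for a read to count as
        evidence of cleavage/polyadenylation.
    cluster_gap:
        Maximum nucleotide gap between neighbouring sites merged into one
        polyA cluster (single-linkage chaining).
    occupancy_min:
        Minimum mean share of a gene's 3'-end reads for a PAC to enter
        event classification.
    usage_change_min:
        Minimum absolute change in PAC usage (proportion of the gene's
        reads) for a PAC to be called significantly shifted; inclusive
        boundary.
    padj_max:
        BH-adjusted p-value cutoff shared by the differential-expression
        and differential-usage tests.
    fc_min:
        Fold-change threshold for differential gene expression; strict
        (fold change must exceed it).
    flank:
        Half-width (nt) of the window around a PAC representative position
        scanned for G-quadruplex propensity.
    g4h_min:
        G4Hunter positivity threshold (score strictly above).
    cgcc_min:
        cG/cC positivity threshold (score strictly above).
    g4nn_min:
        Documented threshold of the neural-network G4 score used by the
        G4RNA screener. The network itself is not implemented here (no
        published weights); the value is carried only so configuration
        files round-trip, and no stage reads it.
    dpdu_min:
        Minimum |delta PDU| for a gene to survive candidate selection;
        inclusive (events below 0.12 are removed).
    ip_window:
        Number of genomic nucleotides immediately 3' of a cleavage site
        examined by the internal-priming filter.
    ip_max_a:
        A site is discarded when the downstream window contains at least
        this many adenines in total.
    ip_max_run:
        ... or a run of at least this many consecutive adenines.
    exclude_cgcc_only:
        When true, windows positive only by cG/cC do not satisfy the
        G4 requirement during candidate selection (mechanised stand-in for
        manual curation of cG/cC-only false positives).
    g4h_window:
        Sliding-window width (nt) of the G4Hunter score.
    """

    min_reads: int = 5
    min_tail: int = 25
    cluster_gap: int = 10
    occupancy_min: float = 0.05
    usage_change_min: float = 0.10
    padj_max: float = 0.1
    fc_min: float = 1.5
    flank: int = 100
    g4h_min: float = 0.9
    cgcc_min: float = 4.5
    g4nn_min: float = 0.5
    dpdu_min: float = 0.12
    ip_window: int = 10
    ip_max_a: int = 7
    ip_max_run: int = 6
    exclude_cgcc_only: bool = True
    g4h_window: int = 25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "min_reads", "min_tail", "cluster_gap", "occupancy_min",
            "usage_change_min", "padj_max", "fc_min", "flank", "g4h_min",
            "cgcc_min", "g4nn_min", "dpdu_min", "ip_window", "ip_max_a",
            "ip_max_run", "g4h_window",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(f"{name} must be positive, got {value!r}")
        if not self.occupancy_min < 1:
            raise ConfigError(
                f"occupancy_min must be < 1, got {self.occupancy_min!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML / ``key: value`` file.

        Unknown keys are rejected so typos do not silently fall back to
        defaults.
        """
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
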