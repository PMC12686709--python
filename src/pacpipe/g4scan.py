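"""G-quadruplex propensity scoring of the sequence flanking each PAC.

Two sequence scores are computed on the sense-strand (transcribed)
sequence spanning each PAC's representative position +/- the flank
width:

* **G4Hunter** — every base in a maximal run of k guanines scores
  min(k, 4); every base in a cytosine run scores -min(k, 4); all other
  bases score 0. The reported value is the maximum, over all sliding
  windows (width 25 nt, or the sequence length if shorter), of the
  window mean. Scores therefore live in [-4, 4]; G-rich, G-clustered
  sequences score high.

* **cG/cC** — each maximal G-run of length k contributes k(k+1)/2 to
  cG (so consecutiveness is rewarded superlinearly), C-runs likewise to
  cC, and the score is cG / max(cC, 1). The unit denominator floor
  keeps C-free G-rich sequences at large finite values.

A window is *positive* when at least one score exceeds its threshold
(G4Hunter > 0.9 or cG/cC > 4.5 by default), and the provenance of the
call is recorded so cG/cC-only positives can be down-weighted during
candidate selection. The neural-network score of the G4RNA screener is
not implemented (no published weights); the disjunctive positivity rule
runs over the two sequence scores.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .sites import reverse_complement

log = logging.getLogger(__name__)

_VALID = set("ACGTU")


def _check_sequence(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def _run_lengths(seq: str, base: str) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of ``base``."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def g4hunter_base_scores(seq: str) -> np.ndarray:
    """Per-base G4Hunter scores (run-capped at +/-4)."""
    seq = _check_sequence(seq)
    scores = np.zeros(len(seq))
    for start, length in _run_lengths(seq, "G"):
        scores[start : start + length] = min(length, 4)
    for start, length in _run_lengths(seq, "C"):
        scores[start : start + length] = -min(length, 4)
    return scores


def g4hunter_score(seq: str, window: int = 25) -> float:
    """Maximum sliding-window mean of the per-base G4Hunter scores.

    The window is ``min(window, len(seq))`` so short sequences are
    scored over their full length.
    """
    scores = g4hunter_base_scores(seq)
    if scores.size == 0:
        raise ValueError("empty sequence")
    w = min(window, scores.size)
    cumsum = np.concatenate([[0.0], np.cumsum(scores)])
    means = (cumsum[w:] - cumsum[:-w]) / w
    return float(means.max())


def cgcc_score(seq: str) -> float:
    """Consecutive-G over consecutive-C score, cG / max(cC, 1)."""
    seq = _check_sequence(seq)
    c_g = sum(k * (k + 1) // 2 for _, k in _run_lengths(seq, "G"))
    c_c = sum(k * (k + 1) // 2 for _, k in _run_lengths(seq, "C"))
    return c_g / max(c_c, 1)


def score_window(seq: str, config: PipelineConfig) -> dict:
    """Both scores plus the disjunctive positivity call for one window."""
    g4h = g4hunter_score(seq, config.g4h_window)
    cgcc = cgcc_score(seq)
    positive_by = []
    if g4h > config.g4h_min:
        positive_by.append("G4H")
    if cgcc > config.cgcc_min:
        positive_by.append("cGcC")
    return {
        "g4h_max": g4h,
        "cgcc": cgcc,
        "positive": bool(positive_by),
        "positive_by": ",".join(positive_by),
    }


def scan_pac_flanks(
    pacs: pd.DataFrame,
    genome: Mapping[str, str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Score the sense-strand flank of every PAC.

    The flank spans representative_pos +/- ``config.flank`` on the
    reference (2*flank + 1 nt for an interior PAC, truncated at
    chromosome ends); minus-strand PACs are scored on the reverse
    complement so the scanned sequence is always the transcribed
    strand.
    """
    chrom_seq = {
        c: (genome[c] if isinstance(genome[c], str) else str(genome[c][:])).upper()
        for c in pacs["chrom"].unique()
    } if len(pacs) else {}
    rows = []
    for row in pacs.itertuples():
        ref = chrom_seq[row.chrom]
        lo = max(0, row.representative_pos - config.flank)
        hi = min(len(ref), row.representative_pos + config.flank + 1)
        if hi - lo < 2 * config.flank + 1:
            log.info("flank of %s truncated at chromosome end", row.pac_id)
        seq = ref[lo:hi]
        if row.strand == "-":
            seq = reverse_complement(seq)
        rows.append(
            {
                "pac_id": row.pac_id,
                "chrom": row.chrom,
                "flank_start": lo,
                "flank_end": hi,
                "strand": row.strand,
                "flank_seq": seq,
                **score_window(seq, config),
            }
        )
    columns = ["pac_id", "chrom", "flank_start", "flank_end", "strand",
               "flank_seq", "g4h_max", "cgcc", "positive", "positive_by"]
    return pd.DataFrame(rows, columns=columns)
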