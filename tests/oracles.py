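"""Independent brute-force reference implementations used by the tests.

Each oracle re-derives a pipeline quantity by the most direct method
available (exhaustive scans, pairwise merging, literal rule
re-evaluation) and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_force_single_linkage(positions: list[int], gap: int) -> list[list[int]]:
    """O(n^2) pairwise-merge clustering: merge any two clusters that
    contain positions within ``gap`` of each other, to a fixed point."""
    clusters = [{p} for p in positions]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    abs(a - b) <= gap
                    for a in clusters[i]
                    for b in clusters[j]
                ):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(sorted(c) for c in clusters)


def brute_force_g4hunter(seq: str, window: int = 25) -> float:
    """Literal per-base scoring plus exhaustive window scan."""
    seq = seq.upper().replace("U", "T")
    scores = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        j = i
        while j < len(seq) and seq[j] == ch:
            j += 1
        k = j - i
        if ch == "G":
            scores.extend([min(k, 4)] * k)
        elif ch == "C":
            scores.extend([-min(k, 4)] * k)
        else:
            scores.extend([0] * k)
        i = j
    w = min(window, len(scores))
    return max(
        sum(scores[i : i + w]) / w for i in range(len(scores) - w + 1)
    )


def brute_force_cgcc(seq: str) -> float:
    """Run enumeration with the triangular-number weighting."""
    seq = seq.upper().replace("U", "T")

    def run_score(base: str) -> int:
        total, run = 0, 0
        for ch in seq + "$":
            if ch == base:
                run += 1
            else:
                total += run * (run + 1) // 2
                run = 0
        return total

    return run_score("G") / max(run_score("C"), 1)


def brute_force_internal_priming(
    downstream: str, max_a: int, max_run: int
) -> bool:
    """Literal re-evaluation of the A-count / A-run rule."""
    if sum(1 for ch in downstream if ch == "A") >= max_a:
        return True
    run = best = 0
    for ch in downstream:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    return best >= max_run


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Direct median-of-ratios recomputation over zero-free genes."""
    keep = (counts > 0).all(axis=1)
    ref = np.exp(np.log(counts[keep]).mean(axis=1))
    return np.array(
        [np.median(counts[keep, j] / ref) for j in range(counts.shape[1])]
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
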