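"""Synthetic 3'-end sequencing datasets with known APA and G4 structure.

The generator emulates the statistical structure of a polyA-targeted
3'-end sequencing experiment over two conditions with replicates:
multi-PAS genes in long last exons, negative-binomial per-gene depth,
multinomial allocation of reads over polyA sites according to
per-condition usage vectors, cleavage-site heterogeneity (symmetric
truncated-geometric jitter), untemplated-A tails of at least 25 nt,
internal-priming decoys at templated A-tracts, and (GGGN)3GGG
G-quadruplex motifs planted near a subset of polyA sites, with
dinucleotide-shuffled control windows planted away from any gene.

Every dataset is accompanied by a ground-truth manifest (gene models,
true PAS positions, usage vectors, the expected delta PDU implied by
them, planted G4s, decoys and controls) so each downstream stage can be
verified against what was simulated.

Genome composition outside planted features is i.i.d. with a human
3'-UTR-like base bias (A/T 0.32, C/G 0.18, ~36% GC); a uniform
composition would litter flanks with accidental G4Hunter-positive
windows and make motif/control contrasts meaningless. Each true PAS is
followed by a 12-nt U-rich downstream element (poly-T on the sense
strand), the canonical DSE of polyadenylation sites; as a side effect
no genuine cleavage site can ever satisfy the internal-priming filter,
so only planted decoys exercise it. The shuffled controls preserve the
dinucleotide composition of the flank *before* motif insertion: they
ask whether the scorers fire on the neighbourhood's composition alone.
A shuffle of the motif-bearing flank would retain the motif's G runs
(dinucleotide shuffles preserve GG adjacency counts exactly) and stay
positive by construction, controlling for nothing.

Layout: one 50-kb chromosome per 10 genes, each gene in a 5-kb slot
with a 300-nt first exon, a 200-nt intron and a 3-kb last exon, leaving
room for 2-4 polyA sites spaced >=400 nt downstream of the stop codon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .apastats import pdu_from_usage
from .formats_io import (
    GeneModel,
    write_design,
    write_end_records,
    write_fasta,
    write_gene_models,
)
from .sites import reverse_complement

CONDITIONS = ("control", "treated")

CHROM_SIZE = 50_000
GENES_PER_CHROM = 10
SLOT = CHROM_SIZE // GENES_PER_CHROM

#: background base probabilities for A, C, G, T (~36% GC, 3'-UTR-like)
BACKGROUND_PROBS = (0.32, 0.18, 0.18, 0.32)
#: length of the U-rich downstream element planted 3' of each PAS
DSE_LENGTH = 12

GENE_KIND_NULL = "null"
GENE_KIND_APA = "apa"
GENE_KIND_SPLICING = "splicing"


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study design and noise parameters of a simulated dataset.

    ``apa_usage_control`` / ``apa_usage_treated`` are the
    (proximal, distal) usage setpoints of genes carrying a planted APA
    shift; the defaults place 37% of control reads and 55% of treated
    reads on the distal site, an 18-point gain of the long isoform.
    """

    n_genes: int = 100
    pacs_per_gene: tuple[int, int] = (2, 4)
    replicates_per_condition: int = 3
    depth_mean: float = 1000.0
    nb_dispersion: float = 0.05
    cleavage_jitter_max: int = 5
    tail_mean: float = 40.0
    tail_min: int = 25
    internal_priming_fraction: float = 0.05
    noise_fraction: float = 0.01
    g4_planted_fraction: float = 0.10
    apa_fraction: float = 0.10
    splicing_fraction: float = 0.05
    apa_usage_control: tuple[float, float] = (0.63, 0.37)
    apa_usage_treated: tuple[float, float] = (0.45, 0.55)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.replicates_per_condition < 1:
            raise SimConfigError("replicates_per_condition must be >= 1")
        kmin, kmax = self.pacs_per_gene
        if not 2 <= kmin <= kmax:
            raise SimConfigError("pacs_per_gene must satisfy 2 <= min <= max")
        for name in ("internal_priming_fraction", "noise_fraction",
                     "g4_planted_fraction", "apa_fraction",
                     "splicing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.apa_fraction + self.splicing_fraction > 1:
            raise SimConfigError("apa_fraction + splicing_fraction must be <= 1")
        if self.tail_min < 25:
            raise SimConfigError("tail_min must be >= 25")
        if self.tail_mean < self.tail_min:
            raise SimConfigError("tail_mean must be >= tail_min")
        if self.depth_mean <= 0 or self.nb_dispersion <= 0:
            raise SimConfigError("depth_mean and nb_dispersion must be positive")
        for cond in ("apa_usage_control", "apa_usage_treated"):
            u = getattr(self, cond)
            if len(u) != 2 or abs(sum(u) - 1) > 1e-9 or min(u) < 0:
                raise SimConfigError(f"{cond} must be 2 nonnegative values summing to 1")


@dataclass
class SimTruth:
    """Ground-truth manifest of one simulated dataset."""

    config: dict
    conditions: list[str]
    samples: list[str]
    genes: list[dict] = field(default_factory=list)
    controls: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def plant_g4(sequence: str, motif: str, offset: int) -> str:
    """Overwrite ``sequence`` with ``motif`` starting at ``offset``.

    The result differs from the input only on the motif span.
    """
    if offset < 0 or offset + len(motif) > len(sequence):
        raise IndexError(
            f"motif of length {len(motif)} at offset {offset} does not fit "
            f"in sequence of length {len(sequence)}"
        )
    return sequence[:offset] + motif + sequence[offset + len(motif):]


def sample_pac_counts(
    gene_total: int, usage: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial split of a gene's read total over its polyA sites."""
    if gene_total < 0:
        raise ValueError(f"gene_total must be >= 0, got {gene_total}")
    usage = np.asarray(usage, dtype=float)
    if abs(usage.sum() - 1) > 1e-9 or (usage < 0).any():
        raise ValueError("usage must be a probability vector summing to 1")
    return rng.multinomial(gene_total, usage)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide multiset (Euler-path walk).

    Picks random last-exit edges until they form a tree into the final
    vertex, shuffles the remaining edges, and walks the Eulerian path —
    the classic approach for generating sequence-composition controls.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | {seq[-1]})
    last_vertex = seq[-1]
    non_final = [v for v in vertices if v != last_vertex and v in edges]
    while True:
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in non_final}
        ok = True
        for v in non_final:
            node, seen = v, set()
            while node != last_vertex:
                if node in seen or node not in last_exit:
                    ok = False
                    break
                seen.add(node)
                node = last_exit[node]
            if not ok:
                break
        if ok:
            break
    pools: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_exit:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v in last_exit:
            rest.append(last_exit[v])
        pools[v] = rest
    out = [seq[0]]
    node = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[node].pop(0)
        out.append(nxt)
        node = nxt
    return "".join(out)


def _g4_motif(rng: np.random.Generator) -> str:
    spacers = rng.choice(list("AT"), size=3)
    return "GGG" + spacers[0] + "GGG" + spacers[1] + "GGG" + spacers[2] + "GGG"


def _jitter(rng: np.random.Generator, n: int, jmax: int) -> np.ndarray:
    """Symmetric truncated-geometric cleavage jitter (p = 0.5)."""
    if jmax == 0 or n == 0:
        return np.zeros(n, dtype=int)
    mags = np.arange(jmax + 1)
    probs = 0.5 ** mags
    probs /= probs.sum()
    magnitude = rng.choice(mags, size=n, p=probs)
    sign = rng.choice([-1, 1], size=n)
    return magnitude * sign


def _gene_layout(
    index: int, strand: str, rng: np.random.Generator, n_pas: int,
    kind: str,
) -> dict:
    """Genomic coordinates of one gene inside its 5-kb slot."""
    chrom = f"chr{index // GENES_PER_CHROM + 1}"
    s = (index % GENES_PER_CHROM) * SLOT
    if strand == "+":
        first_exon = (s + 200, s + 500)
        intron = (s + 500, s + 700)
        last_exon = (s + 700, s + 3700)
        stop_pos = last_exon[0] + 59
        decoy = s + 600
    else:
        last_exon = (s + 200, s + 3200)
        intron = (s + 3200, s + 3400)
        first_exon = (s + 3400, s + 3700)
        stop_pos = last_exon[1] - 60
        decoy = s + 3300
    # transcript-coordinate distances of last-exon PASs from the stop codon
    dists = []
    d = int(rng.integers(250, 401))
    n_utr = n_pas - 1 if kind == GENE_KIND_SPLICING else n_pas
    for _ in range(n_utr):
        dists.append(d)
        d += int(rng.integers(400, 701))
    pas = []
    if kind == GENE_KIND_SPLICING:
        # one PAS mid first exon, upstream of the stop codon
        pos = first_exon[0] + 150 if strand == "+" else first_exon[1] - 151
        pas.append({"pos": int(pos), "dist_from_stop": None,
                    "region": "internal_exon"})
    for dist in dists:
        pos = stop_pos + dist if strand == "+" else stop_pos - dist
        pas.append({"pos": int(pos), "dist_from_stop": int(dist),
                    "region": "UTR3_last_exon"})
    exons = sorted([first_exon, last_exon])
    return {
        "chrom": chrom,
        "slot_start": s,
        "exons": exons,
        "intron": intron,
        "stop_codon_pos": int(stop_pos),
        "pas": pas,
        "decoy": int(decoy),
        "control_slot": (s + 3800, s + 4800),
    }


def _usage_vectors(
    kind: str, n_pas: int, config: SimConfig, rng: np.random.Generator
) -> dict[str, list[float]]:
    if kind == GENE_KIND_APA:
        return {
            "control": list(config.apa_usage_control),
            "treated": list(config.apa_usage_treated),
        }
    if kind == GENE_KIND_SPLICING:
        return {"control": [0.25, 0.45, 0.30], "treated": [0.50, 0.30, 0.20]}
    u = rng.dirichlet([5.0] * n_pas)
    u = list(np.round(u / u.sum(), 12))
    u[-1] = 1.0 - sum(u[:-1])
    return {"control": u, "treated": list(u)}


def _expected_delta_pdu(gene: dict) -> float | None:
    dists = [p["dist_from_stop"] for p in gene["pas"]]
    if any(d is None for d in dists):
        return None
    usage_c = np.array(gene["usage"]["control"])
    usage_t = np.array(gene["usage"]["treated"])
    dists = np.array(dists, dtype=float)
    return float(
        pdu_from_usage(usage_t, dists) - pdu_from_usage(usage_c, dists)
    )


def generate_dataset(config: SimConfig, out_dir: str | Path) -> SimTruth:
    """Generate a complete synthetic dataset under ``out_dir``.

    Writes ``genome.fa``, ``annotation.gtf``, one ``reads_<sample>.bed``
    per sample, ``design.tsv`` and ``truth.json``; returns the truth
    manifest. Identical configurations (including the seed) produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_chroms = (config.n_genes + GENES_PER_CHROM - 1) // GENES_PER_CHROM
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    genome = {
        name: rng.choice(list("ACGT"), size=CHROM_SIZE, p=BACKGROUND_PROBS)
        for name in chrom_names
    }

    n_apa = int(round(config.apa_fraction * config.n_genes))
    n_spl = int(round(config.splicing_fraction * config.n_genes))
    kinds = np.array(
        [GENE_KIND_APA] * n_apa + [GENE_KIND_SPLICING] * n_spl
        + [GENE_KIND_NULL] * (config.n_genes - n_apa - n_spl)
    )
    rng.shuffle(kinds)

    kmin, kmax = config.pacs_per_gene
    samples = [
        f"{cond}_{r + 1}"
        for cond in CONDITIONS
        for r in range(config.replicates_per_condition)
    ]
    truth = SimTruth(
        config={**asdict(config)}, conditions=list(CONDITIONS), samples=samples
    )

    models = []
    for i in range(config.n_genes):
        kind = str(kinds[i])
        strand = str(rng.choice(["+", "-"]))
        if kind == GENE_KIND_APA:
            n_pas = 2
        elif kind == GENE_KIND_SPLICING:
            n_pas = 3
        else:
            n_pas = int(rng.integers(kmin, kmax + 1))
        layout = _gene_layout(i, strand, rng, n_pas, kind)
        gene_id = f"G{i:04d}"
        chrom = layout["chrom"]
        arr = genome[chrom]

        # internal-priming decoy: templated A-tract on the sense strand
        # immediately 3' of the decoy cleavage position
        decoy = layout["decoy"]
        if strand == "+":
            arr[decoy + 1 : decoy + 11] = "A"
        else:
            arr[decoy - 10 : decoy] = "T"

        # U-rich DSE (poly-T on the sense strand) 3' of every true PAS
        for pas in layout["pas"]:
            if strand == "+":
                arr[pas["pos"] + 1 : pas["pos"] + 1 + DSE_LENGTH] = "T"
            else:
                arr[pas["pos"] - DSE_LENGTH : pas["pos"]] = "A"

        usage = _usage_vectors(kind, n_pas, config, rng)

        # plant a G4 motif near one PAS: always for APA genes (next to
        # the shifted distal site), at random otherwise
        g4_records = []
        if kind == GENE_KIND_APA:
            plant, pas_index = True, len(layout["pas"]) - 1
        elif kind == GENE_KIND_NULL and rng.random() < config.g4_planted_fraction:
            plant, pas_index = True, int(rng.integers(len(layout["pas"])))
        else:
            plant, pas_index = False, -1
        if plant:
            motif = _g4_motif(rng)
            offsets = list(range(-80, -24)) + list(range(25, 66))
            offset = int(offsets[rng.integers(len(offsets))])
            pas_pos = layout["pas"][pas_index]["pos"]
            # composition control: the flank as it reads before the motif
            # goes in, dinucleotide-shuffled and parked intergenically
            pre_flank = "".join(arr[pas_pos - 100 : pas_pos + 101])
            if strand == "-":
                pre_flank = reverse_complement(pre_flank)
            shuffled = dinucleotide_shuffle(pre_flank, rng)
            c_lo = layout["control_slot"][0]
            arr[c_lo : c_lo + len(shuffled)] = list(shuffled)
            truth.controls.append(
                {
                    "chrom": chrom,
                    "start": int(c_lo),
                    "end": int(c_lo + len(shuffled)),
                    "gene_id": gene_id,
                    "seq": shuffled,
                }
            )
            if strand == "+":
                g_start = pas_pos + offset
                arr[g_start : g_start + len(motif)] = list(motif)
            else:
                g_start = pas_pos - offset - len(motif) + 1
                arr[g_start : g_start + len(motif)] = list(
                    reverse_complement(motif)
                )
            g4_records.append(
                {
                    "pas_index": pas_index,
                    "offset": offset,
                    "motif": motif,
                    "genomic_start": int(g_start),
                    "genomic_end": int(g_start + len(motif)),
                }
            )

        models.append(
            GeneModel(
                gene_id=gene_id, chrom=chrom, strand=strand,
                exons=tuple(tuple(e) for e in layout["exons"]),
                stop_codon_pos=layout["stop_codon_pos"],
            )
        )
        truth.genes.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "kind": kind,
                "exons": [list(e) for e in layout["exons"]],
                "stop_codon_pos": layout["stop_codon_pos"],
                "pas": layout["pas"],
                "usage": usage,
                "expected_delta_pdu": None,
                "g4": g4_records,
                "decoys": [decoy],
                "control_slot": list(layout["control_slot"]),
            }
        )
        truth.genes[-1]["expected_delta_pdu"] = _expected_delta_pdu(
            truth.genes[-1]
        )

    # ---- reads ----------------------------------------------------------
    r_nb = 1.0 / config.nb_dispersion
    p_nb = r_nb / (r_nb + config.depth_mean)
    design = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    )
    for sample in samples:
        condition = sample.rsplit("_", 1)[0]
        chroms, positions, tails, ids = [], [], [], []
        strands = []
        serial = 0

        def emit(gene: dict, pos_arr: np.ndarray, tail_arr: np.ndarray) -> None:
            nonlocal serial
            n = len(pos_arr)
            chroms.extend([gene["chrom"]] * n)
            strands.extend([gene["strand"]] * n)
            positions.extend(int(p) for p in pos_arr)
            tails.extend(int(t) for t in tail_arr)
            ids.extend(
                f"{sample}:{gene['gene_id']}:{serial + k}" for k in range(n)
            )
            serial += n

        for gene in truth.genes:
            total = int(rng.negative_binomial(r_nb, p_nb))
            alloc = sample_pac_counts(
                total, np.array(gene["usage"][condition]), rng
            )
            for pas, count in zip(gene["pas"], alloc):
                if count == 0:
                    continue
                jit = _jitter(rng, count, config.cleavage_jitter_max)
                pos = pas["pos"] + jit
                tail = config.tail_min + rng.poisson(
                    config.tail_mean - config.tail_min, count
                )
                emit(gene, pos, tail)
            n_ip = int(round(total * config.internal_priming_fraction))
            if n_ip:
                tail = config.tail_min + rng.poisson(
                    config.tail_mean - config.tail_min, n_ip
                )
                emit(gene, np.full(n_ip, gene["decoys"][0]), tail)
            n_noise = int(round(total * config.noise_fraction))
            if n_noise:
                utr = [p["pos"] for p in gene["pas"] if p["dist_from_stop"]]
                lo, hi = min(utr), max(utr)
                pos = rng.integers(lo, hi + 1, size=n_noise)
                tail = rng.integers(0, config.tail_min, size=n_noise)
                emit(gene, pos, tail)

        records = pd.DataFrame(
            {
                "chrom": chroms,
                "strand": strands,
                "cleavage_pos": positions,
                "tail_length": tails,
                "sample_id": sample,
                "read_id": ids,
            }
        ).sort_values(["chrom", "cleavage_pos", "read_id"], kind="stable")
        write_end_records(records, out_dir / f"reads_{sample}.bed")

    write_fasta(
        {name: "".join(genome[name]) for name in chrom_names},
        out_dir / "genome.fa",
    )
    write_gene_models(models, out_dir / "annotation.gtf")
    write_design(design, out_dir / "design.tsv")
    truth.to_json(out_dir / "truth.json")
    return truth
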