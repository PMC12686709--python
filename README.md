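# pacpipe

Alternative polyadenylation (APA) from 3′-end sequencing, and its
relationship to nearby RNA G-quadruplexes (rG4s).

Most human genes carry several polyadenylation sites (PASs); which one
the cleavage machinery picks decides the length of the 3′-UTR and with
it the transcript's stability, localization and translatability.
`pacpipe` implements the computational chain that takes per-read 3′-end
evidence (the last templated nucleotide of each read plus its
untemplated-A tail length) and produces, per gene, a quantitative APA
verdict and a G-quadruplex context for it:

1. **Site calling** — a PAS is the exact nucleotide supported by ≥5
   pooled reads with untemplated-A tails of ≥25 nt; sites whose
   downstream genomic decamer is A-rich (≥7 A or a run of ≥6) are
   removed as internal-priming artifacts.
2. **Clustering** — sites within 10 nt chain into polyA clusters
   (PACs), annotated against gene models (3′-UTR of the last exon,
   internal exon, intron, intergenic) with their transcript-coordinate
   distance from the stop codon.
3. **Statistics** — per-gene differential expression (negative-binomial
   Wald test; called at fold change > 1.5, BH-adjusted p < 0.1) and
   per-PAC differential usage (Welch t on arcsine-√ usage; significant
   at |Δusage| ≥ 10 points, padj < 0.1).
4. **PDUI** — the percentage of distal polyA-site usage. For PACs at
   stop-codon distances d₁ ≤ … ≤ d_K with condition-mean usages uᵢ,

       PDUI = Σᵢ uᵢ · (dᵢ − d₁) / (d_K − d₁)

   which for two PACs is exactly LU/(LU+SU), the long-isoform share.
   ΔPDUI = PDUI(treated) − PDUI(control); positive means 3′-UTR
   lengthening. Events are classified lengthening / shortening / both
   (an internal PAC of ≥3 shifts) / splicing (PACs across exons or in
   introns), using only PACs with ≥5% occupancy.
5. **G4 scanning** — the sense-strand ±100 nt around each PAC is scored
   with G4Hunter (run-weighted per-base scores, max 25-nt window mean;
   positive > 0.9) and cG/cC (triangular run weighting, positive > 4.5).
6. **Candidate selection** — last-exon events with |ΔPDUI| ≥ 0.12 and at
   least one G4-positive flank (cG/cC-only positives excluded by
   default) survive the funnel.

A first-class synthetic-data generator (`pacpipe.simdata`) emulates a
PAC-seq experiment — 2 conditions × 3 replicates, negative-binomial
depth, multinomial PAS usage, cleavage jitter, ≥25-nt tails,
internal-priming decoys, planted (GGGN)₃GGG motifs and
composition-matched shuffled controls — and writes a ground-truth
manifest so every stage is verifiable without external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort (100 genes; 10 with a planted distal-usage shift
0.30 → 0.55 and a G4 motif near the shifted PAC; 5 with a cross-exon
shift; 85 null):

```sh
python analysis/01_simulate_cohort.py      # writes results/data/
python analysis/02_call_and_cluster.py     # sites + PACs
python analysis/03_apa_statistics.py       # DE, usage tests, events
python analysis/04_g4_proximity.py         # flank G4 scores
python analysis/05_select_candidates.py    # the funnel
```

prints (seed 1):

```
509717 end reads across 6 samples
3274 sites called; 100 removed as internal priming; 3174 kept
292 PACs; by region: {'UTR3_last_exon': 287, 'internal_exon': 5}
100 genes counted; 0 DE calls (fold > 1.5, padj < 0.1)
292 PACs tested for usage shifts; 33 significant
15 APA events: lengthening=10, splicing=5
delta PDUI range: [+0.230, +0.265]
292 PAC flanks scored; 31 positive (0 by cG/cC alone)
planted-motif flanks recovered positive: 20/20
shuffled composition controls positive: 0/20
funnel: analyzed=100 -> significant_apa=15 -> non_splicing=10 -> with_pg4=10 -> dpdu_passing=10
candidates: 10; planted APA+G4 recovered: 10/10; splicing-planted among candidates: 0
```

Reading this: the 100 exactly-decoy sites planted by the simulator are
the 100 removed as internal priming; every usage-shifted gene is found
(15 significant events), the five cross-exon genes are correctly set
aside as "splicing", the ten planted lengthening genes carry ΔPDUI
estimates around their true +0.25, and all ten — and nothing else —
come out of the candidate funnel. No expression changes were planted,
and none are called.

The same stages are exposed as a CLI (`pacpipe simulate`, `call-sites`,
`cluster`, `apa`, `g4scan`, `select`, `run-all`, `report`) for use on
any dataset in the documented formats (FASTA, GTF, BED6 with the tail
length in the score column, TSV design table).

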