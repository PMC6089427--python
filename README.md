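# barcodedelim

Consensus delimitation of molecular operational taxonomic units (MOTUs) from
aligned DNA barcode sequences — the COI workflow used in continental-scale
surveys of cryptic fish diversity, packaged as a tested, reusable pipeline.

## The problem

DNA-barcode surveys ask how many distinct mitochondrial lineages hide inside
named species. A single delimitation method can mislead, so practice is to
demand agreement between **three independent lines of evidence** on the same
alignment:

1. **Registry-style OTUs** — single-linkage clusters of the pairwise
   distance matrix under a fixed divergence threshold (emulating
   Barcode-Index-Number assignment; new sequences join a reference OTU only
   when their similarity reaches a threshold such as 98.88%).
2. **Automatic Barcode Gap Discovery (ABGD)** — the "barcode gap" is the
   separation between intraspecific and interspecific distance
   distributions. On the ranked pairwise distances *d*(1) ≤ … ≤ *d*(m), the
   gap is the first local maximum of slope beyond a prior limit *P* that is
   *X* times wider than any gap below the prior; the sequences are split by
   single linkage at the gap and the search recurses within each group,
   over a grid of priors *P* ∈ [*P*min, *P*max].
3. **Reciprocal monophyly** — each candidate OTU must form an exclusive
   clade on a neighbor-joining tree (bootstrap supports optional; an
   externally produced tree can be substituted via Newick).

An OTU supported by all three is a **Full** OTU; any disagreement (cluster
split or merged by ABGD, non-monophyly, a source missing) makes it
**Partial**.

Distances are p, Kimura-2-parameter, or Tamura–Nei (TN93, optionally gamma
rate-corrected), computed under pairwise deletion:

    K2P:  d = -½ ln(1 - 2P - Q) - ¼ ln(1 - 2Q)
    TN93: d = -k₁ ln(w₁) - k₂ ln(w₂) - k₃ ln(w₃)

with P (transitions) and Q (transversions) split into the A↔G and C↔T
classes and weighted by base frequencies for TN93; with gamma shape α each
−ln(w) becomes α(w^(−1/α) − 1).

A synthetic-data module generates multi-lineage barcode alignments with
known truth (652 sites, fish-COI base composition, configurable intra- and
inter-lineage divergence), so the whole pipeline is testable without any
sequence downloads.

## Worked example

Simulate four lineages (within-lineage divergence 0.5%, between 8%) and run
the full pipeline with taxonomy-calibrated ABGD settings (*P*max = 0.01,
*X* = 1):

```sh
barcodedelim simulate --n-lineages 4 --seqs-per-lineage 5 \
    --intra 0.005 --inter 0.08 --seed 42 --out-dir sim
barcodedelim run --fasta sim/sim.fasta --metadata sim/metadata.tsv \
    --out-dir results --study-mode --seed 1
```

which prints

```
4 clusters, 4 ABGD groups, 4 Full OTUs -> results
```

`results/consensus.tsv` holds the verdicts — every lineage is recovered by
all three approaches:

```
Current Taxonomy  cluster  ABGD group(s)  Reciprocal monophyly  OTU match
lineage 1         1        1              Yes                   Full
lineage 2         2        2              Yes                   Full
lineage 3         3        3              Yes                   Full
lineage 4         4        4              Yes                   Full
```

`results/abgd_scan.tsv` shows how the partition count responds to the prior
(over-splitting at tiny priors, stabilizing at the true four groups):

```
prior_P_low  prior_P_high  n_priors  n_groups  partition_id
0.00100      0.00129       2         11        1
0.00167      0.00278       3         6         2
0.00359      0.00464       2         5         3
0.00599      0.01000       3         4         4
```

and `results/otu_summaries.tsv` gives the per-OTU distance summary in
percent: e.g. group 1 has 5 members, maximum intra-OTU distance 0.93%, mean
0.56%, and its nearest neighbour (group 4) sits at 7.3% — a comfortably
positive barcode gap (`results/barcode_gap.tsv`), so the OTU is resolved.
`results/mds.tsv` holds classical-MDS coordinates of the between-OTU
distance matrix for ordination plots, and `results/tree.nwk` the NJ tree.

Every stage is also invokable on its own (`distances`, `cluster`, `abgd`,
`assign`, `tree`, `consensus`, `summarize`); composing them by hand through
their TSV/Newick files gives identical results to `run`.

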