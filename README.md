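# straindiff

Pairwise comparative genomics of closely related bacterial strains.

When two strains of the same lineage are ~90% identical at the nucleotide
level (average nucleotide identity below the ~95% species threshold, yet
with near-perfectly conserved gene order), their differences concentrate in
a small set of discrete regions: horizontally acquired islands carrying
transposases and integrases, deletions, short divergent replacements, and
the occasional translocation.  `straindiff` re-implements, as a tested and
reusable library + CLI, the analysis chain by which such regions are found
and interpreted:

* **Synthetic genome pairs with ground truth** — an annotated ancestor is
  evolved into two derived genomes by codon-aware substitutions and
  structural events; every event is recorded in a truth log, so the whole
  pipeline can be validated end to end.
* **Region classification** — exact unique k-mer anchors are chained into
  homology blocks; each genome is partitioned into *collinear* (same gene
  order), *translocated* (homologous block in a different context),
  *divergent* (non-homologous but feature-bearing on both sides) and
  *exclusive* (feature-bearing sequence present in one genome only)
  regions, with overlap accounting against externally predicted genomic
  islands.
* **Orthology and ANIb** — one-directional best-hit protein orthology
  (Smith–Waterman, BLOSUM62, Karlin–Altschul e-values; query coverage ≥ 80%,
  e-value ≤ 10⁻⁵), positional collinearity, homolog presence matrices,
  gene-order (synteny) comparison, and fragment-based average nucleotide
  identity (1020-bp fragments, 30%-identity / 70%-length retention).
* **[NiFe]-hydrogenase motif typing** — wildcard motifs (large-subunit
  L1–L4; small-subunit proximal/medial/distal FeS-cluster binding) classify
  hydrogenase subunits into functional groups (1b respiratory, 1d
  membrane-anchored periplasmic, 2b sensory), with single-residue
  deviations reported explicitly and twin-arginine (Tat, `RRxFxK`) export
  signals detected near the N-terminus.
* **Functional plasticity** — KO/COG annotation reconciliation across
  orthologs, exclusive annotation sets (transposases excluded by default),
  clustering of exclusive genes into regions, transporter breadth,
  transposase censuses, and a from-formula one-sided Welch t-test for
  CRISPR/transposase co-occurrence.
* **Expression and rRNA heterogeneity** — ΔCt relative quantification
  normalised to a housekeeping gene (efficiency 2.0 by default) with
  inter-run calibration and Gaussian error propagation; multi-copy 16S
  alignment with consensus-masking detection and hypervariable-region
  (V1–V9) mapping.

## Worked example

Simulate a 120 kbp genome pair and run the full pipeline:

```bash
straindiff run-all --seed 7 --out runs/demo
```

```
stages: simulate, classify-regions, orthologs, ani, func-delta
manifest: runs/demo/manifest.json
```

`runs/demo/region_summary.csv` then holds the per-class region table; for
seed 7 the classifier reports 5 exclusive regions (3 owned by genome A, 2
by genome B — each an island inserted into its owner or a deletion from
the partner), plus 1 divergent region and 1 translocation, exactly
matching the simulated events.  The pairwise identity of the two simulated
strains:

```bash
straindiff ani --fna-a runs/demo/fixture/ancestor_A.fna \
               --fna-b runs/demo/fixture/ancestor_B.fna --out ani.csv
# ANIb = 88.54%
```

which matches the simulated 12% pairwise divergence.  A hydrogenase
classification on a protein FASTA:

```bash
straindiff hydrogenase-classify --faa proteins.faa \
    --large GHNINEIG_00797 --small GHNINEIG_00798 --out report.csv
```

prints, for a small subunit whose medial FeS-binding window reads
`FPIQAGHGCIGCS`:

```
group 1d medial: A instead of S at position 5
group 1d: all 5 motifs compatible (max_mismatch=1)
Tat motif RRxFxK present in the small subunit at position 3
compatible groups: 1d
```

i.e. the subunit pair is called group 1d with one tolerated single-residue
deviation, and the small subunit carries a periplasmic export signal.

The CRISPR/transposase test on a genome survey table
(`genome_id,crispr_present,transposase_count`):

```bash
straindiff plasticity-test --survey survey.csv
# mean transposases: CRISPR+ 27.3, CRISPR- 14.6; t=..., one-sided p=...
```

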