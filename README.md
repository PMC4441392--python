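# genome3d

Beads-on-a-string 3D genome reconstruction from Hi-C-derived distances, with
tooling to *improve* sparse reconstructions by integrating predicted
interactions: distances projected from an evolutionary related organism
through ortholog families, and functional distances predicted from codon
usage frequency similarity.

## What it does

- **Map preparation** (`genome3d.contacts`): bin raw contact records at
  10 kbp, balance the map by iterative correction, fit a 100-bin
  frequency-vs-genomic-separation profile, and convert contact frequencies
  to nanometric target distances (linear interpolation, 130 bp/nm chromatin
  packing). Damped maps simulate a smaller experiment (divide counts,
  threshold at 1, round, re-bin, rank-assign distances).
- **Reconstruction** (`genome3d.reconstruct`): minimize the sum of squared
  errors between model bead-pair distances and targets, subject to nucleus
  containment, adjacent-bead stretch, minimum bead separation, optional
  nucleolus membership and fixed beads. Penalty scheme around an L-BFGS
  solver with analytic gradients; random restarts with lexicographic
  (violation, objective) model selection.
- **Predicted distances** (`genome3d.predicted`): ortholog-family mean
  projection of a second organism's distance map; codon usage frequency
  distance (symmetrized Kullback-Leibler against the mixture midpoint) from
  CDS FASTA; median scaling onto the target distance distribution and
  quantile band selection.
- **Sampling** (`genome3d.sampling`): uniform sparsification, coordinate
  permutation (random maps), and the degree-weighted "poor-get-richer"
  merge that adds predicted interactions preferentially to poorly covered
  beads.
- **Benchmarks & statistics** (`genome3d.benchmark`, `genome3d.gstats`):
  normalized set distance (NSD) co-localization, telomere radius,
  chromosome-arm ratios, inter-model similarity, 2,000-bin
  distance-covariate correlations, PPI graph distances, telomere
  clustering; one-tailed Wilcoxon tests and a 10,000-draw category
  permutation test.
- **Synthetic data** (`genome3d.synthetic`): seed-deterministic ground-truth
  genomes (clustered centromeres, peripheral telomeres, chromosome
  territories), distance-decaying Poisson contacts, planted co-localized
  locus sets, CDS with spatially structured codon usage, and a jittered
  "organism B" with an ortholog table — so the entire pipeline is testable
  offline.

## CLI

```bash
genome3d --seed 1 simulate --preset small --out data/
genome3d distances --contacts data/contacts.tsv --layout data/genome.tsv \
    --out dist.tsv --profile-out profile.tsv
genome3d --seed 2 sparsify --distances dist.tsv --layout data/genome.tsv \
    --fraction 0.05 --out sparse.tsv
genome3d --seed 3 integrate-cufs --distances sparse.tsv --layout data/genome.tsv \
    --cds data/cds.fasta --genes data/genes.bed --add-fraction 1.0 --out merged.tsv
genome3d --seed 4 reconstruct --distances merged.tsv --layout data/genome.tsv \
    --starts 4 --out model.xyz --report report.json
genome3d benchmark --models model.xyz --layout data/genome.tsv \
    --sets data/planted_compact.bed --out report.json
genome3d --seed 5 compare --a reports_a.json --b reports_b.json --paired \
    --n-perm 10000 --out compare.json
```

Other subcommands: `randomize` (permute map coordinates), `damp` (simulate a
smaller experiment), `integrate-ortho` (ortholog-projected distances).

## File formats

All I/O is plain text: genome layout TSV (`name, length_bp, centromere_bp`),
contact TSV (`chrom_i, pos_i, chrom_j, pos_j, count`), distance-map TSV
(`bead_i, bead_j, distance_nm`), BED locus sets (optional 4th column =
subset label), ortholog TSV (`gene_a, gene_b`), CDS FASTA, and XYZ/PDB model
exports (PDB records the nm scale in a REMARK header).
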