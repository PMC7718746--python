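# damidkit

Analysis toolkit for Targeted DamID (TaDa) occupancy profiling.  It covers
the downstream half of a DamID experiment — everything after read mapping —
plus the categorical phenotype statistics used alongside it:

- **GATC digestion** (`damidkit.fragments`): build the genome-wide map of
  DpnI/GATC fragments (the resolution unit of DamID signal) and assign
  fragments to transcripts by interval overlap.
- **Signal tracks** (`damidkit.tracks`): per-fragment log2(Dam-fusion/Dam)
  ratio tracks with reads-per-million equalization and a pseudocount;
  SD-scaling, replicate averaging, replicate Pearson concordance, and
  bedgraph I/O.
- **Occupancy calling** (`damidkit.occupancy`): length-weighted mean
  occupancy per transcript, with an empirical one-sided permutation
  p-value (genome-wide shuffles of (length, value) fragment pairs),
  Benjamini-Hochberg FDR, and reduction to one best transcript per gene.
- **Differential occupancy** (`damidkit.differential`): replicate-paired
  subtraction of genotype tracks, up/down calling on the averaged
  difference track, a numerator Pol II-bound filter for up-genes, and a
  fold-change threshold for down-genes.
- **Polycomb filter** (`damidkit.pcfilter`): genes with significant Pc
  occupancy in control, Pol II occupancy in both genotypes, and scaled
  Pc occupancy crossing 1.0 downward in the knockdown.
- **Phenotype statistics** (`damidkit.phenotype`): count reconstruction
  from printed percentages, two-tailed Fisher exact tests
  (point-probability definition, log-space exact enumeration), and Wilson
  score intervals without continuity correction.
- **Synthetic data** (`damidkit.simulate`): seeded toy genomes, gene
  models, ground-truth occupancy configurations and gamma-multinomial
  (negative-binomial-like) per-fragment counts, so the full pipeline is
  testable end to end without external data.

Small reference tables (phenotype scoring percentages and the
de-repressed gene table) ship under `damidkit.data`.

## Tests

```sh
python -m pytest tests/
```

The suite includes unit and property tests per module plus
`tests/test_acceptance.py`, which checks calibration (type-I error of the
permutation caller), truth recovery on the default synthetic design,
exhaustive-enumeration equivalence of the Fisher test, Wilson interval
coverage, and the reproducible printed statistics.

## CLI

The `damidkit` entry point chains the pipeline end to end:

```sh
damidkit simulate --seed 1 --outdir sim/
damidkit digest --fasta sim/genome.fa --gff sim/annotation.gff3 \
    --out-bed fragments.bed --out-assignment assignment.tsv
damidkit ratio --fusion-counts sim/counts_control_Dam-PolII_rep0.tsv \
    --dam-counts sim/counts_control_Dam_rep0.tsv \
    --fragments fragments.bed --out ctl0.bedgraph
damidkit aggregate --tracks ctl0.bedgraph --tracks ctl1.bedgraph \
    --fragments fragments.bed --out ctl_avg.bedgraph
damidkit occupancy --track ctl_avg.bedgraph --fragments fragments.bed \
    --assignment assignment.tsv --n-perm 1000 --seed 1 --out occupancy.tsv
damidkit diff --kd-tracks kd0.bedgraph --kd-tracks kd1.bedgraph \
    --ctl-tracks ctl0.bedgraph --ctl-tracks ctl1.bedgraph \
    --fragments fragments.bed --assignment assignment.tsv \
    --numerator-occupancy kd_genes.tsv --out differential.tsv
damidkit pcfilter --pc-ctl-track pc_ctl.bedgraph --pc-kd-track pc_kd.bedgraph \
    --fragments fragments.bed --assignment assignment.tsv \
    --pc-sig-ctl pc_occ.tsv --polii-ctl ctl_genes.tsv --polii-kd kd_genes.tsv \
    --out pcfilter.tsv
damidkit phenostats --table phenotypes.tsv --control ctl --out stats.tsv
```

All genomic coordinates are 0-based half-open internally and in BED /
bedgraph output; GFF3 is converted at the boundary.

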