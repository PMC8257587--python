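# permdiff

Permutation-null differential expression for isobaric (TMT) proteomics and
microarray transcriptomics, with NMF clustering of multi-model fold-change
matrices and Sørensen–Dice process-network construction. Every stage is
exercisable end-to-end on synthetic data with planted structure — no
downloads required.

## What it does

- **Proteomics (`dep`)** — peptide filtering (uniqueness, isolation purity
  > 0.75, max-log2-intensity above the 5th percentile), DE-peptide calling
  against a pooled TMT-channel-permutation null (two-tailed empirical p
  < 0.05 **and** |log2-median-ratio| above a cutoff derived from the 5th/95th
  null percentiles, with a >2-replicate quantification rule), and rollup to
  differentially expressed proteins (≥2 direction-consistent unique DE
  peptides), plus cross-fraction overlap.
- **Transcriptomics (`deg`)** — the integrative statistic: per-gene pooled-t
  and log2-median-ratio, 1000-resample empirical nulls, Stouffer-combined
  overall p (human rule: overall p < 0.05 and |LMR| > cutoff from the
  2.5/97.5 null percentiles) or the stricter yeast rule (p_T ≤ 0.01, |LMR| ≥
  cutoff from the 5/95 percentiles); probe collapsing; assembly of the
  quantile-normalized genes × models fold-change matrix over the DEG union.
- **NMF clustering (`nmf`)** — lossless positive/negative column embedding,
  multiplicative-update NMF (Frobenius loss, per-iteration loss history,
  deterministic NNDSVDa or seeded random init), element-permutation nulls for
  the gene activation values (right-sided empirical p, membership at
  p < 0.01), and cluster ranking by activation Euclidean norm.
- **Similarity (`similarity`)** — direction-consistent sibling-peptide
  selection, Pearson correlation of fold changes between experiments with a
  sample-permutation null (right-sided, 5000 permutations), hypergeometric
  DEP-overlap tests, and average-linkage/Euclidean model dendrograms
  (Newick export).
- **Enrichment & networks (`network`)** — one-sided hypergeometric gene-set
  enrichment against GMT collections (pass: p < 0.1 and ≥5 genes; optional
  EASE-style variant) and the Dice process network (edge iff shared genes
  ≥ 3 and Dice > 0.4, or an automatic 95th-percentile cutoff), exported as
  GraphML/SIF.
- **Simulators (`simulate`)** — TMT peptide tables, log2 microarray
  matrices, multi-model fold-change matrices with planted block clusters,
  and GMT collections with exact planted overlaps; all pure functions of
  (parameters, seed) with first-class truth tables.

## CLI

All stages share `--config config.yaml`, `--seed N`, `--out-dir DIR`, log to
stderr + `run.log`, write TSV outputs plus a deterministic `manifest.json`,
and are bit-reproducible under a fixed seed.

```bash
permdiff simulate tmt --n-proteins 1000 --frac-de 0.05 --fold 4 --seed 1 --out-dir sim
permdiff dep --peptides sim/peptides.tsv --channels sim/channels.tsv \
    --contrast senescent:young --fraction nucleus --seed 1 --out-dir dep_nuc

permdiff simulate microarray --n-genes 2000 --seed 2 --out-dir ma
permdiff deg --matrix ma/expression.tsv --groups ma/groups.tsv \
    --contrast case:control --variant human --seed 2 --out-dir deg_rs
permdiff fc-matrix --deg-dir deg_rs --deg-dir deg_lmb --model rs --model lmb \
    --out-dir fc

permdiff nmf --fc-matrix fc/fc_matrix.tsv --k 20 --n-perm 100 --top 10 --out-dir nmf
permdiff simulate gmt --n-terms 50 --universe 2000 --out-dir gmt
permdiff network --clusters nmf/clusters.tsv --gmt gmt/sets.gmt --cutoff auto \
    --out-dir net

permdiff similarity --dir-a dep_nuc --dir-b dep_cyt \
    --contrast-a senescent:young --contrast-b senescent:young --out-dir sim_out
```

Config defaults carry the published thresholds (100 channel permutations,
1000 transcriptomic resamplings, 5000 correlation permutations, k=100,
top-10 clusters, enrichment p < 0.1 with ≥5 genes, Dice > 0.4 with ≥3
shared genes); desk-scale runs override them via `--config`/flags.

## Layout

```
src/permdiff/
  config.py           thresholds, permutation counts, deterministic child seeds
  io.py               TSV/GMT/GraphML/SIF readers & writers, run manifests
  stats.py            quantile normalization, T/LMR, empirical nulls & p,
                      Stouffer combination, Z-score transform
  proteomics.py       peptide filters, DE-peptide calls, protein rollup
  transcriptomics.py  DEG calling (human/yeast), fold-change matrix
  nmf.py              embedding, MU-NMF, activation significance, ranking
  similarity.py       sibling peptides, FC correlation, overlap, dendrograms
  enrichment.py       hypergeometric enrichment, Dice process network
  simulate.py         synthetic data generators with planted truth
  cli.py              `permdiff` command-line entry points
```
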