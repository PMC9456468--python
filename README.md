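# keyreg

Key-regulator discovery from paired transcriptome/proteome evidence.

Given replicated two-population comparisons from three cell lines, the
pipeline:

1. **Differential expression** (`keyreg.de`) — transcripts via per-gene
   Welch t-tests on log2 ratios with Benjamini–Hochberg adjustment and a
   2-fold gate; proteins via emPAI (`10^(observed/observable) − 1`)
   normalized per replicate to the geometric mean of observed peptide
   counts, a "detected in ≥ 2 of 3 replicates" presence filter, and a
   2-fold gate on mean normalized abundances.
2. **TF candidates** (`keyreg.promoter`) — PWM scanning of promoter windows
   ([−1000, +100) around the TSS, both strands, log2-odds scores) with
   per-matrix thresholds calibrated by exact dynamic programming to
   minimize false-negative + false-positive rate ("minSUM" style), and a
   one-sided label-permutation enrichment test of hit density (per kb)
   against background promoters, BH-adjusted across the library.
3. **Master regulators** (`keyreg.mr`) — radius-bounded downstream cones on
   a directed regulatory network, a distance-weighted coverage score in
   [0, 1], and a permutation Z-score / empirical p against random gene sets
   of matched size (defaults: radius 10, score ≥ 0.2, Z ≥ 1.0, FDR ≤ 0.05).
4. **Rank integration** (`keyreg.rank`) — one point per membership in each
   of the six evidence lists (3 cell lines × {transcript, protein}) per
   category, singleton discard, TF ∩ MR intersection, total = TF + MR rank
   (maximum 12).

`keyreg.simulate` generates complete synthetic studies with a planted
regulator (network cascade, binding motif in DE-gene promoters, expression
shift, protein abundance fold) for end-to-end parameter-recovery
benchmarks. All generators and analyses are deterministic given a seed.

## CLI

```sh
keyreg --out-dir out --seed 1 simulate                  # synthetic study bundle
keyreg --out-dir out de-transcripts expr_LINE1.tsv --cell-line LINE1
keyreg --out-dir out de-proteins peptides_LINE1.tsv --cell-line LINE1
keyreg --out-dir out scan promoters.fasta pwms.jaspar \
       --yes-genes de_genes.txt --no-genes background.txt
keyreg --out-dir out mr-search network.sif --hits de_genes.txt
keyreg --out-dir out rank tf_ranks.tsv mr_ranks.tsv     # ranks-only mode
keyreg --config config.yaml --out-dir out --seed 1 run-all
```

Formats: expression and peptide tables are TSV with replicate columns named
`<population>_<replicate>` (populations `high`/`low`; peptide tables also
carry an `observable` column); promoters are FASTA; motif libraries are
JASPAR PFM or TRANSFAC matrix text; networks are SIF or two-column edge
TSV. All outputs are TSV; `run-all` writes per-stage tables, the final
`key_regulators.tsv` (entity, TF rank, MR rank, total rank), and a
`run_log.json` with every threshold, the seed and input digests. Reruns
with the same config and seed are byte-identical.

A `config.yaml` for `run-all` names the input files and thresholds:

```yaml
expression: {LINE1: expr_LINE1.tsv, LINE2: expr_LINE2.tsv, LINE3: expr_LINE3.tsv}
peptides:   {LINE1: pep_LINE1.tsv,  LINE2: pep_LINE2.tsv,  LINE3: pep_LINE3.tsv}
promoters: promoters.fasta
background_promoters: background.txt   # ids of background promoters
pwms: pwms.jaspar
network: network.sif
params: {fold_threshold: 2.0, alpha: 0.05, radius: 10, score_min: 0.2,
         z_min: 1.0, fdr_max: 0.05, n_permutations: 2000, seed: 1}
```

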