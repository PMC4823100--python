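# aerlnc

Analysis pipeline for lncRNAs regulated by **unliganded (apo) estrogen
receptor alpha** in breast cancer cells, and for their use as a luminal
subtype signature.

In hormone-deprived luminal breast cancer cells, ERα keeps working
without its ligand: knocking it down changes the expression of a
specific set of long non-coding RNAs. This package implements, end to
end, the computational workflow that defines and characterizes such a
set:

1. **Catalog construction** — a minimal negative-binomial Wald test on
   knockdown vs control counts (median-of-ratios normalization,
   moderated method-of-moments dispersion), consensus integration of DE
   calls from multiple algorithms with sign concordance, and the
   catalog filters: lncRNA biotypes only, transcript length ≥ 200 bp,
   and a blacklist of discordant annotations. Abundances are reported
   as RPKM = normalized reads / (longest-isoform kb × million mapped
   reads).
2. **Cis-regulation** — distance from each gene TSS to the nearest
   binding-site summit (capped at 1,000 kb), tested against 1,000
   biotype-matched random lncRNA sets with the one-sided Wilcoxon
   rank-sum test, plus a resampling empirical p-value.
3. **ChIP signal profiling** — binned tag-density matrices (±1 kb, 50 bp
   bins, 200 bp read extension, CPM) and promoter/enhancer calls from
   the H3K4me3/H3K4me1 ratio.
4. **Signature selection** — per-gene merit = mean over ten stratified
   CV folds of the χ² statistic between the equal-frequency-discretized
   gene and the subtype labels; genes with merit > 15 form the
   signature, evaluated by cross-validated MLP classification, Ward.D2
   clustering purity, and PCA.
5. **Guilt-by-association** — Pearson screen of all genes against a
   focal lncRNA; hits need |r| ≥ 0.7 *and* p < 0.001 (t-transform,
   n − 2 df).
6. **qRT-PCR harmonization** — two runs (N = 22, N = 20) merged by
   ranking, log-transforming, pairing order statistics through type-7
   quantiles, fitting the run-2-on-run-1 line (geometric-mean
   regression, 200-iteration bootstrap keeping the fit with smallest
   out-of-bag MSE), and adjusting run 2 onto run 1's location/scale;
   ER+ vs ER− tested by the two-sided Wilcoxon rank-sum test with
   Shapiro–Wilk checks.

Every stage has a synthetic-data generator (`aerlnc.synthetic_data`)
that plants known structure — regulated genes, proximal binding sites,
a luminal signature, correlated co-expression partners, a batch effect —
and returns its ground truth, so the whole pipeline is testable without
any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1 by default), writing tables under `results/`:

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_build_catalog.py   --seed 1
python analysis/03_distance_enrichment.py --seed 1
```

which prints:

```
catalog: 82 regulated lncRNAs (52 down / 30 up)
most abundant (RPKM in control):
  GENE01320: RPKM 1674.0, log2FC -2.12, down
recovered 98.8% of the 82 planted regulated genes
down-regulated (52 genes): median nearest-site distance 8.6 kb, Wilcoxon p = 6.1e-24, empirical p = 0.001
```

82 of the 2000 simulated genes were planted as knockdown-responsive
lncRNAs (65% down, mirroring the down/up imbalance such experiments
show); the catalog recovers almost all of them, and their TSSs sit
~9 kb from the nearest binding site — orders of magnitude closer than
biotype-matched random lncRNAs, which is the hallmark of direct
cis-regulation. Continuing with `04`–`07` profiles promoter marks at
catalog TSSs (100% promoter-like), selects a 32-gene signature whose
top-29 merit ranks contain 28 of the 29 planted luminal genes,
classifies the 55-sample panel at 98.2% ten-fold accuracy, recovers a
planted co-expression module at 10/10 with no false hits, and merges
the two qRT-PCR runs (ER+ vs ER− Wilcoxon p ≈ 1.6e-06).

The same pipeline is available as a CLI (`aerlnc demo --seed 1`, plus
per-stage subcommands `simulate`, `de`, `catalog`, `distance`,
`signal`, `merit`, `classify`, `cluster`, `coexpress`, `qpcr`), every
output carrying a provenance header and the demo closing with a
checksum manifest: the same seed reproduces identical bytes.

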