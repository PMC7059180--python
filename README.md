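# lncprio

Prioritizing disease-associated long noncoding RNAs (lncRNAs) from bulk
RNA-seq of multi-region case/control brain cohorts.

lncRNAs are hard to rank by differential-expression statistics alone: they
are lowly expressed and highly variable between individuals, so the genes
with the smallest FDR-adjusted p-values are often barely-expressed
transcripts nobody can validate, while robustly expressed, reproducibly
changed lncRNAs are buried mid-list. `lncprio` implements the full analysis
chain for this problem — cohort QC, expressed-gene and region-specificity
calling, covariate- and cell-type-compensated negative-binomial
differential expression, and a *combined calculated score* (CCS) that
merges expression level with disease significance:

    CCS(g) = log2(1 + CPM̄(g)) · (−log10 p(g))

so a candidate must be both expressed and changed to rank highly. Around
the score sit the study's class-level statistics (lncRNA-vs-PCG
variability and |log2FC| contrasts with bootstrap CIs, exact 2×2
enrichment tests, PRC2-target downregulation analysis, cross-region and
age-trend correlations, qPCR ΔΔCt quantification) and a cross-dataset /
cross-species candidate validation step. A synthetic-cohort generator with
full ground truth (planted fold changes, covariate confounding, a
case-associated cell-type composition shift, a PRC2 target set enriched
for downregulation) makes every stage testable end to end.

The differential-expression model is a per-region NB GLM with log link,
library-size offset, and covariates for age, sex, RIN and per-cell-type
marker scores ("compensation elements" for dopaminergic neurons,
astrocytes and microglia, which absorb tissue-composition change);
dispersions are moment-estimated with leverage correction and shrunk
toward an abundance trend; the condition effect is tested by a
quasi-likelihood F reference on the 1-df likelihood-ratio deviance.
See `docs/methods.md` for the statistical details and defaults.

## Worked example

Simulate a three-region cohort (2,000 genes, 14 PD vs 9 control donors per
region) and run the whole pipeline on it:

```sh
lncprio simulate --seed 7 --out data/
cat > cfg.yaml <<EOF
counts: data/counts.tsv
metadata: data/samples.tsv
markers_gmt: data/markers.gmt
prc2_gmt: data/prc2.gmt
out_dir: out/
seed: 7
EOF
lncprio run --config cfg.yaml
```

which prints (abridged):

```
Libraries retained: 63 (excluded: 6)
Expressed genes in SN (mean CPM > 1): 1694
...
DE in SN (FDR < 0.05): 3 (0 down, 3 up)
Candidate lncRNAs in SN: 1 selected from a pool of 1 with q < 0.1
  G1815  CCS=45.7  log2FC=+4.68  q=0.00453
CCS diagnostics (SN): rho(CCS, -log10 p) = 0.893; rho(CCS, |log2FC|) = 0.749
Variability (SN): median SD lncRNA = 0.706 vs PCG = 0.543 (Mann-Whitney p = 4.57e-34)
|log2FC| contrast [all]: lncRNA - PCG = +0.418 (99% CI +0.227 to +0.607)
SN-specific fraction: lncRNA 27/239 vs PCG 32/1455; fold = 5.14 (Fisher p = 2.08e-09)
```

Reading the numbers: 6 of 69 simulated libraries fail the annotated-read /
RIN filters; ~1,700 genes are expressed per region; the compensated NB
model finds 3 substantia-nigra DE genes at FDR < 0.05, of which one lncRNA
(G1815, a planted upregulated gene) survives the q < 0.1 candidate filter
and tops the CCS ranking. The class statistics recover the planted
structure: lncRNAs are more variable than protein-coding genes, carry
larger absolute fold changes (99% bootstrap CI excluding zero), and are
~5-fold enriched for region-specific expression — the qualitative
signature the score was designed around.

Each stage is also available separately (`lncprio qc`, `lncprio de`,
`lncprio prioritize`, `lncprio stats <subcommand>`), and everything is
importable as a library:

```python
import lncprio
counts, catalog, samples, truth = lncprio.simulate_dataset(lncprio.SimConfig(), seed=7)
```

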