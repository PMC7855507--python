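# regenseq

Consensus differential-expression calling, category overrepresentation, and
cell-type association for spinal-cord-injury (SCI) transcriptomics — the
post-quantification analysis used to compare regenerating and
non-regenerating spinal cords in the gray short-tailed opossum
(*Monodelphis domestica*), rebuilt as a tested, reusable Python package
driven by a synthetic-data generator with known ground truth.

## Who this is for

Researchers analysing two-group bulk RNA-seq count data who want a
deliberately conservative gene list: a gene is only accepted when **at least
2 of 3 independent scorers** call it differentially expressed at
Padj ≤ 0.05 and |log2FC| ≥ 1. The package also provides the downstream
stages that make such lists interpretable: Venn set algebra across
time-points and injury ages, GO-style binomial overrepresentation with
Bonferroni control, and cell-type association against a 7-cell-type CNS
reference transcriptome.

## The method

**Three DE scorers, one exact-test core.** Each scorer tests per-gene count
differences between injured and control groups with an exact negative-binomial
conditional test, conditioning on the total pseudo-count T of both group sums:
under the null, the group sums A and B are NB with sizes n₁/φ and n₂/φ, so

    P(A = a | A + B = T) ∝ f₁(a) · f₂(T − a),   a = 0 … T

and the two-sided p-value doubles the smaller tail (capped at 1). In the
φ → 0 limit this is exactly the binomial conditional test with success
probability n₁/(n₁+n₂). The scorers differ only in depth normalization —
upper-quartile (UQ), median-of-ratios (MOR), and depth-rescaled FPKM
pseudo-counts (equivalent to total-count factors) — mirroring the distinct
normalization strategies of the published DE tools the consensus design was
built around. Dispersions are method-of-moments estimates shrunk 50/50
toward the expression-decile trend; p-values are Benjamini–Hochberg
adjusted per scorer.

**Consensus voting.** Genes passing Padj ≤ 0.05 and |log2FC| ≥ 1 in ≥ 2
scorers with concordant direction enter the consensus set; the reported
fold change is the mean over the significant scorers only.

**Overrepresentation.** For a study set of n genes and a category with K of
N universe genes, over- and underrepresentation tails of Binomial(n, K/N)
are computed; the smaller tail and its direction are reported and
Bonferroni-corrected over the categories tested.

**Cell-type association.** Consensus genes map onto a reference giving each
gene's FPKM in seven CNS cell types (astrocytes, neurons, endothelial cells,
microglia, OPCs, newly formed and myelinating oligodendrocytes). Genes with
no ID mapping or with all reference values ≤ 0.1 FPKM are excluded and
reported; the rest become percentage-of-sum profiles (rows sum to 100),
clustered hierarchically (1 − Pearson correlation, average linkage,
deterministic leaf order) within time-point blocks, with top-10 up/down
rankings of genes unique to one injury age.

## Worked example

```python
from regenseq import (SimulationConfig, simulate_counts, CountMatrix,
                      run_de_suite, threshold_filter, vote)

cfg = SimulationConfig(n_genes=2000, fraction_de=0.05, lfc_magnitude=2.0,
                       dispersion=0.1, n_replicates_per_group=4, seed=1)
injured, control, truth = simulate_counts(cfg)
cm = CountMatrix.concat(injured, control)

results = run_de_suite(cm, test_group="injured")          # UQ, MOR, FPKM
filtered = {m: threshold_filter(r) for m, r in results.items()}
consensus = vote(filtered, label="+1d")

planted = set(truth.gene_ids[truth.de_flags])
print(len(consensus.genes))                                # 103
print(round(len(consensus.genes & planted) / len(planted), 2))   # 0.98
print(round(len(consensus.genes - planted) / len(consensus.genes), 3))  # 0.049
```

Of 100 planted DE genes (5% of 2,000 at |log2FC| = 2), the ≥2-of-3 consensus
recovers 98% while 4.9% of its calls are false — the conservative voting
keeps the list clean at small replicate numbers.

The same workflow runs from the shell:

```
regenseq simulate --seed 1 --out-dir run --n-genes 2000
regenseq de --counts run/counts.tsv --metadata run/metadata.tsv --out-dir run/de
regenseq consensus --de-tables run/de/de_UQ.tsv --de-tables run/de/de_MOR.tsv \
    --de-tables run/de/de_FPKM.tsv --out run/consensus.tsv
regenseq run-all --seed 1 --out-dir run_all     # full pipeline + manifest
```

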