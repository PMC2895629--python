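# pollenscreen

Stage-resolved screening of pollen transcriptomes.

Pollen develops through five stages — uninucleate microspore (UNM),
bicellular pollen (BCP), immature tricellular pollen (TCP), mature pollen
grain (MPG) and germinated pollen grain (GPG) — and an expression-array
experiment over these stages plus three sporophytic control tissues (callus,
root, leaf) asks: which transcripts are enriched or downregulated at a
particular stage, which are pollen-preferential, and which are expressed
constitutively everywhere?  `pollenscreen` implements that screening pipeline
as a tested, reusable Python package, together with expression-pattern
clustering, qRT-PCR confirmation statistics, cross-species conservation
summaries, and promoter word enrichment.  Because raw array data of this kind
is often unavailable, the package ships a synthetic-data generator with
planted ground truth, so every stage of the pipeline is verifiable end to end.

## The statistics

All screens work on per-tissue replicate medians.  For a focal pollen stage
with median $X_i$ and the set of reference tissue medians
$\{m_1,\dots,m_r\}$ (the focal stage is **excluded** from its own reference),

$$Z = \frac{X_i - \mu}{\mathrm{SD}}, \qquad
  \text{ratio} = \frac{X_i}{\max_j m_j},$$

with $\mu$ and SD the mean and sample standard deviation of the reference
medians.  Two reference sets are used:

| screen | reference tissues | cutoffs (defaults) |
|---|---|---|
| stage-enriched | 7 other tissues | ratio ≥ 2.0 and Z ≥ 3.75 |
| stage-downregulated | 7 other tissues | ratio ≤ 0.5 and Z ≤ −1.7245 |
| pollen-preferential | callus, root, leaf | ratio ≥ 2.0 and Z ≥ 3.19 |

The max-of-others ratio makes per-stage enriched sets provably disjoint: a
gene with ratio ≥ 2 at one stage has ratio ≤ ½ at every other.  Constitutive
transcripts are those with a present (P) detection call in ≥ 2 of 3
replicates in all eight tissues.

Standardized 5-stage profiles (per-gene mean 0, variance 1) are clustered by
seeded k-means for k = 3…7, and k is selected by the Pearson χ² association
between cluster assignment and functional category — the k with the most
significant association wins (df = (k−1)(C−1); for 5 clusters × 6 categories,
df = 20).  qPCR confirmation compares array and ΔΔCt profiles against the
exact two-tailed critical correlation $r^* = t^*/\sqrt{t^{*2}+n-2}$, which at
n = 8 samples gives 0.707 (α = 0.05) and 0.834 (α = 0.01).  Conservation
analysis filters 12-column BLAST tabular hits at E-value < 10⁻⁵ and keeps the
best bit-score subject per query.  Promoter words (3–8 nt) are tested
gene-level by a binomial upper tail against their presence probability in a
background promoter collection, with Benjamini–Hochberg correction within
each word length.

## Worked example

```python
from pollenscreen import SimulationConfig, simulate_dataset, run_screens, profile_correlation
from pollenscreen.clustering import standardize_profiles, select_cluster_number

cfg = SimulationConfig(seed=42, n_genes=5000)
dataset, annotation, truth = simulate_dataset(cfg)

result = run_screens(dataset)
for stage, genes in result.enriched.items():
    planted = set(truth.enriched_at(stage))
    print(f"{stage}: {len(genes)} enriched ({len(planted & genes)}/{len(planted)} planted recovered)")
print(f"pollen-preferential: {len(result.preferential)}")
print(f"constitutive: {len(result.constitutive)}")
print(f"r(MPG, GPG) = {profile_correlation(dataset).loc['MPG', 'GPG']:.2f}")

pref = truth.of_class("pollen-preferential")
profiles = standardize_profiles(dataset, list(pref))
cats = truth.table.loc[profiles.profiles.index, "functional_group"]
best_k, trace = select_cluster_number(profiles, cats, (3, 7), seed=0)
print(f"selected k = {best_k}")
```

prints

```
UNM: 160 enriched (88/88 planted recovered)
BCP: 102 enriched (102/102 planted recovered)
TCP: 104 enriched (104/104 planted recovered)
MPG: 92 enriched (92/92 planted recovered)
GPG: 106 enriched (106/106 planted recovered)
pollen-preferential: 1544
constitutive: 4281
r(MPG, GPG) = 0.79
selected k = 5
```

Every planted stage-enriched gene is recovered at its planted stage; the
extra UNM selections are pollen-preferential genes whose early-peaking
temporal pattern genuinely crosses the cutoffs.  The χ² selection recovers
the five planted temporal templates (k = 5) from the cluster-linked
functional categories.

The same pipeline is available from the shell:

```bash
pollenscreen simulate --seed 42 --n-genes 5000 --out-dir data/
pollenscreen screen --matrix data/matrix.tsv --calls data/calls.tsv \
    --design data/design.tsv --seed 42 --out-dir run/
pollenscreen report --run-dir run/ --out summary.txt
```

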