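# snpkinpca

Streaming kinship estimation, PCA and clustering of population structure
from VCF-formatted SNPs.

## The problem

Genome sequencing of large cohorts produces VCF files with tens of
millions of SNPs across thousands of samples. Principal component
analysis of such data is the standard first look at population structure,
but tools that load the full genotype matrix need memory proportional to
the number of sites. `snpkinpca` instead streams the VCF one site at a
time: each site updates two running `[n × n]` arrays (a pairwise
numerator and a pairwise weight) and is then discarded, so peak memory
depends on the **sample count only**. PCA is then an eigendecomposition
of the resulting `n × n` kinship matrix, followed by unsupervised
clustering of samples on the top principal components and a concordance
score against any prior group labels.

It is aimed at population and quantitative geneticists who want kinship →
PCA → clustering → plots from a single command without format conversion.

## Methods in brief

**Site filtering.** Indels, multiallelic and monomorphic-in-sample sites
are always discarded. Optional per-marker filters: minor allele frequency
(`maf ≥ t`), missingness (`miss ≤ t`) and a two-sided Hardy–Weinberg
exact test (`p ≥ t`; Wigginton-style enumeration conditional on allele
counts).

**Kinship (five estimators).** With dosage `g ∈ {0,1,2}` and ALT
frequency `p` per site:

| method | per-site pairwise term | missing-data policy |
|---|---|---|
| `Centered_IBS` (VanRaden) | `(g_i−2p)(g_j−2p)`, final ÷ `Σ 2p(1−p)` | mean-impute (`z = 0`) |
| `Normalized_IBS` (GCTA-style) | `(g_i−2p)(g_j−2p) / 2p(1−p)` | pairwise-complete |
| `IBSKinship` | `(2 − |g_i−g_j|)/2` | pairwise-complete |
| `IBSKinshipImpute` | same, after `g := 2p` imputation | all sites, all pairs |
| `p_distance` | `|g_i−g_j|/2`, reported as `1 − mean` | pairwise-complete |

**PCA.** Full symmetric eigendecomposition of K; scores are the unit-norm
top eigenvectors with a deterministic sign convention.

**Clustering.** Default: K-Means over K ∈ [2, 10] picks the K with the
best mean silhouette on the top three PCs, then a full-covariance
Gaussian mixture is fitted by EM, best of 1000 restarts (the first seeded
at the K-Means centroids). K-Means-only and DBSCAN are alternatives.
Concordance with prior labels is optimal one-to-one cluster↔group
matching accuracy (Hungarian assignment on the confusion matrix).

## Worked example

```python
from snpkinpca import PopulationModel, RunConfig, run_pipeline, simulate_structured_vcf

# synthetic world: 4 populations x 50 samples, 2000 SNPs, Balding-Nichols F=0.2
model = PopulationModel()
vcf, truth = simulate_structured_vcf(model, "ex.vcf")
outputs = run_pipeline(RunConfig(in_vcf=vcf, out_prefix="ex", group_path=truth))
```

or equivalently from the shell:

```sh
snpkinpca -InVCF ex.vcf -OutPrefix ex -InSampleGroup ex.vcf.truth
```

This writes `ex.kinship.matrix`, `ex.eigenval`, `ex.eigenvec`,
`ex.cluster`, `ex.pca2d.svg`, `ex.pca3d.svg` and `ex.log`. With the
defaults above:

- `ex.log` reports `sites_read=2000`, `monomorphic=17`, `sites_used=1983`
  — 17 simulated sites drifted to fixation and were gated out.
- `ex.eigenval` starts `20.2626, 19.4532, 18.2982, 1.49654, ...`: three
  eigenvalues stand far above the bulk, exactly the number of axes needed
  to separate 4 populations.
- `ex.cluster` ends `#K=4 method=EM-Gaussian concordance=1` — the
  pipeline infers 4 clusters that match the generative population labels
  perfectly.

Re-clustering without re-reading genotypes:

```sh
snpkinpca -InKinship ex.kinship.matrix -OutPrefix ex2 -InSampleGroup ex.vcf.truth
```

reproduces `ex.eigenvec` and `ex.cluster` byte for byte.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates the standard 4-population world from the given seed, runs the
default end-to-end pipeline (streaming kinship → PCA → best-K →
EM-Gaussian → concordance), prints the inferred K and concordance, and
writes the results JSON.

## Layout

- `src/snpkinpca/vcf_io.py` — streaming VCF reader, dosage encoding, sample subsetting
- `src/snpkinpca/site_filter.py` — site statistics, HWE exact test, filters
- `src/snpkinpca/kinship.py` — the five single-pass estimators and the kinship file format
- `src/snpkinpca/pca.py` — eigendecomposition and PCA outputs
- `src/snpkinpca/clustering.py` — best-K K-Means, EM-Gaussian, DBSCAN, concordance
- `src/snpkinpca/pipeline.py`, `cli.py`, `viz.py` — orchestration, flags, 2D/3D plots
- `src/snpkinpca/fixtures.py` — Balding–Nichols synthetic VCF generator
- `docs/methods.md` — model details, defaults and limitations
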