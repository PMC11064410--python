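# Methods

## Streaming model

The pipeline never holds a genotype matrix. The VCF reader yields one
site at a time; each accepted site updates a `KinshipAccumulator` holding
two symmetric `[n × n]` float64 arrays — a pairwise numerator and a
pairwise weight — plus two scalars (`Σ 2p(1−p)` for the centered
estimator, and the used-site count). Finalization divides numerator by
denominator and symmetrizes exactly. Peak memory is therefore
`O(n²)` in the sample count and independent of the number of SNPs; the
test suite asserts this structurally (same array objects, same byte
sizes, no new attributes after a 10× longer stream) rather than by RSS
measurement, which is scheduler-noisy.

Summation is plain double-precision in file order, no compensated
summation; site-order invariance is verified to 1e-12 on test-sized data.

## Genotype encoding

Only the GT subfield is read. `0/0→0`, `0/1`,`1/0→1`, `1/1→2`; `|` and
`/` are equivalent. Any `.` allele (including half-missing `0/.`) and
haploid calls map to MISSING — the diploid dosage model cannot represent
one allele unambiguously; the first haploid call triggers a one-time
warning. Allele indices beyond the ALT count are format errors with the
line number. FILTER/QUAL/DP/GQ are ignored: all filtering here is
site-statistic based.

## Site filtering

Mandatory gate: a site survives only if it has exactly one ALT, REF and
ALT are single bases A/C/G/T, and both alleles are observed among called
genotypes. Monomorphic-in-sample sites are gated (they carry no pairwise
information and break frequency standardization at p ∈ {0,1}); true
minor-allele-count-1 sites are biallelic and are left to the MAF filter.

Optional thresholds (defaults `maf_min=0.001`, `miss_max=0.25`,
`hwe_min=0`, all CLI-overridable): boundary values are kept (≥/≤), and
`hwe_min=0` makes the HWE filter inert. The HWE test is the two-sided
exact test conditional on observed allele counts, computed on called
genotypes only via log-gamma; configurations whose probability is within
a 1e-10 relative band of the observed one count as ties and are included
(exact rational ties would otherwise be lost to float rounding). An
exact-rational enumeration oracle pins the test for every configuration
up to 50 genotypes.

## Kinship estimators

Allele frequency `p` used for centering/standardizing is always the
site's ALT frequency among called genotypes. Missing-data policies:

- `Centered_IBS`: mean-imputation (`z = g − 2p := 0`), denominator
  `Σ 2p(1−p)` over used sites — the standard centered-GRM construction.
- `Normalized_IBS`: per-site standardized product averaged over
  pairwise-complete sites; a sample missing at a site leaves all its
  pair weights for that site untouched.
- `IBSKinship`, `p_distance`: pairwise-complete averages of shared-allele
  and differing-allele fractions respectively. `p_distance` is reported
  as similarity `1 − d` so all five estimators are orientation-compatible
  inputs to PCA.
- `IBSKinshipImpute`: missing dosages imputed to the site mean `2p`
  (real-valued), after which every site contributes to every pair. The
  alternative reading — imputing the major-allele genotype — was
  rejected as lossier; the choice is frozen by the oracle tests.

A sample pair sharing zero called sites under a pairwise-complete method
is an error naming the pair. All five estimators are pinned against an
independent dense-matrix implementation at 1e-10.

The kinship file is plain text: a tab-separated header of sample IDs,
then one row per sample (ID + n floats). Cells are written at `%.17g` so
the round-trip is bit-exact and a `-InKinship` re-run reproduces the
direct run identically; 10 significant digits would already round-trip
the matrix to ~1e-11 but can flip printed digits of near-degenerate
trailing eigenvectors.

## PCA

Full `eigh` decomposition, eigenvalues sorted descending. Scores are the
raw unit-norm eigenvectors (smartpca/GCTA convention), not
eigenvalue-scaled projections; sign is fixed by making the
largest-magnitude entry of each eigenvector positive (lowest index wins
ties). Negative eigenvalues — possible when missing data makes a
pairwise-complete matrix slightly non-PSD — are kept in `.eigenval` but
clipped to zero in variance-explained fractions. Default retained PCs:
10; clustering consumes the top 3.

## Clustering

- **Best-K**: K-Means (k-means++, 10 restarts) for each K in [2, 10];
  the K maximizing mean silhouette wins, ties toward smaller K.
  Silhouette was chosen as a bounded, deterministic-under-seed criterion;
  it is known to over-split very small panels (n ≲ 30), where the K range
  should be narrowed by hand.
- **EM-Gaussian**: full-covariance mixture at the chosen K; 1000
  restarts, the first initialized at the K-Means centroids, the rest at
  Gaussian perturbations of them at the per-dimension data scale.
  Per-restart: pooled data covariance as the initial component
  covariance, uniform weights, convergence at relative log-likelihood
  change < 1e-6 or 500 iterations, covariance diagonals regularized by
  +1e-6. The highest converged log-likelihood wins; hard labels are
  argmax posteriors. The restart protocol (rather than data resampling)
  is the interpretation adopted for a "many bootstraps" refinement whose
  output is a single hard clustering of all samples.
- **DBSCAN**: default `eps` = mean distance to the 4th nearest neighbor,
  `min_pts = 4`; noise is labeled −1 and excluded from K.
- **Concordance**: Hungarian assignment on the cluster×group confusion
  matrix; matched agreement over scored samples, samples with prior
  label "NA" excluded. Equals 1 iff the partitions coincide on scored
  samples with equal cluster counts.

All stochastic steps derive from one seed (default 12345); identical
configuration and seed give byte-identical numeric outputs (SVG output is
also made deterministic by fixing the hash salt and dropping date
metadata).

## Synthetic data

`simulate_structured_vcf` emulates a structured panel: ancestral
frequencies Beta(1,1) clipped to [0.05, 0.95] (so most simulated sites
segregate), per-population frequencies Balding–Nichols
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, genotypes Binomial(2, pop freq), i.i.d.
across sites. Defaults — 4 populations × 50 samples, 2000 SNPs, F = 0.2,
no missingness or contamination — are the standard test world: F = 0.2
differentiation is large relative to binomial sampling noise at 2000
sites, so the default pipeline recovers the generative K and labels.
Contaminant indel/multiallelic/monomorphic records and missing genotypes
can be injected at stated fractions with exact counts.

What the generator does **not** emulate: linkage disequilibrium,
admixture/clines, relatedness within populations, genotyping error
correlated with depth, or realistic site frequency spectra. A green
end-to-end test therefore establishes correct mechanics and recovery of
island-model structure, not performance on admixed or LD-rich cohorts.
Balding–Nichols frequencies can drift to fixation in one population by
chance; such sites are handled by the monomorphic gate, which is why
simulated worlds report a small `monomorphic` discard count.

## Degenerate inputs and numeric edges

- Zero kept sites → explicit "no sites survive filters" error.
- All-identical points in best-K → error (silhouette undefined).
- Asymmetry beyond 1e-8 in a user-supplied kinship matrix → error.
- EM component collapse (singular covariance or empty component) voids
  that restart; all restarts degenerate is an error.
- Haploid/partial genotypes never silently enter dosage arithmetic.

## Known limitations

- Single-threaded; `-Threads` is accepted for interface compatibility
  only, and results are thread-count invariant by construction.
- No BCF/PLINK input, no tabix random access, no LD pruning, no
  per-sample missingness filter, no projection of new samples onto
  existing PCs.
- Eigendecomposition is dense `O(n³)`: fine for thousands of samples,
  not for hundreds of thousands.
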