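# Methods

`islescan` implements a genome scan for local adaptation contrasting two
groups of populations ("mainland" vs "island") genotyped on a medium-density
SNP array.  This note records the statistical models, the synthetic-data
generator that stands in for real genotypes, and the numerical and design
choices a maintainer would want to know.

## Synthetic genotypes

Real mainland–island genotype sets of this kind are rarely deposited, so the
package ships a generator whose defaults are the reference scenario used in
tests and in `scripts/acceptance.py`: 90 mainland and 147 island samples, 26
autosomes of 100 Mb carrying 1,500 markers each (~39k markers, emulating a
50k array after QC), background differentiation 0.05, one strongly
differentiated locus on chromosome 4, three parent–offspring-like pairs, 1%
missing genotypes, and sampling coordinates at two Gaussian-jittered cluster
centres on a lon/lat scale.

**Allele frequencies.** Each marker draws an ancestral frequency
`p0 ~ Uniform(0.05, 0.95)`; population frequencies follow the
Balding–Nichols model, `p_i ~ Beta(p0(1-c)/c, (1-p0)(1-c)/c)`, where the
drift parameter `c` equals the expected F_ST against the ancestor.
Degenerate draws (numerically 0 or 1) are redrawn.

**Planted "adapted" loci.** A locus requested at `fst_selected` is drawn
from the same Beta family but rejection-sampled until its realized Nei F_ST
`1 - H_S/H_T` lies within 0.05 of the request.  A raw Balding–Nichols draw
at a large `c` is too erratic to serve as a planted signal — its median
realized differentiation is far below `c` (a Beta with `a+b = (1-c)/c = 1.5`
at `c = 0.4` mostly lands near the ends) — so pinning the realized value is
what makes "a locus planted at F_ST 0.4" a well-defined stimulus.

**Linkage disequilibrium.** Haplotypes are built by a first-order Markov
copying process: each haplotype carries a latent uniform per marker that is
either copied from the previous marker or redrawn.  Two markers that share
the latent uniform are comonotone, so their correlation equals the Fréchet
bound `A(p, p') = (min(p,p') - pp') / sqrt(pq p'q')`; averaged over the
frequency distribution this bound is `A2bar ≈ 0.34`, which caps the
attainable r².  A single switch rate would make E[r²] decay exponentially
with distance, which is the wrong shape; instead every haplotype draws its
own per-kb switch rate `s ~ Gamma(1/2, θ)`, giving shared-segment survival
`E[e^{-sd}] = (1+θd)^{-1/2}` and hence

    E[r²](d) ≈ A2bar / (1 + θ d),

the same hyperbolic (Sved-type) shape as the target `1/(1+4βd)`.  θ is
calibrated by bisection so that the least-squares Sved fit applied to the
implied expected curve — evaluated over the realized map's own pair-distance
distribution — returns the requested `ld_beta`.  Calibration targets
unbiased *recovery of β*, not pointwise curve equality, because the
attenuation ceiling makes the target unattainable below ~4 kb.  Measured
recovery error is under 10% at 2×200 samples and 10k markers (the budgeted
tolerance is 25%, reflecting the Markov approximation).

**What the generator does not emulate.** Frequencies and LD are generated
independently, so there is no hitchhiking: a planted locus is a one-marker
spike in frequency space and its neighbours are unaffected.  The
`impose_sweep` helper fills this gap for diagnostics testing by rewriting a
window around a focal marker with a linearly relaxing frequency profile
(population 1 pulled toward fixation at 0.98, population 2 toward 0.25 —
deliberately below 0.5, since an exactly intermediate frequency maximizes
heterozygosity and would cancel the diversity dip the classifier looks
for).  There is also no recombination-rate variation, no mutation model,
and no ascertainment bias; missingness is uniform rather than
marker-clustered.  Tests passing on these data therefore certify the
estimators and the pipeline plumbing, not robustness to array artefacts.

## Quality control

Fixed filter precedence so exclusion accounting is reproducible: samples by
call rate (< 0.95 removed), then relatedness; markers by autosome membership
("1".."26"), call rate (< 0.95), MAF (< 0.05, strict), Hardy–Weinberg exact
test (p < 1e-5), then LD pruning (r² > 0.5 in 50-SNP windows stepping 5,
dropping the lower-MAF member, ties to the later position).  A marker counts
toward the first criterion it fails.

Relatedness uses method-of-moments IBD estimation in the PLINK `--genome`
style: identity-by-state class totals are compared with their expectations
under IBD states 0/1/2 computed from sample allele frequencies, and
`pihat = P(IBD=1)/2 + P(IBD=2)`.  PLINK's finite-sample correction factors
are omitted; the bias is O(1/n) and irrelevant at the 0.25 pruning
threshold.  Pruning is greedy: repeatedly remove the sample in the most
pairs above threshold (ties: lower call rate, then lexicographically later
id), which retains a maximal set in star-shaped families.

The Hardy–Weinberg test enumerates every heterozygote count compatible with
the observed allele counts (log-space weights `2^h / (n_AA! n_AB! n_BB!)`)
and sums probabilities not exceeding the observed configuration's — the
standard exact SNP-HWE construction.

## Differentiation scans

**Per-SNP F_ST** is the Weir–Cockerham variance-component estimator
`θ = a/(a+b+c)` from two-population genotype counts, with observed
heterozygosity entering `b` and `c`.  Negative estimates are truncated to 0
for ranking and window averaging; the signed value is retained.  Outliers
are values strictly above the 99.999th percentile of the truncated empirical
distribution (order statistics with linear interpolation — at n markers this
bound sits between the largest and second-largest value).  Windowed
estimates average truncated θ in non-overlapping 500-kb windows tiled from
position 1; windows with fewer than 4 SNPs are discarded.

Note on parameter recovery: the *mean of per-SNP ratios* is not a consistent
estimator of the drift parameter (a Jensen-type bias of about −16% relative
at c = 0.1, present even with population frequencies known exactly).
`fst_overall` therefore implements the standard multilocus ratio-of-sums
`Σa / Σ(a+b+c)`, which recovers c; recovery is exercised at
c ∈ {0.02, 0.05, 0.1}.

Detection power of the percentile rule is itself a computed quantity
(`planted_outlier_detection_pct` in the acceptance output): under the
Balding–Nichols background the extreme tail is heavy — with c = 0.05 and
10,000 markers, roughly 0.5 neutral loci per genome exceed parametric
θ = 0.5 — so a locus pinned at F_ST 0.4 tops the genome-wide ranking in only
~60% of replicates.  Real array data tend to have a much lighter-tailed
empirical F_ST distribution, where the same rule isolates a single marker.

**FLK.** Population allele frequencies are whitened by the drift covariance
F of a population tree: with `p̂0 = (1'F⁻¹p)/(1'F⁻¹1)`,
`T = (p - p̂0 1)' F⁻¹ (p - p̂0 1) / (p̂0(1-p̂0))` is referred to χ² with
npop−1 degrees of freedom, and p-values are BH-FDR adjusted (significant at
FDR ≤ 0.1, boundary inclusive).  F comes from a neighbor-joining tree of
Reynolds distances `D = -ln(1-θ)` (ratio-of-sums coancestry estimator with
the finite-sample correction); `F[i,j]` is the branch length shared by the
root-to-leaf paths, after midpoint rooting (3+ populations) or an equal
split of the single edge (2 populations, no outgroup).  With two populations
the per-population drift is unidentifiable — pairwise Reynolds distance
estimates the *mean* of the two drifts, so the equal split halves each
branch and roughly doubles T.  Two-population FLK p-values are therefore
useful as ranks, not as calibrated tail probabilities; the null-calibration
test supplies the matched F and verifies the statistic itself is χ²
distributed (KS < 0.02 at 10k markers).

## Linkage disequilibrium

r² for unphased data is the composite estimator: squared Pearson correlation
of dosage vectors over pairwise-complete samples.  The per-marker LD score
is `1 + Σ r²` over markers within half the window size (500 kb or 1 Mb) on
each side, truncated at chromosome ends; the leading 1 is the self term.
Score distributions of the two origins are compared by the two-sided
Wilcoxon rank-sum test (exact when the combined n ≤ 20 without ties, else
the normal approximation with midranks, tie and continuity corrections).

Sampling inflation is removed by the Hill–Robertson correction
`r'² = (r² - 1/N)/(1 - 1/N)` with N the haplotype count (twice the
pairwise-complete individuals).  The decay of r'² with distance d (kb) is
fitted by nonlinear least squares to the Sved-type curve `y = 1/(1+4βd)`
(Levenberg–Marquardt, β initialized by closed-form inversion at the
distance-weighted mean point, relative-change tolerance 1e-10, SE from the
Gauss–Newton information, CI95 = β ± 1.96·SE), on pairs within 2,500 kb.
Pairs with non-positive r'² are excluded by default — the convention for
corrected empirical r², whose non-positive values are correction artefacts.
That truncation is *not* innocuous for data with symmetric additive noise:
it biases β̂ down by ~30% in a direct experiment, so the Monte-Carlo
recovery check runs with `exclude_nonpositive=False` (mean β̂ within 0.005
of 0.10, CI coverage ~95% at noise sd 0.05, 5,000 pairs).  Both a
within-gene pair universe (`pairs_within_genes`) and an all-pairs mode
(`ld_pairs`) are exposed, since either can be the relevant universe.

## Population structure and association

The genomic relationship matrix is VanRaden method 1 (`ZZ'/Σ2p(1-p)`,
missing dosages mean-imputed per marker), with an IBS alternative behind a
flag.  PCA takes the top eigenvectors scaled by the square roots of their
eigenvalues; percent variance is `100·λ_i/trace(K)` and the
largest-magnitude loading of each component is made positive for
deterministic signs.

The association scan is an EMMAX-style approximation for the binary origin
phenotype (0 island, 1 mainland, treated as quantitative; intercept-only
fixed effects, since herd is confounded with origin).  REML variance
components of `y = μ + u + e`, `u ~ (0, σ²_g K)`, are estimated once by
profiling the REML log-likelihood in `δ = σ²_e/σ²_g` on the spectrum of the
intercept-projected K (49-point log grid, refined by bounded scalar
minimization to 1e-8); they are then held fixed while each mean-imputed SNP
is tested by GLS on the whitened data (Wald t, n−2 df).  With K = I the scan
reduces exactly to per-SNP ordinary least squares (verified to 1e-8).
Diagnostics: BH-FDR (genome-wide significant below 0.05),
`pve = β̂² var(g)/var(y)` reported as a proportion in [0, 1], the genomic
inflation factor `λ = median(χ²₁ quantiles of p)/0.4549`, and a Q-Q table.

## Spatial statistics and the selective-process diagnostic

Global Moran's I of PC1 over sampling coordinates uses row-standardized
inverse-distance weights by default (k-nearest-neighbour optional; exact
duplicate coordinates require a jitter).  `E[I] = -1/(n-1)`; Z and the
two-sided p come from the randomization-variance formula, with an optional
seeded permutation p.  The point pattern itself is described by
nearest-neighbour distances and a Gaussian-kernel intensity surface
(Silverman bandwidth default, 10%-margin grid; the unweighted intensity
integrates to ~n) plus a Nadaraya–Watson surface of the values.

Around an outlier marker, the ±1 Mb profile of truncated F_ST, avHo (mean
observed heterozygosity of the two populations) and dHo (their difference)
is smoothed by degree-1 loess with tricube weights over the `ceil(span·n)`
nearest markers (span 0.21, no robustness iterations); local-linear fits
reproduce straight lines exactly and degenerate to a single weighted linear
fit at span 1.  The qualitative local-adaptation pattern — co-located F_ST
peak, avHo dip, |dHo| peak — is operationalized as: smoothed F_ST maximum
and smoothed |dHo| maximum both within 100 kb of the focal marker, and
smoothed avHo at the focal position below the window median.  The margins
are reported so a borderline call can be inspected; the 100-kb co-location
and the median comparison are configuration-exposed because no principled
constants exist for a visual rule.

## Candidate features

Features (genes, QTLs) from BED (0-based half-open) or GFF3 (1-based
inclusive) are converted to the internal 1-based half-open convention.  A
feature is reported for a marker when the gap to its nearest edge is at most
500 kb (inclusive; 0 if the marker lies inside).  Published tables of this
kind sometimes print distances under a different, unstated edge/orientation
convention; the edge-gap rule here is pinned and tested.

## Reproducibility and problem sizes

All randomness flows from a single seed through named `SeedSequence`
substreams; `run_all` writes a summary JSON that is byte-identical across
runs at the same config and seed.  The test suite and the acceptance script
use the reference scenario at full 50k-array scale for the pipeline run
(one to two minutes end to end) and smaller replicate grids — 10k markers,
2×60 to 2×200 samples, 20 seeds — for calibration and power experiments,
sizes chosen to give Monte-Carlo error comfortably inside the stated
tolerances.

## Known limitations

* PED files carry no allele list, so polarity at markers monomorphic in the
  data cannot round-trip through text format (binary BED/BIM does).
* Two-population FLK p-values are inflated by the drift-scale
  unidentifiability discussed above; with three or more populations the
  midpoint-rooted tree identifies the scale.
* The percentile outlier rule's power against a heavy-tailed neutral
  background is limited (see the scan section); the windowed statistic and
  the FLK-agreement report mitigate but do not remove this.
* The mixed model treats a binary phenotype as quantitative, as is standard
  for this approximation; no logistic mixed model is provided.
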