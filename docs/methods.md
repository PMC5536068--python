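# Methods

`mirdc` implements an integrative analysis of paired miRNA and mRNA
expression profiles from a two-condition, within-subject design (each of N
subjects contributes one diseased and one normal sample). It answers two
questions: which pathways change their *expression* between conditions, and
which pathways change their *co-expression* with individual miRNAs or with
the whole assayed miRNome — the latter capturing regulatory rewiring that
differential expression alone cannot see.

## Model and statistics

### Paired differential expression

For each feature (gene or miRNA) the within-pair log2 differences
d_k = x_diseased,k − x_normal,k are tested with a two-tailed paired
Student's t (df = N−1). BH step-up FDR is applied per omic. The fold
change is reported on the signed-linear convention fc = 2^d̄ for d̄ ≥ 0 and
−2^(−d̄) otherwise, so |fc| ≥ 1 and the sign tracks direction. Features
whose differences have zero variance are flagged (t, p = NaN) rather than
given an arbitrary p.

### Random-set restandardized enrichment for DE

Gene i's t statistic is mapped to a non-negative score
s_i = |Φ⁻¹(F_df(t_i))|, where F_df is the t CDF; under the null the s_i
behave like |N(0,1)| draws whatever the df. A set Γ of K of the G genes is
scored by

    Z(Γ) = √(K(G−1)/(G−K)) · (S̄ − μ)/σ,

with S̄ the member mean and μ, σ the mean and population standard deviation
of all G scores. Under random set membership (sampling K of G scores
without replacement) Z has mean 0 and variance 1 exactly — the √(K(G−1)/(G−K))
prefactor is the finite-population correction.

Significance respects two nulls at once. The sample-label null is addressed
by permutation: condition labels are swapped independently within each
subject pair (the 2^N relabelings that preserve the paired design's
exchangeability), and the entire pipeline t → s → (μ, σ) → Z is recomputed
for each relabeling — recomputing the moments inside the permutation is the
*restandardization*, which folds the gene-identity null into the reference
distribution. The p-value is one-sided (only large Z is evidence of
deregulation), estimated as (1 + #{Z_b ≥ Z_obs})/(B+1) for B sampled
relabelings. The identity relabeling is excluded from the random draws
because the add-one term already stands for it; in exhaustive mode (all 2^N
relabelings, feasible for N ≤ 20) the estimate is the plain enumeration
fraction including the identity. Relabelings whose Z matches Z_obs within
1e−9 count as ties, so exact symmetries (e.g. the full mirror swap) are
handled conservatively. The same relabelings are shared by every set in a
run so set-level results are comparable.

The score transform's df follows the statistic actually computed — paired,
df = N−1, by default — with a two-sample (2N−2) switch exposed for
compatibility with the classical two-sample formulation of the score.

### Differential co-expression (DC)

Within each condition the co-expression of gene i and miRNA j is the
Spearman coefficient ρ_ij (Pearson correlation of average-rank vectors),
computed for all G×M pairs via one matrix product of standardized rank
matrices. Ranks make the measure invariant to monotone per-feature
transforms, so whether expression was logged upstream is irrelevant.
The DC score is

    s_ij = |T(ρ_ij) − T(ρ̃_ij)|,    T(x) = √((N−3)/1.06) · atanh(x),

the absolute change of the variance-stabilized Fisher z between conditions.
The 1.06 factor is the Fieller inflation of the Fisher-z variance for
Spearman coefficients; with it, T(ρ̂) is approximately N(0,1) under
independence (empirically Var(T) ≈ 0.92–0.97 for N between 10 and 30), so
s_ij behaves like the absolute difference of two standard normals when
nothing changes. ρ̂ is clipped at 1 − 1e−7 before the transform; features
constant within a condition yield flagged (NaN) entries that are excluded
from all means with K reduced accordingly.

### DC pathway enrichment

Two random-set statistics are built from the score matrix. Per miRNA j,

    Z_j(Γ) = √(K(G−1)/(G−K)) · (S̄_j − μ_j)/σ_j

with column-j moments; miRNome-wide,

    Z(Γ) = √(KM(GM−1)/(M(G−K))) · (S̄ − μ)/σ

with S̄ the mean over the K×M member block and μ, σ from the full G×M
matrix. Since M(G−K) = GM − KM, the miRNome statistic is exactly the
generic random-set form with K → KM and G → GM, and at M = 1 the two
coincide (asserted in tests to 1e−12). The raw s_ij are used without an
additional quantile re-mapping: T is already approximately standard normal
under the null, so the scores are on the scale the transform in the DE
branch exists to produce.

Permutation significance again uses within-pair swaps, with the Spearman
matrices, scores and moments recomputed in full for every relabeling. BH
corrects across sets in miRNome mode and across all set×miRNA pairs in
per-miRNA mode; both families are recorded in the output metadata. A miRNA
is called DC with a pathway when its per-miRNA enrichment p < 0.01
(configurable).

### Integrative reporting

The DE-significant and DC-significant pathway lists (default α = 0.01) are
compared with a one-sided Fisher's exact test on the 2×2 incidence table,
alongside the chance-expected count round(n_sets·α) — for the collection
sizes typical of GO-term and canonical-pathway collections (1454 and 1330
sets) that is 15 and 13 at α = 0.01. miRNAs are ranked by the number of DE
pathways they are DC with; a user-supplied list of disease-associated
miRNAs can be validated with a one-sided Wilcoxon rank-sum test of its
ranking counts against all remaining miRNAs (the deterministic limit of
comparing with random miRNA lists; a seeded Monte-Carlo resampling variant
is available) plus a Fisher test of its overlap with DE miRNAs.

## Synthetic data

The generator emulates the structure of such a study: per-feature baselines
(N(8,1), a typical log2 intensity scale), a per-subject random intercept
shared between a subject's two samples (sd = 0.5 × noise_sd, giving mild
within-pair correlation), and unit-sd Gaussian noise. Differential
expression is planted as an additive shift in the diseased condition.
Differential co-expression is planted on the latent Gaussian scale: member
genes of a planted pathway are generated as c·z_m + √(1−c²)·ε against the
coupled miRNA's standardized values, with condition-specific coupling c, so
the marginal variance is constant while the within-condition correlation
changes. The population Spearman correlation implied by latent coupling r
is (6/π)·asin(r/2), used when translating planted couplings into expected
rank correlations. DC-planted genes inherit their pairing correlation
through the coupled miRNA's intercept rather than carrying their own.

What the generator does *not* emulate: probe-level microarray noise,
batch effects, heavy-tailed or count-scale expression, correlated gene
blocks outside planted pathways, and realistic gene-set overlap structure.
Passing recovery and calibration tests therefore shows the statistics are
correct and well calibrated under an idealized Gaussian paired design, not
that the pipeline is robust to array artefacts — those are assumed handled
by upstream normalization.

## Numerical choices

- Population (divide-by-G) standard deviations in all random-set moments.
- Score-transform CDF values clipped to [1e−16, 1−1e−16]; correlations to
  |ρ| ≤ 1 − 1e−7; both keep statistics finite at the boundary.
- Permutation ties counted with a 1e−9 slack (conservative).
- p estimates never return 0: add-one form for sampled relabelings, and
  exhaustive enumeration always counts the identity.
- Zero-variance features: flagged NaN in DE; excluded-with-K-reduction in
  DC means; an all-degenerate score vector raises an error instead of
  producing Z.
- BH is computed by `statsmodels.stats.multitest.multipletests`; NaN
  p-values are excluded and reinserted as NaN.
- One parent seed per pipeline run derives independent per-stage seeds via
  `numpy.random.SeedSequence`.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| B | 1000 | within-pair relabelings per enrichment run |
| alpha_de | 0.01 | pathway-level DE significance |
| alpha_dc | 0.01 | per-(set, miRNA) DC significance |
| alpha_feature | 0.05 | per-feature DE threshold (0.01 also reported) |
| min/max set size | 5 / G−1 | gene-set size bounds after mapping |
| noise_sd | 1.0 | generator noise, log2 units |
| intercept ratio | 0.5 | subject-intercept sd as a fraction of noise_sd |

Small sets (K < 5) are dropped because the random-set moments become
unstable; a set equal to the whole universe is dropped because G−K = 0.

## Verification problem sizes

Calibration is assessed on null studies of G=300 genes, M=20 miRNAs, N=10
pairs with 30 random sets, B=200 relabelings and 20 seeds (600 p-values per
engine); recovery on 20 replicates of G=1000, M=50, N=15 with one planted
pathway (K=30) whose coupling to one miRNA changes 0 → 0.8, against a
20-set collection. With a single planted (pathway, miRNA) pair the
miRNome-wide statistic is diluted by the 1/M block fraction (expected
Z ≈ 2), so a single replicate has limited power there; the miRNome check is
therefore aggregated — the planted pathway must attain the highest
replicate-averaged Z — while the per-miRNA statistic (expected Z ≈ 14) is
required to attain the smallest p in ≥90% of individual replicates.

## Known limitations

- The permutation scheme assumes exchangeability of condition labels
  within a pair; covariates that differ within pairs are not modeled.
- Spearman correlation at small N is coarse (N=10 gives a grid of
  achievable values); the variance stabilization is approximate, with
  Var(T) slightly below 1 at these N, making the DC score mildly
  conservative.
- Per-miRNA mode tests G×M pairs with BH across all of them; at small B
  the p-value floor 1/(B+1) limits how far FDR can discriminate.
- No probe-to-gene collapsing or identifier aliasing: one row per feature,
  matched case-sensitively after whitespace trimming.
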