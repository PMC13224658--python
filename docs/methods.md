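# Methods

`pollenscape` implements a two-generation landscape-genetic analysis of
pollen-mediated gene flow for clonal, self-incompatible, insect-pollinated
herbs sampled across discrete habitat patches, together with a synthetic
generator that emulates the sampling design so that every stage can be
verified against known truth without any external data.

## Genotype handling and clone identification

Adults ("shoot clusters", the field sampling unit) and offspring are scored
at a panel of microsatellite loci; alleles are integer fragment lengths,
assumed pre-binned, with 0 coding a missing allele. Two samples share a
multilocus genotype (MLG) when their sorted allele pairs agree at every
locus. The default matching policy is **strict**: a sample with a missing
locus never equals a fully typed sample. This is conservative and
deterministic; a **tolerant** policy (missing loci act as wildcards, groups
closed transitively by union-find) is available behind a flag. Because the
counting convention for "repeated MLGs" is ambiguous, the QC report emits
three counts: repeated groups, samples involved, and redundant copies.

Deduplication keeps pollen receptors unconditionally; other adults in a
repeated-MLG group are removed, keeping the lexicographically smallest
sample id as representative when no receptor is present (reproducible
tie-break). Offspring are removed only as *apparent twins* — several
identical-MLG offspring of the same mother — and never for sharing an MLG
with a parent. Deduplication is idempotent.

Cluster clonality is summarised per shoot-count class (<5, 5–20, >20
shoots); clusters with a single genotyped shoot carry no information and are
excluded from denominators.

Before paternity, each offspring is checked against its mother: loci where
the two share no allele are set to missing, up to `max_mismatch` loci
(default 1, matching the handful of one-locus mismatches such data sets
typically show); offspring with more mismatches are excluded as
incompatible and logged.

## Paternity assignment

Each offspring of a known mother is assigned either to one candidate donor
from its own patch (all adult genotypes of the patch, receptors included —
analysis is per patch because the likelihood assumes random mating within
the candidate pool) or to UNASSIGNED, meaning pollen from an unsampled or
immigrant father.

Per locus the trio likelihood is the error mixture
`(1 − e)·T(g_off | g_mother, g_father) + e·P_HWE(g_off)` where `T` is the
Mendelian transmission probability, `P_HWE` the Hardy–Weinberg genotype
probability under the patch allele frequencies, and `e` a **locus-level**
genotyping error probability (the scale on which microsatellite error rates
are published; the helper `locus_error_rate` converts a per-allele-slot
rate, `1 − (1 − e_slot)^6` for the six slots a trio exposes per locus).
For an unsampled father the paternal allele is integrated over the patch
allele frequencies. Loci missing in any participant are skipped. With
selfing disallowed (the default — the species is strictly self-
incompatible), any candidate with the mother's MLG, including the mother,
has zero likelihood.

The prior that the true father is among the candidates, `p_sampled`
(default 0.5), is spread uniformly over the candidate set, so a candidate
scores `log(p_sampled/|C|) + log L` against
`log(1 − p_sampled) + log L_unsampled`. Spreading the prior (rather than
giving each candidate the full mass) is standard categorical-allocation
practice and is what keeps the false-assignment rate of unsampled-father
offspring low.

No sibship reconstruction is attempted: unsampled fathers are integrated
per offspring, so the configuration posterior factorises over offspring.
The stochastic search is simulated annealing over per-offspring father
labels; because of the factorisation, one sweep validly re-draws **every**
label from its conditional posterior at the current temperature (Gumbel-max
on the score matrix divided by T), which is the one-at-a-time Gibbs
proposal run to completion and is exactly vectorisable. Default schedule:
200 sweeps, T₀ = 2.0, geometric cooling 0.95 per sweep; the best
configuration visited is returned, and a fixed seed makes a run
bit-reproducible. Five runs with seeds `seed+0..4` feed a consensus: a
donor is accepted when it appears in at least 2 of 5 runs with maximal
support; ties fall back to UNASSIGNED. Support counts are analogous to, but
not numerically comparable with, the acceptance probabilities of
sibship-based assignment software.

## Pollen-flow measures

`PF_within` is the proportion of a receptor's genotyped offspring assigned
to an own-patch donor; `1 − PF_within` is the pollen immigration rate.
Unassigned offspring count as immigrant pollen, which makes the estimate a
lower bound on within-patch flow (unsampled within-patch genets deflate it;
the generator's ground truth quantifies that bias in the tests).

Offspring allelic richness `A_r` is rarefied at the gene-copy level: per
locus with `N` typed copies and `N_i` copies of allele i, the expected
distinct-allele count in a draw of `g = 10` copies (five diploid offspring)
is `Σ_i [1 − C(N−N_i, g)/C(N, g)]`, computed exactly (no resampling); `g`
truncates to `N` when fewer copies exist. Receptors with fewer than five
genotyped offspring are excluded. `A_r` is reported as the **mean over
loci** (the sum is also emitted): per-locus means are the scale on which
median values around 3 arise for microsatellite panels of this size, while
sums would be ~7-fold larger.

Donor statistics report, per effective donor, assigned offspring and
Euclidean distances to its receptors, and distance from its cluster point
to the nearest point of its patch boundary; aggregates include the fraction
of clusters donating and the medians of these quantities.

## Landscape metrics

Composition is measured in discs of 50, 250 and 1000 m around each
receptor: percent cover of maize, semi-natural grassland and oilseed rape
(grassland and rapeseed defined only at 1000 m, per the availability matrix
of the study design), clipped lengths of roads, water courses and woody
linear elements (woody elements only at 250/1000 m), and the number of
occupied plant populations intersecting the buffer, the receptor's own
population excluded (250/1000 m). Requesting a metric at an unavailable
radius is an error, not a zero. Uncovered ground counts as OTHER, so covers
sum to 100%.

The directional decomposition: each linear element is clipped to the
buffer; a multi-part clip yields independent pieces. For each piece the
axis is the unit vector from the receptor to the piece's half-arc-length
midpoint; every segment vector contributes its absolute projection on the
axis (parallel) and on the normal (orthogonal). The O:P ratio pools
component sums over all pieces of a type (not per-element averages); if the
pooled parallel component is < 1e-9 m the ratio caps at 1e3 (configurable);
a type absent from the buffer yields a missing value. The midpoint is taken
**after** clipping, keeping the axis local to what a forager inside the
buffer encounters; a pre-clip option exists.

Polyline clipping against the buffer is solved analytically per segment
against the true circle (not a polygonised disc), which makes lengths and
O:P components rotation-invariant to float precision; area cover uses a
256-gon disc whose relative area error (~1e-7) is negligible for percent
cover. All coordinates must be planar metric; no geographic CRS math is
performed.

## Statistical models

All landscape metrics are Box-Cox transformed (shift `1 − min(x)` when
non-positive values occur; λ maximising the Box-Cox normal log-likelihood
on a [−2, 2] grid with step 0.05) and then standardised to mean 0, sd 1.
Constant metrics are dropped and logged.

Three response families, all with patch random intercepts:

* **ZI-Poisson** for per-cluster assigned-offspring counts;
* **ZI-binomial** for `PF_within`, with the number of genotyped offspring
  per receptor as the binomial trials;
* **Gaussian LMM** for `A_r`.

The zero-inflated mixed model has a conditional linear predictor
`η = Xβ + u_g` (log or logit link) and a zero-inflation predictor
`logit(π) = Zγ + v_g`, with independent random intercepts
`u_g ~ N(0, σ_u²)`, `v_g ~ N(0, σ_v²)` (no cross-component correlation). A
**positive zero-inflation coefficient means a higher probability of an
extra zero** — the opposite direction to the conditional part. The group
marginal likelihood integrates (u, v) by 2-D Gauss–Hermite quadrature
(default 9 nodes per dimension) adapted at the per-group posterior mode
(vectorised damped-Newton mode search with analytic derivatives, Cholesky
scaling of the local curvature). Optimisation is L-BFGS-B over
(β, γ, log σ_u, log σ_v) with seeded random restarts; bounds keep
log σ in [log 1e-4, log 50], so σ → 0 boundary solutions are representable.
Standard errors come from the finite-difference Hessian of the
log-likelihood at the optimum; AICc uses
`−2ℓ + 2k + 2k(k+1)/(n−k−1)` with k counting fixed effects plus the two
variance parameters.

The Gaussian LMM uses its closed-form profiled likelihood: with a single
random intercept, V is block diagonal in ψ = σ_u²/σ_e², so GLS estimates,
the profiled variance and log|V| are explicit and ML/REML reduce to a 1-D
optimisation over log ψ with the σ_u = 0 boundary checked exactly (boundary
solutions are flagged singular). ML is used during selection; REML for the
final averaged report. Wald tests use a t reference with residual
df = n − k_fixed by default (a normal reference is selectable) — a
documented simplification in place of Satterthwaite df.

Model selection follows the three-step procedure: (1) single-metric
screening at p ≤ 0.15, separately for the conditional and zero-inflation
components; area metrics are additionally probed with a quadratic term
(kept when it lowers AICc and the quadratic term passes the screen — so a
purely unimodal signal still qualifies), and linear-element lengths with an
interaction with their own type's O:P ratio; (2) metric pairs with Pearson
|r| > 0.7 are mutually exclusive within a component; (3) all admissible
subsets (marginality enforced: quadratic and interaction terms require
their main effects) are fitted with ML, models with ΔAICc ≤ 2 are kept,
Akaike weights `w ∝ exp(−Δ/2)` renormalised, and coefficients are
**conditionally** averaged (a term's average uses only the kept models
containing it) with Burnham–Anderson unconditional standard errors
`Σ w'_m √(se_m² + (β_m − β̄)²)` and 95% CIs `β̄ ± 1.96·SE`. A guard caps
the candidate list at 12 terms. Exclusivity is applied within each
component (the same metric may legitimately appear in both the conditional
and zero-inflation parts).

## Synthetic studies

The generator emulates the sampling design: a 5 km × 5 km planar window
holding 9 non-overlapping forest patches; a land-use tiling (250 m cells,
classified maize / semi-natural grassland / rapeseed / other by configured
fractions, extending 1 km beyond the window so edge buffers stay covered);
and linear elements of the three types whose orientation relative to the
nearest patch centre is a scenario knob (random / parallel / orthogonal).

Shoot-cluster sizes follow a zero-truncated negative binomial (r = 0.2,
p = 0.0943), tuned so ~85% of clusters hold fewer than 10 shoots with a
heavy upper tail. A cluster is monoclonal with probability 0.62 / 0.46 /
0.28 for <5 / 5–20 / >20 shoots; polyclonal clusters hold 2 + Poisson(0.7)
genets with integer shoot counts (each genet owns ≥ 1 shoot). Genotypes are
Hardy–Weinberg draws from per-locus Dirichlet(1) frequencies over 7 loci
with 97 alleles in total. Field sampling takes one shoot per cluster; a
configurable fraction receives a multi-shoot clonality subsample, drawn
without replacement from the cluster's shoots. Per patch, 6–14 receptor
clusters are chosen; each receptor targets 1–41 offspring.

Mating is trapline-driven: foraging routes of 10–30 cluster visits move to
one of the 5 nearest same-patch clusters or switch to a random other patch
with probability `p_switch`. A visit to a receptor cluster draws a pollen
donor from a carryover queue over previously visited genets with geometric
weights κ^age (age 0 = the immediately preceding visit; κ = 0 reduces to
"always the previous plant", with 0⁰ ≡ 1), subject to self-incompatibility:
a donor with the receptor's MLG never sires, and an optional gametophytic
S-locus (disabled by default, since S-alleles are hypothesised rather than
characterised for such species) additionally rejects pollen carrying a
maternal S-allele. Offspring are Mendelian draws from mother × donor; the
true father genet, its patch and the immigrant flag are recorded.
Receptors that never reach their target are reported as starved. Route
fidelity across bouts is not modelled (a `repeat_routes` flag pins one
route). Genotyping error replaces each allele slot independently with a
frequency-weighted random allele with probability e (default 0.012).

All randomness derives from one master seed through named substreams
(landscape, genets, routes, errors), so any stage can be regenerated
independently; runs are byte-reproducible.

What the generator does **not** emulate: pollinator energetics and optimal
foraging, nest sites, flowering phenology, multi-year dynamics, seed
dispersal, and real GIS geometry. Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under a plausible mating
mechanism — not that any particular field estimate is right.

## Problem sizes used in the test suite

The test suite runs everything at desk scale, chosen as the smallest sizes
at which each check is statistically meaningful: exhaustive search
equivalence on ≤10 offspring × ≤4 candidates (the full configuration space
is enumerated vectorised); paternity recovery on 5 patches of 50 candidates
× 100 offspring at the full 7-locus resolution; ZI-GLMM calibration on 200
simulated data sets of 9 groups × 10 observations; the end-to-end
directionality experiment on 80 pipeline runs (4 patch-switch rates × 20
seeds) with 5 patches of 20–60 clusters; screening calibration on 1000
replicates of 81 receptors. The acceptance script runs one full study at
9 patches with 24–200 clusters per patch.

## Known limitations

* The assignment likelihood has no sibship reconstruction; shared unsampled
  fathers are invisible to it, and support counts saturate at 5 when the
  factorised posterior is unimodal.
* `PF_within` inherits the field method's downward bias from unsampled
  genets in large, polyclonal clusters.
* The ZI mixed model assumes independent random intercepts across
  components and a common error rate across loci.
* LMM screening p-values use a fixed residual-df t approximation.
* Landscape inputs must be pre-projected planar coordinates; polygon
  validity is repaired where shapely can, otherwise an error is raised.
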