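# Methods

This package is a self-contained testbed for two model-selection tests of
universal common ancestry (UCA) versus independent origins (IO) of protein
families, together with the simulation machinery needed to evaluate them.
This note records the models, the numerical choices, and what the shipped
test conditions do and do not show.

## The two hypotheses

Both tests compare the same pair of hypotheses on a set of protein
sequences partitioned into origin groups (here two, called *E* and *B*
after the eukaryote and bacteria quartets of the motivating design):

* **UCA** — all sequences are connected by a single phylogeny.
* **IO** — each group evolves on its own tree, with no connecting branch.

For a reversible, stationary substitution process, IO is mathematically the
limit of the UCA tree in which the branch connecting the groups becomes
infinitely long: the transition matrix `exp(Qt)` converges to the rank-one
matrix of stationary frequencies, and the joint likelihood factorizes into
the product of the two group likelihoods. `phylo.io_limit_gap` measures
`|logL_joint(t) − logL_E − logL_B|` directly, and the test suite asserts
its monotone decay. Two caveats discovered while building the demonstration:

* the factorization holds per rate category; under discrete-gamma rates
  shared across the whole tree the category mixture couples the groups, so
  the demonstration uses single-rate models;
* the rate of convergence is governed by the subdominant eigenvalue of the
  rate matrix. For rtREV this is ≈ −0.279, leaving residuals of order 1e−5
  at t = 50 on 100-site instances; the numerically exact (< 1e−6) check is
  therefore made on a uniform-exchangeability model, whose subdominant
  eigenvalue is −20/19.

## Substitution models

Empirical amino-acid models (rtREV, LG) are stored as published
exchangeabilities and frequencies; the rate matrix is the GTR-form
`Q_ij = s_ij π_j`, row sums zero, rescaled to one expected substitution per
site per unit time. `+F` replaces model frequencies with observed alignment
frequencies (no pseudocount; a 1e−8 floor guards degenerate inputs).
Among-site rate variation is the mean-of-category discrete gamma (four
equal-probability categories by default, renormalized to mean exactly 1).
Transition probabilities come from the symmetric eigendecomposition of
`diag(π)^½ Q diag(π)^−½`; negative entries from roundoff below 1e−9 in
magnitude are clipped to zero, anything larger is an error.

## Likelihood and ML fitting

The phylogenetic likelihood is Felsenstein pruning with per-site scaling;
gaps and unknown residues are missing data (all-ones partial vectors), so a
column that is entirely gaps within a group contributes exactly zero — the
property that lets the IO hypothesis score the *same* global alignment as
the UCA hypothesis after splitting it by group.

Branch lengths are fit by coordinate ascent: bounded Brent line searches on
one branch at a time against cached "below"/"above" conditional vectors.
For speed the conditionals are refreshed once per sweep; because they go
stale as branches update within the sweep, the fitter verifies the total
log-likelihood after each sweep and falls back to exact per-branch
refreshed sweeps whenever a fast sweep fails to improve — overall ascent is
therefore guaranteed. The gamma shape is profiled on an outer Brent search
in log space over [0.05, 100]. Convergence is declared when a round
improves by less than 1e−4; non-convergence is flagged on the result, not
silently ignored. Branch lengths are bounded by 50 expected
substitutions/site; starting lengths come from Poisson-corrected pairwise
distances.

## The ΔAIC test

Each hypothesis is fit on the same fixed alignment: one joint tree (UCA)
and one tree per group (IO), with

    ΔAIC = AIC(B) + AIC(E) − AIC(BE),  positive values favoring UCA.

Parameter counts per tree are the identifiable branch lengths (2n−3 for a
binary tree, counting a degree-2 root's two branches as one), one gamma
shape, and 19 free frequencies when `+F` is fit per tree (the default;
parameter counting per shared-frequency hypothesis is available as a
toggle through the criterion helper). AICc uses the number of alignment
columns as the sample size. `aligned` mode invokes the progressive
aligner; `unaligned` mode stacks the (equal-length, indel-free) sequences
as they are — the control that isolates the aligner's contribution.

## The progressive aligner

A deliberately small MUSCLE-class stand-in: 3-mer fractional-count
distances, UPGMA guide tree, profile–profile global affine-gap DP with
frequency-vector profiles, "once a gap, always a gap", no refinement
stage. The score matrix is the half-bit integer log-odds matrix of rtREV
at distance 1.0 (diagonal 5..10, BLOSUM-like). Gap penalties are open −11,
extend −2 per additional column. The extension penalty is deliberately set
at the expected score of two unrelated residues under the matrix (≈ −2.0
half-bits): with a cheaper extension the optimal global path through two
*unrelated* profiles runs long gap blocks instead of mismatches and the
gap load roughly doubles. With this calibration the eight-sequence
independent-origins replicates of the full-length preset align with ≈ 8–9%
gap cells, inside the 7–11% range reported for MUSCLE on the original
design — the one quantity of the aligner that the downstream experiments
are sensitive to. Gap-load quantities remain aligner-dependent and are
asserted with explicit tolerance.

## The coestimation ΔBF test

The sampler treats the *unaligned* sequences as data and the alignment as
a latent variable on a fixed rooted topology: explicit internal-node
sequences plus one match/delete/insert homology path per branch. Indels
follow TKF91 (birth λ per link, death μ per residue, λ < μ), giving the
standard three-state pair transducer per branch and a geometric(λ/μ)
equilibrium length prior at the root. Gamma rate categories are
marginalized independently per match event per branch (a branch-site
variant; the shared rates-across-sites coupling is not tracked through
indel events — with four categories and the data sizes here the practical
difference is small, and both hypotheses are treated identically).

One MCMC cycle is: exact Gibbs redraw of every branch path (stochastic
traceback on the scaled linear-space forward matrix); exact Gibbs redraw
of every internal residue; two insert/delete proposals per internal node,
accepted on *path-marginalized* branch probabilities with the affected
paths then redrawn from their exact conditionals (a collapsed
Metropolis-within-Gibbs move — the naive slot-editing proposal is not
reversible); multiplier proposals on each branch length; random-walk
proposals on the gamma shape and on (λ, ρ = λ/μ). Priors: branch lengths
iid Exponential(mean 0.2), gamma shape LogNormal(0, 1), λ
Exponential(mean 0.02), ρ Uniform(0.2, 0.95). All configurable.

The recorded likelihood of each sample is the substitution likelihood of
the leaf residues given the sampled homology (leaf columns obtained by
transitive closure of the match links; internal states marginalized by
pruning; absent leaves missing data). This is the `P(D | alignment, θ)`
side of the decomposition in which the indel process is the alignment
prior — the quantity whose harmonic mean estimates the marginal likelihood
of the unaligned data. Marginal likelihoods use the harmonic-mean
estimator computed in log space; it is known to be unstable and biased
upward, more so for diffuse posteriors, and a variance-based instability
flag is reported with each result. The test statistic is

    ΔBF = log P(B+E) − log P(B) − log P(E),

with strong-evidence decisions outside ±10 log units and "inconclusive"
between.

## Synthetic data

`simulate.evolve` draws the root from π, assigns each site a gamma
category once (rates across sites), and applies `exp(Q r t)` down each
branch; indels are never simulated in the replication presets, so the
"unaligned" control mode is well defined. Scenario presets:

| preset | sites | replicates | model |
|---|---|---|---|
| `fig2` | 6591 | 200 | rtREV+Γ+F |
| `fig2-scaled` | 1000 | 20 | rtREV+Γ+F |
| `fig3` | 500 | 100 | LG+Γ |
| `fig3-scaled` | 100 | 20 | LG+Γ |

The original study's true trees and branch lengths are archived on Dryad
and not printed; the presets use stand-in quartets
`((X1:0.4,X2:0.4):0.2,(X3:0.4,X4:0.4):0.2)` — deep but alignable — and a
stand-in simulation shape α = 0.8. Reproduction of the original figures is
therefore qualitative/proportional, not parameter-exact. Replicates are
generated from one master seed via spawned `SeedSequence` children, so any
replicate is reproducible in isolation and identical seeds give
byte-identical FASTA.

The generator emulates: equilibrium composition, among-site rate
variation, within-group phylogenetic correlation, and between-group
statistical independence. It does not emulate: indels (by design),
compositional heterogeneity across lineages, site-specific profiles, or
selection — so passing tests show the *tests'* behavior under their own
model assumptions, not robustness to real-data violations of them.

## Scaled test conditions and what they show

Full-scale reproduction of the coestimation experiment is a multi-week
computation (the original analyses ran over a week per replicate on one
thread). The shipped checks therefore run at desk scale, with problem
sizes chosen as the package's own test conditions:

* ΔAIC bias experiment: 20 replicates × 1000 sites. The qualitative result
  is scale-free (every replicate flips from IO to UCA when the aligner is
  inserted) and reproduces at full strength.
* Gap load: median over full-length (6591-site) replicates.
* Coestimation experiment: 6 replicates × 100 sites × 1200-cycle chains,
  plus a 20-replicate drift check at 50 sites. At 100 sites the ΔBF signal
  on IO data (per-site ≈ −0.1 to −0.3, matching the original per-site
  histogram) is mostly *inside* the fixed ±10 decision band, and
  harmonic-mean noise — dominated by rare deep likelihood excursions,
  which are deeper in the small per-domain runs and hence push ΔBF toward
  UCA, the familiar "HME favors the larger model" pathology — is of
  comparable magnitude. The headline 86%/12% decision split is a
  500-site × long-chain phenomenon and is not expected to survive this
  scaling, while the sign and per-site magnitude of ΔBF do; the shipped
  fraction test records this expectation against pre-registered binomial
  bands rather than widening them.

## Known limitations

* The aligner is a single-pass progressive method; MUSCLE's objective and
  refinement are intentionally out of scope, and gap statistics transfer
  only approximately.
* The HME is used because the study design calls for it; stepping-stone or
  thermodynamic-integration estimators would be strictly better and are
  not implemented.
* Topology is never sampled (fixed true topologies by default, NJ
  available); there is no tree search beyond that.
* TKF91 only (no TKF92/long-indel model); codon and nucleotide models are
  out of scope.
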