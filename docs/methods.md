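# Methods

## State space

A motif is a 4-bit acetylation pattern over the H4 tail lysines
(K5, K8, K12, K16), ordered N-terminal → internal.  The wild-type space has
16 motifs; removing a site (the K16R mutant, or any counterfactual
"disable" operation) halves it.  Transitions only add acetyl groups — the
in-vitro assay contains no deacetylase — so the motifs form a directed
acyclic lattice with the unmodified tail as source and the fully
acetylated tail as the unique absorbing sink.  The n-site lattice has
n·2^(n−1) edges (32 wild-type).  Canonical motif order is by acetyl count,
then by site-index tuple, which makes all report tables stable across runs.

## Model families

Let S_m be the free-substrate abundance of motif m (fraction of total H4,
so Σ(S+C) = 1), C_m the enzyme-bound abundance, E the free enzyme, all in
the same fractional units; time is in minutes.  The observable is
y_m = S_m + C_m: mass spectrometry sees every H4 tail whether or not an
enzyme sits on it.

**Mass action** (enzyme in excess).  Each lattice edge (m, i) carries a
first-order rate k[m,i]; dS/dt = A·S with A the edge-rate generator.  The
system is linear, which provides the package's main solver oracle: the
trajectory must equal `expm(A t) @ S(0)`.

**Michaelis–Menten** (shared enzyme pool at complex equilibrium).  Edge
flux v[m,i] = kcat[m,i]·E_tot·S_m / (Km + Σ_j S_j), i.e. all motifs compete
for one enzyme pool with a common Km.  *Identifiability note:* on this
closed substrate pool Σ_j S_j ≡ 1 for all time, so the denominator is
constant and the family is observationally equivalent to mass action with
k = kcat·E_tot/(Km+1).  Km and kcat are not separately identifiable from
motif time courses, and a converged Michaelis–Menten fit always lands
exactly 2 AIC units above the mass-action fit (same likelihood, one extra
parameter).  The family is kept because it represents a distinct mechanistic
hypothesis whose AIC penalty is itself informative; any enzyme-limitation
signature in data is evidence for the processive family, which models the
enzyme explicitly.

**Processive** (explicit enzyme).  Reactions:

    E + S_m   → C_m            kon·E·S_m         (binding)
    C_m       → E + S_m        koff·C_m          (release)
    C_m       → C_{m+e_i}      kcat[m,i]·C_m     (on-complex catalysis)
    C_m + S_n → S_m + C_n      k_transfer·C_m·S_n (within-array hand-off)

The hand-off reaction realizes the spatial variant — a bound enzyme can
move to another tail of the same array without passing through the free
pool, so intra-array transfer is faster than rebinding from solution;
k_transfer = 0 disables it.  Processivity arises when kcat ≫ koff: the
enzyme acetylates several sites per binding event.  Conservation laws
(Σ(S+C) = 1 and E + ΣC = E_tot) hold exactly in the reaction scheme and to
1e−8 in the integrator, and are tested.

**Parameterizations.**  Catalytic rates are either shared per site
("site" mode, 4 rates wild-type — the reduced parameterization used for
fast calibration and all recovery studies) or free per lattice edge
("edge" mode, 32 rates — required for the per-motif site-preference
profile).  Acetyl-CoA is assumed saturating and is not modeled.

**Units and defaults.**  E_tot defaults to 0.25 substrate fractions (one
enzyme complex per four H4 tails, the 50 nM-on-200 nM assay
stoichiometry).  Default solver: LSODA with analytic Jacobians for all
three families, rtol 1e−8 / atol 1e−10 (1e−6/1e−9 inside fitting loops,
where speed matters and the likelihood is noise-dominated).  Negative
round-off is clipped in the observation layer only, never in solver state.

**Quasi-steady-state limits.**  Michaelis–Menten → mass action as
Km → ∞ at fixed kcat·E_tot/Km.  Processive → Michaelis–Menten with
Km = koff/kon requires a *joint* limit: fast exchange relative to catalysis
(koff ≫ kcat) *and* negligible substrate sequestration (E_tot ≪ Km).  The
limit tests scale koff to 2.4e7/min with Km = 5000 to reach 1e−4 trajectory
agreement; at textbook-looking values (koff ~ 1e4, Km ~ 1) the bound
fraction is several percent and the two families differ visibly.

## MS quantification

The tryptic H4 peptide G4–R17 (sequence GKGGKGLGKGGAKR) carries all four
sites; the K16R peptide G4–R16 (GKGGKGLGKGGAR) carries three.  Chemical acetylation with
acetic anhydride-D6 before digestion converts every non-enzymatically
acetylated lysine to a heavy D3-acetyl form, 3.0188 Da heavier per group,
so n_light + n_heavy equals the lysine count and the light count encodes
the motif's acetyl number.  Relative abundance of a motif is its MS1 peak
area divided by the summed areas of all species of the peptide; the
detection limit (0.003%) is applied as a strict-below *flag* — values are
never zeroed, and fitting omits flagged points by default.

Theoretical m/z uses standard monoisotopic residue masses (pyteomics) plus
light acetyl +42.010565, D3-acetyl +45.029395 and proton 1.007276 Da; the
peptide N-terminus is treated as unmodified because derivatization precedes
digestion.  The published m/z triple for the doubly charged wild-type ions
differs from this computation by ~1 Da at neutral mass for the stated
composition; the package reports the computed value and keeps the published
numbers as reference metadata, asserting only their internal heavy/light
spacing.

## Calibration and model comparison

Additive Gaussian noise on relative abundances, three modes: fixed σ;
a single σ profiled analytically at its conditional MLE (default; counted
as one AIC parameter); or per-motif profiled σ (floored at 1e−3).  The
per-motif mode exists because sum-normalization couples the noise across
motifs: a motif at abundance a inherits variance ≈ σ²(1 + a²·n_motifs)
from the normalization, so a single σ is overconfident for dominant motifs.
Interval-coverage studies use the per-motif mode; AIC comparisons use the
default single σ.

Fitting minimizes the residual sum of squares — identical argmax to the
Gaussian likelihood in all modes up to the per-motif weighting — with
bounded trust-region least squares (`scipy.optimize.least_squares`, TRF)
on log₁₀ parameters, default bounds 1e−5 to 1e3.  Multi-start: a pool of
10× n_starts uniform draws in the log-bounds is scored once, and local
optimization runs from the best n_starts candidates.  The pool step is
essential: the NLL landscape has plateaus where one log-rate saturates
(any rate ≫ 1/min is indistinguishable from "instantaneous"), and scalar
quasi-Newton searches started at random routinely stall there.  The
finite-difference step for the residual Jacobian is 1e−3 log units — large
enough to dominate ODE truncation noise.  Integration failures inside the
objective return a large finite penalty with a pull-back term, and are
logged.  Fits are deterministic given (data, spec, n_starts, seed).

AIC = 2k − 2 log L; families with ΔAIC ≥ 10 relative to the best are
rejected; exact AIC ties resolve toward fewer parameters.

## Posterior sampling and predictions

Posterior ∝ likelihood × bounded uniform prior on log₁₀ parameters
(same default bounds).  The sampler is emcee's affine-invariant ensemble
(adaptive parallel tempering would be an equally valid backend — the
contract is the diagnostics, not the sampler's identity): ≥ max(2, 2·ndim)
walkers, first 50% of steps discarded, convergence monitored by
split-chain R̂ < 1.05 and mean acceptance fraction.  Non-convergence sets
a warning flag on the ensemble rather than raising.  Walkers start in a
tight ball around the MLE when one is supplied, else uniformly in the
prior box.  Sampling is deterministic given the seed.

Credibility intervals are central quantile intervals (99% default) with
linear interpolation of order statistics — stated because 99% bands from
a few thousand retained samples are convention-sensitive.  Prediction
bands simulate every retained sample (thinned evenly to 200) under a
scenario (time grid, initial state, disabled sites); individual failures
are dropped and logged, >10% failing is an error.  The K16R counterfactual
is the wild-type-calibrated ensemble simulated with every K16 reaction
removed; on the per-site parameterization this predicts K12 mono-acetylation
as the dominant product, qualitatively matching K16R-mutant measurements
(the prediction's absolute level runs higher than the mutant data — the
counterfactual keeps wild-type binding kinetics, whereas the real K16R
substrate engages the enzyme less efficiently).

The site-preference profile (per-edge parameterization only) reports, for
each motif, the posterior-median kcat toward each free site normalized to
that motif's maximum; exact ties are broken by site order and flagged.

## Synthetic data generator

`generate_dataset` simulates a preset and adds i.i.d. Gaussian noise per
(motif, time, replicate), then clips to [0, 1] and renormalizes each
(time, replicate) column to sum to 1 — mirroring how relative abundances
are formed from peak areas.  Defaults follow the experimental design:
3 replicates, times {0, 5, 15, 30, 60} min (0 is the no-enzyme control;
5, 30, 60 are anchored by the reported measurements; 15 is interpolated),
σ = 0.01, detection limit 3e−5.  `generate_peak_table` converts a truth
trajectory into MS1 areas with unit-mean lognormal multiplicative noise of
chosen CV, for testing the quantification path end-to-end.

Four versioned presets (exact parameters in `synthetic.py`):

- **wildtype** — processive, kon 20, koff 0.4, kcat
  K16 = 30 ≫ K12 = 0.022 > K8 > K5 (1/min), E_tot 0.25.  Tuned once to the
  experiments' printed envelope: ~54% K16ac mono at 5 min, K12acK16ac
  ~13% at 30 min, motifs lacking K16ac ≤ 1% (here ≤ 0.01%), tetra-ac
  appearing late.  The binding regime matters as much as the rates: with
  kon·S/koff ≫ 1 the enzyme pool saturates and the kinetics are genuinely
  non-linear, which is what makes the processive mechanism identifiable
  (ΔAIC ≈ 100 over mass action).  A pseudo-first-order tuning can hit the
  same envelope while being statistically indistinguishable from the
  linear families — a degenerate study design, deliberately avoided.
- **k16r** — the same catalytic hierarchy on the 3-site lattice with
  weaker binding (kon 0.4), landing at ~13% K12ac at 60 min with rare
  di-/tri-acetylation.
- **zip-suppressed** — wild-type rates with koff raised to 8/min:
  accelerated enzyme turnover suppresses oligo-acetylation in favor of
  K16ac mono, emulating the RNA-addition outcome.
- **k12-preferring** — a weak, K12-selective enzyme (kcat K12 = 1.5,
  K5 = 0.6, kon 0.025, koff 6), emulating a Tip60-like specificity
  (~6% K12ac, ~2% K5ac at 60 min, oligo-ac < 2%).

What the generator does *not* emulate: replicate-level batch effects
(different enzyme preparations differ systematically, not just by i.i.d.
noise), missing di-acetyl positional isomers that MS2 cannot resolve,
retention-time or spectral artifacts, and abundance-dependent MS noise.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the declared noise model, not robustness to real-data
pathologies.

## Problem sizes in the test and acceptance runs

All recovery studies use the reduced (per-site) parameterization, 3
replicates, 5 time points, σ = 0.01.  Model-selection recovery fits all
three families on 10 seeded wild-type datasets (4 pool-ranked starts
each).  Parameter recovery and 99%-interval coverage run 20 seeded rounds
of fit + MCMC on the mass-action family (site rates 0.02/0.04/0.08/0.15
per min — all four well identified on the 5-point grid), 16 walkers × 400
steps.  The counterfactual check uses one wild-type fit, 16 walkers × 300
steps, 150 ensemble simulations.  These sizes keep the whole suite around
6–7 minutes on one CPU while leaving every statistical margin intact.

## Known limitations

- Per-edge (32-parameter) fits are supported but slow at desk scale; the
  site-preference profile is therefore exercised on small lattices and
  synthetic ensembles in the tests.
- The profiled per-motif noise mode is a pseudo-likelihood (profiling, not
  marginalizing, the scales); with 15 points per motif its intervals are
  approximate.
- The Michaelis–Menten family's non-identifiability (above) is inherent to
  closed-pool motif data, not a solver artifact.
- Left-censored handling of below-detection-limit points is out of scope;
  masked points are omitted from the likelihood.
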