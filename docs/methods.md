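# Model and methods

`aggresim` simulates the maturation of a microbial aggregate (granule,
floc or biofilm cross-section) as an individual-based model (IbM) of
three bacterial populations, B1, B2 and B3, coupled to a 2D
diffusion-reaction field of soluble substrates.  The three populations
share identical growth kinetics ("theoretical equal fitness"); everything
that differs between them is their metabolic stoichiometry, which encodes
the ecological interaction:

| ecology                    | net effect        | metabolism                         |
|----------------------------|-------------------|------------------------------------|
| `neutralism`               | [0, 0, 0]         | B1: A→D, B2: B→D, B3: C→D          |
| `competition`              | [−, −, −]         | all: A→B                           |
| `commensalism`             | [0, +, +]         | B1: A→B, B2: B→C, B3: C→D          |
| `commensalism_competition` | set by environment| commensal chain + shared O₂ uptake |

All stoichiometric coefficients have magnitude 1/Y_XS (mol substrate per
mol biomass), negative for consumption.

## Physical model

Each soluble component φ(x, y, t) obeys Fick's second law with a
reaction term, ∂φ/∂t = D ∇²φ + R, discretized with a five-point Laplacian
on a uniform grid (node size h, half-open node ownership).  The domain is
partitioned into the aggregate, a boundary layer of fixed thickness, and
the bulk liquid; bulk nodes are Dirichlet-pinned to the bulk
concentration.  Because diffusion equilibrates ~10⁸ times faster than
biology, the field is solved to *pseudo-steady state* on every biology
step.  The convergence rule is applied per diffusion-region node:

    |RES| ≤ 1% · φ    where φ is appreciable,
    |RES| ≤ tol_abs   on near-zero nodes,

with RES the dimensionless five-point residual plus (h²/D)·R, and
tol_abs = 10⁻⁶ mol/L at full concentration scale.

Two solver strategies satisfy the same rule: the default direct scheme
(sparse LU of the Laplacian, factorized once per zone relabelling and
shared across substrates because the dimensionless operator does not
depend on D) and a damped Jacobi iteration with periodic reaction
refresh.  Plain Picard iteration on a frozen reaction term falls into
period-2 oscillation at stiff Monod depletion fronts, so the direct
scheme treats consumption semi-implicitly: each cell's uptake of
substrate s is linearized as k·φ_s with
k = |ν| μ̂ X / (V (K_S + φ_old)), where μ̂ is the gross rate with the
substrate's own Monod factor removed.  The resulting matrix stays an
M-matrix (non-negative solutions guaranteed) and the fixed point equals
the exact nonlinear Monod balance.  Field updates are adaptively
under-relaxed when the residual stalls.

## Biological model

Each microbe is a discrete agent with position, biomass X (mol), a
population identity and an activity state.  Its net growth rate is

    μ = μ_max · Π_s [φ_s/(K_S + φ_s)] · Π_i [K_I/(K_I + φ_i)] − b,

evaluated at the concentrations of the single node that owns the cell
centre.  Mass integrates by forward Euler, X ← X(1 + μ dt_bac).  The
**reaction term uses the gross catabolic rate μ + b**: a maintaining cell
keeps consuming substrate (and releasing its catabolic product) even when
its net growth is zero or negative.  This is the Pirt reading of
maintenance; with the alternative (uptake ∝ max(μ, 0)) interior
concentrations level off exactly at the subsistence level and no cell
ever starves to dormancy, which contradicts the inactive cores seen in
mature aggregates.

At M_max the cell divides: the daughter receives a stochastic fraction
α ~ U(0.45, 0.55) of the mass and is placed adjacent to the parent
(centre distance = sum of post-split radii) at a uniform random angle;
biomass is conserved exactly.  A cell shrinking to M_min becomes
inactive - it neither grows nor decays and contributes nothing to the
reaction term - and reactivates when local conditions would again give it
a positive growth rate.  Radii follow from mass via a fixed biomass
density ρ assuming spheres.

Overlap is resolved by hard-sphere shoving: every pair closer than
(1−f)(r₁+r₂) (accepted overlap f = 0.05) is displaced along its centre
line by half the deficit, in parallel sweeps with a small (1%) overshoot
that prevents the sweep dynamics from settling into a limit cycle of
marginal violations.  Shoving moves positions only.  Shear detachment,
when enabled, removes every cell whose centre lies further than the cap
radius from the biomass-weighted centroid.

## Integration scheme

Per outer step: (1) fields to pseudo-steady state; (2) biology advanced
by dt_bac = min(dt_max, ε/max|μ|) with ε = 0.05 so no cell changes mass
by more than 5%; (3) divisions, shoving, optional detachment, zone
relabelling; (4) bulk update.  The default bulk mode keeps constant
Dirichlet concentrations (the regime of all preset experiments); an
optional well-mixed reactor balance updates the bulk from the boundary
flux.  Runs are bit-reproducible given the seed.  Steady state is
declared when the active relative abundances, bulk concentrations and
per-population median growth rates all change by less than a relative
tolerance over a trailing window.

## Default parameters

The source material for this model never states its kinetic table, so the
defaults are package choices, exposed in full through configuration:

| parameter | default | rationale |
|---|---|---|
| μ_max | 0.7 h⁻¹ | division on the ~1 h timescale of fast growers |
| b_max | 0.15 h⁻¹ | starved cells reach dormancy within a maturation run |
| K_S (A–D) | 10⁻⁵ mol/L (0.01 mM) | limitation window at 0.05–1 mM bulk |
| K_S (O₂) | 0.5 mg/L (1.56·10⁻⁵ mol/L) | conventional oxygen half-saturation |
| Y_XS | 0.5 mol/mol | symmetric half-yield chain |
| M_max | 1.2·10⁻¹⁴ mol | cell radius 1 μm at division |
| M_min | 0.3·M_max | dormancy at ~⅔ of the linear size |
| ρ | M_max/(4π/3) mol/μm³ | r(M_max) = 1 μm |
| D (A–D) | 3.6·10⁻⁶ m²/h | small-organic solute scale |
| D (O₂) | 7.2·10⁻⁶ m²/h | faster, as for small solutes |
| boundary layer | 20 μm | finite external mass-transfer resistance |
| overlap fraction | 0.05 | shoving acceptance threshold |

## Problem sizes ("desk" scale)

The default experiment scale runs a 71×71 grid at h = 2 μm with a 30-cell
inoculum in a 20 μm disc, and stops at steady state, at the configured
end time, or at a 42 μm radius guard before the boundary layer would
leave the grid.  With the fast default kinetics the substrate depletion
length at the study concentrations is 5–30 μm, so each concentration
label occupies the same qualitative position relative to the aggregate
radius as in a much larger simulation, while a run completes in tens of
seconds.  Because desk aggregates are smaller, the strongly-limited
regimes of the study sit about one concentration step lower than the
full-scale labels; the replicate experiments therefore use 0.05–0.2 mM
where the full-scale study quotes 0.1–0.5 mM.  The eco-interaction
modulus is computed from unscaled concentrations and is unaffected.  A
`paper` scale (257×257 grid, multi-week horizons) is provided for
full-size runs and is not exercised by the test suite.

## Analysis definitions

* **Relative abundance**: count fraction per population, optionally over
  active cells only (the default for all reported statistics).
* **Fitness**: the actual growth rate μ; summarized as the median over a
  population's active cells.
* **Colony size**: sweeping 2° angular bins about the aggregate centre,
  each bin is labelled by its radially outermost active cell; maximal
  circularly contiguous same-label runs form sections with perimeter
  P_c = 2π⟨r⟩(θ/360) and relative size P_c/P_T.  Bins without cells split
  runs.  ⟨r⟩ averages the labelling (peripheral) cells; an alternative
  averaging over all colony cells can be obtained by filtering the cell
  table directly.
* **Biological Thiele modulus**: φ_Bio = R·q_S·X/(D_S·C_S), the ratio of
  the diffusion time R²/D_S to the Monod reaction time
  (Y/μ_max)(K_S+C_S)/X.  The specific uptake rate at bulk concentration
  is q_S = (1/Y)·μ_max·C_S/(K_S+C_S).
* **Eco-interaction modulus**:
  φ_EI = [(n_A q_A)/(D_A C_A)] / [(n_O₂ q_O₂)/(D_O₂ C_O₂)], with n_i the
  active-cell abundance of consumers of substrate i.  φ_EI > 1 predicts a
  commensal (layered) environment, φ_EI < 1 a competitive (columned) one;
  a ±0.1 band around 1 is classified as mixed.
* **Stratification indices**: the layering index is the Spearman rank
  correlation between the commensal chain order and each population's
  median centre distance of active cells (−1 = perfectly layered);
  populations holding less than 5% of the active community are excluded
  from the ranking (the median position of a few remnant cells is noise),
  and fewer than two qualifying populations — competitive exclusion —
  leaves the indices undefined.  The
  segregation index is one minus the mean Miller-Madow-corrected
  normalized Shannon entropy of the composition over 20° angular bins in
  the outer quarter of the radius (1 = perfectly columned).
* **Statistics**: Welch's unequal-variance t-test for abundances and
  colony sizes across conditions; paired t-tests for fitness between
  populations within simulations; Pearson correlation between abundance
  and fitness medians.  Degenerate (zero-variance) inputs are flagged.

## What the experiments show, and what they do not

The replicate experiments reproduce, at desk scale: near-equal active
abundances in neutralism; columned stratification with statistically
indistinguishable abundances and fitness in competition; layered
stratification and ~1:0.6:0.3 active-abundance proportions in strongly
limited commensalism; environment-controlled stratification in the mixed
ecology, classified consistently by φ_EI; and the fragility of layered
(but not columned) stratification under a 30 μm shear cap.

Known desk-scale limitations:

* Runs end when the aggregate reaches the radius guard, which is early in
  the full maturation process.  At that point the successor populations
  of the commensal chain are still expanding into their niches, so their
  active-cell fitness medians can *exceed* B1's - the opposite of the
  mature-state ordering F(B1) > F(B2) > F(B3).  Consequently the strong
  positive abundance-fitness correlation of the commensal chain is not
  reproduced at this scale; the corresponding checks are expected to fail
  and are retained as honest documentation of the gap.
* The mixed ecology under competitive dominance suppresses B2/B3 more
  strongly than a full-scale run (count ratios lag their asymptotic
  values when growth stops at the guard radius).
* No inactive core fully develops in the fastest-growing conditions.

The synthetic fixtures (`concentric`, `sectors`, `mixed`, `random`)
emulate only the geometry of the stratification patterns, with analytic
masses and growth rates; they validate the analysis metrics, not the
simulator.
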