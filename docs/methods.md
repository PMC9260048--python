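# Methods

## The analysis pipeline

A TMS coil placement induces an electric field |E| on the cortical
surface. The pipeline thresholds |E| at 0.9 V/m (inclusive, so a vertex
exactly at threshold belongs to the seed) to obtain the stimulated seed
patch, reports its area from the mesh triangles, and characterizes the
seed's functional connectivity through a vertex×vertex Pearson dense
connectome. Each seed vertex is assigned to the canonical network (of the
eight Yeo/Schaefer networks, in the fixed order Vis, SomMot, DAN, VAN,
Limbic, FPN, TempPar, DMN) to which its mean FC is maximal; the
percentage of seed vertices per network is the engagement profile, the
quantity all statistics operate on.

Conventions worth stating precisely:

* **Seed area** counts a face only when all three of its vertices are
  suprathreshold. This is conservative at the patch boundary and means a
  nonempty seed on a coarse mesh can have zero area.
* **Seed FC maps** use the plain arithmetic mean of r over seed vertices
  ("average FC to every other node"); Fisher z averaging is reserved for
  averaging whole correlation matrices over runs and over subjects, where
  it is standard. Seed vertices are not excluded from the map domain
  (their self-correlation of 1 is part of the seed column average); a
  display helper can mask them.
* **Vertex network FC** excludes only the vertex itself from its own
  network's mean, since the self-correlation would bias every vertex
  toward its own network. Signed (not absolute) correlations are used
  throughout; argmax ties break to the earlier network in the fixed
  order.
* Vertex indexing is 0-based everywhere in memory; file formats carry
  explicit vertex-id columns.

## The three-variant framework

Inter-subject variability in engagement is decomposed by pairing E-field
seeds and connectomes three ways: subject seed × group-average connectome
(`geom`: geometry-driven variability), template seed × subject connectome
(`fconly`: FC-driven variability), and subject seed × subject connectome
(`combined`). The group connectome is the cohort's own Fisher-z average;
in the original study design this role is played by an external, much
larger reference average, and the configuration accepts any connectome
file in its place. Subjects whose field never reaches threshold are
excluded with a logged count and dropped pairwise (complete-case) from
cross-variant correlations.

## Statistical engine

The engagement matrix (subjects × 8 networks, rows summing to 100) is
analyzed with the classical one-way repeated-measures decomposition:
SS_total = SS_subjects + SS_levels + SS_error,
F = MS_levels/MS_error on df (k−1, (k−1)(n−1)). Effect size is partial
η² = SS_levels/(SS_levels+SS_error) — the "partial" choice is recorded in
output metadata since η² is ambiguous in within-subject designs. No
sphericity correction is applied by default (a Greenhouse–Geisser epsilon
is available behind a flag); engagement percentages are compositional and
the default mirrors the plain RM-ANOVA the analysis is defined with.
Pairwise post hocs use the studentized range q = |Δmean|/√(MS_error/n)
with the same MS_error and df_error (Tukey HSD for a within-subject
factor); at k = 2 the adjusted p equals the paired-comparison p exactly.
Degenerate inputs are explicit: a zero level effect reports F = 0, p = 1;
zero error variance with a nonzero effect reports F = +∞, p = 0 with a
warning; zero-variance paired differences raise rather than return an
infinite t.

## The synthetic cohort

The generator produces a desk-scale study with the same analyzable
structure as a real surface-based cohort. Defaults (the packaged study
conditions): 40 subjects, level-4 icosphere (2,562 vertices) of radius
20 mm standing in for a single hemisphere, 32 spatially contiguous
parcels dealt round-robin to the eight networks, two coil placements
("dlpfc"-like and "ofc"-like), four 200-sample runs per subject.

**E-field surrogate.** value(v) = A·exp(−‖v−c‖²/(2σ²)) with the focus c
projected to its nearest mesh vertex, so the peak equals A exactly at one
vertex and the 0.9 V/m isocontour radius has the closed form
σ√(2 ln(A/0.9)). Subject geometry variability enters entirely through
per-subject field realizations on the shared mesh — log-normal amplitude
and width factors (median 1; log-sd 0.12 and 0.10) and a 2 mm/axis
Gaussian focus jitter — because the downstream analysis sees geometry
only through the E-field map. The template field uses identity factors.
Placement nominals (A = 1.5, σ = 4.85 mm; A = 1.25, σ = 3.75 mm) were
calibrated once on the default mesh so the thresholded subject areas land
near the study-scale reference ranges (≈54 ± 18 mm² and ≈16 ± 8.5 mm²)
under the all-three-vertices area rule, and are frozen.

**Connectome generator.** Vertex time series follow a latent factor
model: x_i(t) = Σ_m c_im f_m(t) + w_sh·g(t) + σ_n·ε_i(t) with eight
network factors f_m, a global signal g, and defaults w = 0.8 (within-
network loading), w_sh = 0.4, σ_n = 0.6, giving a population
within-network correlation (w²+w_sh²)/(w²+w_sh²+σ_n²) ≈ 0.69 and
cross-network ≈ 0.14. Pearson matrices are computed per run and averaged
in Fisher z space (run-wise FC averaging is the default; averaging
concatenated time series first is available behind a flag, since either
order is defensible). Matrices are correlation matrices of actual time
series, hence symmetric, unit-diagonal and positive semidefinite by
construction.

Two deliberate design choices shape the generator:

1. **Cohort-level base signals.** The factors, global signal and vertex
   noise of each run are drawn once per cohort and shared across
   subjects; a subject individualizes only through vertex-wise loading
   perturbations δ_im ~ N(0, s²) with s = `fc_perturbation_scale`
   (default 0.15). FC variability is therefore a single knob, and s = 0
   makes every subject's connectome — and hence the geometry-only and
   combined variants — *identical by construction*, so the framework's
   degeneracy identities hold exactly rather than approximately.
2. **Boundary mixing.** Loadings c_im spread over networks with a spatial
   kernel exp(−d²/(2λ²)) on the distance from vertex i to the nearest
   vertex of network m (rows normalized; λ = `boundary_mixing_mm`,
   default 2 mm). Deep-parcel vertices load almost purely on their own
   network, while boundary vertices genuinely mix — which is what makes a
   vertex's maximum-FC network ambiguous there and lets individual FC
   perturbations flip assignments. Without mixing (λ = 0, the pure
   one-factor-per-vertex model) every vertex's argmax network is
   identically its parcel's network, FC-driven engagement variability is
   exactly zero, and the cross-variant correlations the framework exists
   to measure are undefined. λ = 0 remains available and is the regime in
   which the pure factor-model formulas are exact.

**Reproducibility.** All randomness derives from `master_seed` through
named SeedSequence spawn keys: (0,) parcellation, (1, subject) subject
parameters, (2, run) base signals, (3, subject) FC perturbations. Distinct
subjects never share a stream; the same master seed reproduces the cohort
bitwise. Zero-spread parameter draws short-circuit to exact identity
values so degenerate cohorts are bitwise degenerate.

**Planted-network cohorts.** For parameter-recovery checks a cohort can
plant a network under one placement: parcels within a disc around the
focus (radius defaulting to the template isocontour radius plus a jitter
allowance) are reassigned to the planted network, whose loading is
multiplied by 3. The recovery oracle is `expected_profile`, the
population-limit engagement computed in closed form from the factor-model
covariance Σ = CCᵀ + w_sh²J + σ_n²I — an expectation independent of the
Monte Carlo pipeline it checks.

## What the generator does and does not emulate

It emulates: focal, subject-varying suprathreshold patches with
realistic area dispersion; block-structured connectomes with a global
signal, run structure and subject individuality; contiguous parcels
covering eight networks; the template-versus-subject field contrast. It
does **not** emulate cortical folding (distances are Euclidean on a
sphere; no geodesics), BOLD hemodynamics or temporal autocorrelation,
subcortical structures, negative FC structure (anticorrelated networks),
or distance-dependent FC decay. Passing tests therefore demonstrate the
*pipeline's* correctness and the framework's internal logic on data with
the right structure — not that real cohorts would show the same
engagement splits or correlation magnitudes.

## Numerical choices and problem sizes

Connectome computations run in float64; per-subject run-averaged matrices
are cached in float32 (≈25 MB each at the default 2,562 vertices), and
the oracle-equivalence tests that assert 1e-12 agreement use small
float64 instances. Fisher averaging clips |r| at 1−1e-7 before arctanh
and forces the diagonal back to 1. Degenerate mesh faces (collinear)
contribute zero area with a logged warning, since real surface extracts
contain slivers. The packaged default of 40 subjects at subdivision
level 4 keeps a full two-target, three-variant analysis within a few
minutes on a single core; tests use level 2–3 meshes with 4–8 subjects
except for the one recovery check that runs the default-scale cohort.

## Known limitations

* Engagement profiles are compositional; the RM-ANOVA treats them as
  ordinary within-subject scores, as the analysis framework specifies.
* On coarse meshes (level ≤ 2) the all-three-vertices area rule often
  yields zero-area seeds; area-based statistics need level ≥ 3.
* The synthetic parcellation assigns networks to parcels arbitrarily, so
  *which* network a placement engages is a property of the seed's
  position relative to the parcellation draw, not of the network labels.
* Twin structure, age/sex covariates and any between-subject modeling
  are out of scope; all inference is within-subject or correlational.
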