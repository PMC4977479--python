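# Methods

`stericrules` models the aggregation of antibody–receptor complexes onto a
rigid, two-stranded, multivalent antigen (the motivating system is the shrimp
allergen tropomyosin binding IgE–FcεRI complexes on a mast-cell membrane).
Its central idea is that molecular geometry enters a rule-based kinetic model
only through a *steric adjacency*: which pairs of binding regions are close
enough that an antibody bound at one reduces access to the other.

## Model

### Geometry and steric adjacency

Each of the antigen's two strands carries six binding regions, `A`–`F`
(twelve in total).  For every unordered region pair a distance in nm is
supplied as data, together with a curvature label:

* **negative curvature** (the molecule folds back on itself): the straight
  **linear** distance is used, because hindrance acts through space;
* **nonnegative curvature**: the **path** distance along the molecule is
  used, because positive curvature pulls regions apart in space.

Given a cutoff distance `d_c`, regions `a` and `b` hinder each other iff
their effective distance `r` satisfies `r ≤ d_c` (the boundary counts as
hindered; the half-resolution worked example in the fixtures — C–D at exactly
5.5 nm under a 5.5 nm cutoff — is treated as hindered).  Adjacency is
monotone in `d_c`, so a grid scan of cutoffs partitions into maximal
intervals of constant adjacency (`adjacency_breakpoints`); the rule set, and
hence every downstream result, is constant within an interval.

Distances are data, not computed from structures: structure preparation is
out of scope.  Curvature labels are likewise per-pair inputs; the package
does not classify curvature automatically.

### Rules

For a region with steric neighbors `n_1..n_s`, one forward binding rule is
generated per occupancy pattern of the neighbors — `2**s` rules in binary
counting order, regions in strand order, so exports are byte-reproducible.
The all-free pattern binds at `k_f1 = 1.0 molecule⁻¹s⁻¹`; every other
pattern at the hindered rate `0 ≤ k_f2 < k_f1`.  The older "no binding under
hindrance" variant is exactly `k_f2 = 0`, so one code path serves both.
Unbinding is uniform at `k_r = 0.01 s⁻¹`.  One antibody binds one region;
crosslinking of antigens and per-region epitope-count weighting of rates are
deliberately excluded.

**Directed hindrance maps.**  Adjacencies derived from distances are
symmetric by construction.  The published 60°-rotated demonstration rule
table, however, is directional for one pair: region D's accessibility
depends on B, but not conversely.  `StericAdjacency` therefore tolerates
directed maps (with `require_symmetric()` available as an assertion), and
the `rotated60` fixture ships as an explicit hindrance map rather than a
distance table — no symmetric distance table can produce it.  Physically a
directed entry reads: a bulky complex parked at a recessed region can block
a neighbor whose reciprocal effect is negligible.

### Dynamics

Because each strand's configuration is just the occupancy of its six
regions, the state space is the `2**6 = 64` occupancy vectors per strand and
the network is enumerated exhaustively (generate-then-integrate): 192
binding and 192 unbinding reactions per strand, each binding consuming one
free receptor.  Mass-action ODEs are written in raw molecule counts
(bimolecular constants in molecule⁻¹s⁻¹, no volume factor) and integrated
with LSODA and an analytic Jacobian — the binding transient is stiff
(per-site propensities ~10³/s against `k_r = 0.01/s`).

Standard copy numbers are 100 molecules of each strand and 1000 receptors,
integrated for 1000 steps of 0.01 s (10 s).  The two strands are independent
by assumption; whether they share the 1000-receptor pool or each see the
full pool alone is ambiguous in the source description, so both modes exist:
`shared_receptor_pool=True` (default, one ODE system) and `False` (each
strand type integrated alone).  The acceptance workflows use the shared
pool.

**Steady-state criterion.**  The horizon is fixed at 10 s rather than
integrating to machine steady state.  A slow mode relaxing on the `1/k_r`
scale persists there (max|dy/dt| ≈ 3×10⁻² molecules/s), but integrating to
1000 s moves the reported size distributions only in the fourth decimal, so
the 10 s state is steady for every quantity the package reports.  The
convergence flag uses a relative residual — max|dy/dt| below `1e-3` of the
total strand copy number per second — and warns rather than silently
extending the horizon; the absolute residual is always reported.

A seeded Gillespie simulator over the identical network serves as an exact
finite-copy-number oracle; the test suite requires ODE/SSA agreement of
per-size-class counts within three standard errors over 200 runs on three
topologies (bins that all runs observe as empty are bounded by the rule of
three, 3/n_runs).

### Aggregates and scoring

Strands bind independently, so the whole-antigen aggregate-size distribution
is the discrete convolution of the per-strand distributions, always over the
13 sizes 0–12.  Histograms are compared by

    sigma = sum_i (P_target_i − P_model_i)² / 13 .

For probability vectors the maximum of this statistic is `2/13 ≈ 0.154`
(disjoint point masses), not 1; the package implements the formula exactly
and does not enforce a unit upper bound.  Repeated-run campaigns are
summarized by binning runs (default: 60 runs into 10 sets of 6) and taking
the standard error of the bin means.

### Rate-constant fitting

`k_f2` is the only free kinetic parameter.  It is fitted by an adaptive
Metropolis–Hastings walk on sigma: always accept a candidate with
`sigma_n ≤ sigma_c`; accept a worse one with probability
`exp(−Δsigma/T)`; on rejection redraw uniformly from the allowed range
0.00–0.40 molecule⁻¹s⁻¹; on acceptance take one adaptive step (sizes
1×10⁻⁴ and 1×10⁻⁵ molecule⁻¹s⁻¹).  Proposals are quantized to the small
step, so the search lives on an exact 40 001-point grid: traces are
bit-reproducible for a seed and sigma evaluations are memoized.

Design choices where the scheme is underdetermined:

* **Step adaptivity.**  The walk descends with the *large* step while moves
  keep improving, switches to the small step (reversing direction) when an
  accepted move overshoots a minimum, and resets to the large step with a
  fresh random direction after each redraw.  The alternative reading —
  small steps whenever sigma is decreasing — makes every descent
  O(range/10⁻⁵) ≈ 2×10⁴ evaluations on this smooth, mostly monotone
  landscape and was measured to be unusably slow; fast-descend /
  refine-on-overshoot preserves the published accept/reject and redraw
  rules while making recovery practical.
* **Temperature.**  Not stated in the source scheme.  The default
  `T = 1e-3` accepts a sigma increase of 10⁻³ with probability ≈ 0.37.
  Sensitivity: per-step sigma changes are ~10⁻⁸–10⁻⁶, so at `T = 1e-3`
  nearly every local move is accepted and the walk explores diffusively;
  at `T ≲ 1e-8` uphill moves are rejected, triggering the global redraws
  that do the real searching.  Precision fits (tests, the acceptance
  script) therefore run cold (`T = 1e-8`).
* **Initialization.**  Default midpoint 0.20; precision fits start at 0.0,
  ascending from the fully-hindered limit where all fitted values of
  practical interest lie.
* **Stopping.**  2000 iterations, or 200 consecutive candidates without a
  best-sigma improvement, or (optionally) a sigma floor `sigma_stop`;
  precision fits use `sigma_stop = 1e-9`.

Because the rule set is constant within an adjacency interval, `scan_cutoff`
runs one optimization per interval (16 for the full 3.0–20.0 nm grid on the
full-resolution fixture) instead of one per 0.1 nm grid point; a
`per_point=True` mode reproduces the literal loop.  The winner is reported
as the full cutoff *interval*; sigma ties resolve toward the smallest
cutoff.

### Membrane Monte Carlo

The target-generating simulator is a deliberate simplification of a
polygon-mesh rigid-body method: molecules are disks on a 2D membrane patch.
One rigid antigen carries 12 point sites (two parallel rows of six, default
spacing 7 nm, row gap 2 nm); receptors are disks of radius 5 nm.  Per
10 µs step: the antigen aggregate (antigen plus bound receptors, moving
rigidly) and every free receptor take Gaussian displacements with
`D = D0/size` (`D0 = 0.09 µm²/s`, size = bound receptors, minimum 1) and
the aggregate a Z-rotation with `D_rot = 0.5/size rad²/s`; moves are
rejected on disk overlap, site-exclusion violation, or boundary exit
(non-periodic 200×200 nm box).  Site–receptor pairs within the binding
distance (6 nm) bind with probability `min(1, k_on·dt)`; bound receptors
unbind with `min(1, k_off·dt)`; each site and each receptor holds at most
one bond.  A run's aggregate size is its final bond count; campaigns of 60
seeded runs feed the error-bar machinery.

Steric hindrance is emergent: a bound receptor excludes others from a
receptor-diameter neighborhood, so sites spaced inside ~10 nm compete.
Reduced model resolution is emulated abstractly by shrinking exclusion
radii (volume loss increases site accessibility).  The exclusion radius
(0.5 nm per site), binding distance, and rotational diffusion constant are
not published quantities; they are order-of-magnitude reconstructions,
exposed in `MCConfig`.  Energetics are absent, so the simulator constrains
packing structure, not kinetics, and forward rate constants cannot be read
off it — which is exactly why the rule-based fit exists.

## Fixtures are reconstructions

The source material prints rule tables and fitted cutoff intervals but not
the underlying distance matrices.  The shipped fixtures (`native`,
`s_shaped`, `u_shaped`, `rotated45` distance tables; `rotated60` hindrance
map) are synthetic reconstructions whose distances were chosen once so
that:

* the full-resolution conformations produce the nearest-neighbor chain
  adjacency A–B–C–D–E–F exactly over their published cutoff intervals
  (native 7.0–8.7 nm, S-shaped 6.8–8.3 nm, U-shaped 6.8–8.6 nm);
* the native table reproduces the half-resolution worked example
  (strand I C–D = 5.5 nm hindered at a 5.5 nm cutoff, strand II C–D =
  5.6 nm not);
* `rotated45` and `rotated60` reproduce their published rule tables at the
  demonstration cutoff 8.1 nm.

They are labeled as reconstructions in the data files.  Consequently, tests
that "recover 7.0–8.7 nm" validate the machinery against the construction,
not against independent measurements.

## What the synthetic targets do and do not show

Self-generated targets (the model evaluated at a known `k_f2` and cutoff)
exercise identifiability: the scan must find the generating adjacency
interval and rate from the histogram alone.  Passing shows the pipeline is
correct and the parameters are recoverable at these copy numbers; it does
not show that the disk-based membrane simulator — let alone a real membrane
— is matched by the rule-based family, because published mesh-based target
histograms exist only as figures and real binding data for this
antigen–antibody pair does not exist.  Fitted values against the built-in
membrane simulator are therefore properties of this package's study
conditions, not reproductions of published fits.

## Problem sizes

Default study conditions are stated above (100/100/1000 copies, 10 s ODE
horizon; 200×200 nm box, 24 receptors, 5×10⁵ MC steps, 60 runs).  The test
suite runs the ODE/SSA comparison at full copy numbers with 200 stochastic
runs per topology; the recovery test scans 6.5–10.0 nm (five adjacency
intervals bracketing the generating cutoff) over 20 seeds with a 300-
iteration optimizer budget per interval; membrane tests use the scaled
`MCConfig.test_profile()` (80×80 nm, 10 receptors, boosted `k_on`, 4000
steps).  The acceptance script runs the full 3.0–20.0 nm scan.  These sizes
are the package's chosen defaults for its verification suite.

## Known limitations

* The ODE model is mean-field; finite-copy-number effects are only checked
  against the Gillespie oracle, not corrected for.
* The membrane simulator omits energetics, receptor–receptor binding,
  antigen–antigen interaction, and 3D geometry; its exclusion radii are
  reconstructions.
* Fitting assumes the target histogram is a single distribution; fitting to
  per-run campaigns uses their pooled mean.
* With a warm temperature the optimizer explores diffusively (see above);
  cold runs depend on the redraw mechanism and may need more iterations on
  landscapes with several near-degenerate minima.
* Directed hindrance maps cannot arise from distance tables; they exist
  only for transcribed published rule tables.
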