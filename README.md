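# stericrules

Geometric rule-based modeling of multivalent antigen–antibody aggregation.

Traditional rule-based kinetic models count binding sites but ignore where
the sites *are*.  For a multivalent antigen such as shrimp tropomyosin
(Pen a 1) binding membrane-anchored IgE–FcεRI antibody–receptor complexes,
geometry matters: an antibody parked at one binding region can physically
block its neighbors.  `stericrules` encodes that geometry into the rules
themselves, using nothing more than the pairwise distances between binding
regions and a single *cutoff distance* `d_c`.

For audiences: computational immunologists and systems biologists studying
receptor aggregation, and rule-based-modeling practitioners who want
geometry without particle-based spatial simulation.

## The method

The antigen is a rigid two-stranded rod with six binding regions per strand
(`A`–`F`, 12 total).  Two regions on a strand *hinder* each other when their
effective distance `r` — the linear distance in areas of negative curvature,
the along-molecule path distance otherwise — satisfies `r ≤ d_c`.  Each
region with `s` hindering neighbors expands to `2**s` forward binding rules,
one per neighbor occupancy pattern:

* all neighbors free → unhindered rate `k_f1 = 1.0 molecule⁻¹s⁻¹`,
* any neighbor bound → hindered rate `k_f2 < k_f1`,

with uniform unbinding at `k_r = 0.01 s⁻¹`.  The rules expand to the exact
64-state-per-strand reaction network, whose mass-action ODEs give per-strand
occupancy distributions `P_I, P_II`; strands bind independently, so the
whole-antigen aggregate-size distribution over sizes `n = 0..12` is the
convolution

    P(n) = Σ_m P_I(m) · P_II(n−m).

Model and target histograms are scored by the normalized residual sum of
squares `σ = Σ_{i=1..13}(P_target − P_model)²/13`, and the two free
parameters — the cutoff `d_c` (scanned 3.0–20.0 nm in 0.1 nm steps, one fit
per interval of constant rule set) and the hindered rate `k_f2` (adaptive
Metropolis–Hastings over 0.00–0.40) — are optimized against the target.  A
disk-based rigid-body membrane Monte Carlo simulator (one antigen and 24
receptor disks at 600/µm² on a 200 × 200 nm patch) generates target
histograms with the statistical structure the fit expects.  Details and all
modeling choices: [docs/methods.md](docs/methods.md).

## Worked example

Recover a known hindered rate and cutoff from a synthetic target
(`examples/04_fit_hindered_rate.py`):

```bash
$ python examples/04_fit_hindered_rate.py
winning cutoff interval: (7.0, 8.7) nm (true value 8.0 nm lies inside)
recovered k_f2 = 0.00500 (true 0.00500)
sigma = 0.00e+00, model evaluations = 1028

per-interval best fits:
  d_c in [ 6.5,  6.9]  k_f2 = 0.00530  sigma = 4.52e-06
  d_c in [ 7.0,  8.7]  k_f2 = 0.00500  sigma = 0.00e+00
  d_c in [ 8.8,  9.4]  k_f2 = 0.00420  sigma = 1.73e-05
  d_c in [ 9.5,  9.8]  k_f2 = 0.00400  sigma = 2.77e-05
  d_c in [ 9.9, 10.0]  k_f2 = 0.00380  sigma = 5.19e-05
```

The target was generated by the model itself at `d_c = 8.0 nm`,
`k_f2 = 0.005`.  The scan cannot pin a single cutoff — every cutoff in
7.0–8.7 nm produces the identical nearest-neighbor rule set — so it reports
the whole interval, which contains the generating value; within it the
fitted `k_f2` is exact (`σ = 0`), while neighboring rule sets fit strictly
worse (`σ ≥ 4.5×10⁻⁶`).  That interval-plus-rate pair is the method's
readout of average steric hindrance.

Other entry points, one capability each, under `examples/`:
rule construction and BNGL export (01), ODE steady states and per-region
binding probabilities (02), strand convolution and σ scoring (03), the
membrane Monte Carlo campaign with binned error bars (05).

A thin CLI wraps the same workflows:

```bash
stericrules rules --fixture rotated60 --kf2 0.005 --out out/
stericrules demo curvature --out out/      # U-shaped vs 45° vs 60°
stericrules mc --profile test --seed 1 --runs 12 --out out/
```

Built-in fixtures (`native`, `s_shaped`, `u_shaped`, `rotated45`,
`rotated60`) are synthetic distance-table reconstructions that reproduce the
published rule-set topologies and cutoff intervals; see docs/methods.md.

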