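# Methods

This note records the models the package implements, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
benchmarks do and do not establish.

## Scope and representation

All structural machinery operates at Cα resolution: collective variables,
RMSF, PCA and the elastic network are all defined on Cα positions, and the
PDB reader honors only Cα ATOM records.  Coordinates are in Å, energies in
kcal/mol, times in ps, residue numbering 1-based; a missing chain id
defaults to `A`.  RT uses k_B = 0.0019872041 kcal/(mol·K) with T = 300 K
unless configured.

## Collective variables

Two CVs describe the clamp: the Euclidean distance between the unweighted
Cα centroids of the two domains' residue groups, and a smooth contact
count — the sum over cross-domain Cα pairs of the rational switching
function (1−(d/d0)^p)/(1−(d/d0)^q) with defaults d0 = 8 Å, p = 6, q = 12
(the removable singularity at d = d0 is filled with p/q).  Centroids are
unweighted because the model is Cα-only with equal masses.

Binary contacts, used for contact frequencies and the FCC, are Cα–Cα
distances strictly below a single cutoff, default 4.5 Å.  The literature
offers no unique contact criterion at Cα resolution; 4.5 Å matches
heavy-atom practice rescaled to the compact Cα-only toy systems and is
configurable everywhere.  **Absolute contact frequencies ω_ij depend
directly on this one knob**; rankings and the FCC are much less sensitive.

## Well-tempered metadynamics reconstruction

Hills carry their recorded (already-tempered) heights; the accumulated
bias V(s) is the plain Gaussian sum, and the surface is
G(s) = −((T+ΔT)/ΔT)·V(s), min-shifted to zero.  "Bias temperature 3300 K"
is interpreted as ΔT = 3300 K, i.e. bias factor γ = (T+ΔT)/T = 12 at
300 K, following the convention of the biasing software the hill dialect
is modeled on.  Grid bins default to the hill widths (0.125 Å in d, 0.25
in the contact count) — Nyquist-like sampling of the Gaussian kernel.

Bins whose accumulated bias falls below a small fraction (default 5%) of
the maximum were never visited; they are marked *unsampled* and carry no
imputed G.  The distance profile is the thermodynamic marginal
G(d) = −RT·ln Σ_n e^{−G(d,n)/RT}·Δn over sampled bins, and
ΔG_unb = (mean of G over the unbound plateau) − (min of G over the bound
region).  When no regions are given, the bound region is the full sampled
range and the plateau is the last 20% of it; the synthetic potentials
declare their own regions (barrier ± 3σ, plateau inset 1 Å from the
reflecting wall — hills deposited against a wall lose Gaussian mass beyond
it, which otherwise reads as a spurious rise).

Because the bias is deposited in discrete hills one grid-bin wide, the
reconstructed profile carries bin-scale noise (~0.2 kcal/mol per run at
the benchmark length).  A min-statistic over a flat region selects the
extreme of that noise and would bias ΔG upward by several tenths of a
kcal/mol.  The marginal profile is therefore smoothed with a Gaussian
kernel of 3 bins (0.375 Å) before region statistics — an order of
magnitude below the ≥1.2 Å feature widths of the landscapes, so the shape
is preserved (wells of σ = 1.5 Å shallow by ≲0.1 kcal/mol, a distortion
the recovery benchmark absorbs within its ±0.3 tolerance).  Smoothing is
configurable and can be disabled.

## Reweighting

Three schemes produce per-frame unbiasing weights, always non-negative and
normalized, and uniform under zero bias:

* `final_bias`: w_t ∝ exp(V(s_t, t_final)/RT) — ignores the bias's time
  dependence, biased toward early frames.
* `time_dependent`: w_t ∝ exp((V(s_t, t) − c(t))/RT) with the running
  offset c(t) = RT·ln[Σ e^{βγ'V}/Σ e^{β(T/ΔT)V}] evaluated on the grid at
  each deposition epoch (γ' = (T+ΔT)/ΔT).
* `balanced_exponential`: the geometric mean of the two exponential
  weights above, balancing the early-frame bias of the final-bias scheme
  against the noise of the instantaneous one.  The scheme's defining
  contract here is the consistency check below, which is how the approach
  is validated in practice.

The consistency check: the FES from the reweighted histogram of the biased
CVs must agree with the bias-derived FES on mutually sampled bins.  The
comparison removes the mean difference first — a free energy is defined up
to an additive constant, and each surface's own min anchor is a noisy
extreme — and discards the first 40% of frames, where the bias is far from
converged.  On converged synthetic runs all three schemes agree within
0.5 kcal/mol RMSE on a 0.25 Å × 0.5 grid.

## Contact scoring

ω_ij is the (weighted) fraction of frames in which cross-domain pair
(i, j) is in contact; with uniform weights this is the biased variant,
with metadynamics weights the reweighted one.  S_i = Σ_j ω_ij.  Score
dispersion across replicate runs is reported as a standard deviation,
while ΔG_unb uses the standard error of the mean — two conventions kept
deliberately distinct.  Frequencies are intended to be computed over
frames up to the detected detachment time, so S_i reflects contact
persistence during unbinding; the detachment detector returns the earliest
time from which the contact count stays at zero for a full 200 ps window.
Domain membership comes from the structure's domain-label map, never from
hard-coded residue ranges, so toy systems and real proteins share one code
path.

## Collective motions

Superposition is the least-squares Kabsch fit (proper rotations only).
PCA eigendecomposes the 3N×3N covariance of aligned Cα coordinates about
the global trajectory mean; replicas are pooled by frame concatenation
after alignment to a common reference.  The ANM uses the standard
superelement Hessian with a uniform spring constant for pairs within a
cutoff (default 15 Å); exactly six near-zero eigenvalues are removed (five
for collinear geometries, which lack one rotation).  Eigenvector sign is
fixed by making the largest-magnitude component positive.  Mode agreement
is the absolute cosine of unit-normalized vectors.

## FRET distances

d_exp = R0·(1/E − 1)^(1/6) − linker, with R0 = 5.1 nm and linker = 1 nm.
Distances that come out non-positive after the linker subtraction are
flagged, not dropped or clamped — silent dropping would bias any
comparison.  Model distances are residue-centroid (single Cα here)
distances per frame, pooled across replicas; dye photophysics beyond the
scalar linker correction is out of scope.

## Thermodynamic coupling

The current model I0 = c0·(1/(1 + c1·e^{ΔG_unb/RT}))^n follows from a
two-state Boltzmann occupancy of the open state,
p_open = 1/(1 + e^{ΔG_quiesc→open/RT}) with
ΔG_quiesc→open = ΔG_unb + ΔG_unb→open, so c1 = e^{ΔG_unb→open/RT} and the
fitted c1 converts back as ΔG_unb→open = RT·ln c1.  The exponent n absorbs
cooperativity of sensor–channel engagement (n < 1: anti-cooperative).  The
two-state reduction of the underlying three-state (quiescent / detached /
open) picture is an assumption of this implementation.

The fit runs in (log c0, log c1, n) to enforce positivity — essential
because realistic c1 is ≪ 1 — with n bounded to [0, 5], multi-starts over
log-spaced c1 (11 values × 3 n inits), weights 1/SEM² on I0 when SEMs are
available (unweighted mode provided, since real panels may lack usable
SEMs), and parameter standard errors from the Jacobian at the optimum.
Degenerate panels (all currents equal, fewer than four distinct ΔG
values) are rejected with an explanatory error rather than fitted.

## Synthetic systems

The generators define the study conditions; each is a pure function of
(parameters, seed) and ships its planted truth alongside the data.

**Analytic landscape.** U(d, n) = W(d) + (k_n/2)(n − n0(d))² with W a sum
of Gaussian wells/barriers on a reflecting domain d ∈ [3, 22] Å, k_n = 3
kcal/mol, and a tanh switch taking n0 from 6 (bound) to 1.5 (plateau).
Constant tether stiffness makes the n-marginal contribute only a constant
to G(d), so the planted ΔG equals the well depth; the quadrature oracle
integrates e^{−βU} over n ∈ [0, n_max] on a fine grid.  The plateau
tether center sits 3.4 thermal widths above the reflecting wall at n = 0,
making the truncation thermodynamically negligible (<10⁻³ kcal/mol).

**Sampler.** Overdamped (Brownian) dynamics — only equilibrium sampling
correctness matters for FES validation, and first-order dynamics is
simpler to verify (with zero hill height the long-run histogram matches
the Boltzmann density; this is a unit test).  D = 1 Å²/ps, dt = 0.005 ps,
chosen so the stiffest term (a fresh 0.3 kcal/mol hill of width 0.125 Å)
stays well inside the stability limit.  Hills every 1000 steps with
heights h0·e^{−V/k_BΔT}; the bias force is tabulated on a 0.0625 × 0.125
grid, patched analytically at each deposition, and looked up
nearest-bin in the integration loop.  The recovery benchmark uses
3·10⁶ steps per replicate and seven replicates (~1 minute total on one
CPU), which converges the mean to well within the ±0.3 kcal/mol band.

**Toy complex.** Two Cα rods at 3.8 Å spacing; the first n_interface
domain-B beads sit at seed-shuffled gaps between 0.82 and 0.96 of the
contact cutoff above their domain-A partners (nearest non-partner
cross-distance 5.3 Å), so the reference contact set is exact and the
order in which contacts break under rigid separation is planted.  One
domain-A residue is placed ≥10 Å from every domain-B bead — the
never-binding control whose S_i must be exactly zero.  Detachment
trajectories translate domain B along +y so the centroid distance tracks
a driving series exactly before an (optional, small) isotropic jitter.

**Swing-out dimer.** Two copies of the toy complex are repacked into
compact 4×3×3 lattice lobes hung from a shared plate through two vertical
arms — a tuning-fork.  The planted mode is the anti-phase lateral swing
with flexure growing linearly with depth below the plate; by construction
of the geometry this is also the softest internal mode of the elastic
network (at the 7.7 Å cutoff the truth object recommends for the 3.8 Å
lattice), orthogonal by symmetry to all six rigid-body modes.  Frames
oscillate along exactly that field plus isotropic Gaussian noise.

**Mutant panels.** I0 sampled as model·(1 + ε), ε ~ N(0, cv), truncated
at zero; per-point SEM set to cv·(ideal current).  The benchmark grid
spans ΔG_unb = 2–9 kcal/mol (13 mutants), c0 = 15 pA/pF,
c1 = e^{−4.81/RT}, cv = 5%.

## What the benchmarks do and do not show

Passing benchmarks establish that the estimators are implemented
correctly and are unbiased at the planted conditions: they recover known
free-energy differences, discriminate planted interfaces, find planted
modes, invert the Förster relation exactly, and recover generating
parameters of the current model.  They do **not** establish force-field
accuracy, convergence rates on rugged 3N-dimensional protein landscapes,
sidechain-level contact chemistry, dye-orientation effects in FRET, or
any property of the real sensor protein — real-system numbers (per-mutant
ΔG_unb, absolute binding scores, measured cooperativity) require
cluster-scale MD and experiments that are out of scope here.

## Known limitations

* The bias-derived FES near reflecting boundaries is systematically
  underfilled (no image hills); measurement regions should stay ~1 Å away
  from walls, as the synthetic potentials' declared regions do.
* The balanced-exponential weights are implemented as the geometric mean
  of the two textbook schemes; other formulations exist, and the module's
  guarantee is the FES-agreement contract, not a specific formula.
* `smooth_profile` treats disjoint sampled segments independently and
  will slightly shallow features comparable in width to its kernel.
* The ANM uses a uniform spring constant; distance-weighted variants are
  not provided.
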