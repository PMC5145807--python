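# Methods

This note documents the models and numerical conventions behind
`pore-annotate`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Units and constants

Coordinates are carried in Å, energies in kJ/mol, times in ns, charges in
elementary charges, temperatures in K.  kT is R·T = 0.008314 kJ/mol/K × T
(2.577 kJ/mol at the default 310 K).  Force constants follow the MD-engine
convention of kJ mol⁻¹ nm⁻²; every place a bias or restraint is evaluated
converts explicitly through `units.bias_energy` (1 nm² = 100 Ų), and a
dedicated test pins the conversion (k = 1000 kJ mol⁻¹ nm⁻² at 1 Å
displacement must give 5 kJ/mol) because a silent factor-100 error here
would deform every PMF while leaving the code superficially plausible.

## Structures, trajectories, selections

PDB (fixed-column) and GRO files are parsed through biotite; a validation
pass runs first so malformed ATOM/HETATM records and ragged multi-model
files are reported with line or frame numbers.  Multi-model PDB is the
mandatory trajectory dialect; frames receive times 0, dt, 2dt, … ns.
United-atom structures are accepted as-is; no hydrogens are built, and no
missing-atom repair is attempted.

The van der Waals radius table is the HOLE-style set (C 1.85, N 1.75,
O 1.65, S 2.00, H 1.00, P 2.10 Å, default 2.00 Å for anything else), with
atom-name-prefix overrides taking precedence over element lookup.  The
table is a package decision — probe-radius parameter sets vary between
HOLE installations — and is fully overridable.

The selection language is a deliberately small grammar (field keyword plus
values, `resid` ranges, `and`/`or`/`not`, parentheses) implemented as a
recursive-descent parser that reports error positions.  It covers what the
analyses need (isolating pore-lining helices, water oxygens, ion species)
without aspiring to a full MD-analysis query language.

Elastic-network (GNM) restraint specification emits all unordered Cα pairs
with separation inside a [7, 9] Å band at 1000 kJ mol⁻¹ nm⁻², the standard
parameters for conformation-preserving networks; pair search uses a k-d
tree but is tested against a brute-force all-pairs filter.

## Pore-radius profiling

The radius at axial position z is the largest probe sphere centered in the
plane normal to the channel axis: r(c) = min_i(|c − xᵢ| − vdWᵢ) with |·|
the full 3-D distance, maximised over the in-plane center c.  The search
is Monte Carlo simulated annealing (default 30 geometric temperature
stages × 50 moves, temperature 1.0 → 0.01 in objective units, proposal
step 1.0 → 0.1 Å) followed by a deterministic Nelder–Mead polish.  Two
details matter:

* A center whose objective is negative overlaps an atom and is not a valid
  probe position; moves from a valid center into overlap are rejected
  outright.  Besides being physically motivated, this prevents the chain
  from tunnelling through a thin pore wall into the unbounded exterior,
  where the objective grows without limit.
* Marching along the axis seeds each plane with the previous plane's
  optimum, keeping the center line continuous through tilted pores.  A
  plane with no atom within reach (default 15 Å) reports an "unbounded"
  sentinel (`inf`).

The channel axis defaults to the direction of maximal coordinate variance
of the (selected) atoms — correct for an elongated transmembrane bundle —
and can be overridden.  Ties in `min_radius` resolve to the smaller z.
On lattice-built model pores the annealed optimum agrees with an
exhaustive two-stage in-plane grid search to < 0.05 Å; note the oracle's
search extent must stay inside the lumen, since the global optimum over
the whole plane lies outside any finite wall.

Gate candidates are contiguous runs with radius below 4.5 Å (the
hydrophobic-gating radius regime).  Lining residues are those with a heavy
atom whose surface lies within 2.8 Å (a water diameter-ish offset; the
choice is a package decision) of the local probe surface, and the
hydrophobic fraction classifies residues by the positive side of the
Kyte–Doolittle scale.

## Hydration analyses

Water tracks record the axial coordinate of each selected water oxygen,
with an in-pore mask (radial distance ≤ cylinder radius, z within the
mouths).  With a periodic box, radial distances are minimum-image and z is
unwrapped per particle between consecutive frames.

* **Dewetted fraction** — fraction of frames with zero waters in the gate
  slab; invariant under frame permutation.
* **Flux** — completed traversals between the two mouth planes with
  two-gate hysteresis: a particle must enter from beyond one plane and
  exit beyond the other without first returning past its entry plane, so
  boundary jitter never counts.  Both directions are logged; the headline
  rate is total bidirectional events per ns (reported flux values in the
  literature rarely state direction handling, so both components are kept).
  The counter is validated exactly against an independently coded
  state-machine oracle on random-walk ensembles, and time-reversing a
  trajectory must swap up/down counts exactly.
* **Density and Boltzmann inversion** — n(z) is the mean in-pore count per
  bin (default 1 Å) per frame; Σ bins × frames equals the total
  observation count as an integer identity.  E(z) = −kT ln n(z) + kT ln C
  with C the mean density over the outermost three bins at each pore end,
  implementing "zero at the two ends of the pore".  Bins never visited in
  n_frames frames yield the finite lower bound E ≥ −kT ln(1/n_frames) +
  kT ln C with a mask, so fully dewetted (closed) pores serialise cleanly
  instead of producing infinities.
* **Hydration shells** — per-frame counts of water oxygens within a first
  cutoff and between first and second cutoffs of a single ion.  Defaults
  3.2/5.5 Å suit Na⁺ (3.9/6.2 Å recommended for Cl⁻); shell cutoffs are
  radial-distribution conventions, not printed constants, and are
  parameters.

## WHAM

Standard self-consistent WHAM: P(z_b) = Σᵢ nᵢ(z_b) / Σᵢ Nᵢ exp[(Fᵢ −
wᵢ(z_b))/kT], Fᵢ = −kT ln Σ_b P(z_b) exp[−wᵢ(z_b)/kT], iterated from
Fᵢ = 0 until max|ΔFᵢ| < 10⁻⁶ kT (cap 10⁵ iterations; non-convergence is an
error carrying the last residual).  Two numerical choices were made after
observing estimator behaviour on ground-truth landscapes:

* Histograms span the *window-center range* (default 0.5 Å bins), not the
  full sample range.  In the far tails beyond the last anchor the bias
  varies by several kT across a bin and the bin-center approximation
  biases the estimate low — anchoring the zero there propagated a
  ~1 kJ/mol error to the whole profile.  Nᵢ counts only in-range samples
  so the normalisation of spill-over windows stays correct.
* The zero shift matches the equilibrium-inversion convention: the *mean
  density* over the outermost three sampled bins at each end maps to zero
  energy.  With identical bins, WHAM on a single unbiased window then
  agrees with direct Boltzmann inversion of its histogram to < 10⁻⁹
  kJ/mol — a dual-route consistency check kept as an acceptance test.

Unsampled bins are masked (NaN), never interpolated.  Bootstrap errors
resample each window's sample vector with replacement (window identity
preserved — only "a bootstrapping procedure" is conventional here) and
report the per-bin standard deviation over replicates, seeded.  The
convergence diagnostic re-runs WHAM on cumulative time slices (default
0.1 ns segments) and reports the central barrier per slice; a stationary
sampler gives a flat series, drifting windows do not.

On the standard protocol — 21 windows at 1 Å spacing, k = 1000 kJ mol⁻¹
nm⁻², 310 K, 2000 samples per window — a 15 kJ/mol Gaussian barrier is
recovered within 1 kJ/mol across seeds.

## Voltage

Slab charge density ρ(z) (e/Å³, frame-averaged, volume-normalised by the
box cross-section) integrates twice via cumulative trapezoids with
φ = dφ/dz = 0 at the lower box edge, εr = 1 — the conventions of the
GROMACS potential tool; SI conversion to volts happens once at the output
boundary via a centralised constant.  Against the parallel-plate capacitor
closed form ΔV = σd/ε0 the integrator is exact to < 0.1% at 0.25 Å bins,
converging under grid refinement.  Compartment bookkeeping labels the
region between the two membrane slabs α and the periodic remainder β
(every ion lands in exactly one compartment per frame; the α−β imbalance
per species is the driving gradient of a computational-electrophysiology
setup).  Ion crossings reuse the hysteresis traversal detector per
membrane pore; a zero count is a meaningful outcome and is reported as
such.  The ion-swap engine that maintains the imbalance is an MD-runtime
procedure and out of scope — this module analyses its outputs.

## Annotation thresholds

CLOSED requires a water barrier ≥ 10 kJ/mol (≈ 4 kT at 310 K) at some gate
*or* a gate dewetted ≥ 50% of frames; OPEN requires every barrier ≤
5 kJ/mol (≈ 2 kT) with a continuously wetted pore and no lower-bound-only
barrier estimates; everything else is INDETERMINATE, and the overall
verdict is the worst gate.  The two cutoffs are this package's calibration
from the barrier regime reported for annotated pLGIC structures —
non-conductive conformations show ≈ 9–25 kJ/mol, conductive ones
≲ 4 kJ/mol — placed with a deliberate indeterminate band between them; no
published numeric cutoff exists, so both are configurable and embedded in
every report's provenance block.  Flux is reported as evidence but does
not veto a barrier-based call; "a degree of dewetting" in qualitative
descriptions is encoded as a dewetted fraction at the 0.5 criterion.
Verdicts are monotone in barrier height (raising a barrier can never flip
CLOSED toward OPEN) and the classifier is a pure function of its inputs.

## Synthetic generators

The generators emulate exactly the statistical features the analyses
consume, and no more:

* **Model pores** are cylindrical/hourglass lattices of pseudo-atoms
  (1.85 Å carbon-like radii, leucine-named rings so gate detection sees an
  apolar lining).  With lattice spacing s the inscribed-probe perturbation
  is ≤ ≈ s²/(8R); the default s = 1 Å keeps it below 0.05 Å.  Expected
  radii are closed-form (wall − vdW).
* **Pore water** is sampled by independent per-particle Metropolis chains
  along z with stationary density ∝ exp(−U(z)/kT), bounded proposal steps
  (identity continuity), uniform/reflected-random-walk x,y inside the
  cylinder, and a discarded burn-in.  Only stationary distributions matter
  for density, dewetting and inversion analyses, so Metropolis rather
  than Langevin dynamics is used; kinetic observables (diffusion, realistic
  flux time correlations) are *not* emulated.  Traversal-detector fixtures
  instead use unbounded bounded-step random walks, which produce genuine
  crossings with realistic boundary jitter.
* **Umbrella windows** sample exp(−(U + ½k(z−c)²)/kT) per window with
  proposal step 1.2 Å and 5× thinning — chosen so chain autocorrelation is
  small relative to the window width at the default k, keeping recovery
  noise well inside the 1 kJ/mol acceptance band without touching the
  protocol parameters (spacing, k, T).
* **Charged slabs** are two net-neutral pseudo-atom sheets, the capacitor
  oracle for the Poisson integrator.

Every generator is a pure function of parameters and seed (byte-identical
repeats).  Acceptance-scale problem sizes — 250 waters × 4000 frames
(10⁶ in-pore observations) for inversion recovery, 21 × 2000 samples for
WHAM, 10⁴ × 200-step walks for flux — were chosen as the smallest sizes at
which sampling noise sits comfortably inside the stated recovery bands.

Passing on these fixtures demonstrates estimator correctness, not MD
realism: real pore water is interacting, its density couples to protein
flexibility, and real umbrella windows carry correlated, sometimes
unequilibrated series (the convergence diagnostic exists precisely to
catch the latter).

## Degenerate inputs and edge policies

Empty selections error unless explicitly allowed; an all-zero density is
an error (nothing to invert) while partially empty bins become masked
lower bounds; WHAM errors on non-convergence and on windows with no
in-range samples; adjacent windows sharing no occupied bin trigger a
warning (disconnected PMF); fewer than two Cα atoms cannot form a network;
overlapping membrane slabs and inverted gate planes are errors.  Barrier
readout for a known-center landscape uses the bin at the barrier center
(±1 bin) rather than a window maximum, which would bias high under noise.

## Known limitations

* The profiler assumes a single, roughly axis-aligned channel; curved or
  branched pathways (MOLE-style pathfinding) are out of scope.
* Boltzmann inversion reports lower bounds, not values, wherever sampling
  never visited a bin; long closed-gate simulations only tighten the bound.
* The annotation verdict cannot separate closed from
  desensitized/inactivated conformations, by design.
* Binary trajectory formats are not read natively; convert to multi-model
  PDB (or extend `structure_io` behind the same `Trajectory` contract).
* Conductance prediction and ion-selectivity quantification are not
  attempted.
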