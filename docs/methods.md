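# Methods

This note records the models, conventions and numerical choices behind
`memperm`, and what the desk-scale validation does and does not demonstrate.

## Counting permeability

A translocation is complete only when the molecule dissociates from the
bilayer on the far side. Internally the unwrapped membrane-normal coordinate
η(t) is classified, per frame, against the membrane image nearest to it:
*dissociated above*, *membrane-associated*, or *dissociated below*, where
dissociated means strictly beyond the leaflet phosphate plane plus a margin
(default 0.5 nm; the literature criterion specifies dissociation but no
distance, so the margin is a config knob recorded in output metadata). Bulk
regions between periodic membrane images carry an integer zone index; an event
is a change of that index. Consequences of this construction:

* excursions to the phosphate region that return to the same side add no
  event, and re-entries to the bilayer centre without dissociation cannot
  split one crossing into two;
* passage through the periodic box boundary keeps the zone index constant, so
  it can never masquerade as a membrane crossing;
* ties at the threshold resolve to "associated" (strict inequality), which is
  deterministic and stable under time-grid refinement.

The rate constant is k(t) = N(t)/t. The steady state is the earliest grid
point t_ss from which k stays within ±5% of its mean over [t_ss, t_end]
(window-mean reading; comparing to the final value or between consecutive
windows are reasonable alternatives the criterion's source does not
distinguish). The minimum window defaults to 20% of the trajectory. "No
steady state" is a reportable outcome: within this framework it indicates the
molecule does not cross by passive diffusion at a measurable rate.

Permeability: P = k_ss / (2 A C), the factor 2 because both crossing
directions are counted at equilibrium. The molar forms r = k/N_A and
J = r/A are carried for reporting only — Avogadro's number cancels in P.
C defaults to solute count over total box volume; a bulk-phase variant
(count over A·∫exp(−G/k_BT)dη) is used when a landscape is known, and is the
right comparand for the solubility–diffusion oracle because that oracle
references G to the bulk. Replicas are combined as mean ± sample SD, with a
pooled estimate (total events over total time) that coincides with the mean
for equal-length replicas.

## Free-energy profiles and barrier fits

ΔG(η) = −k_B T ln ρ(η) on a uniform grid (default bin width 0.1 nm = 1 Å,
matching the conventional resolution for such profiles), with
k_B = 1.987204259×10⁻³ kcal mol⁻¹ K⁻¹. Empty bins are masked, never imputed
or smoothed: −kT ln 0 is undefined and masking is the only assumption-free
choice. Profiles are referenced so min(ΔG) = 0. Replica averaging is bin-wise
mean and sample SD; a bin empty in any replica is masked in the average.

The two-Gaussian barrier model is fit by least squares (analytic Jacobian,
multi-start initialization with symmetric seeds at ± the profile's extremum
position, both signs of amplitude; best residual wins). The fitted curve is
classified as *two maxima flanking a central minimum* or *two minima flanking
a central maximum* from its extremum pattern on a fine grid, and the barrier
height ΔG‡ is |central extremum − mean of the two flanking extrema| evaluated
on the analytic form. The reported width σ is the mean of the two fitted
Gaussian widths (a single combined width is conventional; per-Gaussian widths
are available on the fit object). σ is treated as nm along η.

Min-referencing a *sampled* profile leaves a small positive bulk baseline
(the minimum of many noisy bulk bins sits below their mean), which the pure
two-Gaussian form can only absorb by widening. `fit_double_gaussian(...,
fit_offset=True)` therefore adds a jointly fitted constant baseline; parameter
recovery from equilibrium samples uses it, while noiseless fixtures do not
need it.

Width uncertainty: fixed-x residual bootstrap. Synthetic curves = fitted form
+ residuals resampled with replacement, refit from the point estimate;
percentile (2.5–97.5%) interval on σ over (default) 2000 replicates; seeded.
More than 10% refit failures aborts with a diagnostic. Coverage was checked
by repetition: with Gaussian noise of 0.05 kcal/mol on a known curve, the CI
contains the true σ in ≥90% of 60 seeded repetitions.

## Contact analysis

A contact is a (solute atom, lipid atom) pair within 0.33 nm under the
minimum-image convention — a purely distance-based criterion (no angle term),
all atoms including hydrogens, counted once per frame per pair. Neighbour
search uses MDAnalysis' grid-based `capped_distance`; the test suite holds it
to exact agreement with an O(N²) double loop on randomized boxes where the
minimum image matters. A cutoff exceeding half the smallest box edge is
refused. Counts pool over solute copies by default (per-copy rows available).
Head/tail aggregation uses an editable per-species YAML table of atom names;
unassigned names raise, listing them. Colour-map binning sends count c to
floor(c/c_max·(n_bins−1)) with n_bins = 200.

## Synthetic trajectories and the analytic oracle

The Langevin generator integrates the overdamped equation
η ← η − (D/k_BT) G′(η) dt + √(2 D dt) ξ (Euler–Maruyama) for non-interacting
particles on a prescribed landscape inside a periodic box (default geometry
mirrors the study conditions: 5×5×12 nm³ box, 8 solute copies per replica,
440 K, five replicas). D is spatially constant — position-dependent D would
require a spurious-drift correction and the oracle only needs constant-D
cases. Forces are evaluated at the wrapped position; the returned track is
unwrapped. A run refuses to start if the per-step drift displacement
(D/k_BT)·max|G′|·dt exceeds the analysis bin scale (0.1 nm); in practice
dt ≪ min(σ)²/D. Square-barrier landscapes are non-differentiable and are
rejected by the integrator (they remain available to the quadrature oracle).

The oracle is the inhomogeneous solubility–diffusion closed form
P = [∫ exp(G/k_BT)/D dη]⁻¹ over the membrane slab, with G referenced to 0 in
bulk; on a flat landscape it reduces to D/L (0.125 nm/ns = 12.5 cm/s for
D = 0.5 nm²/ns over 4 nm). For piecewise-constant barriers the integral is
done exactly; otherwise by adaptive quadrature.

Two details matter when comparing the counting estimator to the oracle:

* the analytic slab must span the dissociation thresholds (plane ± margin),
  since that is the region a counted event traverses;
* counts are taken from the trajectory at a finite sampling interval
  dt_s. Brief sub-sample excursions past a threshold are invisible, which
  depresses counts roughly as if each threshold moved outward by
  ~0.58·√(2 D dt_s) (the standard discrete-monitoring barrier shift). The
  validation stride keeps that shift to ~1–2% of the slab width, well inside
  the statistical band. Real MD analyses at coarse frame strides inherit the
  same effect.

The standard error used in the 3-SE comparisons is the larger of the
replica-SEM and the Poisson error from the total event count; at five
replicas the sample SD itself is noisy and the event count is the more stable
scale estimate.

Equilibrium correctness of the integrator is checked by a χ² test on ≥10⁶
*independent* particles initialized from the exact Boltzmann sampler
(inverse-transform on a dense quadrature grid) and evolved for many steps:
the stationary measure must be preserved. Raw time series are autocorrelated
(slowest mode τ = L²/π²D ≈ 29 ns for the default box), so a multinomial χ²
on pooled time samples would spuriously reject; time-series uniformity is
instead tested with an effective sample size set by τ, and the kinetics are
validated end-to-end against the analytic permeability.

## Toy membranes and packaged tables

The toy membrane builder places pseudo-lipids (phosphate reference atom at
± half-thickness, interfacial and tail pseudo-atoms toward the midplane) on a
per-leaflet grid in the published BBB model composition (8 species; CHOL
29.3%, OSM 18.9%, SAPE 14.5%, …), plus solute copies at configurable depths,
and writes GRO/PDB topologies and XTC/DCD trajectories. Published mole
percentages are converted to integer per-leaflet counts by normalized
largest-remainder apportionment (quotas p_i/Σp·n, floors, leftovers to the
largest fractional remainders): deterministic and sum-preserving — the listed
percentages sum to 91.7, so normalization is required before rounding. The
builder refuses boxes denser than 100 atoms/nm³.

Packaged CSV tables carry the published per-molecule permeabilities,
literature candidates, and barrier metrics for the reporting stage. The
literature comparison picks the candidate nearest to P_eff and reports
|P_eff − P_lit|/P_lit; an empty candidate list yields a "no literature value"
row rather than an error.

## Temperature extrapolation

Ordinary least squares of ln P on 1/T, evaluated at the target temperature
(default 310 K). The Arrhenius axes are the standard physical reading of a
"least squares linear fit" for rate-like quantities; a plain P-vs-T fit can be
run for sensitivity checks. With two points the fit interpolates exactly.
Uncertainty on the extrapolated value is first-order delta method on the fit
covariance (three or more points). The multi-temperature inputs needed to
validate a specific published 440 K → 310 K extrapolation are not available
at desk scale, so this stage is validated mechanically (closed form,
collinearity, endpoint bounds).

## Geometry conventions

The membrane normal is the box z axis (planar patch; no instantaneous-surface
fitting). Leaflet planes are per-leaflet mean phosphate positions; the
midplane is their mean. Leaflet assignment is by sign of the normal coordinate
relative to the lipid median, sticky with a ±0.5 nm hysteresis band so
lipids fluttering at the midplane do not flip-flop. Solute tracking defaults
to centre of mass (single-atom tracking available); the tracking point and
trajectory stride are config knobs because published analyses rarely state
them. Coordinates are converted to nm and times to ns at the reader boundary
(MDAnalysis natively uses Å and ps); source files are single precision, which
bounds round-trip agreement at ~10⁻⁵ nm.

## Problem sizes used in the default validation

Langevin-vs-analytic comparisons run five replicas of eight particles for
400/800/1600 ns (barrier heights 0/1/2 kcal/mol), giving ~300 events per
case; parameter recovery uses 10⁶ Boltzmann samples; oracle-equivalence
checks use 20 randomized fixtures each. These sizes give 3-SE bands of
~15% on permeability and ~0.01 kcal/mol precision on recovered barriers.

## What passing tests do not show

The generator is a 1-D overdamped model: solutes do not interact with each
other or reshape the membrane, diffusivity has no position dependence, the
landscape is static and the membrane perfectly planar, and there is no
solvent or electrostatics. Passing validation therefore demonstrates that the
*estimators* (event counting, rate/steady-state logic, density inversion,
fitting, contact counting) are correct, not that any particular all-atom
force field or elevated-temperature protocol reproduces experimental
permeabilities. Known method limitations carry over: molecules that cross by
non-passive mechanisms show no steady state; very fast permeants can
oversample the counting assumptions; and ΔG‡ alone does not predict P when
barrier width or interfacial retention dominates.
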