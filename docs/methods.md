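# Methods

This note records the models, parameter choices and known limitations of
the package, in the spirit of a simulation package's model documentation.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Species mass model

The reference state is the neutral, fully reduced, fully protonated
protein: the sum of residue compositions plus one water (residue formulas
from pyteomics). Adduct bookkeeping is then purely integer arithmetic on
the hydrogen count:

* **Zn²⁺ binding**: −2 H per metal. The "fully displaced" reference
  assumes every Zn²⁺ replaces two thiol protons; *proton retention* —
  protons that remain in the cluster despite metal binding — is modelled
  as a single integer +H offset for the whole ion, because per-site
  retention is not resolvable from an envelope position.
* **Disulfides**: −2 H each (0–10 scanned).
* **Charging**: +1 H and +1 charge per proton; a Na⁺ carrier swaps one H
  for Na. m/z is computed as (composition mass)/z; the electron mass
  (~0.0001 m/z at z = 5) is neglected.

**Degeneracy.** A disulfide is −2 H and a retained proton +1 H, so
(n_ss, offset) and (n_ss + 1, offset + 2) produce identical masses. The
grid fit is therefore only fully identifiable when the offset range is
restricted to {0, 1} (parity separates the candidates); wider grids are
resolved by a documented tie-break toward fewer disulfides. The default
fit scans offsets {0}.

**Isotope patterns** are computed per element by
exponentiation-by-squaring convolution of the single-atom
natural-abundance distribution, then convolved across elements. Peaks
below an absolute probability threshold (default 1e-5, internal pruning
100× finer) are dropped and peaks closer than 1 mDa are centroided
together; for the ~6.5 kDa Zn₇ ion this yields ~70 centroids. The
implementation is validated against brute-force isotopologue enumeration
for ≤10-atom compositions to 1e-9.

**Rendering and fitting.** Each isotope peak becomes a Gaussian of FWHM
(m/z)/R (resolving power R, default 10,000); species envelopes superpose
linearly. The fit metric is the residual sum of squares on the observed
grid after optimal linear scaling — the simplest metric consistent with
least-squares envelope matching; no baseline or peak-shape model beyond
the Gaussian is attempted (Lorentzian/pseudo-Voigt out of scope).

## Ion mobility

**TW calibration** uses the standard power-law protocol: corrected drift
time t′ = t − c·√(m/z) (enhanced-duty-cycle coefficient c = 1.41 ms/√Th
by default), corrected Ω′ = Ω·√μ/z with μ the ion–buffer reduced mass,
and a log–log least-squares fit Ω′ = A·t′^B. N₂ buffer gas is the
default (He selectable); a calibration is *accepted* only at R² ≥ 0.98.
ATD → CCS-distribution transforms carry the |dt/dΩ| Jacobian so unit area
is preserved; points outside the calibrant time span are flagged as
extrapolation.

**CIU₅₀.** The fingerprint's intensity-weighted CCS centroid per energy
column is fitted with a sum of (n_states − 1) logistic steps between
fitted plateau CCS levels — the functional form popularized by CIU
analysis suites. Initialization: midpoints at the steepest-gradient
energies, plateaus at the first/last column centroids, widths at 1/20 of
the energy span; midpoints are bounded by the span and transitions within
2% of an edge are flagged. On the default conditions (50–150 eV in 2.5 eV
steps, two Gaussian states at 1000/1150 Å² of width 25 Å², intensity
noise sd 0.02) the estimator's bias is below 1 eV and its spread below
3 eV over 200 replicates (tested).

**Conformer detection** smooths the CCS density with a Gaussian kernel
(default bandwidth 0.5% of the CCS span — wide enough to suppress
single-bin intensity noise, an order of magnitude narrower than real
conformer peaks), picks peaks above a 5% prominence threshold (chosen so
minor extended families at ~5% weight survive), and refines
centroid/width/weight by least-squares Gaussian-mixture fitting. Labels
α, β, γ, … are assigned by ascending CCS. KDE of CCS samples uses
Silverman bandwidth unless overridden; the bandwidth is echoed in the
output metadata.

**Gating** zeroes density outside a CCS/time window and renormalizes —
the selection step of multistage cyclic-IM workflows. The
interconversion metric reports the fraction of post-activation density in
a compact region; ≤ε (default 0.05) supports an "irreversible" verdict.

## Projection-approximation CCS

For each uniformly random orientation (seeded), the shadow area of the
union of disks (bead radius + probe radius) is estimated by Monte-Carlo
rejection sampling in the projected bounding box; the CCS is the mean
over orientations with its standard error. Defaults: 32 orientations ×
4000 points; residue beads 3.8 Å, Zn 1.4 Å, probe 1.0 Å (He-like; N₂
preset 1.82 Å). PA systematically underestimates the CCS of concave
shapes relative to trajectory-style methods, and one-bead-per-residue
spheres underestimate the envelope of an all-atom surface, so absolute
values from the CG engine sit well below calibrated experimental CCS; a
global scale factor (default 1.0) is exposed, and all engine-level
claims are relative (orderings, spreads, correlations), never absolute.

## Coarse-grained unfolding engine

The engine is a deliberately minimal emulator of gas-phase unfolding,
not a replacement for atomistic force fields; its acceptance surface is
qualitative orderings plus its own analytic oracles.

**Model.** One bead per residue (average residue masses) plus one bead
per Zn²⁺. Terms: harmonic bonds (k = 100 kcal mol⁻¹ Å⁻², native
lengths), harmonic angles (k = 10 kcal mol⁻¹ rad⁻², native angles), 12-6
native contacts (ε = 1 kcal/mol at the native distance, pairs ≥3 apart
in sequence within 8 Å, partitioned into intra-α/intra-β/inter-domain),
WCA excluded volume (σ = 3.8 Å residues, 2.0 Å Zn), in-vacuo Coulomb
(332.0637 kcal Å mol⁻¹ e⁻², dielectric 1), and harmonic Zn–S cross-links
(k = 50 kcal mol⁻¹ Å⁻², r₀ = 2.3 Å, exactly 4 per metal from the cluster
map). Links strain but never break: bond rupture is out of scope and
shows up as strain energy. The z charging protons are placed as unit
charges on the z most peripheral basic residues (uniform smearing would
be an alternative; the heuristic is documented, not load-bearing).

**Integration.** BAOAB-discretized Langevin dynamics in AKMA-style units
(kcal/mol, Å, amu; time unit 48.8882 fs). Defaults: 10 fs timestep,
friction 1 ps⁻¹. With zero friction the scheme reduces to velocity
Verlet, which the energy-conservation check exploits (drift <0.1% over
10⁴ steps at 2 fs). Kinetic energy satisfies equipartition at 300 K
within 5%. Every protocol is deterministic under its seed.

**Collective variables.** Rg is mass-weighted over protein beads only
(metals excluded); end-to-end is the first/last backbone bead distance; a
bead-coordinate CV exists for 1-D oracle systems.

**Steered MD** applies a moving harmonic restraint k(CV − target(t))²/2
with k given in kcal mol⁻¹ nm⁻² (presets 10/25/50) and a linear target
schedule; the signed restraint force (reported in pN), the work integral
∫F dCV, and per-replicate peak forces (default 25 replicates) are the
read-outs. Desk-scale pulls (10⁴–10⁵ steps ≈ 0.1–1 ns) strain rather
than fully unravel the Zn-loaded species — consistent with the model's
point that the Zn–S network and interdomain contacts resist extension —
so force summaries, not end-state structures, carry the comparisons.

**Well-tempered metadynamics** deposits Gaussian hills (default height
0.2 kcal/mol, width 0.25 CV units, every 200 steps) with height scaled by
exp(−V/((γ−1)k_BT)), γ = 8. The free energy is −γ/(γ−1)·V_bias; the
reported estimate is time-averaged over the second half of the deposition
history, which suppresses hill noise. Convergence is diagnosed from
hill-height decay (last tenth below half the initial height). On the
analytic double well V(x) = h((x²−a²)/a²)² the estimator recovers the
closed-form barrier h within 10%.

## Synthetic data: what it does and does not emulate

The generators provide controlled ground truth, not instrument realism:

* **Spectra** are linear superpositions of rendered envelopes plus
  additive truncated-Gaussian intensity noise. No baseline drift,
  detector saturation, space-charge effects or adduct tailing.
* **Fingerprints** use a sequential logistic hand-off between Gaussian
  CCS states — the conventional CIU picture; simultaneous multi-state
  mixing and energy-dependent peak widths are not modelled.
* **Structures**: each domain is grown as a compact confined random walk
  (bond 3.8 Å), metals start at their cysteines' centroid, and an energy
  minimization with chain bonds, Zn–S harmonics, excluded volume and
  weak domain-centre tethers settles Zn–S edges near 2.3 Å. Domain
  centres 20 Å apart with 9.5 Å confinement radii give the Zn₇ fixture
  an Rg of ~11 Å (compact, dumbbell-shaped). The specific Cys→metal
  wiring is a documented, fixed placeholder (β = N-terminal 9 Cys, α =
  C-terminal 11, each metal taking four consecutive thiolates with
  wrap-around sharing), because the per-species wiring is not
  experimentally resolved; maps are JSON files and overridable.

Passing tests therefore demonstrate that the *analysis* layer recovers
known ground truth under the stated noise model — they do not certify
performance on real instrument data with structured noise.

## Numerical choices

* Pair distances are clamped at 0.05 Å so overlapping beads give large
  finite energies, never NaN; angle norms are clamped identically.
* The CIU₅₀ optimizer is `scipy.optimize.curve_fit` with bounds;
  non-convergence returns the initial guess flagged, never raises.
* Grid-search ties in the species fit break toward fewer disulfides,
  then smaller retention offset (reported via the full residual table).
* Structure generation retries up to 5 perturbed seeds if relaxation
  leaves non-bonded beads closer than 2 Å (reported as a warning).
* Thermal/SMD problem sizes in the shipped drivers and tests (6000 steps
  per temperature rung, 3–25 replicates × 4000 steps, CCS at 8–12
  orientations × 1000–1500 points per stored frame) were chosen as the
  smallest budgets at which the qualitative orderings are stable across
  seeds.

## Known limitations

* No charge-state deconvolution of overlapping proteoforms; one species
  family per fit window.
* The cyclic-IM emulation reproduces selection outcomes (gating +
  renormalization), not multipass path-length physics.
* No explicit-solvent desolvation, Na⁺ ejection dynamics, mobile-proton
  chemistry, or covalent rupture in the CG engine.
* Absolute CG CCS values are systematically low (see above); only
  relative statements are meaningful.
* Hydrogen bonds are undefined on CG beads (the API refuses rather than
  guesses); without explicit hydrogens the all-atom criterion degrades to
  distance-only and says so.
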