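# Methods

`chirospec` quantifies site-specific stereoselectivity in the conjugation of
a tris-chelate Ru(II) polypyridyl photosensitizer to a multiheme cytochrome,
from circular-dichroism (CD) spectra, and summarizes the molecular-dynamics
contact geometry used to rationalize that selectivity.  This note records
the models, conventions and numerical choices behind each stage.

## Spectrum model and arithmetic

A spectrum is a strictly ascending wavelength grid (nm) with one value per
point and one of four unit tags: observed ellipticity (millidegrees), molar
ellipticity, mean residue ellipticity (both deg cm² dmol⁻¹) and molar
circular dichroism Δε (M⁻¹ cm⁻¹).  Instrument exports often arrive in
descending scan order; readers normalize to ascending order on input.
Arithmetic (averaging repeated scans, background subtraction, difference
spectra) is defined only between spectra with identical unit tags and grids
(absolute grid tolerance 1e−9 nm); resampling is a separate, explicit linear
interpolation step that refuses extrapolation.  No smoothing is applied
anywhere.  Scan averaging sorts the per-wavelength values before summation
so the mean is exactly permutation-invariant despite floating-point
non-associativity.

## Calibration conventions

The observed ellipticity θ (mdeg) converts to molar ellipticity as

    [Θ]_M = 100 · θ(deg) / (c · l) = θ(mdeg) / (10 · c · l),

with c the protein concentration in mol/L and l the pathlength in cm; the
mean-residue flavor divides by the number of peptide bonds N, and
Δε = [Θ]/3298.  The published form of the molar-ellipticity equation is
dimensionally ambiguous about the concentration unit (mM vs M); the
convention above is the standard spectroscopic one and reproduces the
observed magnitude range (~10⁴ deg cm² dmol⁻¹ for a 70-bond protein at
~20 µM in a 0.1 cm cuvette).  Concentrations are carried in mol/L
throughout; mM and µM exist only at the I/O boundary.  The 3298 divisor is
treated as exact.  Whether the mean-residue normalization should use 71
residues or 70 peptide bonds is not decidable from the source data, so N is
always an explicit input.

Cytochrome concentration is quantified from the heme Soret band with
ε₄₀₆ = 332.9 mM⁻¹cm⁻¹, and labeling stoichiometry from elemental Ru and Fe
content assuming 3 heme irons per protein.  All constants live in an
immutable `ExtinctionConstants` configuration object with these defaults.

## Helicity indices

Far-UV spectra of helical polypeptides show a positive band near 190 nm and
negative bands near 204–208 and 222 nm.  The indices

    R1 = |[Θ]_max / [Θ]_min|,   R2 = |[Θ]_222 / [Θ]_min|

are scale-invariant probes of helical content (R1) and helix type (R2 below
~0.9 suggests 3₁₀-helix admixture).  Extrema are located by exhaustive scan
inside configurable windows, default 188–196 nm (positive) and 200–212 nm
(negative) — wide enough to bracket both the 204 nm minimum seen in this
protein family and the canonical 208 nm α-helix position — with the 222 nm
value read from the nearest grid point.  An extremum on a window edge is
flagged, not silently accepted.  Indices are reported as absolute ratios;
table presentation rounds half-away-from-zero to 2 decimals.

## Enantiomer assignment and the ee calculus

The bound chromophore's near-UV ligand-centered band shows a bisignate
exciton couplet whose sign order encodes the propeller handedness: a
positive-to-negative sequence with decreasing wavelength for one chirality
and the inverse for the other.  The sign convention is anchored to the
enantiopure Λ reference complex, Δε₂₉₅ = +114 M⁻¹cm⁻¹: positive Δε at
295 nm ⇒ Λ-enriched.

The host-protein contribution is removed by subtracting the parent-mutant
spectrum from the conjugate spectrum and dividing the residual by the
Ru:protein labeling ratio.  Subtract-then-scale is the adopted order (the
host contributes at full stoichiometry regardless of labeling); the two
orders coincide at a labeling ratio of 1.

From the normalized Δε at 295 nm the signed optical purity is
op = Δε₂₉₅/Δε_max, numerically equal to the enantiomeric excess, and the
mole fractions solve E_Λ − E_Δ = op, E_Λ + E_Δ = 1:

    E_Λ = (1 + op)/2,  E_Δ = (1 − op)/2,
    er = E_major/E_minor,  Δ/Λ = E_Δ/E_Λ.

Numerical choices: |op| up to 2% above 1 is clipped to ±1 with a warning
(noise can push the measured amplitude marginally past the enantiopure
reference); beyond that it is an error.  |Δε| below 1 M⁻¹cm⁻¹ (configurable)
is reported as racemic — below plausible instrument noise at the working
concentrations.  The reference wavelength defaults to 295 nm and is read
from the nearest grid point, with linear interpolation off-grid.  All
quantities are kept unrounded internally; the report layer rounds fractions
and ratios to 3 decimals and ee% to 1 decimal, and recomputes the printed
Δ/Λ ratio from the rounded fractions, which is how such tables are
conventionally typeset.  The enantiomeric ratio er is always computed
directly from the unrounded fractions.

Two estimators of the couplet amplitude are provided.  The point estimator
(the Δε value at the reference wavelength) is the conventional reporting
path.  When the couplet band shape is known — synthetic data, or a measured
enantiopure reference spectrum — `estimate_op` instead takes the ordinary
least-squares coefficient of the difference spectrum on the unit-purity Λ
couplet over the whole near-UV grid.  This is unbiased under additive
zero-mean noise and shrinks the op standard error from roughly
noise_sd·√2/(label_ratio·114) (≈0.03 at 2 M⁻¹cm⁻¹ noise and 0.82 labeling)
to well under 0.01, which is what makes reliable recovery possible at
realistic noise.

A mass-balance check covers the complementary observation on the unreacted
chromophore: starting from a racemic labeling pool,
bound·op_bound + free·op_free = 0, so the recovered free fraction must be
enriched in the opposite enantiomer whenever the conjugate is enriched at
all.

## Contact-distance statistic

For each trajectory frame the statistic is the exact minimum Euclidean
distance over all cross pairs between two atom selections (chromophore
ligand atoms × heme/protein atoms), with the realizing pair recorded.
Selections are explicit atom-id lists — aromaticity is a selection input,
not something the package perceives — and hydrogens are excluded by element
symbol, falling back to the atom-name leading character when no element
column exists.  Summary statistics use the sample (n−1) standard deviation,
treating frames as a sample of the equilibrium ensemble; an optional
frame-skip discards an equilibration prefix.  A threshold split partitions
frames into proximal/distal conformers (strictly-below goes proximal) with
per-subset mean, SD and occupancy; a threshold outside the observed range
flags an empty subset rather than erroring.  Coordinates are assumed
pre-imaged and whole (no periodic-boundary handling) — a documented
limitation.  Multi-MODEL PDB and concatenated-XYZ I/O goes through
MDAnalysis; PDB coordinates carry 0.001 Å format precision.

## Synthetic data: what it emulates and what it does not

The spectrum generator produces conjugate/parent pairs as

    conjugate = host + label_ratio · (E_Λ − E_Δ) · couplet_Λ + noise,
    parent    = host + independent noise,

with Gaussian couplet lobes (+295 nm, −270 nm, σ = 10 nm, amplitude 114
M⁻¹cm⁻¹ for unit purity — the Δ couplet is the exact negation), a broad
host shoulder (Gaussian at 285 nm, σ = 25 nm, 10% of the couplet amplitude)
standing in for aromatic/heme near-UV background, and i.i.d. Gaussian noise
per grid point.  Default study conditions for recovery experiments: 1 nm
grid over 240–330 nm, noise 2 M⁻¹cm⁻¹, labeling ratios {0.82, 0.93, 1.0} —
the stoichiometries measured for the three conjugates.  Real couplets have
vibronic structure and the real host baseline is not Gaussian; only sign,
amplitude and linear mixing matter to the analysis under test, so passing
recovery tests demonstrates correctness of the arithmetic and estimator
under the stated noise model, not instrument-grade robustness.

The reaction-pair generator enforces chiral conservation from a racemic
pool at a given molar excess (default twofold, the synthesis condition),
erroring on infeasible compositions.  The trajectory generator prescribes
the per-frame minimum distance exactly by construction (one contact atom
per set at the drawn separation, all spectator atoms strictly farther from
the opposing set), drawing separations from a normal — optionally a
two-component mixture for conformer-split testing — truncated at 0.1 Å,
with frames 10 ps apart.  It emulates the statistic's distribution, not
molecular mechanics.

Published trajectory means (6.03 ± 0.77 Å and the like) require the
original 300–400 ns production runs and are not reproducible from synthetic
data; the package's guarantee for this stage is exact agreement with
brute-force all-pairs computation and rigid-motion invariance.

## Pipeline determinism and problem sizes

The pipeline runs from a single YAML configuration; outputs depend only on
the config and referenced files, so reruns are byte-identical.  The run log
echoes every constant and names the formula behind each reported column.
All randomness in generators flows from one explicit integer seed per call.

Test and acceptance problem sizes: 450 synthetic recovery runs (30 seeds ×
5 op values × 3 labeling ratios) on a 91-point grid; 201-point op grid for
the fraction-formula equivalence; 50 random 20×20-atom frames for the
distance oracle; 500–1000-frame synthetic trajectories for mean and
occupancy recovery — sizes at which the sampling-theory tolerances used in
the assertions are comfortably discriminating.

## Known limitations

- No baseline-drift correction, smoothing or spectral deconvolution into
  secondary-structure basis sets; R1/R2 are ratio indices, not fractional
  helicity estimates.
- The racemic threshold and the 2% |op| overshoot tolerance are heuristics
  tied to typical instrument noise, not fitted quantities.
- Trajectory analysis assumes constant atom identity across frames, no
  periodic imaging, and user-correct atom selections.
- The couplet least-squares estimator assumes the reference band shape is
  correct; a mis-specified shape biases the recovered amplitude.
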