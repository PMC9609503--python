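# Methods

This note documents the models, numerical choices and limitations behind
`ramagg`.  It is written for users who need to judge what the pipeline's
outputs mean and what its validation on synthetic data does and does not
demonstrate.

## Spectral model

All bands are area-normalised Lorentzians,
L(ν̃; ν̃₀, γ, A) = (A/π)·γ/((ν̃−ν̃₀)² + γ²), so that the fitted parameter A
is the analytic band area, 2γ the FWHM and A/(πγ) the height.  This
parametrisation makes the area→fraction arithmetic of the Amide I analysis
exact: no numerical integration is involved, and truncating the fit window
does not truncate the area.

The default wavenumber grid is 300–1800 cm⁻¹ at 1 cm⁻¹ spacing, the working
range of dispersive protein Raman measurements.  Intensities are expressed
in units of the phenylalanine 1004 cm⁻¹ band height ("anchor units") after
normalisation.

## Preprocessing

Order is fixed: spike removal → baseline subtraction → normalisation, and
the two flags (`baseline_removed`, `normalized`) are carried in the
spectrum metadata.

**Spike removal.**  Cosmic-ray spikes are single-pixel events.  A point is
flagged when its excursion above the mean of its two neighbours exceeds
(a) 8 robust standard deviations (1.4826·MAD) of that second-difference
statistic and (b) 10 % of the global intensity maximum.  Both gates are
needed: (a) alone mislabels genuine narrow bands on noiseless data, because
with zero noise any curvature is "infinitely significant"; (b) alone would
miss small spikes in noisy data.  With both, a Lorentzian of FWHM ≥ 8 cm⁻¹
sampled at 1 cm⁻¹ has a relative excursion ≤ 1/17 ≈ 6 % and is never
touched, while spikes ≥ 20× the noise floor and a sizeable fraction of the
signal are always caught.  Flagged points are replaced by linear
interpolation of their unflagged neighbours.

**Baseline.**  The default method mimics a user-drawn baseline: linear
interpolation through the spectrum's value at 18 anchor wavenumbers chosen
in the flat inter-band regions of the HEWL spectrum.  Each node value is
averaged over ±3 cm⁻¹ (kept symmetric at the axis edges); without this,
single-pixel noise at each anchor propagates a random offset under every
band, roughly doubling the uncertainty of the Amide I fractions at 2 %
noise.  An asymmetric-least-squares baseline (Eilers smoother, λ = 1e5,
p = 0.01, 10 iterations) is available for curved backgrounds; it is
implemented in-package with scipy.sparse because no installed library
provides it.

**Normalisation.**  The spectrum is divided by the *fitted* height of the
1004 cm⁻¹ band (single Lorentzian + constant offset inside ±8 cm⁻¹), not the
raw maximum, which makes the divisor robust to noise; a raw-max mode exists
as a config option.  The band must reach at least 0.1 % of the global
maximum, else a normalisation error is raised.  Re-normalising an
already-normalised spectrum is a no-op, making the operation exactly
idempotent.  All downstream ratio- and fraction-type observables are
invariant to the absolute scale by construction.

## Amide I deconvolution

Exactly four components are fitted on 1600–1720 cm⁻¹, initialised at the
canonical positions 1647 (random coil), 1657 (α-helix), 1671 (β-sheet) and
1688 cm⁻¹ (β-turn), plus a linear background term that absorbs the small
pedestal the anchor baseline leaves under the band (distant Lorentzian
tails are locally almost linear).  Components are labelled by their
initialisation centre, so the adjacent β-sheet and β-turn components can
never exchange identities during fitting.  Secondary-structure percentages
are 100·A_c/ΣA_c and always sum to 100.

**Why the component shapes are pinned.**  The four constituents lie 10–17
cm⁻¹ apart with ~20 cm⁻¹ FWHM: they overlap heavily.  If centres (±5 cm⁻¹)
and widths (8–40 cm⁻¹) are left free, the area estimates become
non-identifiable — at 2 % intensity noise the recovered fractions scatter
by 7–15 pp (median of the worst component, 50 seeded replicates), because
width, centre and background trade off against area along near-flat valleys
of the cost surface.  With centres and widths pinned at their canonical
values the problem is linear in the areas, is solved by bounded linear
least squares (areas ≥ 0), and reaches the theoretical noise floor
(≈ 0.7 pp s.d. at 2 % noise; worst observed error 2.8 pp over 50
replicates).  Pinning component shapes in a fixed-component-count
deconvolution is standard practice in protein Amide I analysis; both knobs
(`center_drift`, `fwhm_bounds`) remain keyword arguments for exploratory
use, and the general-purpose `fit_lorentzians` keeps free shapes with the
loose bounds.

The Amide III analysis (1200–1310 cm⁻¹, components at 1240 and 1280 cm⁻¹,
constant background) reports the fitted height of the 1280 cm⁻¹ component
as an independent α-helix tracker.  On pipeline-preprocessed spectra this
indicator carries a small (~2–3 %) systematic underestimate because the
1315 cm⁻¹ baseline anchor sits on the 1280/1341 band tails; it is used as a
*relative* time-course marker, for which a constant bias is irrelevant.

## Markers

Each marker is read off a regional multi-Lorentzian fit with a constant
background; overlapping bands (830/850 Fermi doublet, 900/932 skeletal
pair, 1341/1363 Trp doublet) are always fitted jointly, since independent
fits would bias heights and positions.  "Intensity" means fitted height
throughout (switchable to area).  Per-point uncertainties come from the
Gauss–Newton covariance of the fit; failed or non-converged fits and dead
(all-zero) spectra yield missing values, never imputed ones.  Series with
fewer than 3 valid points are flagged unusable for kinetics.

## Kinetics

Marker series are fitted with the 4-parameter logistic
y(t) = y₀ + (y_max−y₀)/(1+exp(−k(t−t₅₀))) by weighted least squares.
Multi-start over t₅₀ ∈ {observed time points} × k ∈ {0.05, 0.5} h⁻¹ avoids
local minima without randomness.  The plateaus are bounded within the data
range ± 2× its span: without this the optimizer can escape onto the
degenerate ridge of huge amplitude and vanishing slope that mimics any
monotone curve.  A fit is "converged" only when the optimizer succeeded
*and* the fitted amplitude exceeds 3× the residual RMS — flat series
deliberately return non-converged with direction "none".

Lag time is the conventional tangent construction: the maximum-slope
tangent intersects the initial plateau at t₅₀ − 2/k, floored at 0.  The
classification threshold defaults to 2 h, the smallest gap in the default
sampling grid (0, 0.5, 1, 3, 6, 12, 24, 48, 72, 96, 120, 240 h): a lag
shorter than the sampling resolution is not a "distinct" lag.  The median
lag across converged marker fits decides: > 2 h → amyloid_like, otherwise
amorphous_like; no converged fits → indeterminate.

## Structure analyses

PDB text is parsed with gemmi (multi-MODEL → trajectory; waters and hetero
groups excluded by default; elements inferred from atom names when the
element column is absent).  Writing uses an in-package fixed-column writer
(1e-3 Å precision, the PDB format limit).

* **RMSD** — selections (default backbone N/CA/C/O) are centred and the
  optimal rotation obtained from `scipy.spatial.transform.Rotation
  .align_vectors` (Kabsch); the result is symmetric and rigid-transform
  invariant to ≤ 1e-6 Å.
* **COM distance** — mass-weighted by default; atomic masses from a small
  element table.
* **Cys–Cys maps** — SG atoms (CB fallback), full rectangular inter-chain
  matrix plus the minimum pair; disulphides are called at SG–SG ≤ 2.5 Å.
* **Secondary structure** — φ/ψ windows (α: φ∈[−100°,−30°] ∧ ψ∈[−67°,−7°];
  β: φ∈[−180°,−70°] ∧ ψ∈[80°,180°]∪[−180°,−170°]); runs shorter than 3
  residues demote to "other"; percentages are over residues with computable
  φ and ψ and sum to 100.  A dihedral-window scheme was chosen over
  H-bond-pattern (DSSP-style) assignment because it needs no hydrogen
  placement and is self-contained; it will disagree with DSSP near helix
  termini and in distorted strands.
* **Non-bonded contacts** — geometric criteria with common structure-viewer
  defaults: H-bond donor–acceptor ≤ 3.5 Å (D–H···A angle ≥ 120° when
  hydrogens exist, distance-only otherwise), salt bridge (Lys/Arg N⁺ to
  Asp/Glu carboxylate O) ≤ 4.0 Å, π–cation ≤ 6.0 Å and π–π ≤ 5.5 Å on ring
  centroids.  A pair that qualifies as a salt bridge is *not* double-counted
  as a hydrogen bond (kind precedence), so per-kind counts are disjoint.
  His counts as cationic only when flagged (appropriate near neutral pH;
  excluded by default for the alkaline context).  All cutoffs are
  configurable.

## Synthetic data: what it emulates, and what it does not

The generator encodes the study conditions: spectra are sums of library
bands on a polynomial baseline with additive Gaussian noise and optional
single-pixel spikes (≥ 20× noise, plus most of the signal maximum, so they
are unambiguous).  Amide I component areas are set proportional to the
ground-truth percentages (total area 50 anchor-units·cm⁻¹, giving realistic
band heights of 0.16–0.8 relative to phenylalanine).  Time courses
interpolate between the folded state (α/β/turn/coil = 50/23/17/10 %) and
the aggregated end state (20/45/20/15 %; the turn/coil end values are a
package choice — only α and β endpoints are externally fixed — taken so
the four fractions sum to 100 with a mild rise in both).  Marker
trajectories follow the observed phenomenology: 505 cm⁻¹ height → 5 % of
start, 759 cm⁻¹ FWHM 9 → 12 cm⁻¹, 830 cm⁻¹ position 834.5 → 829.7 cm⁻¹,
932 cm⁻¹ and 1280 cm⁻¹ heights falling, 1341/1363 ratio decaying from ≈1.3,
1446 cm⁻¹ broadening.  Three regimes: `static` (control, constant),
`isodesmic` (exponential saturation 1−e^(−kt), immediate change, no lag;
default rate 0.02 h⁻¹ so the transition completes within the 240 h window),
`nucleated` (logistic with default t₅₀ = 48 h, k = 0.5 h⁻¹, lag ≈ 44 h).

Toy structures are ideal-geometry peptides grown by NeRF placement at
caller-chosen φ/ψ; side chains carry only the functional atoms the
analyses need, in an extended rotamer.  Dimer trajectories translate a
rigid copy of the chain so the inter-chain COM distance interpolates
exactly between the requested endpoints; planted contacts are constructed
on short "stalks" in the inter-chain gap and satisfy the detection criteria
exactly in the final frame (a fixed-point iteration reconciles the planted
atoms with the COM placement to < 1e-12 Å).  The 129-residue lysozyme-like
monomer with cysteines at positions 6/30/64/76/80/94/115/127 and the four
native disulphide pairs is *synthetic* — ideal extended geometry, not
crystallographic coordinates.

What passing on synthetic data does **not** show: real spectra have
correlated (non-white) noise, fluorescence backgrounds far rougher than low
order polynomials, band shapes with Gaussian character (Voigt profiles),
and component positions that genuinely drift with environment; real
trajectories have internal motions the rigid-body generator lacks.  The
validation demonstrates correctness of the estimators under the stated
model, not robustness to every instrumental artefact.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.default_rng`; spectra within a time course draw per-point
child seeds from the course seed.  Identical config + seed reproduce
byte-identical pipeline outputs (no timestamps are written; every output
header carries the config hash).  The validation suite uses 50-replicate
noise studies for the deconvolution, 40 synthetic courses (20 per regime,
12 time points each) for the kinetics classification, and small (24–129
residue) toy structures for the geometry — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping the statistical
comparisons meaningful.
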