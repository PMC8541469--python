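# Methods

This note records the models, parameter choices and numerical decisions
behind `petew`, and what the bundled simulator does and does not capture.

## Scanner model

A single ring of `n_blocks = 20` flat monolithic blocks
(50 × 50 × 20 mm) arranged as a regular polygon around the z axis.  The
apothem (axis → inner face) defaults to 165 mm: a 20-gon of 50 mm faces
closes at ≈ 157.8 mm, which is inconsistent with the 330 mm transaxial
field of view the design targets, so the transaxial FOV is treated as the
operative quantity and the apothem is configurable (165 mm implies ~1.8 mm
inter-block gaps).  Axial FOV 60 mm; energy resolution 10% FWHM at
511 keV, scaled as `FWHM(E) = 0.10·511·sqrt(E/511)` keV (Poisson
photostatistics); hardware acceptance window 350–650 keV applied to each
photon.  Coincidences are accepted between blocks whose circular
separation is at least 5 (of 20) — closer pairs cannot see the transaxial
FOV.  Block faces are virtual-pixellated at a configurable pitch
(1.4–2 mm for estimation; half-open `[lower, upper)` intervals, 0-based,
`u` transaxial, `v` axial).  Depth of interaction is carried in the data
model; the default binning ignores it, an option folds it into the LOR
endpoints.

## Photon transport

Per decay, a back-to-back photon pair is emitted isotropically from the
sampled annihilation point.  Positron range and acollinearity are ignored
(sub-millimetre at this geometry, below the 1.4–2 mm pixel scale).
Photons are tracked through a phantom of axis-aligned water/air cylinders
(later cylinders override earlier ones, enabling cold inserts) by Woodcock
delta tracking with the water attenuation as majorant.  Cross sections:

* Compton: exact free-electron Klein–Nishina, `μ_C(E) = n_e σ_KN(E)` with
  the analytic total cross section and rejection-sampled scattering angle;
  water electron density 3.3428·10²⁰ mm⁻³ (μ_C(511 keV) = 0.00958 mm⁻¹,
  matching the NIST incoherent value).
* Photoelectric: the standard `E⁻³` parameterisation, anchored at
  0.002 mm⁻¹ at 50 keV for water — negligible above the acceptance window
  but kept for correctness at tracked energies down to the 50 keV cutoff
  (far below 350 keV, so the cutoff cannot affect any output).

Not modelled: Rayleigh scattering (≈1% of the water cross section at
511 keV), electron transport, bound-electron (incoherent scattering
function) suppression of small-angle Compton.  These are the main physics
terms separating this simulator from a full Monte Carlo code.

## Detector response

Default: every photon crossing a block's inner face deposits its full
arrival energy at the face-crossing point (ideal monolithic detector);
recorded DOI is half the crystal depth.  Option `detector_model="cascade"`
instead runs a 1-D slab transport inside the 20 mm LYSO crystal
(photoelectric vs Klein–Nishina Compton with LYSO cross sections,
photofraction ≈ 0.32 at 511 keV): photons can deposit only part of their
energy and escape, giving an energy-dependent detection efficiency, a
Compton continuum of partial deposits and a first-interaction DOI.

Measured on the 160 mm cylinder fixture, the cascade moves only a few
percent of unscattered events into the 350–430 keV window; full detector
simulations of comparable scanners show ~14% true contamination there,
the remainder coming from inter-crystal scatter between blocks, which is
out of scope here.  This is the largest known fidelity gap: with a nearly
scatter-pure low window, the DEW estimator loses the systematic
over-estimation a contaminated low window produces, and the simulated
window purities come out higher than a full simulation's.

## Energy windows and calibration

Windows: LEW 350–430, photopeak 430–650 (DEW) or 430–550 (TEW), UEW
550–650 keV.  Classification: both photons in the photopeak → photopeak
event; else LEW if either photon is in the LEW (priority — a photon that
lost ≥ 81 keV has certainly scattered), else UEW.  The truth table is
exhaustively tested.

Coefficients `k_w` are fitted on labelled data.  DEW: the quotient
(scattered photopeak counts)/(LEW counts); applied to its own calibration
data this reproduces the labelled unscattered photopeak total exactly — a
self-consistency identity the tests assert at machine precision.  TEW:
the per-window quotients would each alone reproduce the scattered
photopeak total, so summing them double-counts; instead `(k_LEW, k_HEW)`
are fitted jointly by non-negative least squares across the calibration
ensemble (default: the seven water cylinders, radii 40–160 mm).  In
per-bin mode, bins with fewer than 50 calibration events (configurable)
fall back to the global coefficients; desk-scale studies use global mode
throughout.

## LOR-space smoothing

Raw per-window counts per LOR bin are far too sparse at desk scale, so
they are smoothed over the 4-D bin-centre coordinate
`x = (u_a, v_a, u_b, v_b)` with a truncated Gaussian kernel:
Mahalanobis² ≤ χ²₄(0.95) ≈ 9.488 (the 95% kernel volume contour),
diagonal bandwidth `H_ii = (2/(3n))^{1/4} σ_i²` (Silverman's rule of
thumb with d = 4), `σ_i` the per-window count-weighted standard deviation
of the i-th coordinate.  Windows with fewer than 100 events borrow the
bandwidth pooled over all windows; degenerate coordinates fall back to
the squared pixel pitch.  The kernel never crosses block-pair boundaries
(the 4-coordinate distance is only meaningful within a faced pair) and is
discretely normalised to sum to one over the lattice, re-normalised per
source bin where the face edge clips its support — so each window's total
count is conserved exactly (verified to 1e-6 relative; the identity is
algebraic).  The production smoother scatter-adds per-source kernels with
prefix-sum edge weights; an FFT convolution and a dense double loop serve
as references, and all three agree to 1e-9 in the tests.

## Scatter fraction and the additive term

Per bin, `C_ph,scatter = k_LEW C̃_LEW (+ k_HEW C̃_UEW)` and
`SF = (C̃_LEW + C_ph,scatter)/C̃_Total`, clamped to [0, 1]; `C̃_Total`
includes all accepted windows (LEW + photopeak + UEW under TEW).  The
numerator counts the whole LEW as scatter (its literal definition); a
purity-corrected variant weighting the LEW by `(1 − f_true)` is available
and off by default.  An optional cap of `C_ph,scatter` at the bin's
smoothed photopeak content exists for dense acquisitions; it is off by
default because at desk-scale counts it binds on sparse-bin noise and
biases the global SF down by ~0.1 (measured at 10⁵ events on the 160 mm
cylinder), while the uncapped estimator tracks the labelled SF to
≤ 0.02–0.03 mean absolute deviation across the cylinder series.  The
global SF is the count-weighted aggregate `Σ num / Σ C̃_Total` over all
bins.

For reconstruction, each measured event carries its bin's scatter
estimate.  Two equivalent forms are implemented: the constant additive
term `S_i = SF(b)·C_raw(b)` with the raw counts taken at the
reconstruction discretisation (exact on dense data; verified against a
brute-force fixed-point oracle on a two-voxel system), and the fractional
form that inflates the forward model to `fwd/(1−SF_i)`.  At sparse counts
the observed count of an occupied bin (≈1) overstates its expected rate,
so the constant form over-corrects; the fractional form uses only the
well-estimated ratio and is what the validation studies use.  Both share
the same dense-count fixed point.

## Reconstruction

List-mode MLEM with the additive term in the forward model, and OSEM with
block-pair round-robin subsets and matching subset sensitivities; one
subset reproduces MLEM bit for bit.  The projector is an incremental
Siddon traversal made robust by sorting the voxel-plane crossings and
indexing each segment at its midpoint — intersection lengths sum to the
analytic chord (tested to 1e-9 on random rays).  The allowed-LOR set of
the sensitivity image is discretised at the LOR-bin level (default 5 mm
recon pixels at desk scale; 1.4–2 mm is feasible for production use) and
cached per (geometry, grid, subset).  Initial image: uniform 1; epsilon
floor 1e-12 guards empty forward projections; voxels with zero
sensitivity are masked from updates.  For fixed `S` the Poisson list-mode
log-likelihood is non-decreasing across iterations (asserted numerically
at 1e-8 relative).  Attenuation/normalisation factors in `a_ij` are
deliberately off by default so the scatter term's effect is isolated.

## Study fixtures and problem sizes

* Cylinder series: water cylinders, 60 mm tall, radii 40–160 mm, central
  line source read as a 5 mm diameter × 60 mm uniform cylinder.
* Out-of-FOV: 25 mm radius × 160 mm source inside a 120 mm × 160 mm water
  cylinder — both taller than the 60 mm axial FOV.
* Utah phantom: 100 mm radius × 50 mm warm cylinder, two 25 mm radius
  rods offset ±35 mm; one rod 10:1 activity per unit volume, one cold.
  Default reconstruction: LM-OSEM, 4 iterations × 3 subsets, 4 mm
  transaxial voxels.

Acquisition size is expressed in decays (or a target accepted-coincidence
count), standing in for activity × time; the validation studies use
5·10⁴–2·10⁵ accepted coincidences per run so a full pipeline executes in
minutes on one CPU, with statistical errors (≲0.005 on a scatter
fraction) well below the physics-fidelity differences discussed above.
The tests run the same studies at 1–3·10⁴ accepted events.

## Known limitations

* Absolute scatter fractions carry the simplified-physics signature: the
  cylinder-series values come out ~0.03–0.05 above and the out-of-FOV
  truth ~0.1 below what a full Monte Carlo simulation of the same setups
  reports.  Internal consistency (estimator vs labelled truth) is the
  reliable quantity at desk scale.
* Coefficients calibrated on the compact cylinders over-predict photopeak
  scatter for the much softer out-of-FOV scatter spectrum (TEW
  over-estimates that fixture's SF by ~0.12) — the transfer of predefined
  coefficients across object classes is a real limitation of the window
  method at this fidelity, not a code artifact.
* DEW ≥ TEW ordering across all radii, a pattern driven by low-window
  true contamination in full simulations, does not reproduce under the
  nearly scatter-pure low window of the default detector model.
* Randoms, dead time, pile-up and LYSO intrinsic radioactivity are not
  modelled; time stamps are carried but unused.
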