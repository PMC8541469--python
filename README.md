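# petew — energy-window scatter correction for list-mode PET

Compton scattering in the patient (or phantom) misplaces a large share of
the coincidences a PET scanner records: one or both 511 keV annihilation
photons change direction and lose energy before detection, so the line of
response (LOR) no longer passes through the annihilation point.  Model-based
corrections (single scatter simulation) need an attenuation map and struggle
with multiple scatter and with activity outside the field of view.  With
modern detectors (~10% energy resolution at 511 keV) the recorded *energies*
themselves carry the scatter information.

`petew` implements a fast energy-dependent scatter correction that operates
directly on list-mode data — no sinograms, no attenuation map — plus the
desk-scale Monte Carlo simulator needed to calibrate and validate it.  It is
aimed at people building or studying dedicated PET systems (e.g. single-ring
brain scanners with monolithic blocks) who want a practical scatter estimate
per LOR and a scatter-corrected iterative reconstruction.

## The method

Events are classified by the energies (`E1`, `E2`) of their two photons
inside the 350–650 keV acceptance window:

* **DEW** (dual energy window): low window LEW = 350–430 keV, photopeak
  430–650 keV;
* **TEW** (triple energy window): LEW = 350–430, photopeak 430–550, upper
  window UEW = 550–650 keV.

A photopeak event has both photons in the photopeak; an auxiliary-window
event has a photon in that window (a LEW photon has lost ≥ 81 keV and has
almost surely scattered, so LEW takes priority).  Calibration constants
`k_w` map auxiliary-window counts to the scattered photopeak counts,

    C_ph,scatter(i) = k_LEW · C_LEW(i)                      (DEW)
    C_ph,scatter(i) = k_LEW · C_LEW(i) + k_HEW · C_UEW(i)   (TEW)

fitted on ground-truth-labelled simulated data (DEW: the count quotient;
TEW: joint non-negative least squares over a calibration ensemble of water
cylinders).  Because a desk-scale acquisition has far fewer counts than LOR
bins, per-window counts are first smoothed over the 4-D LOR coordinate
`x = (u_a, v_a, u_b, v_b)` with a truncated Gaussian kernel (95% volume
contour) whose diagonal bandwidth follows Silverman's rule of thumb,
`H_ii = (2/(3n))^{1/4} σ_i²`.  The scatter fraction per LOR bin is then

    SF(i) = (C_LEW(i) + C_ph,scatter(i)) / C_Total(i)  ∈ [0, 1]

and enters list-mode MLEM/OSEM as an additive term in the forward model,

    n_j^{k+1} = n_j^k / Σ_{i∈I} a_ij · Σ_{i∈M} a_ij / (Σ_j a_ij n_j^k + S_i)

with `a_ij` exact ray–voxel intersection lengths (Siddon traversal), `I`
the allowed system LORs and `M` the measured events.  `S_i` can be a
constant per-event term or, equivalently at convergence, the fractional
form `fwd_i · SF_i/(1−SF_i)` that is robust at sparse counts.

The bundled simulator tracks back-to-back photon pairs through cylinder
phantoms with exact Klein–Nishina Compton scattering and photoelectric
absorption (Woodcock delta tracking), detects them on a 20-block polygonal
ring (50×50×20 mm monolithic blocks, configurable), blurs deposited energy
with the scanner's resolution, and labels every coincidence with its true
scatter history and annihilation position — the ground truth the
calibration and all validation studies rest on.

## Worked example

Calibrate the TEW coefficients on the seven-cylinder ensemble (water
cylinders of radius 40–160 mm with a central 5 × 60 mm line source) and
estimate the scatter fraction of the largest phantom:

```python
from petew import PipelineConfig
from petew.evaluate import simulate_cylinder_series
from petew.model import EnergyWindowScatterModel

cfg = PipelineConfig()
sets = simulate_cylinder_series(cfg, seed=7, target_accepted=20_000)
results = EnergyWindowScatterModel(sets).fit()
print(results.summary())

lm160 = sets[-1]
print(f"160 mm cylinder: truth SF = {lm160.event_scattered.mean():.3f}, "
      f"TEW estimate = {results.global_scatter_fraction(lm160):.3f}")
```

prints

```
Energy-window scatter correction
================================================
window configuration : TEW
  LEW          350 - 430 keV
  photopeak    430 - 550 keV
  UEW          550 - 650 keV
coefficient mode     : global

      coef      value    std err
     k_lew     1.1871     0.0788
     k_uew     0.9353     0.2142

calibration members  : 7
  [0] n=   32584  truth SF=0.170
  [1] n=   24681  truth SF=0.250
  ...
  [6] n=   22396  truth SF=0.588

160 mm cylinder: truth SF = 0.588, TEW estimate = 0.600
```

`k_lew ≈ 1.19` says each low-window count predicts about 1.2 scattered
photopeak counts; the truth column shows the labelled scatter fraction
rising monotonically with phantom radius; and the TEW estimate of the
160 mm phantom lands within ~0.01 of its ground truth.  The same chain is
available from the shell:

```sh
petew simulate --phantom cylinder:160 --target-accepted 50000 --seed 1 --out cyl160.lmb
petew calibrate cyl160.lmb --window TEW --out k.json
petew estimate --input cyl160.lmb --coefficients k.json
petew evaluate utah --seed 1 --out runs/utah     # corrected vs uncorrected images
```

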