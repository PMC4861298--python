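# retromoco

Retrospective rigid-body motion correction for multi-shot 3D MRI, built as
a fully synthetic-testable toolkit.  Ultra-high-resolution brain protocols
(350–380 µm at 7T) take 30–60 minutes, during which the head inevitably
moves; this package implements the complete correction chain that makes
such scans feasible, at desk scale and without any scanner data:

* **digital phantoms** — nested-ellipsoid head models with proton-density /
  T1 / T2 / T2\* maps and a scalp-fat shell, plus smooth complex coil
  sensitivities;
* **acquisition models** — multi-shot Cartesian sampling for MP2RAGE, 3D-TSE
  and 3D-GRE protocols: partial-Fourier masks, GRAPPA patterns, shot
  ordering, navigator cadence and scan-time accounting;
* **forward model** — per-shot rigid motion corrupts the multi-channel
  k-space via the Fourier rotation/shift theorem,
  `m(k) = exp(-2πi k·t) F(Rᵀk)`;
* **fat navigators** — rapid low-resolution fat-only volumes acquired between
  shots; head pose is estimated by multi-resolution rigid registration
  (6-DOF, MSE metric), with GRAPPA reconstruction of the undersampled
  navigator k-space;
* **the correction** — per RF channel, each shot's samples get the conjugate
  phase ramp `exp(+2πi k·t)` and the rotated coordinates `k' = Rᵀk`, and the
  non-Cartesian cloud is reconstructed with an adjoint 3D NUFFT
  (Kaiser–Bessel gridding, no density compensation under the small-motion
  assumption), followed by root-sum-of-squares channel combination;
* **MP2RAGE T1 mapping** — periodic steady state of the two-train Bloch
  recursion, the bias-free `UNI = Re(S1*S2)/(|S1|²+|S2|²)` combination, and
  lookup-table T1 quantification;
* **post-processing** — penalized-least-squares bias-field correction,
  co-register-and-average of repeated scans, Fourier-domain downsampling,
  and PSF / effective-resolution / scan-economics calculators.

## Worked example

```bash
python examples/motion_correction_demo.py
```

simulates a 48³ multi-shot scan with a drift-plus-jerk motion trace (up to
2.5 mm / 2.5°), tracks it with fat navigators and corrects the k-space:

```
NRMSE vs motion-free reference:
  uncorrected : 0.5576
  corrected   : 0.0359   (15.5x lower error)
pose tracking error (median over shots): 0.025 mm, 0.266 deg
```

The uncorrected image is dominated by motion ghosting (56% error vs the
motion-free reconstruction); after correction the error falls to the level
set by rotation-induced k-space gaps.  Other examples cover PSF /
effective-resolution analysis (`psf_effective_resolution.py`: ¾ partial
Fourier with zero-filling broadens the effective PSF by ~15%, so 350 µm
nominal resolves ~400 µm), protocol timing (`scan_timing.py`: 36 min GRE
host time, 42 min with a navigator every 7.6 s; 312 MP2RAGE inversion
cycles × 6 s = 31 min), MP2RAGE T1 mapping and GRAPPA reconstruction.

A thin CLI wraps the same library:

```bash
retromoco demo --seed 1 --out out/
retromoco simulate --seed 1 --out sim/
retromoco estimate-motion --navs sim/navigators.nii.gz --out sim/trace.tsv
retromoco correct --shots sim/shots.h5 --trace sim/trace.tsv --out corr.nii.gz
retromoco psf --n 512 --pf 0.75
retromoco timing --protocol gre
retromoco economics --a 500 --b 350
```

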