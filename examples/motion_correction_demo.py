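"""End-to-end retrospective motion correction on a synthetic acquisition.

Simulates a 48^3 GRE-like multi-shot scan of a digital head phantom whose
pose drifts and jerks between shots (up to 2.5 mm / 2.5 deg), tracks the
motion with fat-selective navigator volumes, estimates it back by rigid
registration, and corrects the k-space shot by shot with the rotated-
coordinate adjoint NUFFT.  Prints the before/after error against the
motion-free reconstruction.
"""

import numpy as np

from retromoco.io import RunConfig
from retromoco.pipeline import run_demo

cfg = RunConfig(n=48, n_coils=6, n_shots=12, amp_mm=2.5, amp_deg=2.5,
                seed=7)
bundle = run_demo(cfg)
rep = bundle["report"]

print(f"NRMSE vs motion-free reference:")
print(f"  uncorrected : {rep.nrmse_uncorrected:.4f}")
print(f"  corrected   : {rep.nrmse_corrected:.4f}   "
      f"({rep.nrmse_uncorrected / rep.nrmse_corrected:.1f}x lower error)")
print(f"pose tracking error (median over shots): "
      f"{np.median(rep.pose_error_mm):.3f} mm, "
      f"{np.median(rep.pose_error_deg):.3f} deg")
print("\nThe corrected image recovers the motion-free reconstruction up to")
print("rotation-induced k-space gaps; the tracking errors show the")
print("navigator registration resolves well below a tenth of a voxel.")
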