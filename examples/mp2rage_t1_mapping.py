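"""Quantitative T1 mapping with the MP2RAGE signal model.

Solves the two-train steady-state Bloch recursion for the 7T protocol
(TI 800/2700 ms, flips 5/7 deg, 6 s cycle), combines the train signals
into the bias-free UNI image, builds the UNI(T1) lookup table, and
recovers the tissue T1 values of a digital phantom from its synthetic
UNI volume.
"""

import warnings

import numpy as np

import retromoco as rm
from retromoco.mp2rage import (MP2RAGEParams, build_lookup, mp2rage_signals,
                               t1_map, uni_combine, uni_image)

p = MP2RAGEParams()
print(f"protocol: TI {p.ti1_ms:.0f}/{p.ti2_ms:.0f} ms, flips "
      f"{p.alpha1_deg:.0f}/{p.alpha2_deg:.0f} deg, {p.n_echoes} echoes per "
      f"train, cycle {p.tr_cycle_ms:.0f} ms\n")

print("tissue        T1/ms      S1        S2       UNI")
for name, t1 in (("WM", 1200.0), ("GM", 2000.0), ("CSF", 4000.0)):
    s1, s2 = mp2rage_signals(t1, p)
    print(f"{name:8s} {t1:9.0f} {s1:+9.5f} {s2:+9.5f} "
          f"{uni_combine(s1, s2):+9.4f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = build_lookup(p)
print(f"\nlookup: UNI strictly decreasing over T1 "
      f"{table.t1_ms[0]:.0f}-{table.t1_ms[-1]:.0f} ms")

ph = rm.make_phantom(48, seed=0)
uni = uni_image(ph.t1_ms * (ph.pd > 0), p)
est, clipped = t1_map(uni, table)
brain = (ph.pd > 0) & (ph.fat_fraction == 0)
err = np.abs(est[brain] - ph.t1_ms[brain])
print(f"phantom T1 recovery: median error {np.median(err):.2f} ms "
      f"({clipped} voxels clamped)")
print("\nUNI depends on T1 only (coil gain cancels in the ratio), so the")
print("lookup inverts it voxelwise into a quantitative T1 map.")
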