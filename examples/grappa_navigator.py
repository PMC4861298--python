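"""GRAPPA reconstruction of an undersampled navigator acquisition.

Undersamples the k-space of an 8-channel synthetic head by a factor 2 in
one phase-encode dimension (keeping a 24-line calibration block),
calibrates GRAPPA kernels by least squares on the block, synthesizes the
missing lines and compares against the fully-sampled reference.
"""

import numpy as np

import retromoco as rm
from retromoco.acquisition import AcquisitionPlan
from retromoco.navigator import (grappa_calibrate, grappa_reconstruct,
                                 _extract_acs)
from retromoco.nufft import cart_fft, cart_ifft
from retromoco.postproc import nrmse

n = 48
ph = rm.make_phantom(n, seed=0)
coils = rm.make_coils(n, 8, seed=1)
chans = np.stack([cart_fft(ph.pd * c) for c in coils.maps])

plan = AcquisitionPlan(matrix=(n, n, n), pf=(1.0, 1.0), grappa=(2, 1),
                       calib=(24, 0))
mask = plan.pe_mask_2d()
under = chans * mask[None, None, :, :]
print(f"acquired {mask.mean():.0%} of phase-encode lines "
      f"(R=2 + 24-line calibration)")

weights = grappa_calibrate(_extract_acs(chans, plan), plan.grappa)
full = grappa_reconstruct(under, weights, plan)


def rss(k):
    return np.sqrt(np.sum(np.abs(np.stack([cart_ifft(x) for x in k])) ** 2,
                          axis=0))


print(f"zero-filled reconstruction error : {nrmse(rss(under), rss(chans)):.4f}")
print(f"GRAPPA reconstruction error      : {nrmse(rss(full), rss(chans)):.4f}")
print("\nThe kernels predict each skipped line from its neighbours across")
print("all channels; with 8 distinct coil profiles the missing data are")
print("recovered to a fraction of a percent on noiseless data.")
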