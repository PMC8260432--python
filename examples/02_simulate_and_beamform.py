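"""Simulate a multistatic capture of a point target and beamform it with
plane-wave and diverging-wave transmits.

A single scatterer at (0, 20 mm) in a homogeneous 1500 m/s medium should
image within half a wavelength (150 um at 5 MHz) of its true position for
every transmit scheme and aperture mode.
"""
import numpy as np

import echosos as es
from echosos import beamform as bf
from echosos import rfsim

transducer = es.Transducer()  # 128 elements, 300 um pitch, 5 MHz
grid = es.default_phantom_grid(38e-3, 30e-3, 0.3e-3)
medium = es.make_homogeneous_phantom(grid, 1500.0)

pert = np.zeros(grid.shape)
ix, iz = np.argmin(np.abs(grid.x)), np.argmin(np.abs(grid.z - 20e-3))
pert[ix, iz] = 1.0
target = (grid.x[ix], grid.z[iz])
scat = es.ScattererField(pert, grid, 0.01, 1.0, 0)

print("simulating 128-event multistatic capture ...")
ms = rfsim.simulate_multistatic(transducer, medium, scat)

bgrid = es.Grid(80, 320, 0.15e-3, 37.5e-6, -6e-3, 14e-3)
for name, data in [("DW center element", rfsim.recompose_dw(ms, [63])),
                   ("PW 0 deg", rfsim.recompose_pw(ms, [0.0])),
                   ("PW +10 deg", rfsim.recompose_pw(ms, [10.0]))]:
    for mode, psi in [("full", 0.0), ("adapted", 15.0)]:
        frame = bf.das_beamform(data, 0, bgrid,
                                bf.BeamformConfig(aperture_mode=mode,
                                                  psi_psf=psi))
        env = bf.envelope(frame.values)
        env[~frame.valid] = 0
        i, j = np.unravel_index(np.argmax(env), env.shape)
        err = np.hypot(bgrid.x[i] - target[0], bgrid.z[j] - target[1])
        print(f"{name:>18} | {mode:>7} aperture psi={psi:+5.1f} deg -> "
              f"peak error {err * 1e6:6.1f} um")
# Errors at or below one beamform pixel (~75-150 um) mean the geometric
# delay model, the recomposition and the beamformer agree.
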