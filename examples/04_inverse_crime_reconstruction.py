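"""Tomographic slowness reconstruction validated by an inverse crime.

Delays are generated exactly by the differential path matrix for a +2%
circular inclusion (1530 on 1500 m/s) under the diverging-wave pairing
(delta_channel=17, M=9, 128 elements), then inverted — first noiseless,
then with 5% relative Gaussian delay noise. This isolates the solver from
tracking errors: it must recover the inclusion almost perfectly.
"""
import numpy as np

import echosos as es
from echosos import displacement as disp
from echosos import forward, invert
from echosos.forward import PathMatrix
from echosos.rfsim import TxDescriptor

sigma0 = 1 / 1500.0
transducer = es.Transducer()
grid = es.default_phantom_grid()
truth = es.make_geometric_phantom(grid, "circle", center=(0.0, 25e-3),
                                  radius=6e-3, contrast=0.02)
recon_grid = grid.coarsen(1.5e-3)
truth_r = es.resample_to(truth, recon_grid)

pairs = disp.select_pairs(es.PairingSpec(scheme="dw", delta_channel=17, M=9),
                          range(128))
table = [(j, i, 0.0) for i, j in pairs]
meas_grid = grid.coarsen(1.0e-3)
X, Z = meas_grid.meshgrid()
ex = transducer.element_x
valid = np.zeros((len(pairs), meas_grid.nx, meas_grid.nz), bool)
for k, (i, j, _) in enumerate(table):
    cone = np.tan(np.deg2rad(35.0))
    valid[k] = (np.abs(X - ex[i]) <= Z * cone) & \
               (np.abs(X - ex[j]) <= Z * cone)
ds = es.DelaySet(np.zeros_like(valid, float), np.ones_like(valid, float),
                 valid, table, meas_grid, scheme="dw")
L = es.build_L(ds, recon_grid, {e: TxDescriptor("dw", element=e)
                                for e in range(128)}, ex)
dtau = L.matrix @ (truth_r.slowness.ravel() - sigma0)
print(f"path matrix: {L.n_rows} measurements x {L.matrix.shape[1]} pixels, "
      f"delays up to {np.abs(dtau).max() * 1e9:.0f} ns")

sub = forward.subsample_measurements(
    PathMatrix(L.matrix, recon_grid, dtau, L.row_meta), 10_000, seed=1)
recon, diag = invert.solve_sos(sub, invert.ReconConfig(lam=1e-6))
print(f"noiseless: RMSE {es.rmse(recon, truth_r):.2f} m/s "
      f"({diag['n_iter']} L-BFGS iterations)")

rng = np.random.default_rng(7)
noisy = dtau * (1 + 0.05 * rng.standard_normal(dtau.size))
subn = forward.subsample_measurements(
    PathMatrix(L.matrix, recon_grid, noisy, L.row_meta), 10_000, seed=1)
reconn, _ = invert.solve_sos(subn, invert.ReconConfig(lam=5.0))
cnr = es.cnr(reconn, truth_r.masks["inclusion"], truth_r.masks["background"])
print(f"5% delay noise, lambda=5: RMSE {es.rmse(reconn, truth_r):.2f} m/s, "
      f"CNR {cnr:.0f}")
# Sub-m/s RMSE on +-30 m/s contrast shows the L1 objective, regularizer
# and L-BFGS solve are correct; real-data error is dominated by tracking.
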