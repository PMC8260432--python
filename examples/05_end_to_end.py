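"""Full imaging chain on a homogeneous medium, both transmit schemes.

Ray-simulated multistatic RF -> band-pass -> PW/DW recomposition ->
delay-and-sum beamforming -> NCC displacement tracking -> differential
path matrix -> L1-regularized inversion -> evaluation. With a correct
chain, a homogeneous 1500 m/s medium must come back within +-3 m/s almost
everywhere; any bias here would corrupt every later reconstruction.

Takes a few minutes (two full acquisitions at the 96-channel demo scale).
"""
import numpy as np

import echosos as es

for scheme in ("dw", "pw"):
    cfg = es.RunConfig(scheme=scheme, seed=1)
    recon, result, info = es.run_end_to_end(cfg)
    mask = info["eval_mask"]
    frac = np.mean(np.abs(recon.values - 1500.0) <= 3.0, where=mask)
    print(f"{scheme.upper()}: {info['n_events']} events, "
          f"{info['n_valid_delays']} valid delays, {info['n_rows']} L rows, "
          f"solver {info['solver']['n_iter']} iterations")
    print(f"     RMSE {result.rmse:.2f} m/s | mean "
          f"{recon.values[mask].mean():.1f} m/s | "
          f"{frac:.1%} of evaluated pixels within +-3 m/s of truth")
# Both schemes should report >= 95% within +-3 m/s; the diverging-wave
# chain typically comes back tighter than plane waves, whose global SoS
# offset is only weakly constrained by the limited-angle geometry.
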