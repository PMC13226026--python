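"""Forward-simulate and quantify each imaging modality on known ground truth.

Each block simulates the raw signal a scanner would record for a known truth
and runs the matching quantification operator: the estimate should land on the
truth (exactly in the noiseless case, closely under realistic noise).
"""

import numpy as np

from placentapd import (
    ExtinctionMatrix,
    compute_ri,
    compute_vi,
    fit_tic,
    simulate_doppler_cycles,
    simulate_pa_signals,
    simulate_tic,
    simulate_vascular_map,
    unmix_so2,
)

rng = np.random.default_rng(11)

# --- photoacoustics: dual-wavelength forward model + linear unmixing ---------
eps = ExtinctionMatrix()
pair = simulate_pa_signals(so2_true=0.62, total_hb=1.0, eps=eps, noise_sd=5.0, rng=rng)
print(f"PA signals at 750/850 nm: {pair.signals[0]:.1f} / {pair.signals[1]:.1f} a.u.")
print(f"unmixed sO2: {unmix_so2(pair, eps):.4f}  (truth 0.6200)")

# --- CEUS: lognormal bolus TIC + kinetic fit --------------------------------
tic = simulate_tic(rbv_true=20_000.0, noise_sd=2.0, rng=rng)
fit = fit_tic(tic)
print(f"\nTIC fit: t0={fit.t0:.2f} s, time-to-peak={fit.time_to_peak:.2f} s, "
      f"peak enhancement={fit.peak_enhancement:.0f} a.u.")
print(f"WiAUC estimate: {fit.wiauc:.0f} a.u.  (truth 20000)")

# --- Doppler: per-cycle velocities -> resistance index ----------------------
cycles = simulate_doppler_cycles(psv_true=80.0, edv_true=28.0, n_cycles=5,
                                 noise_sd=1.5, rng=rng)
print(f"\nDoppler cycles PSV={np.round(cycles.psv, 1)} mm/s")
print(f"UtA-RI estimate: {compute_ri(cycles):.4f}  (truth {(80 - 28) / 80:.4f})")

# --- MV-flow: vascular map -> threshold fraction ----------------------------
vmap = simulate_vascular_map(density_true=0.33, grid_shape=(256, 256),
                             contrast=100.0, noise_sd=10.0, threshold=50.0, rng=rng)
print(f"\nVI estimate: {compute_vi(vmap):.2f} %  (truth 33.00 %)")
print("\nEach estimate sits within its measurement noise of the truth;")
print("the pipeline relies on these operators being unbiased.")
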