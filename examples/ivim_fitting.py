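"""Fit the biexponential IVIM model to a synthetic two-region DWI phantom.

Builds a small noisy multi-b-value stack (a CSF-like block with high
perfusion fraction f and a tissue-like block), fits every voxel, and prints
per-region f statistics against the ground truth.
"""

from csfoi import ivim, synthetic

config = synthetic.SyntheticDWIConfig(
    grid_shape=(10, 6, 6),
    region_params=(
        synthetic.RegionParams("csf_like", f=0.75, D=3e-3, D_star=3e-2, S0=1000.0),
        synthetic.RegionParams("tissue_like", f=0.15, D=8e-4, D_star=1e-2, S0=800.0),
    ),
    noise_model="rician",
    snr=40.0,
    seed=7,
)
sim = synthetic.simulate_dwi(config)
sigma = 1000.0 / config.snr  # known simulation noise level
maps = ivim.fit_ivim_volume(sim.stack, ivim.FitOptions(noise_sigma=sigma))

print(f"fitted {int((maps.fit_flags == ivim.FitFlag.OK).sum())} voxels "
      f"at b = {config.b_values} s/mm^2, Rician SNR {config.snr:g}\n")
for name, value in sim.label_values.items():
    s = ivim.roi_f_stats(maps, sim.labels, name, value)
    true_f = sim.truth.f_percent[sim.labels == value][0]
    print(f"{name:12s}  mean f = {s.mean_f:5.1f}%  (truth {true_f:.1f}%)  "
          f"range [{s.min_f:.1f}, {s.max_f:.1f}]%  n = {s.n_voxels}")
print("\nf is the fraction of voxel signal in the fast pseudo-diffusion pool;"
      "\nin CSF spaces it tracks pulsatile fluid motion (high f = mobile CSF).")
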