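"""Diffusion-MRI stage: ADC estimation and reporter contrast recovery.

Simulates the two-compartment pellet phantom (control cells at
0.67 µm²/ms, reporter-expressing cells 79% higher) under Rician noise
at SNR 50 with 5 averages, fits the ROI-mean and voxel-wise ADC with
the noise-floor correction, and reports recovery of D and of the
contrast statistic ΔD/D₀. Also renders the 8-bit diffusion map.
"""

from pathlib import Path

import numpy as np

from reporterdiff import io as rio
from reporterdiff.dwmri import fit_adc_map, render_diffusion_map
from reporterdiff.pipeline import RunConfig, run_pipeline
from reporterdiff.synth import (Compartment, PelletPhantomSpec,
                                make_pellet_phantom)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

bundle = run_pipeline(RunConfig(stages=["dwmri"], seed=1))
df = bundle.tables["dwmri"]
df.to_csv(OUT / "dwmri_recovery.csv", index=False, float_format="%.12g")
print(df.to_string(index=False))

row = df[df["compartment"] == "delta_d_over_d0_pct"].iloc[0]
print(f"\nreporter contrast: true ΔD/D₀ = {row['d_true']:.1f}%, "
      f"recovered {row['d_roi_fit']:.1f}% "
      f"({100 * row['roi_rel_err']:.2f}% relative error)")

# diffusion map rendering (whole-pellet ROI, 0.2-2.5 µm²/ms window)
spec = PelletPhantomSpec(
    compartments=[Compartment((40, 64), 18, 0.67),
                  Compartment((90, 64), 18, 1.2)],
    snr=50.0, seed=1)
series, truth = make_pellet_phantom(spec)
dmap = fit_adc_map(series, np.isfinite(truth), noise_sigma=1000.0 / spec.snr)
rio.write_rendered_map(render_diffusion_map(dmap, 0.2, 2.5, kernel=3),
                       OUT / "diffusion_map.png")
print(f"wrote {OUT / 'diffusion_map.png'}")
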