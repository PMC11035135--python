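# reporterdiff

Quantification pipeline for an aquaporin-1 (Aqp1) MRI reporter-gene
safety study, rebuilt as a tested, reusable Python package. Aqp1 is a
water channel: overexpressing it speeds water exchange across the cell
membrane, raising the apparent diffusion coefficient (ADC) that
diffusion-weighted MRI measures, so engineered cells become visible on
a diffusion map. Assessing whether that is *safe* requires a panel of
quantitative readouts — and this package implements every one of them,
paired with synthetic ground-truth generators so each estimator is
validated by parameter recovery:

- **Diffusion MRI** (`reporterdiff.dwmri`) — Stejskal–Tanner b-values,
  ROI and voxel-wise ADC fits from the log-linear decay
  `S(b) = S0·exp(−b·D)`, Rician noise-floor correction, median-filtered
  8-bit map rendering, and the reporter contrast `ΔD/D₀ = 100·(D−D₀)/D₀`.
- **Quantitative phase imaging** (`reporterdiff.qpi`) — optical path
  length `OPL(x,y) = ∫(n−n_surr)dz`, dry mass `m = ∬OPL dxdy / α` with
  α = 0.18 µm³/pg, volume, iso-surface area, and sphericity
  `Ψ = π^(1/3)(6V)^(2/3)/S`.
- **qPCR** (`reporterdiff.qpcr`) — relative expression by `2^(−ΔΔCt)`
  with housekeeping normalization, primer efficiency from dilution
  series, Student/Welch t-tests on ΔΔCt.
- **Functional assays** (`reporterdiff.assays`) — T-cell
  Stimulation% from flow-cytometry quadrants, phagocytic index,
  Matrigel invasion area (escaped-pixel fraction × 113.5 mm²),
  viability-normalized caspase folds, and quadratic ELISA
  standard-curve inversion.
- **Synthetic data** (`reporterdiff.synth`) — seeded generators for
  pellet phantoms (mono-exponential signal + Rician magnitude noise),
  ellipsoidal-cell tomograms, Ct tables with planted fold changes, and
  per-assay fixtures, each returning a ground-truth record.
- **I/O and orchestration** (`reporterdiff.io`, `reporterdiff.pipeline`,
  `reporterdiff.cli`) — NIfTI/TIFF + JSON-sidecar round trips and a
  seeded simulate → estimate → report pipeline.

## Worked example

```python
import numpy as np
from reporterdiff.synth import PelletPhantomSpec, Compartment, make_pellet_phantom
from reporterdiff.dwmri import roi_mean_signal, fit_adc, percent_delta_diffusivity

spec = PelletPhantomSpec(
    compartments=[Compartment((40, 64), 18, d_true=0.67),   # control cells
                  Compartment((90, 64), 18, d_true=1.2)],   # Aqp1-like cells
    snr=50.0, averages=5, seed=1)
series, truth = make_pellet_phantom(spec)
sigma = 1000.0 / spec.snr          # known noise level of the simulation
fits = {}
for d in (0.67, 1.2):
    decay = roi_mean_signal(series, np.isclose(truth, d))
    fits[d] = fit_adc(decay, noise_sigma=sigma).D
print(f"D0 = {fits[0.67]:.3f}, D = {fits[1.2]:.3f} um^2/ms")
print(f"contrast = {percent_delta_diffusivity(fits[1.2], fits[0.67]):.1f} %")
```

prints

```
D0 = 0.672, D = 1.194 um^2/ms
contrast = 77.8 %
```

i.e. the ROI fits recover both compartment diffusivities to well under
1% and the reporter contrast statistic to within ~2% of its planted
79.1% value, despite SNR-50 Rician noise.

The numbered drivers under `analysis/` run the same recovery study per
assay family and write their tables under `results/`:
`01_simulate_phantoms.py`, `02_diffusion_recovery.py`,
`03_morphometry.py`, `04_expression.py`, `05_functional_assays.py`,
`06_report.py`. The `reporterdiff` command exposes the same steps for
files on disk (`reporterdiff adc --series s.nii --mask m.tif --out map.nii`).

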