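"""Generate one example synthetic dataset per pipeline stage.

Writes a diffusion-weighted pellet series (NIfTI + b-value sidecar), a
refractive-index tomogram (TIFF + metadata), and a qPCR Ct table (CSV),
each with its ground-truth record, under results/simulated/. These are
the same generators the tests and downstream drivers use; this script
just materializes one instance of each for inspection.
"""

import json
from pathlib import Path

import numpy as np

from reporterdiff import io as rio
from reporterdiff.synth import (Compartment, CtDesignSpec, EllipsoidCell,
                                GeneSpec, PelletPhantomSpec,
                                TomogramSceneSpec, make_ct_table,
                                make_pellet_phantom, make_tomogram)

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

# two-compartment pellet: control vs reporter-expressing cells
spec = PelletPhantomSpec(
    compartments=[Compartment((40, 64), 18, 0.67),
                  Compartment((90, 64), 18, 1.2)],
    snr=50.0, seed=SEED)
series, truth = make_pellet_phantom(spec)
rio.write_diffusion_series(series, OUT / "pellet.nii")
np.save(OUT / "pellet_truth_D.npy", truth)
print(f"pellet: {series.stack.shape} stack, b = {list(spec.bvalues)} ms/µm², "
      f"true D = {{0.67, 1.2}} µm²/ms -> {OUT / 'pellet.nii'}")

# tomogram of two ellipsoidal cells
tspec = TomogramSceneSpec(
    shape=(96, 96, 72),
    cells=[EllipsoidCell((6.0, 6.0, 9.0), (4.0, 4.0, 4.0), 1.363),
           EllipsoidCell((14.0, 13.0, 10.0), (5.0, 3.5, 3.0), 1.363)],
    seed=SEED)
tom, cell_truth = make_tomogram(tspec)
rio.write_tomogram(tom, OUT / "tomogram.tif")
(OUT / "tomogram_truth.json").write_text(json.dumps(cell_truth, indent=1))
print(f"tomogram: {tom.n.shape} grid, {len(cell_truth)} cells, "
      f"true masses {[round(t['mass_pg'], 2) for t in cell_truth]} pg")

# Ct table with planted fold changes
cspec = CtDesignSpec(
    genes=[GeneSpec("Aqp1", 16.0), GeneSpec("BiP", 2.0),
           GeneSpec("CHOP", 1.0)],
    noise_sigma=0.15, seed=SEED)
table, fold_truth = make_ct_table(cspec)
table.data.to_csv(OUT / "ct_table.csv", index=False)
(OUT / "ct_truth.json").write_text(json.dumps(fold_truth, indent=1))
print(f"ct table: {len(table.data)} wells, planted folds {fold_truth}")
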