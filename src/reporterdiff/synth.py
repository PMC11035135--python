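"""Ground-truth synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure of one acquisition in
the reporter-safety study and returns the simulated data together with
a truth record, so every estimator can be validated by parameter
recovery:

* cell-pellet diffusion phantoms — circular compartments with known
  diffusivity, mono-exponential signal over a stimulated-echo b-value
  schedule, magnitude (Rician) noise and arithmetic averaging of
  repeated acquisitions;
* refractive-index tomograms of ellipsoidal cells with known index
  contrast, hence known analytic volume, surface area (Thomsen
  approximation), and dry mass;
* qPCR Ct tables with planted fold changes and Gaussian replicate
  noise;
* small assay fixtures (quadrant counts, invasion masks, bead images,
  dilution series, ELISA standard curves).

All randomness comes from one ``numpy.random.Generator`` seeded per
call; identical spec + seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwmri import DiffusionSeries
from .qpi import ALPHA_UM3_PER_PG, DEFAULT_VOXEL_UM, Tomogram
from .qpcr import CtTable, PERFECT_DOUBLING_SLOPE

__all__ = [
    "DEFAULT_BVALUES",
    "Compartment",
    "PelletPhantomSpec",
    "EllipsoidCell",
    "TomogramSceneSpec",
    "GeneSpec",
    "CtDesignSpec",
    "make_pellet_phantom",
    "make_tomogram",
    "make_ct_table",
    "make_assay_fixtures",
    "ellipsoid_volume",
    "ellipsoid_surface_thomsen",
]

#: default stimulated-echo b-value schedule, four values spanning
#: 1–3 ms/µm² (the exact in-range values are configurable)
DEFAULT_BVALUES = (1.0, 1.6667, 2.3333, 3.0)


# ---------------------------------------------------------------------------
# diffusion pellet phantom
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    """Circular pellet cross-section with uniform true diffusivity."""

    center: tuple[float, float]     # voxels (row, col)
    radius: float                   # voxels
    d_true: float                   # µm²/ms
    s0: float = 1000.0              # a.u.

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("compartment radius must be positive")
        if self.d_true < 0 or self.s0 <= 0:
            raise ValueError("need d_true >= 0 and s0 > 0")


@dataclass
class PelletPhantomSpec:
    """Parameterization of a synthetic cell-pellet diffusion acquisition.

    Acquisition defaults mirror a 7 T stimulated-echo protocol: 128×128
    matrix, four effective b-values between 1 and 3 ms/µm², 5 averages.
    ``snr`` is S0 over the per-channel complex noise σ.
    """

    shape: tuple[int, int] = (128, 128)
    voxel_mm: tuple[float, float] = (0.397, 0.397)   # 5.08 cm FOV / 128
    compartments: list[Compartment] = field(default_factory=list)
    background: float = 0.0
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    averages: int = 5
    snr: float = 50.0
    noise: str = "rician"           # rician | gaussian | none
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if (b < 0).any() or np.unique(b).size != b.size:
            raise ValueError("b-values must be nonnegative and distinct")
        if self.noise not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise != "none" and self.snr <= 0:
            raise ValueError("SNR must be positive when noise is on")
        if self.averages < 1:
            raise ValueError("averages must be >= 1")
        for c in self.compartments:
            r, ctr = c.radius, c.center
            if (ctr[0] - r < 0 or ctr[0] + r > self.shape[0]
                    or ctr[1] - r < 0 or ctr[1] + r > self.shape[1]):
                raise ValueError("compartment extends outside the image grid")
        # pairwise overlap check
        for i, a in enumerate(self.compartments):
            for bb in self.compartments[i + 1:]:
                dist = np.hypot(a.center[0] - bb.center[0],
                                a.center[1] - bb.center[1])
                if dist < a.radius + bb.radius:
                    raise ValueError("compartments overlap")


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_pellet_phantom(spec: PelletPhantomSpec
                        ) -> tuple[DiffusionSeries, np.ndarray]:
    """Simulate a diffusion-weighted series of a cell-pellet phantom.

    Returns the series and a voxel-aligned truth map of D (NaN outside
    all compartments). Noiseless signal in a compartment voxel is
    ``S0 exp(-b D)``; Rician noise takes the magnitude of the complex
    signal plus circular Gaussian noise of per-channel σ = S0/SNR, and
    ``averages`` independent magnitude acquisitions are combined by
    arithmetic mean.
    """
    rng = np.random.default_rng(spec.seed)
    b = np.asarray(spec.bvalues, dtype=float)
    nb = b.size
    s0_map = np.full(spec.shape, float(spec.background))
    d_map = np.zeros(spec.shape)
    truth = np.full(spec.shape, np.nan)
    for comp in spec.compartments:
        m = _disk_mask(spec.shape, comp.center, comp.radius)
        s0_map[m] = comp.s0
        d_map[m] = comp.d_true
        truth[m] = comp.d_true

    clean = s0_map[..., None] * np.exp(-d_map[..., None] * b)

    if spec.noise == "none":
        stack = clean
    else:
        # σ referenced to the largest compartment S0 (scanner noise floor
        # is signal-independent)
        s0_ref = max((c.s0 for c in spec.compartments), default=1.0)
        sigma = s0_ref / spec.snr
        acq_shape = (spec.averages, *spec.shape, nb)
        if spec.noise == "gaussian":
            acqs = clean[None] + rng.normal(0.0, sigma, size=acq_shape)
        else:  # rician: magnitude of complex Gaussian perturbation
            re = clean[None] + rng.normal(0.0, sigma, size=acq_shape)
            im = rng.normal(0.0, sigma, size=acq_shape)
            acqs = np.hypot(re, im)
        stack = acqs.mean(axis=0)

    series = DiffusionSeries(
        stack=stack,
        bvalues=b,
        voxel_mm=spec.voxel_mm,
        meta={
            "te_ms": 18.0, "tr_ms": 1000.0,
            "delta_ms": 5.0, "Delta_ms": 300.0,
            "averages": spec.averages, "noise": spec.noise,
            "snr": spec.snr, "seed": spec.seed,
        },
    )
    return series, truth


# ---------------------------------------------------------------------------
# refractive-index tomogram scene
# ---------------------------------------------------------------------------

@dataclass
class EllipsoidCell:
    """Ellipsoidal cell with uniform interior refractive index."""

    center: tuple[float, float, float]   # µm
    semi_axes: tuple[float, float, float]  # µm
    n_cell: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")


@dataclass
class TomogramSceneSpec:
    """Scene of non-overlapping ellipsoidal cells in medium."""

    shape: tuple[int, int, int] = (96, 96, 64)
    voxel_um: tuple[float, float, float] = DEFAULT_VOXEL_UM
    cells: list[EllipsoidCell] = field(default_factory=list)
    n_surr: float = 1.333
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.cells:
            if c.n_cell <= self.n_surr:
                raise ValueError(
                    "cell refractive index must exceed the medium's")
        # conservative overlap test on bounding spheres
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1:]:
                dist = np.linalg.norm(np.subtract(a.center, b.center))
                if dist < max(a.semi_axes) + max(b.semi_axes):
                    raise ValueError("cells overlap (bounding spheres meet)")


def ellipsoid_volume(semi_axes: tuple[float, float, float]) -> float:
    """Analytic ellipsoid volume (4/3)πabc, µm³."""
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_surface_thomsen(semi_axes: tuple[float, float, float],
                              p: float = 1.6075) -> float:
    """Thomsen approximation to the ellipsoid surface area (µm²).

    ``S ≈ 4π [((ab)^p + (ac)^p + (bc)^p) / 3]^(1/p)``, accurate to about
    1.06% worst case; serves as the oracle for tolerance-based surface
    checks.
    """
    a, b, c = semi_axes
    return float(4.0 * np.pi * (((a * b) ** p + (a * c) ** p
                                 + (b * c) ** p) / 3.0) ** (1.0 / p))


def make_tomogram(spec: TomogramSceneSpec
                  ) -> tuple[Tomogram, list[dict]]:
    """Voxelize a cell scene into a refractive-index tomogram.

    Returns the tomogram and a per-cell truth list with analytic volume,
    Thomsen surface area, and dry mass ``(n_cell − n_surr)·V/α``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.full(spec.shape, spec.n_surr)
    vx = spec.voxel_um
    # voxel-center coordinates in µm
    coords = np.meshgrid(
        (np.arange(spec.shape[0]) + 0.5) * vx[0],
        (np.arange(spec.shape[1]) + 0.5) * vx[1],
        (np.arange(spec.shape[2]) + 0.5) * vx[2],
        indexing="ij",
    )
    truth = []
    for cell in spec.cells:
        a, b, c = cell.semi_axes
        x0, y0, z0 = cell.center
        inside = (((coords[0] - x0) / a) ** 2
                  + ((coords[1] - y0) / b) ** 2
                  + ((coords[2] - z0) / c) ** 2) <= 1.0
        grid[inside] = cell.n_cell
        vol = ellipsoid_volume(cell.semi_axes)
        truth.append({
            "center_um": cell.center,
            "semi_axes_um": cell.semi_axes,
            "n_cell": cell.n_cell,
            "volume_um3": vol,
            "surface_um2": ellipsoid_surface_thomsen(cell.semi_axes),
            "mass_pg": (cell.n_cell - spec.n_surr) * vol / ALPHA_UM3_PER_PG,
        })
    if spec.noise_sigma > 0:
        grid = grid + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return Tomogram(grid, voxel_um=vx, n_surr=spec.n_surr), truth


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------

@dataclass
class GeneSpec:
    """One target gene with a planted fold change vs the control group."""

    name: str
    true_fold: float
    baseline_ct: float = 24.0

    def __post_init__(self) -> None:
        if self.true_fold <= 0:
            raise ValueError("fold changes must be positive")


@dataclass
class CtDesignSpec:
    """Design of a two-group qPCR experiment with known fold changes."""

    genes: list[GeneSpec] = field(default_factory=list)
    housekeeping: str = "GAPDH"
    housekeeping_ct: float = 18.0
    case_group: str = "Aqp1"
    control_group: str = "GFP"
    n_samples: int = 3
    n_replicates: int = 3
    noise_sigma: float = 0.0        # Ct units, per technical replicate
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.housekeeping:
            raise ValueError("a housekeeping gene is required")
        if self.n_replicates < 1 or self.n_samples < 1:
            raise ValueError("need >=1 sample and replicate")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def make_ct_table(spec: CtDesignSpec) -> tuple[CtTable, dict[str, float]]:
    """Generate a replicate Ct table with planted fold changes.

    At 100% amplification efficiency a fold change F shifts the case
    group's target Ct by −log2(F), so the expected ΔΔCt is −log2(F)
    exactly. Gaussian noise of ``noise_sigma`` cycles is added per
    technical replicate.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []

    def emit(group: str, sample: str, gene: str, role: str, base_ct: float):
        cts = base_ct + rng.normal(0.0, spec.noise_sigma, spec.n_replicates) \
            if spec.noise_sigma > 0 else np.full(spec.n_replicates, base_ct)
        for ct in cts:
            rows.append({"sample": sample, "group": group, "gene": gene,
                         "role": role, "ct": float(ct)})

    for group in (spec.case_group, spec.control_group):
        for i in range(spec.n_samples):
            sample = f"{group}_{i + 1}"
            emit(group, sample, spec.housekeeping, "housekeeping",
                 spec.housekeeping_ct)
            for gene in spec.genes:
                shift = -np.log2(gene.true_fold) \
                    if group == spec.case_group else 0.0
                emit(group, sample, gene.name, "target",
                     gene.baseline_ct + shift)

    table = CtTable(pd.DataFrame(rows))
    truth = {g.name: g.true_fold for g in spec.genes}
    return table, truth


# ---------------------------------------------------------------------------
# small assay fixtures
# ---------------------------------------------------------------------------

def make_assay_fixtures(kind: str, params: dict | None = None,
                        seed: int = 0) -> tuple[object, dict]:
    """Generate a small assay fixture plus its ground truth.

    Kinds
    -----
    ``quadrants``
        params: quadrant counts; truth carries the Stimulation%.
    ``invasion_mask``
        params: ``shape``, ``disks`` [(row, col, radius), ...]; truth
        carries the planted pixel count and fraction.
    ``bead_image``
        params: ``shape``, ``cells`` [(row, col, radius, intensity)],
        ``background``; returns (bead image, label mask); truth carries
        the mean planted per-cell integrated intensity.
    ``dilution_series``
        params: ``slope`` (Ct per decade), ``intercept``,
        ``log10_dilutions``, ``sigma``; truth carries the efficiency
        implied by the slope.
    ``standard_curve``
        params: ``coeffs`` (quadratic, highest first),
        ``concentrations``, ``sigma``; truth carries coefficients and
        exact signals.
    """
    rng = np.random.default_rng(seed)
    p = dict(params or {})

    if kind == "quadrants":
        from .assays import QuadrantCounts, stimulation_pct
        q = QuadrantCounts(
            p.get("cd3p_cd25p", 30), p.get("cd3p_cd25n", 70),
            p.get("cd3n_cd25p", 0), p.get("cd3n_cd25n", 0))
        return q, {"stimulation_pct": stimulation_pct(q)}

    if kind == "invasion_mask":
        shape = p.get("shape", (256, 256))
        mask = np.zeros(shape, dtype=bool)
        for row, col, radius in p.get("disks", [(128, 128, 20)]):
            mask |= _disk_mask(shape, (row, col), radius)
        npix = int(mask.sum())
        return mask, {"escaped_pixels": npix,
                      "fraction": npix / mask.size}

    if kind == "bead_image":
        shape = p.get("shape", (128, 128))
        background = p.get("background", 5.0)
        img = np.full(shape, float(background))
        labels = np.zeros(shape, dtype=int)
        per_cell = []
        for i, (row, col, radius, intensity) in enumerate(
                p.get("cells", [(40, 40, 10, 50.0), (90, 90, 10, 80.0)]),
                start=1):
            m = _disk_mask(shape, (row, col), radius)
            labels[m] = i
            img[m] += intensity
            per_cell.append(float(intensity) * int(m.sum()))
        sigma = p.get("sigma", 0.0)
        if sigma > 0:
            img = img + rng.normal(0.0, sigma, shape)
        truth = {"per_cell_integrated": per_cell,
                 "index": float(np.mean(per_cell)),
                 "background": float(background)}
        return (img, labels), truth

    if kind == "dilution_series":
        slope = p.get("slope", PERFECT_DOUBLING_SLOPE)
        intercept = p.get("intercept", 20.0)
        x = np.asarray(p.get("log10_dilutions", [0, -1, -2, -3]), dtype=float)
        ct = intercept + slope * x
        sigma = p.get("sigma", 0.0)
        if sigma > 0:
            ct = ct + rng.normal(0.0, sigma, x.size)
        eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
        return (x, ct), {"slope": float(slope),
                         "efficiency_pct": float(eff)}

    if kind == "standard_curve":
        coeffs = np.asarray(p.get("coeffs", [-0.004, 0.35, 0.05]), dtype=float)
        conc = np.asarray(
            p.get("concentrations", [0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8]),
            dtype=float)
        signal = np.polyval(coeffs, conc)
        sigma = p.get("sigma", 0.0)
        if sigma > 0:
            signal = signal + rng.normal(0.0, sigma, conc.size)
        return (conc, signal), {"coeffs": coeffs,
                                "clean_signal": np.polyval(coeffs, conc)}

    raise ValueError(f"unknown fixture kind {kind!r}")
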