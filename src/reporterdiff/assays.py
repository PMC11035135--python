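"""Per-assay quantification formulas for the cell-function panel.

Each function implements one readout used to compare reporter-expressing
cells against GFP controls:

* T-cell activation from flow-cytometry quadrant counts,
  ``Stimulation% = CD3+CD25+ / (CD3+CD25+ + CD3+CD25−) × 100``;
* phagocytic index, background-subtracted integrated bead fluorescence
  per segmented macrophage;
* Matrigel invasion area, the escaped-cell pixel fraction scaled by the
  total imaged area (113.5 mm² for the 10×10 tile mosaic);
* viability-normalized caspase-3/7 fold change, with apoptotic signal
  divided well-wise by a viable-cell readout (ATP or MTT) before the
  case/control ratio;
* ELISA insulin concentration by inversion of a quadratic standard
  curve over its calibrated dynamic range (0.1–12.8 ng/mL by default),
  optionally normalized to total cellular protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TOTAL_IMAGED_AREA_MM2",
    "INSULIN_RANGE_NG_ML",
    "QuadrantCounts",
    "StandardCurve",
    "stimulation_pct",
    "phagocytic_index",
    "invasion_area",
    "normalized_fold",
    "fit_standard_curve",
    "insulin_concentration",
]

#: total area of the invasion-assay tile mosaic, mm²
TOTAL_IMAGED_AREA_MM2 = 113.5

#: calibrated dynamic range of the insulin ELISA, ng/mL
INSULIN_RANGE_NG_ML = (0.1, 12.8)


@dataclass
class QuadrantCounts:
    """Flow-cytometry quadrant event counts (CD3 × CD25 gating)."""

    cd3p_cd25p: int
    cd3p_cd25n: int
    cd3n_cd25p: int = 0
    cd3n_cd25n: int = 0

    def __post_init__(self) -> None:
        for v in (self.cd3p_cd25p, self.cd3p_cd25n,
                  self.cd3n_cd25p, self.cd3n_cd25n):
            if v < 0 or int(v) != v:
                raise ValueError("quadrant counts must be nonnegative integers")


def stimulation_pct(q: QuadrantCounts) -> float:
    """Percentage of CD3+ T cells that are CD25+ (activated).

    CD3− quadrants are ignored by construction.
    """
    cd3_total = q.cd3p_cd25p + q.cd3p_cd25n
    if cd3_total == 0:
        raise ValueError("no CD3+ events: stimulation undefined")
    return 100.0 * q.cd3p_cd25p / cd3_total


def phagocytic_index(bead_image: np.ndarray, cell_mask: np.ndarray,
                     n_cells: int | None = None,
                     background: str | float = "median") -> float:
    """Average integrated bead fluorescence per macrophage.

    Background (default: the median of non-cell pixels; a float gives a
    fixed level) is subtracted from the bead channel, the result summed
    over cell pixels, and divided by the number of segmented cells.
    ``cell_mask`` may be boolean (then ``n_cells`` is required) or a
    labeled integer mask (cells counted from the labels).
    """
    img = np.asarray(bead_image, dtype=float)
    mask = np.asarray(cell_mask)
    if img.shape != mask.shape:
        raise ValueError("bead image and cell mask shapes differ")
    if not mask.any():
        raise ValueError("cell mask is empty")
    if mask.dtype == bool:
        if n_cells is None or n_cells < 1:
            raise ValueError("boolean mask requires explicit n_cells >= 1")
        count = int(n_cells)
        fg = mask
    else:
        labels = np.unique(mask)
        count = int((labels != 0).sum())
        fg = mask != 0
    if background == "median":
        bg = float(np.median(img[~fg])) if (~fg).any() else 0.0
    else:
        bg = float(background)
    total = float(np.clip(img[fg] - bg, 0, None).sum())
    return total / count


def invasion_area(escaped_mask: np.ndarray,
                  total_area_mm2: float = TOTAL_IMAGED_AREA_MM2) -> float:
    """Area (mm²) occupied by cells that escaped the Matrigel drop.

    The escaped-pixel fraction of the mosaic is scaled by the total
    imaged area.
    """
    mask = np.asarray(escaped_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("escaped-cell mask must be 2-D")
    if total_area_mm2 <= 0:
        raise ValueError("total imaged area must be positive")
    return float(mask.sum() / mask.size * total_area_mm2)


def normalized_fold(case_signal: np.ndarray, control_signal: np.ndarray,
                    case_viability: np.ndarray | None = None,
                    control_viability: np.ndarray | None = None,
                    ) -> tuple[float, float]:
    """Case/control fold change of a plate readout, with s.e.m. over wells.

    When viability readouts are supplied (caspase normalization), each
    well's signal is first divided by its matched viable-cell signal;
    the fold change is then mean(case ratios)/mean(control ratios).
    Without viability the plain signal fold is returned. s.e.m. is
    propagated from the two group means in quadrature.
    """
    case = np.asarray(case_signal, dtype=float)
    ctrl = np.asarray(control_signal, dtype=float)
    if case_viability is not None or control_viability is not None:
        if case_viability is None or control_viability is None:
            raise ValueError("viability must be given for both groups")
        cv = np.asarray(case_viability, dtype=float)
        xv = np.asarray(control_viability, dtype=float)
        if cv.shape != case.shape or xv.shape != ctrl.shape:
            raise ValueError("viability wells must match signal wells")
        if (cv <= 0).any() or (xv <= 0).any():
            raise ValueError("viability signals must be positive")
        case = case / cv
        ctrl = ctrl / xv
    m0 = ctrl.mean()
    if m0 <= 0:
        raise ValueError("control group mean must be positive")
    mc = case.mean()
    fold = float(mc / m0)
    if case.size > 1 and ctrl.size > 1:
        sem_c = case.std(ddof=1) / np.sqrt(case.size)
        sem_0 = ctrl.std(ddof=1) / np.sqrt(ctrl.size)
        rel_c = sem_c / mc if mc != 0 else 0.0
        sem = abs(fold) * float(np.hypot(rel_c, sem_0 / m0))
    else:
        sem = 0.0
    return fold, sem


@dataclass
class StandardCurve:
    """Quadratic map concentration → signal, valid on a stated range."""

    coeffs: np.ndarray                  # highest power first (numpy.polyval)
    conc_range: tuple[float, float] = INSULIN_RANGE_NG_ML

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != 3:
            raise ValueError("standard curve must be quadratic")
        lo, hi = self.conc_range
        if not lo < hi:
            raise ValueError("invalid concentration range")
        # strict monotonicity over the valid range: derivative 2ac + b
        a, b, _ = self.coeffs
        d_lo, d_hi = 2 * a * lo + b, 2 * a * hi + b
        if d_lo * d_hi <= 0 or d_lo == 0:
            raise ValueError(
                "fitted standard curve is not monotone over its range")

    def signal(self, conc: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(self.coeffs, conc)

    @property
    def signal_range(self) -> tuple[float, float]:
        s = sorted(self.signal(np.array(self.conc_range)))
        return float(s[0]), float(s[1])

    def invert(self, signal: float) -> float:
        """Concentration giving ``signal``; error outside calibration."""
        lo, hi = self.signal_range
        if not lo <= signal <= hi:
            raise ValueError(
                f"signal {signal:g} outside calibrated range [{lo:g}, {hi:g}]; "
                "refusing to extrapolate")
        a, b, c = self.coeffs
        roots = np.roots([a, b, c - signal])
        real = roots[np.isreal(roots)].real
        tol = 1e-9 * max(1.0, abs(self.conc_range[1]))
        in_range = [r for r in real
                    if self.conc_range[0] - tol <= r <= self.conc_range[1] + tol]
        if not in_range:
            raise ValueError("no root of the standard curve in the valid range")
        if len(in_range) > 1 and abs(in_range[0] - in_range[1]) > tol:
            raise ValueError("ambiguous inversion: two in-range roots")
        return float(np.clip(in_range[0], *self.conc_range))


def fit_standard_curve(concentrations: np.ndarray, signals: np.ndarray,
                       conc_range: tuple[float, float] | None = None,
                       ) -> StandardCurve:
    """Least-squares quadratic of signal on concentration."""
    c = np.asarray(concentrations, dtype=float)
    s = np.asarray(signals, dtype=float)
    if c.size < 3 or c.size != s.size:
        raise ValueError("need >=3 matched standard points")
    coeffs = np.polyfit(c, s, 2)
    if conc_range is None:
        conc_range = (float(c.min()), float(c.max()))
    return StandardCurve(coeffs, conc_range)


def insulin_concentration(curve: StandardCurve,
                          measured_signals: np.ndarray,
                          total_protein: float | None = None,
                          ) -> np.ndarray:
    """Invert measured ELISA signals to ng/mL insulin.

    With ``total_protein`` (µg) the concentrations are divided by it,
    giving protein-normalized secretion (ng/mL per µg protein).
    """
    sig = np.atleast_1d(np.asarray(measured_signals, dtype=float))
    conc = np.array([curve.invert(v) for v in sig])
    if total_protein is not None:
        if total_protein <= 0:
            raise ValueError("total protein must be positive")
        conc = conc / total_protein
    return conc
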