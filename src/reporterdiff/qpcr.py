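"""Relative expression analysis by the 2^(−ΔΔCt) method.

Quantitative RT-PCR reports, per well, the cycle threshold Ct at which
amplification crosses a fixed fluorescence level. With near-100%
amplification efficiency each cycle doubles the template, so expression
differences map linearly onto Ct differences:

    ΔCt  = Ct(target) − Ct(housekeeping)           per sample
    ΔΔCt = mean ΔCt(case) − mean ΔCt(control)
    fold = 2^(−ΔΔCt)

Technical replicate Ct values within a sample are averaged before ΔCt;
dispersion and significance are assessed across biological samples
only, by a two-sample t-test on the per-sample ΔCt values (Student by
default, Welch by flag; one-sided where the direction of the effect is
known a priori, as for an ER-stress induction).

Primer efficiency is audited from a serial-dilution series: the OLS
slope of Ct on log10(dilution) converts to efficiency
``E = (10^(−1/slope) − 1) × 100``; a perfect-doubling primer gives a
slope of −1/log10(2) ≈ −3.3219 cycles per decade, i.e. 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PERFECT_DOUBLING_SLOPE",
    "CtTable",
    "FoldChangeResult",
    "EfficiencyResult",
    "relative_expression",
    "primer_efficiency",
    "ddct_test",
    "delta_ct_per_sample",
]

#: Ct-vs-log10(dilution) slope of a perfectly doubling primer pair
PERFECT_DOUBLING_SLOPE = -1.0 / np.log10(2.0)

REQUIRED_COLUMNS = {"sample", "group", "gene", "role", "ct"}


@dataclass
class CtTable:
    """Long-format Ct table: one row per technical replicate well.

    Columns: ``sample`` (biological sample id), ``group`` (e.g. Aqp1 /
    GFP or treated / vehicle), ``gene``, ``role`` (``target`` |
    ``housekeeping``), ``ct`` (cycles). Every sample must carry a
    housekeeping entry.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = REQUIRED_COLUMNS - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValueError("all Ct values must be finite and positive")
        for sample, sub in self.data.groupby("sample"):
            if not (sub["role"] == "housekeeping").any():
                raise ValueError(f"sample {sample!r} has no housekeeping gene")

    @classmethod
    def from_csv(cls, path) -> "CtTable":
        """Read a table; wide replicate columns ct_rep1..N are melted."""
        df = pd.read_csv(path)
        rep_cols = [c for c in df.columns if c.startswith("ct_rep")]
        if rep_cols:
            df = df.melt(
                id_vars=[c for c in df.columns if c not in rep_cols],
                value_vars=rep_cols, value_name="ct").drop(columns="variable")
        return cls(df)


@dataclass
class FoldChangeResult:
    gene: str
    ddct: float
    fold: float
    sem_ddct: float
    p_value: float
    sided: str
    sem_fold: float = np.nan   # s.e.m. of per-sample folds, labeled separately


@dataclass
class EfficiencyResult:
    slope: float
    intercept: float
    efficiency_pct: float
    r_squared: float
    valid: bool
    note: str = ""


def delta_ct_per_sample(table: CtTable, target_gene: str,
                        group: str) -> pd.Series:
    """Per-sample ΔCt = mean Ct(target) − mean Ct(housekeeping)."""
    sub = table.data[table.data["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} not present in table")
    tgt = sub[(sub["gene"] == target_gene) & (sub["role"] == "target")]
    if tgt.empty:
        raise ValueError(f"target gene {target_gene!r} absent from group {group!r}")
    hk = sub[sub["role"] == "housekeeping"]
    tgt_means = tgt.groupby("sample")["ct"].mean()
    hk_means = hk.groupby("sample")["ct"].mean()
    missing = set(tgt_means.index) - set(hk_means.index)
    if missing:
        raise ValueError(
            f"sample {sorted(missing)[0]!r} lacks a housekeeping measurement")
    return tgt_means - hk_means.loc[tgt_means.index]


def relative_expression(table: CtTable, target_gene: str, case_group: str,
                        control_group: str, sided: str = "two",
                        welch: bool = False) -> FoldChangeResult:
    """Fold change of a target gene in case vs control by 2^(−ΔΔCt).

    ΔΔCt is the difference of group-mean ΔCt values; its s.e.m. combines
    the two groups' per-sample ΔCt s.e.m.s in quadrature. The p-value
    comes from :func:`ddct_test` on the same per-sample ΔCt values.
    ``sem_fold`` additionally reports the s.e.m. of per-sample folds
    ``2^(−(ΔCt − mean ΔCt(control)))``, a common alternative error bar.
    """
    dct_case = delta_ct_per_sample(table, target_gene, case_group)
    dct_ctrl = delta_ct_per_sample(table, target_gene, control_group)
    ddct = float(dct_case.mean() - dct_ctrl.mean())
    fold = float(2.0 ** (-ddct))

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    sem_ddct = float(np.hypot(_sem(dct_case), _sem(dct_ctrl)))
    per_sample_fold = 2.0 ** (-(dct_case - dct_ctrl.mean()))
    sem_fold = _sem(per_sample_fold)

    if len(dct_case) >= 2 and len(dct_ctrl) >= 2:
        p = ddct_test(table, target_gene, case_group, control_group,
                      sided=sided, welch=welch)
    else:
        p = np.nan
    return FoldChangeResult(target_gene, ddct, fold, sem_ddct, p, sided,
                            sem_fold)


def ddct_test(table: CtTable, target_gene: str, case_group: str,
              control_group: str, sided: str = "two",
              welch: bool = False) -> float:
    """t-test on per-sample ΔCt between two groups.

    Student's equal-variance t by default; ``welch=True`` drops the
    equal-variance assumption. ``sided="one"`` halves the p-value when
    the case-group ΔCt is lower (expression up), as appropriate when the
    direction of the effect is known in advance.
    """
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    x = delta_ct_per_sample(table, target_gene, case_group)
    y = delta_ct_per_sample(table, target_gene, control_group)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 biological samples per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate noiseless data: identical means carry no evidence
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    if sided == "one":
        p = p / 2 if t < 0 else 1 - p / 2
    return float(p)


def primer_efficiency(log10_dilution: np.ndarray,
                      ct: np.ndarray) -> EfficiencyResult:
    """Amplification efficiency from a serial-dilution Ct series.

    OLS of Ct on log10(dilution factor; 1 = undiluted). The expected
    slope is negative (more template amplifies earlier); a nonnegative
    slope yields a result flagged invalid with a diagnostic note rather
    than a silent number.
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >=3 matched (dilution, Ct) points")
    if np.unique(x).size < 2:
        raise ValueError("dilutions are degenerate")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    if slope >= 0:
        return EfficiencyResult(slope, intercept, np.nan, r2, valid=False,
                                note="nonnegative slope: Ct should decrease "
                                     "with template concentration")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyResult(slope, intercept, float(eff), r2, valid=True)
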