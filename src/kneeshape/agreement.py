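"""Method-comparison statistics for paired measurements from two modalities.

Implements the classic Bland-Altman analysis (bias = mean of paired
differences, limits of agreement = bias +/- 1.96 SD with large-sample
confidence intervals), Lin's concordance correlation coefficient, simple
linear-regression R^2, and the smallest detectable difference (SDD) from
test-retest pairs.  Differences are always taken as MR minus CT.

Formulas
--------
bias     = mean(d),   d_i = x_i - y_i
LOA      = bias +/- z * SD(d)            (z = 1.96 by default)
CI(bias) = bias +/- z * SD(d) / sqrt(n)
CI(LOA)  = LOA  +/- z * SD(d) * sqrt(3/n)     (large-sample approximation)
CCC      = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2),
           population (1/n) moments
SDD      = z * SD(test - retest),         SD with n-1 denominator
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedMeasures",
    "AgreementSummary",
    "TestRetestSummary",
    "bland_altman",
    "lin_ccc",
    "r_squared",
    "sdd",
    "summarize_table",
    "TABLE_ORDER",
]

Z_DEFAULT = 1.96

# canonical report order: femur shape, tibia shape, areas, joint-space width
TABLE_ORDER = (
    "B-score", "z-score",
    "MF.tAB", "LF.tAB", "MT.tAB", "LT.tAB", "TrFMed.tAB", "TrFLat.tAB",
    "Medial 3DJSW", "Lateral 3DJSW",
)

UNITS = {
    "B-score": "", "z-score": "",
    "MF.tAB": "mm^2", "LF.tAB": "mm^2", "MT.tAB": "mm^2", "LT.tAB": "mm^2",
    "TrFMed.tAB": "mm^2", "TrFLat.tAB": "mm^2",
    "Medial 3DJSW": "mm", "Lateral 3DJSW": "mm",
}


@dataclass
class PairedMeasures:
    """Aligned MR/CT value vectors for one measure, matched pair-by-pair."""

    measure: str
    x_mr: np.ndarray
    x_ct: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.x_mr = np.asarray(self.x_mr, dtype=float)
        self.x_ct = np.asarray(self.x_ct, dtype=float)
        if self.x_mr.shape != self.x_ct.shape or self.x_mr.ndim != 1:
            raise ValueError("x_mr and x_ct must be 1-D and the same length")

    @property
    def n(self) -> int:
        return len(self.x_mr)

    @property
    def differences(self) -> np.ndarray:
        return self.x_mr - self.x_ct


@dataclass
class AgreementSummary:
    """One row of the cross-modality comparison table."""

    measure: str
    n: int
    bias: float
    bias_ci: tuple
    loa_lower: float
    loa_lower_ci: tuple
    loa_upper: float
    loa_upper_ci: tuple
    r2: Optional[float] = None
    ccc: Optional[float] = None
    units: str = ""
    degenerate: bool = False   # zero difference variance: LOA collapse onto bias


@dataclass
class TestRetestSummary:
    measure: str
    sdd: float
    sd_differences: float
    n_pairs: int


def bland_altman(p: PairedMeasures, z: float = Z_DEFAULT) -> AgreementSummary:
    """Bias and limits of agreement (MR minus CT) with large-sample CIs.

    LOA are symmetric about the bias by construction:
    upper - bias = bias - lower for every input.
    """
    if p.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = p.differences
    bias = float(d.mean())
    s = float(d.std(ddof=1))
    half = z * s
    ci_b = z * s / np.sqrt(p.n)
    ci_l = z * s * np.sqrt(3.0 / p.n)
    return AgreementSummary(
        measure=p.measure, n=p.n, bias=bias,
        bias_ci=(bias - ci_b, bias + ci_b),
        loa_lower=bias - half, loa_lower_ci=(bias - half - ci_l, bias - half + ci_l),
        loa_upper=bias + half, loa_upper_ci=(bias + half - ci_l, bias + half + ci_l),
        units=p.units, degenerate=(s == 0.0),
    )


def lin_ccc(p: PairedMeasures) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    if p.n < 2:
        raise ValueError("CCC needs at least 2 pairs")
    x, y = p.x_mr, p.x_ct
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("both vectors are constant; CCC undefined")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def r_squared(p: PairedMeasures) -> float:
    """Squared Pearson correlation (the simple-regression R^2)."""
    if p.n < 3:
        raise ValueError("R^2 needs at least 3 pairs")
    x, y = p.x_mr, p.x_ct
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector; correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def sdd(test: Sequence[float], retest: Sequence[float],
        measure: str = "", z: float = Z_DEFAULT) -> TestRetestSummary:
    """Smallest detectable difference from test-retest pairs: z * SD(diff).

    The smallest change in the measure distinguishable from test-retest
    noise.  Symmetric in its arguments up to the sign of the differences.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape or test.ndim != 1:
        raise ValueError("test and retest must be 1-D and the same length")
    if len(test) < 2:
        raise ValueError("SDD needs at least 2 pairs")
    s = float((test - retest).std(ddof=1))
    return TestRetestSummary(measure, z * s, s, len(test))


def summarize_table(pairs: Dict[str, PairedMeasures],
                    z: float = Z_DEFAULT) -> pd.DataFrame:
    """One agreement row per measure, in the canonical report order.

    Columns: measure, n, bias and CI, lower/upper LOA and CIs, r2, ccc,
    units.  R^2/CCC are left NaN for degenerate (zero-variance) inputs.
    """
    rows = []
    ordered = [m for m in TABLE_ORDER if m in pairs]
    ordered += [m for m in pairs if m not in TABLE_ORDER]
    for name in ordered:
        p = pairs[name]
        ba = bland_altman(p, z=z)
        try:
            ba.ccc = lin_ccc(p)
        except ValueError:
            ba.ccc = np.nan
        try:
            ba.r2 = r_squared(p)
        except ValueError:
            ba.r2 = np.nan
        rows.append({
            "measure": name, "n": ba.n, "bias": ba.bias,
            "bias_ci_lo": ba.bias_ci[0], "bias_ci_hi": ba.bias_ci[1],
            "loa_lo": ba.loa_lower,
            "loa_lo_ci_lo": ba.loa_lower_ci[0], "loa_lo_ci_hi": ba.loa_lower_ci[1],
            "loa_hi": ba.loa_upper,
            "loa_hi_ci_lo": ba.loa_upper_ci[0], "loa_hi_ci_hi": ba.loa_upper_ci[1],
            "r2": ba.r2, "ccc": ba.ccc,
            "units": p.units or UNITS.get(name, ""),
            "degenerate": ba.degenerate,
        })
    return pd.DataFrame(rows)


def render_table(table: pd.DataFrame) -> str:
    """Human-readable rendering of an agreement table (3-decimal style)."""
    lines = [f"{'measure':<14} {'bias [95% CI]':<28} "
             f"{'LOA lower':>10} {'LOA upper':>10} {'R^2':>7} {'CCC':>7} {'n':>5}"]
    for _, r in table.iterrows():
        lines.append(
            f"{r['measure']:<14} "
            f"{r['bias']:7.3f} [{r['bias_ci_lo']:7.3f}, {r['bias_ci_hi']:7.3f}]  "
            f"{r['loa_lo']:10.3f} {r['loa_hi']:10.3f} "
            f"{r['r2']:7.3f} {r['ccc']:7.3f} {int(r['n']):5d}")
    return "\n".join(lines)
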