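"""Agreement statistics: Sørensen-Dice, Pearson r, single-score ICC, mean
absolute differences.

These are the evaluation statistics used to compare segmentations and torsion
measurements between readers (human or algorithmic):

* the Sørensen-Dice coefficient ``2|A∩B| / (|A|+|B|)`` per bone class,
* Pearson's product-moment correlation with its t-test p-value,
* the single-score intraclass correlation coefficient, interpreted as the
  two-way random-effects, absolute-agreement, single-rater ICC (a one-line
  flag switches to the consistency variant), with its 95% CI from the
  F-distribution bounds,
* the mean absolute difference with a t-based 95% CI.

Degenerate inputs (zero variance) yield NaN with an explicit flag rather
than an exception, so batch evaluations do not abort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume import CLASS_NAMES, LabelMask

__all__ = [
    "dice_coefficient", "dice_per_class", "pearson_r", "icc_single",
    "mean_abs_difference", "AgreementReport", "compare_angle_tables",
]


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen-Dice overlap of two binary masks; two empty masks count as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def dice_per_class(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray,
                   classes: Sequence[int] = (1, 2, 3)) -> dict[str, float]:
    """Dice per bone class for two aligned label masks."""
    da = a.data if isinstance(a, LabelMask) else np.asarray(a)
    db = b.data if isinstance(b, LabelMask) else np.asarray(b)
    return {CLASS_NAMES[c]: dice_coefficient(da == c, db == c) for c in classes}


@dataclass
class StatResult:
    value: float
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"value": None if not np.isfinite(self.value) else float(self.value)}
        if self.ci95 is not None:
            out["ci95"] = [float(v) for v in self.ci95]
        if self.p_value is not None:
            out["p_value"] = float(self.p_value)
        if self.flags:
            out["flags"] = list(self.flags)
        return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Product-moment correlation with p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_r expects two equal-length 1D vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return StatResult(np.nan, p_value=np.nan,
                          flags=["undefined: zero variance in at least one vector"])
    r, p = stats.pearsonr(x, y)
    return StatResult(float(r), p_value=float(p))


def icc_single(table: np.ndarray | pd.DataFrame, *,
               consistency: bool = False) -> StatResult:
    """Single-rater ICC for an ``n subjects x k readers`` table of ratings.

    Default is the two-way random-effects absolute-agreement single-score
    ICC (ICC(2,1)); ``consistency=True`` yields ICC(3,1).  The 95% CI comes
    from the standard F-distribution bounds.  Zero total variance is flagged.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("ratings table must be n>=2 subjects x k>=2 readers")
    if np.isnan(arr).any():
        raise ValueError("ratings table must not contain missing cells")
    if np.allclose(arr, arr.flat[0]):
        return StatResult(np.nan, flags=["undefined: zero total variance"])
    n, k = arr.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "reader": np.tile(np.arange(k), n),
        "rating": arr.ravel(),
    })
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=long, targets="subject", raters="reader",
                                 ratings="rating")
    # pingouin labels the two-way single-score ICCs "ICC(A,1)" (absolute
    # agreement, i.e. ICC(2,1)) and "ICC(C,1)" (consistency, ICC(3,1))
    wanted = "ICC(C,1)" if consistency else "ICC(A,1)"
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    row = res[res["Type"] == wanted].iloc[0]
    icc = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    flags = []
    if not np.isfinite(icc):
        flags.append("undefined: degenerate variance decomposition")
    elif abs(icc) < 1e-10:
        flags.append("no between-subject variance to agree on")
    return StatResult(icc, ci95=(lo, hi), flags=flags)


def mean_abs_difference(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Mean of |x_i - y_i| with a t-distribution 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("mean_abs_difference expects two equal-length vectors, n >= 2")
    d = np.abs(x - y)
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return StatResult(m, ci95=(m, m))
    half = stats.t.ppf(0.975, len(d) - 1) * sd / np.sqrt(len(d))
    return StatResult(m, ci95=(m - half, m + half))


@dataclass
class AgreementReport:
    """Bundle of agreement statistics between two readers."""

    dice: dict[str, float] | None = None
    femoral: dict[str, StatResult] | None = None
    tibial: dict[str, StatResult] | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.dice is not None:
            out["dice"] = {k: float(v) for k, v in self.dice.items()}
        for name, block in (("femoral_torsion", self.femoral),
                            ("tibial_torsion", self.tibial)):
            if block is not None:
                out[name] = {k: v.to_dict() for k, v in block.items()}
        return out


def compare_angle_tables(a: pd.DataFrame, b: pd.DataFrame) -> AgreementReport:
    """Agreement between two per-limb angle tables.

    Tables need ``femoral_torsion_deg`` and ``tibial_torsion_deg`` columns in
    matching row order (one row per limb).
    """
    report = AgreementReport(femoral={}, tibial={})
    for col, block in (("femoral_torsion_deg", report.femoral),
                       ("tibial_torsion_deg", report.tibial)):
        x = a[col].to_numpy(dtype=float)
        y = b[col].to_numpy(dtype=float)
        block["pearson_r"] = pearson_r(x, y)
        block["icc"] = icc_single(np.column_stack([x, y]))
        block["mean_abs_difference"] = mean_abs_difference(x, y)
    return report
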