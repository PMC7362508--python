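"""Observer-agreement and association statistics for per-slice fat volumes.

Implements the variability workflow for threshold-based epicardial fat
volumetry: Bland-Altman differences with 1.96-SD limits of agreement,
per-slice measurement error in ml and in percent of the patient total,
intraclass correlation with the conventional poor/moderate/good/excellent
categories (cut points 0.5, 0.75, 0.9), BSA-indexed fat volume versus BMI
regression, and paired t / Wilcoxon signed-rank comparisons at P < 0.05.

Measurement tables are tidy DataFrames with one row per
(patient, method, observer, repeat, slice) and a ``volume_ml`` column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OBSERVER_COLUMNS",
    "AgreementResult",
    "RegressionResult",
    "ComparisonResult",
    "validate_observer_table",
    "bland_altman",
    "percent_error",
    "icc",
    "interpret_icc",
    "bsa",
    "regress_bmi",
    "paired_compare",
    "pair_measurements",
    "agreement_analysis",
    "P_THRESHOLD",
]

#: significance threshold for all tests
P_THRESHOLD = 0.05

#: required columns of a tidy observer measurement table
OBSERVER_COLUMNS = ("patient", "method", "observer", "repeat", "slice",
                    "volume_ml")


@dataclass
class AgreementResult:
    """Bland-Altman / ICC summary of paired per-slice measurements."""

    mean_diff_ml: float
    sd_diff_ml: float
    loa_low: float
    loa_high: float
    n_pairs: int
    mean_diff_pct: float | None = None
    sd_diff_pct: float | None = None
    icc: float | None = None
    icc_category: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float


class ComparisonResult(NamedTuple):
    p_value: float
    significant: bool


def validate_observer_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBSERVER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"observer table missing columns: {missing}")
    if (table["volume_ml"] < 0).any():
        raise ValueError("volumes must be >= 0")
    return table


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Mean and sample SD of the paired differences ``x - y`` (first
    observation minus second) with limits of agreement at +/- 1.96 SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(mean_diff_ml=mean, sd_diff_ml=sd,
                           loa_low=mean - 1.96 * sd,
                           loa_high=mean + 1.96 * sd,
                           n_pairs=int(x.size))


def percent_error(diff_ml: Sequence[float],
                  patient_totals_ml: Sequence[float]) -> np.ndarray:
    """Per-slice differences as percentages of each slice's patient total
    fat volume (the mean total of the two measurements), elementwise."""
    diff = np.asarray(diff_ml, dtype=float)
    totals = np.asarray(patient_totals_ml, dtype=float)
    if diff.shape != totals.shape:
        raise ValueError("diff_ml and patient_totals_ml must align per slice")
    if np.any(totals <= 0):
        raise ValueError("patient totals must be > 0")
    return 100.0 * diff / totals


def icc(ratings: np.ndarray | pd.DataFrame,
        model: Literal["icc2", "icc3"] = "icc2") -> float:
    """Single-measures intraclass correlation of an (n targets x k raters)
    table.

    ``icc2`` is the two-way random-effects absolute-agreement form
    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n),
    the standard choice for observer-agreement studies; ``icc3`` is the
    two-way mixed consistency form ICC(3,1).  Computed via pingouin's
    ANOVA-based estimator.  A table with zero total variance returns 1.0
    by convention (with a warning).
    """
    vals = np.asarray(ratings, dtype=float)
    if vals.ndim != 2 or vals.shape[1] < 2:
        raise ValueError("ratings must be 2D with >= 2 raters (columns)")
    n, k = vals.shape
    if n < 3:
        raise ValueError("need at least 3 paired rows")
    if np.isnan(vals).any():
        raise ValueError("ratings contain missing cells")
    if np.ptp(vals) == 0:
        warnings.warn("all ratings identical; ICC is 1 by convention",
                      stacklevel=2)
        return 1.0

    import pingouin as pg

    long = pd.DataFrame({
        "target": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": vals.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=long, targets="target", raters="rater",
                                 ratings="score")
    # pingouin labels: ICC(A,1) = two-way random absolute agreement
    # (= ICC(2,1)); ICC(C,1) = two-way mixed consistency (= ICC(3,1))
    types = res.set_index("Type")["ICC"]
    if model == "icc2":
        value = types.get("ICC(A,1)", types.get("ICC2"))
    else:
        value = types.get("ICC(C,1)", types.get("ICC3"))
    # guard against ulp-level excursions outside the admissible range
    return float(np.clip(value, -1.0, 1.0))


def interpret_icc(value: float) -> str:
    """Conventional reliability category: poor < 0.5 <= moderate < 0.75
    <= good < 0.9 <= excellent (upper class wins at the boundaries)."""
    if not -1.0 <= value <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"


def bsa(height_cm: float, weight_kg: float,
        formula: Literal["mosteller", "dubois"] = "mosteller") -> float:
    """Body surface area in m^2.

    Mosteller: sqrt(height * weight / 3600); Du Bois:
    0.007184 * height^0.725 * weight^0.425.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    if formula == "dubois":
        return float(0.007184 * height_cm ** 0.725 * weight_kg ** 0.425)
    raise ValueError(f"unknown BSA formula: {formula!r}")


def regress_bmi(fat_index_ml_per_m2: Sequence[float],
                bmi: Sequence[float]) -> RegressionResult:
    """OLS of BSA-indexed fat volume on BMI with R^2 and the two-sided
    slope p-value (t distribution, n-2 df)."""
    y = np.asarray(fat_index_ml_per_m2, dtype=float)
    x = np.asarray(bmi, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need >= 3 paired (fat index, BMI) observations")
    if np.ptp(x) == 0:
        raise ValueError("BMI is constant; slope undefined")
    res = sps.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=r2, p_value=p)


def paired_compare(a: Sequence[float], b: Sequence[float],
                   kind: Literal["t", "wilcoxon"] = "t") -> ComparisonResult:
    """Two-sided paired comparison with a significance flag at P < 0.05.

    ``t`` is the paired t-test (all-zero differences return p = 1 by
    convention); ``wilcoxon`` the signed-rank test (exact for small n
    without ties) which rejects all-zero differences as degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D of equal length")
    diff = a - b
    if kind == "t":
        if a.size < 2:
            raise ValueError("t-test needs n >= 2 pairs")
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(sps.ttest_rel(a, b).pvalue)
    elif kind == "wilcoxon":
        if np.all(diff == 0):
            raise ValueError("all differences zero; signed-rank undefined")
        p = float(sps.wilcoxon(a, b).pvalue)
    else:
        raise ValueError(f"unknown test kind: {kind!r}")
    return ComparisonResult(p_value=p, significant=bool(p < P_THRESHOLD))


# ---------------------------------------------------------------------------
# observer-table plumbing

def pair_measurements(table: pd.DataFrame, method: str,
                      mode: Literal["intra", "inter"],
                      ) -> pd.DataFrame:
    """Extract the paired per-slice volumes for one method.

    ``intra``: repeat 1 vs repeat 2 of the first observer; ``inter``:
    observer 1 vs observer 2 at repeat 1.  Returns a frame with columns
    (patient, slice, first, second), one row per (patient, slice).
    """
    validate_observer_table(table)
    sub = table[table["method"] == method]
    if mode == "intra":
        obs = sorted(sub["observer"].unique())[0]
        sub = sub[sub["observer"] == obs]
        key = "repeat"
    elif mode == "inter":
        rep = sorted(sub["repeat"].unique())[0]
        sub = sub[sub["repeat"] == rep]
        key = "observer"
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    levels = sorted(sub[key].unique())
    if len(levels) < 2:
        raise ValueError(f"need two {key} levels for {mode}-observer analysis")
    wide = sub.pivot_table(index=["patient", "slice"], columns=key,
                           values="volume_ml", aggfunc="first")
    wide = wide[[levels[0], levels[1]]].dropna()
    if wide.empty:
        raise ValueError("no complete (patient, slice) pairs")
    out = wide.reset_index()
    out.columns = ["patient", "slice", "first", "second"]
    return out


def agreement_analysis(table: pd.DataFrame, method: str,
                       mode: Literal["intra", "inter"],
                       icc_model: Literal["icc2", "icc3"] = "icc2",
                       ) -> AgreementResult:
    """Full per-slice agreement summary for one method and comparison:
    Bland-Altman in ml, percent error against the per-patient mean total
    of the two measurements, and the categorized ICC."""
    pairs = pair_measurements(table, method, mode)
    res = bland_altman(pairs["first"].to_numpy(), pairs["second"].to_numpy())

    per_patient_total = pairs.groupby("patient")[["first", "second"]].sum()
    mean_total = per_patient_total.mean(axis=1)
    totals = pairs["patient"].map(mean_total).to_numpy()
    pct = percent_error(
        pairs["first"].to_numpy() - pairs["second"].to_numpy(), totals)
    res.mean_diff_pct = float(pct.mean())
    res.sd_diff_pct = float(pct.std(ddof=1))

    res.icc = icc(pairs[["first", "second"]].to_numpy(), model=icc_model)
    res.icc_category = interpret_icc(res.icc)
    return res
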