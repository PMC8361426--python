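"""Cohort-level statistics: validation, summaries and Pearson correlations.

The correlation battery mirrors the study's bivariate analysis: Pearson's
r with a two-sided p from the exact t transform, computed per variable
pair on pairwise-complete cases.  No multiplicity correction is applied to
the per-pair p values (matching the reported analysis); a
Benjamini–Hochberg column is emitted alongside for the reader's judgement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cordbold.datasets import MJOA_SUBSCALE_MAXIMA, MJOA_TOTAL_MAX

__all__ = [
    "AssociationResult",
    "validate_cohort",
    "cohort_summary",
    "pearson",
    "correlation_battery",
    "default_battery_pairs",
]


@dataclass(frozen=True)
class AssociationResult:
    variable_x: str
    variable_y: str
    r: float
    p: float
    n: int


def validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Check mJOA subscore consistency; returns a per-record report.

    Flags any record whose subscores exceed their maxima (upper motor 5,
    lower motor 7, upper sensory 3, bladder 3) or whose total differs from
    the subscore sum. The report has one row per record with boolean
    ``valid`` and a semicolon-joined ``problems`` column.
    """
    problems = []
    sub_cols = list(MJOA_SUBSCALE_MAXIMA)
    for _, row in records.iterrows():
        errs = []
        for col, mx in MJOA_SUBSCALE_MAXIMA.items():
            if col in row and not 0 <= row[col] <= mx:
                errs.append(f"{col}={row[col]} outside 0–{mx}")
        if all(c in row for c in sub_cols) and "mjoa_total" in row:
            s = sum(row[c] for c in sub_cols)
            if s != row["mjoa_total"]:
                errs.append(f"subscores sum to {s}, total is {row['mjoa_total']}")
            if not 0 <= row["mjoa_total"] <= MJOA_TOTAL_MAX:
                errs.append(f"total {row['mjoa_total']} outside 0–{MJOA_TOTAL_MAX}")
        problems.append("; ".join(errs))
    report = pd.DataFrame(
        {
            "case_id": records.get("case_id", pd.RangeIndex(1, len(records) + 1)),
            "valid": [p == "" for p in problems],
            "problems": problems,
        }
    )
    return report


def cohort_summary(records: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-variable mean, sample SD (n−1), min and max over numeric columns."""
    if len(records) < 2:
        raise ValueError("summary needs >= 2 records")
    num = records.select_dtypes("number")
    if columns is not None:
        num = num[columns]
    num = num.drop(columns=[c for c in ("case_id",) if c in num.columns])
    return pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "min": num.min(),
            "max": num.max(),
            "n": num.count(),
        }
    )


def pearson(x, y) -> AssociationResult:
    """Pearson's r with a two-sided p from t = r √((n−2)/(1−r²)).

    Missing values are dropped pairwise; constant input is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"Pearson correlation needs n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(variable_x="x", variable_y="y", r=float(r), p=float(p), n=n)


def default_battery_pairs(columns) -> list[tuple[str, str]]:
    """The study's hypothesis pairs present in a cohort table.

    Compression volume against every activation metric, mJOA against
    compression and against cortical percent-BOLD metrics, and symptom
    duration against every activation metric.
    """
    cols = list(columns)
    activation = [c for c in cols if "percent_bold" in c or "voa" in c]
    pairs: list[tuple[str, str]] = []
    if "compression_volume" in cols:
        pairs += [("compression_volume", a) for a in activation]
        if "mjoa_total" in cols:
            pairs.append(("compression_volume", "mjoa_total"))
        elif "mjoa" in cols:
            pairs.append(("compression_volume", "mjoa"))
    mjoa = "mjoa_total" if "mjoa_total" in cols else ("mjoa" if "mjoa" in cols else None)
    if mjoa:
        pairs += [(mjoa, a) for a in activation if "percent_bold" in a]
    if "duration_months" in cols:
        pairs += [("duration_months", a) for a in activation]
    return pairs


def correlation_battery(
    cohort: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """One Pearson test per variable pair, with a BH-adjusted column.

    Returns columns ``x, y, r, p, n, p_bh``; per-pair p values are
    uncorrected (the battery's fidelity target), ``p_bh`` is the
    Benjamini–Hochberg adjusted value emitted for transparency.
    """
    if pairs is None:
        pairs = default_battery_pairs(cohort.columns)
    if not pairs:
        raise ValueError("no variable pairs to test")
    unknown = sorted({v for pair in pairs for v in pair} - set(cohort.columns))
    if unknown:
        raise ValueError(f"unknown variables in battery: {unknown}")
    rows = []
    for x, y in pairs:
        try:
            res = pearson(cohort[x], cohort[y])
            rows.append({"x": x, "y": y, "r": res.r, "p": res.p, "n": res.n, "flag": ""})
        except ValueError as err:
            rows.append(
                {"x": x, "y": y, "r": np.nan, "p": np.nan, "n": 0, "flag": str(err)}
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
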