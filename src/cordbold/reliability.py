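"""Intraclass correlation (ICC) for rater reliability.

Inter-rater agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measurement — computed from the two-way mean squares:

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E) / n)

with MS_R the between-subject, MS_C the between-rater and MS_E the
residual mean squares, n subjects and k raters.  Intra-rater reliability
uses the one-way random-effects single-measurement form ICC(1,1) over one
rater's repeats:

    ICC(1,1) = (MS_B − MS_W) / (MS_B + (k−1) MS_W)

Negative estimates are reported as computed (flagged), never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ICCResult", "icc_inter", "icc_intra", "validate_rater_table"]

REQUIRED_COLUMNS = ("subject_id", "rater_id", "repeat", "value_mm3")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model_label: str
    variance_components: dict
    n_subjects: int
    n_ratings: int
    negative_estimate: bool = False


def validate_rater_table(table: pd.DataFrame) -> None:
    """Require the documented columns and a fully balanced design."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"rater table missing columns: {missing_cols}")
    counts = table.groupby(["subject_id", "rater_id"], sort=False)["repeat"].count()
    full = pd.MultiIndex.from_product(
        [table["subject_id"].unique(), table["rater_id"].unique()],
        names=["subject_id", "rater_id"],
    )
    counts = counts.reindex(full, fill_value=0)
    if counts.nunique() != 1:
        low = counts[counts < counts.max()]
        raise ValueError(
            "unbalanced rater table; incomplete subject × rater cells: "
            + ", ".join(f"{s}/{r} ({c} repeats)" for (s, r), c in low.items())
        )


def _two_way_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Mean squares of a subjects × raters table (one observation per cell)."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_inter(table: pd.DataFrame, summarize_repeats: str = "mean") -> ICCResult:
    """Inter-rater ICC(2,1) on a balanced subject × rater table.

    With ``summarize_repeats='mean'`` each rater's repeats are averaged
    per subject first (the study design took three repeats per rater);
    ``'all'`` treats every (rater, repeat) pair as a separate column.
    """
    validate_rater_table(table)
    if summarize_repeats not in ("mean", "all"):
        raise ValueError("summarize_repeats must be 'mean' or 'all'")
    if table["rater_id"].nunique() < 2:
        raise ValueError("inter-rater ICC needs >= 2 raters")
    if table["subject_id"].nunique() < 2:
        raise ValueError("inter-rater ICC needs >= 2 subjects")

    if summarize_repeats == "mean":
        wide = table.pivot_table(
            index="subject_id", columns="rater_id", values="value_mm3", aggfunc="mean"
        )
    else:
        tbl = table.assign(col=table["rater_id"].astype(str) + "/" + table["repeat"].astype(str))
        wide = tbl.pivot(index="subject_id", columns="col", values="value_mm3")
    values = wide.to_numpy(dtype=float)
    n, k = values.shape

    ms_r, ms_c, ms_e = _two_way_mean_squares(values)
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom <= 0 or np.ptp(values) == 0:
        raise ValueError("total variance is zero; ICC undefined")
    icc = (ms_r - ms_e) / denom
    return ICCResult(
        icc=float(icc),
        model_label="two-way-random-absolute-single",
        variance_components={
            "ms_subjects": float(ms_r),
            "ms_raters": float(ms_c),
            "ms_error": float(ms_e),
        },
        n_subjects=n,
        n_ratings=k,
        negative_estimate=bool(icc < 0),
    )


def icc_intra(table: pd.DataFrame, rater_id: str) -> ICCResult:
    """Intra-rater ICC(1,1) over one rater's repeated measurements."""
    validate_rater_table(table)
    sub = table[table["rater_id"] == rater_id]
    if sub.empty:
        raise ValueError(f"rater {rater_id!r} not present in table")
    wide = sub.pivot(index="subject_id", columns="repeat", values="value_mm3")
    values = wide.to_numpy(dtype=float)
    n, k = values.shape
    if k < 2:
        raise ValueError("intra-rater ICC needs >= 2 repeats")

    grand = values.mean()
    row_means = values.mean(axis=1)
    ms_b = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_w = ((values - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    if denom <= 0:
        raise ValueError("total variance is zero; ICC undefined")
    icc = (ms_b - ms_w) / denom
    return ICCResult(
        icc=float(icc),
        model_label="one-way-random-single",
        variance_components={"ms_between": float(ms_b), "ms_within": float(ms_w)},
        n_subjects=n,
        n_ratings=k,
        negative_estimate=bool(icc < 0),
    )
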