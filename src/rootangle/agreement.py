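"""Agreement and reliability statistics for paired angle measurements.

Implements the validation toolkit used to compare an automated angulation
pipeline against a manual reference standard:

* intraclass correlation coefficients from the two-way ANOVA decomposition —
  ICC(2,1) (two-way random, absolute agreement, single measures) and
  ICC(3,1) (two-way mixed, consistency, single measures) with exact F-based
  95% confidence intervals;
* Bland–Altman bias and 95% limits of agreement with a proportional-bias
  regression test;
* the Dice similarity coefficient for segmentation overlap;
* grouped mean absolute error / ICC tables (by tooth type, arch or side);
* repeat-acquisition sensitivity summaries;
* dataset exclusion accounting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .angulation import AngulationRecord, records_to_dataframe
from .labelmaps import FDISchema

logger = logging.getLogger(__name__)

ICC_MODELS = ("two_way_random_2_1", "two_way_mixed_3_1")

#: Study-scale exclusion accounting inputs: radiographs collected from the
#: archive and the frequency distribution of exclusion criteria.
STUDY_COLLECTED = 7751
STUDY_EXCLUSIONS: tuple[tuple[str, int], ...] = (
    ("primary or mixed dentition period", 3187),
    ("retained primary teeth", 165),
    ("impacted teeth (except third molars)", 539),
    ("missing teeth (one or more)", 2674),
    ("severe deep caries preventing long-axis determination", 81),
    ("pathologic lesions affecting root positions", 253),
    ("dental anomalies of tooth number or morphology", 181),
    ("syndromes affecting the dentition", 4),
    ("imaging artifacts", 453),
)


@dataclass
class ICCResult:
    icc: float
    model: str
    ci_low: float
    ci_high: float
    interpretation: str
    n_subjects: int
    k_raters: int


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    proportional_bias_p: float
    n: int


@dataclass
class SensitivityReport:
    mean_abs_diff: float
    p95_abs_diff: float
    max_abs_diff: float
    frac_gt_1deg: float
    frac_gt_2deg: float
    n_teeth: int


def interpret_icc(icc: float) -> str:
    """Reliability band for an ICC estimate.

    Below 0.50 is poor, 0.50–0.75 moderate, above 0.75 up to 0.90 good, and
    above 0.90 excellent; the shared boundaries 0.75 and 0.90 fall to the
    lower band.
    """
    if icc < 0.50:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def _two_way_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way ANOVA decomposition of an n x k table."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((values - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc(
    table: np.ndarray | pd.DataFrame,
    model: str = "two_way_mixed_3_1",
    alpha: float = 0.05,
) -> ICCResult:
    """Single-measures intraclass correlation of an n-subject x k-rater table.

    ``two_way_random_2_1`` is the absolute-agreement form
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` used for
    examiner reliability; ``two_way_mixed_3_1`` is the consistency form
    ``(MSR - MSE) / (MSR + (k-1) MSE)`` appropriate when one method is a
    fixed instrument (automated vs. manual).  Confidence intervals use the
    exact F-distribution method; a table with zero total variance returns
    ICC 1 with a degenerate interval and a warning.
    """
    if model not in ICC_MODELS:
        raise ValueError(f"model must be one of {ICC_MODELS}")
    values = np.asarray(table, dtype=float)
    if values.ndim != 2:
        raise ValueError("ratings table must be 2-D (subjects x raters)")
    if np.isnan(values).any():
        raise ValueError("ratings table must be complete (no missing cells)")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")

    if np.ptp(values) == 0:
        warnings.warn("all ratings identical: ICC degenerate, reporting 1")
        return ICCResult(1.0, model, 1.0, 1.0, "excellent", n, k)

    msr, msc, mse = _two_way_mean_squares(values)
    df_e = (n - 1) * (k - 1)

    if model == "two_way_mixed_3_1":
        denom = msr + (k - 1) * mse
        r = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0:
            return ICCResult(r, model, r, r, interpret_icc(r), n, k)
        f_obs = msr / mse
        fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df_e)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df_e, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        r = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0 and msc == 0:
            return ICCResult(r, model, r, r, interpret_icc(r), n, k)
        # Satterthwaite degrees of freedom for the absolute-agreement interval
        a = k * r / (n * (1 - r)) if r < 1 else np.inf
        b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df_e
            )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lo = hi = r
    lo = min(lo, r)
    hi = max(hi, r)
    return ICCResult(float(r), model, float(lo), float(hi), interpret_icc(float(r)), n, k)


def ratings_table(
    df: pd.DataFrame,
    subject: str = "subject",
    rater: str = "rater",
    value: str = "value",
) -> pd.DataFrame:
    """Pivot long-format ratings into a complete subjects x raters table."""
    wide = df.pivot_table(index=subject, columns=rater, values=value)
    if wide.isna().any().any():
        raise ValueError("incomplete ratings: every subject needs every rater")
    return wide


def bland_altman(
    a: Sequence[float], b: Sequence[float] | None = None
) -> BlandAltmanResult:
    """Bland–Altman agreement between paired measurements.

    Differences are ``a - b``; bias is their mean, and the 95% limits of
    agreement are ``bias ± 1.96 s`` with ``s`` the sample (n-1) standard
    deviation of the differences.  Proportional bias is assessed by ordinary
    least squares of the differences on the pair means (slope and two-sided
    p-value of its t-test).
    """
    if b is None:
        pairs = np.asarray(a, dtype=float)
        a, b = pairs[:, 0], pairs[:, 1]
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be matching 1-D sequences")
    n = a.size
    if n < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    d = a - b
    m = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(m) > 0:
        fit = stats.linregress(m, d)
        slope, pval = float(fit.slope), float(fit.pvalue)
    else:
        slope, pval = float("nan"), float("nan")
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, slope, pval, n)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks."""
    mask_a = np.asarray(mask_a).astype(bool)
    mask_b = np.asarray(mask_b).astype(bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must have the same shape")
    size_a = int(mask_a.sum())
    size_b = int(mask_b.sum())
    if size_a + size_b == 0:
        warnings.warn("both masks empty: Dice defined as 1 (vacuous agreement)")
        return 1.0
    inter = int((mask_a & mask_b).sum())
    return 2.0 * inter / (size_a + size_b)


def _as_angle_frame(records: Iterable[AngulationRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = records_to_dataframe(list(records))
    df["fdi_code"] = df["fdi_code"].astype(str)
    df["image_id"] = df["image_id"].astype(str)
    return df[["image_id", "fdi_code", "angle_deg"]]


def _match_records(
    a: Iterable[AngulationRecord] | pd.DataFrame,
    b: Iterable[AngulationRecord] | pd.DataFrame,
) -> pd.DataFrame:
    da, db = _as_angle_frame(a), _as_angle_frame(b)
    merged = da.merge(db, on=["image_id", "fdi_code"], suffixes=("_a", "_b"))
    dropped = len(da) + len(db) - 2 * len(merged)
    if dropped:
        logger.info("dropped %d unmatched records", dropped)
    return merged


def grouped_errors(
    ai: Iterable[AngulationRecord] | pd.DataFrame,
    ref: Iterable[AngulationRecord] | pd.DataFrame,
    grouping: str = "tooth_type",
    schema: FDISchema | None = None,
    absolute: bool = False,
) -> pd.DataFrame:
    """Per-group MAE and ICC(3,1) between paired measurement sets.

    Records are matched on (image_id, fdi_code); unmatched records are
    dropped with a log line.  ``grouping`` is one of ``tooth_type``, ``arch``
    or ``side`` (attributes of the FDI code).  With ``absolute=True`` the
    comparison runs on |angle| instead of signed angles.  Returns a frame
    with columns ``group, mae, icc, n``.
    """
    if grouping not in ("tooth_type", "arch", "side"):
        raise ValueError("grouping must be tooth_type, arch or side")
    schema = schema or FDISchema.default()
    merged = _match_records(ai, ref)
    if merged.empty:
        raise ValueError("no matched records")
    if absolute:
        merged["angle_deg_a"] = merged["angle_deg_a"].abs()
        merged["angle_deg_b"] = merged["angle_deg_b"].abs()
    merged["group"] = [
        getattr(schema.lookup(schema.class_of(code)), grouping)
        for code in merged["fdi_code"]
    ]
    rows = []
    for label, grp in merged.groupby("group", sort=True):
        pair = grp[["angle_deg_a", "angle_deg_b"]].to_numpy()
        mae = float(np.abs(pair[:, 0] - pair[:, 1]).mean())
        r = icc(pair, "two_way_mixed_3_1").icc if len(grp) >= 2 else float("nan")
        rows.append({"group": label, "mae": mae, "icc": r, "n": len(grp)})
    return pd.DataFrame(rows, columns=["group", "mae", "icc", "n"])


def repeat_sensitivity(
    run1: Iterable[AngulationRecord] | pd.DataFrame,
    run2: Iterable[AngulationRecord] | pd.DataFrame,
) -> SensitivityReport:
    """Tooth-wise absolute differences between two repeat acquisitions.

    Records are matched on (image_id, fdi_code) — the image id doubling as
    the patient id for repeat pairs — and |difference| is summarized by its
    mean, empirical 95th percentile, maximum, and the fractions exceeding
    1 degree and 2 degrees.
    """
    merged = _match_records(run1, run2)
    if merged.empty:
        raise ValueError("no matched teeth between the two runs")
    d = np.abs(merged["angle_deg_a"].to_numpy() - merged["angle_deg_b"].to_numpy())
    return SensitivityReport(
        mean_abs_diff=float(d.mean()),
        p95_abs_diff=float(np.percentile(d, 95)),
        max_abs_diff=float(d.max()),
        frac_gt_1deg=float((d > 1.0).mean()),
        frac_gt_2deg=float((d > 2.0).mean()),
        n_teeth=int(d.size),
    )


def exclusion_accounting(
    collected: int, exclusion_counts: Iterable[tuple[str, int]]
) -> int:
    """Images remaining after subtracting every exclusion criterion's count."""
    total = 0
    for reason, count in exclusion_counts:
        if count < 0:
            raise ValueError(f"negative exclusion count for {reason!r}")
        total += int(count)
    remaining = int(collected) - total
    if remaining < 0:
        raise ValueError(
            f"exclusions ({total}) exceed the {collected} collected images"
        )
    return remaining


def plot_bland_altman(
    a: Sequence[float], b: Sequence[float], ax=None
) -> "object":
    """Difference-vs-mean plot with bias and 95% limit-of-agreement lines."""
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(res.bias, color="k", lw=1.2, label=f"bias {res.bias:+.2f}°")
    for y, lab in ((res.loa_low, f"LoA {res.loa_low:+.2f}°"),
                   (res.loa_high, f"LoA {res.loa_high:+.2f}°")):
        ax.axhline(y, color="crimson", lw=1.0, ls="--", label=lab)
    ax.set_xlabel("mean of methods (°)")
    ax.set_ylabel("difference between methods (°)")
    ax.legend(loc="best", fontsize=8)
    return ax
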