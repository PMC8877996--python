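"""Agreement and image-quality statistics between segmentations.

Covers the full evaluation suite for comparing a candidate segmentation
against a reference: Dice overlap, volume error normalized by the
reference volume, intraclass correlation of paired volumes, RMSE of
volumes, Bland-Altman percent-difference limits of agreement, lesion
SNR/CNR, and cohort summary rows (Mean / Median / [Min, Max] / STD).

Conventions: the sample standard deviation (n-1 denominator) is used
everywhere, and the ICC form is the two-way random-effects,
single-measure, absolute-agreement coefficient ICC(2,1) — the standard
choice when two measurement methods are compared on the same scale. Both
choices are recorded in the report metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from scipy import stats

from .errors import EmptyInputError, ParameterError
from .volumes import BinaryMask, ImageVolume, check_congruent, volume_ml

__all__ = [
    "dice",
    "normalized_volume_error",
    "icc",
    "rmse",
    "bland_altman_percent",
    "BlandAltman",
    "snr_cnr",
    "RoiStats",
    "cohort_summary",
    "CohortSummary",
    "paired_ttest",
    "AgreementReport",
]

ICC_FORM = "ICC(2,1) two-way random, single measure, absolute agreement"


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; two empty masks score 1 (with a warning)."""
    check_congruent(a, b)
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        warnings.warn("both masks empty: Dice defined as 1.0", RuntimeWarning, stacklevel=2)
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def normalized_volume_error(v_ref: float, v_cand: float) -> float:
    """Volume error as a fraction of the reference: ``|v_ref - v_cand| / v_ref``."""
    if v_ref <= 0:
        raise ParameterError(f"reference volume must be > 0, got {v_ref}")
    return abs(v_ref - v_cand) / v_ref


def icc(volumes_ref: Sequence[float], volumes_cand: Sequence[float]) -> float:
    """Intraclass correlation of paired volumes, form ICC(2,1).

    Two-way random effects, single measure, absolute agreement, computed
    from the classical ANOVA mean squares of the n-cases x 2-raters table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-cases, MSC the between-raters and MSE the
    residual mean square, k = 2 raters.
    """
    ref = np.asarray(volumes_ref, dtype=float)
    cand = np.asarray(volumes_cand, dtype=float)
    if ref.shape != cand.shape:
        raise ParameterError("lists must have equal length")
    n = ref.size
    if n < 2:
        raise EmptyInputError(f"ICC needs at least 2 pairs, got {n}")
    if ref.std() == 0 and cand.std() == 0:
        raise ParameterError("zero variance in both raters: ICC undefined")
    x = np.column_stack([ref, cand])
    k = 2
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((x - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ParameterError("degenerate ANOVA table: ICC undefined")
    return float((msr - mse) / denom)


def rmse(volumes_ref: Sequence[float], volumes_cand: Sequence[float]) -> float:
    """Root-mean-squared error between paired volume lists."""
    ref = np.asarray(volumes_ref, dtype=float)
    cand = np.asarray(volumes_cand, dtype=float)
    if ref.shape != cand.shape:
        raise ParameterError("lists must have equal length")
    if ref.size == 0:
        raise EmptyInputError("rmse of empty lists")
    return float(np.sqrt(np.mean((ref - cand) ** 2)))


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman statistics on per-case percent differences."""

    bias_percent: float
    std_percent: float
    lower_loa_percent: float
    upper_loa_percent: float
    diffs_percent: tuple[float, ...]


def bland_altman_percent(
    volumes_ref: Sequence[float], volumes_cand: Sequence[float]
) -> BlandAltman:
    """Bland-Altman agreement on percent differences.

    Per case: ``100 * (cand - ref) / mean(cand, ref)``. The bias is the
    mean of these, the limits of agreement are ``bias ± 1.96 * STD``
    (sample STD). All pairwise means must be positive.
    """
    ref = np.asarray(volumes_ref, dtype=float)
    cand = np.asarray(volumes_cand, dtype=float)
    if ref.shape != cand.shape:
        raise ParameterError("lists must have equal length")
    if ref.size == 0:
        raise EmptyInputError("empty lists")
    means = (ref + cand) / 2.0
    if np.any(means <= 0):
        raise ParameterError("all pairwise means must be > 0 for percent differences")
    diffs = 100.0 * (cand - ref) / means
    bias = float(diffs.mean())
    std = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return BlandAltman(
        bias_percent=bias,
        std_percent=std,
        lower_loa_percent=bias - 1.96 * std,
        upper_loa_percent=bias + 1.96 * std,
        diffs_percent=tuple(diffs),
    )


@dataclass(frozen=True)
class RoiStats:
    """Lesion-conspicuity statistics of a cyst ROI against adjacent liver."""

    cyst_mean: float
    cyst_std: float
    liver_mean: float
    snr: float
    cnr: float


def snr_cnr(volume: ImageVolume, cyst_roi: BinaryMask, liver_roi: BinaryMask) -> RoiStats:
    """SNR and CNR of a cyst ROI.

    SNR = cyst ROI mean / cyst ROI STD; CNR = (cyst mean - adjacent liver
    mean) / cyst ROI STD. Sample STD (n-1). Both are invariant to a
    positive rescaling of the intensities.
    """
    check_congruent(volume, cyst_roi)
    check_congruent(volume, liver_roi)
    if not cyst_roi.data.any() or not liver_roi.data.any():
        raise EmptyInputError("cyst and liver ROIs must both be nonempty")
    cyst_vals = volume.data[cyst_roi.data]
    liver_vals = volume.data[liver_roi.data]
    c_mean = float(cyst_vals.mean())
    c_std = float(cyst_vals.std(ddof=1)) if cyst_vals.size > 1 else 0.0
    if c_std == 0:
        raise ParameterError("cyst ROI intensity STD is zero: SNR/CNR undefined")
    l_mean = float(liver_vals.mean())
    return RoiStats(
        cyst_mean=c_mean,
        cyst_std=c_std,
        liver_mean=l_mean,
        snr=c_mean / c_std,
        cnr=(c_mean - l_mean) / c_std,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Mean / Median / [Min, Max] / STD of a per-case metric."""

    mean: float
    median: float
    minimum: float
    maximum: float
    std: float
    n: int

    def as_rows(self) -> dict[str, str]:
        return {
            "Mean": f"{self.mean:.4g}",
            "Median": f"{self.median:.4g}",
            "[Min, Max]": f"[{self.minimum:.4g}, {self.maximum:.4g}]",
            "STD": f"{self.std:.4g}",
        }


def cohort_summary(values: Sequence[float]) -> CohortSummary:
    """Summary rows over a per-case metric list (sample STD; 0 for a singleton)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("empty per-case list")
    return CohortSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        std=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n=int(arr.size),
    )


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided Student's t-test; returns (t, p)."""
    res = stats.ttest_rel(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AgreementReport:
    """Paired-cohort agreement between a candidate and a reference method.

    Holds the per-case table plus the cohort statistics: Dice and
    normalized volume error summaries, ICC(2,1), RMSE (mL), and
    Bland-Altman percent limits of agreement.
    """

    per_case: pd.DataFrame
    dice_summary: CohortSummary
    volume_error_summary: CohortSummary
    icc: float
    rmse_ml: float
    bland_altman: BlandAltman
    icc_form: str = ICC_FORM

    @classmethod
    def from_cases(
        cls,
        case_ids: Sequence,
        dice_values: Sequence[float],
        volumes_ref_ml: Sequence[float],
        volumes_cand_ml: Sequence[float],
    ) -> "AgreementReport":
        ref = np.asarray(volumes_ref_ml, dtype=float)
        cand = np.asarray(volumes_cand_ml, dtype=float)
        nve = [normalized_volume_error(r, c) for r, c in zip(ref, cand)]
        per_case = pd.DataFrame(
            {
                "case": list(case_ids),
                "dice": list(dice_values),
                "volume_ref_ml": ref,
                "volume_cand_ml": cand,
                "normalized_volume_error": nve,
            }
        )
        return cls(
            per_case=per_case,
            dice_summary=cohort_summary(dice_values),
            volume_error_summary=cohort_summary(nve),
            icc=icc(ref, cand),
            rmse_ml=rmse(ref, cand),
            bland_altman=bland_altman_percent(ref, cand),
        )

    def to_dict(self) -> dict:
        ba = self.bland_altman
        return {
            "icc_form": self.icc_form,
            "n_cases": int(len(self.per_case)),
            "dice": self.dice_summary.__dict__ | {},
            "normalized_volume_error": self.volume_error_summary.__dict__ | {},
            "icc": self.icc,
            "rmse_ml": self.rmse_ml,
            "bland_altman_percent": {
                "bias": ba.bias_percent,
                "std": ba.std_percent,
                "lower_loa": ba.lower_loa_percent,
                "upper_loa": ba.upper_loa_percent,
            },
        }


def mask_agreement(ref: BinaryMask, cand: BinaryMask) -> dict[str, float]:
    """Single-case agreement: Dice, both volumes (mL), normalized volume error."""
    d = dice(ref, cand)
    v_ref = volume_ml(ref)
    v_cand = volume_ml(cand)
    out = {"dice": d, "volume_ref_ml": v_ref, "volume_cand_ml": v_cand}
    if v_ref > 0:
        out["normalized_volume_error"] = normalized_volume_error(v_ref, v_cand)
    return out
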