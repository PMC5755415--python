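"""Regional caries polarization index and its outlier sensitivity analysis.

The polarization index for one calendar year is the ratio of the maximum
to the minimum parish-level smoothed relative risk: 1 means perfect
equality across the region, larger values mean a wider risk gap.  Because
a single extreme parish can dominate a max/min ratio, the index is
re-computed after excluding parishes whose smoothed RR is a box-plot
(Tukey-fence) outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import round_half_up


def _quartiles(values: np.ndarray, method: str) -> tuple[float, float]:
    if method == "linear":
        q1, q3 = np.percentile(values, [25, 75], method="linear")
    elif method == "hinges":
        # Tukey hinges: medians of the lower/upper halves, median included
        # in both halves for odd n (the SPSS box-plot convention)
        s = np.sort(values)
        n = len(s)
        half = (n + 1) // 2
        q1, q3 = np.median(s[:half]), np.median(s[n - half:])
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    return float(q1), float(q3)


@dataclass(frozen=True)
class OutlierResult:
    outlier_ids: tuple = ()
    extreme_ids: tuple = ()
    q1: float = np.nan
    q3: float = np.nan
    lower_fence: float = np.nan
    upper_fence: float = np.nan
    lower_extreme_fence: float = np.nan
    upper_extreme_fence: float = np.nan


@dataclass(frozen=True)
class PolarizationResult:
    """Index, argmax/argmin parishes, box-plot outliers and the index
    recomputed without them."""

    index: float
    argmax_id: object
    argmin_id: object
    outliers: OutlierResult = field(default_factory=OutlierResult)
    sensitivity_index: float = np.nan


def polarization_index(values, *, ndigits: int | None = 1) -> float:
    """Max/min ratio of parish relative-risk estimates.

    Reported rounded half-up to one decimal by default (``ndigits=None``
    returns the raw ratio).  All values must be positive; fewer than two
    values are an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("polarization index needs >= 2 parishes")
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("all relative-risk estimates must be positive and finite")
    ratio = float(arr.max() / arr.min())
    return ratio if ndigits is None else round_half_up(ratio, ndigits)


def tukey_outliers(values, ids=None, *, quartile_method: str = "linear") -> OutlierResult:
    """Box-plot rule: values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are
    outliers; beyond 3 IQR they are additionally flagged extreme.

    Quartiles use linear interpolation by default; ``quartile_method=
    'hinges'`` switches to Tukey hinges (the SPSS box-plot dialect).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("box-plot outlier rule needs >= 4 values")
    if ids is None:
        ids = np.arange(arr.size)
    ids = np.asarray(ids, dtype=object)
    q1, q3 = _quartiles(arr, quartile_method)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo3, hi3 = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    out_mask = (arr < lo) | (arr > hi)
    ext_mask = (arr < lo3) | (arr > hi3)
    return OutlierResult(
        outlier_ids=tuple(ids[out_mask]),
        extreme_ids=tuple(ids[ext_mask]),
        q1=q1,
        q3=q3,
        lower_fence=lo,
        upper_fence=hi,
        lower_extreme_fence=lo3,
        upper_extreme_fence=hi3,
    )


def sensitivity_index(values, exclude, ids=None, *, ndigits: int | None = 1) -> float:
    """Polarization index after excluding the given parishes.

    Excluding values can only narrow the max/min range, so the result never
    exceeds the unexcluded index.
    """
    arr = np.asarray(values, dtype=float)
    if ids is None:
        ids = np.arange(arr.size)
    ids = np.asarray(ids, dtype=object)
    excl = set(exclude)
    keep = np.array([i not in excl for i in ids])
    if keep.sum() < 2:
        raise ValueError("exclusion leaves fewer than 2 parishes")
    return polarization_index(arr[keep], ndigits=ndigits)


def analyze_polarization(
    values, ids=None, *, quartile_method: str = "linear", ndigits: int | None = 1
) -> PolarizationResult:
    """Full polarization summary for one year: index, extremal parishes,
    box-plot outliers, and the outlier-excluded sensitivity index."""
    arr = np.asarray(values, dtype=float)
    if ids is None:
        ids = np.arange(arr.size)
    ids = np.asarray(ids, dtype=object)
    idx = polarization_index(arr, ndigits=ndigits)
    outl = tukey_outliers(arr, ids, quartile_method=quartile_method)
    sens = (
        sensitivity_index(arr, outl.outlier_ids, ids, ndigits=ndigits)
        if outl.outlier_ids
        else idx
    )
    return PolarizationResult(
        index=idx,
        argmax_id=ids[int(np.argmax(arr))],
        argmin_id=ids[int(np.argmin(arr))],
        outliers=outl,
        sensitivity_index=sens,
    )
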