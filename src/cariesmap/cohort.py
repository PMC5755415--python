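"""Child-level examination records and parish-level caries counts.

The unit of observation is one examined child: exam year, age, sex,
residence parish, birth class (born in the country vs. newly arrived
foreign-born) and a dmfs count (decayed/missing/filled primary-tooth
surfaces).  A child is a *caries case* when dmfs > 0.

Parish-level observed cases O are compared against expected counts E under
internal (indirect) standardization: E_i = sum_s n_{i,s} * r_s with r_s the
region-wide sex-specific case rate, so that sum(E) == sum(O) by
construction and O_i/E_i is the raw standardized morbidity ratio (SMR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up

logger = logging.getLogger(__name__)

#: required columns of a child-record table, in canonical order
CHILD_COLUMNS = (
    "child_id",
    "exam_year",
    "age",
    "sex",
    "parish_id",
    "birth_class",
    "dmfs",
)

BIRTH_CLASSES = ("domestic", "foreign_born")

AGE_MAX_VALID = 19


class PrevalenceUndefinedError(ValueError):
    """Raised when a prevalence is requested for an empty cohort."""


@dataclass(frozen=True)
class Prevalence:
    """A proportion with its numerator and denominator.

    ``percent`` is the proportion in percent rounded half-up to one
    decimal, the convention used when such figures are printed.
    """

    cases: int
    n: int

    @property
    def proportion(self) -> float:
        return self.cases / self.n

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.cases / self.n, 1)


@dataclass(frozen=True)
class PrevalenceRatio:
    ratio: float
    p_value: float
    group_a: Prevalence
    group_b: Prevalence
    infinite: bool = False


def _validate_frame(df: pd.DataFrame, *, source: str = "<memory>") -> pd.DataFrame:
    """Coerce and validate a raw child table; drop (and log) bad rows."""
    missing = [c for c in CHILD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(CHILD_COLUMNS)].copy()

    for col in ("exam_year", "age", "dmfs"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("child_id", "sex", "parish_id", "birth_class"):
        df[col] = df[col].astype("string").str.strip()

    ok = (
        df["exam_year"].notna()
        & df["age"].notna()
        & (df["age"] >= 0)
        & (df["age"] <= AGE_MAX_VALID)
        & df["dmfs"].notna()
        & (df["dmfs"] >= 0)
        & (df["parish_id"].fillna("") != "")
        & (df["sex"].fillna("") != "")
        & df["birth_class"].isin(BIRTH_CLASSES)
    )
    rejected = df.index[~ok]
    for idx in rejected:
        logger.warning("%s: rejected record at row %d: %s", source, idx + 2,
                       df.loc[idx].to_dict())  # +2: header line + 1-based
    if len(rejected):
        logger.warning("%s: rejected %d of %d records", source, len(rejected), len(df))
    df = df.loc[ok].copy()
    for col in ("exam_year", "age", "dmfs"):
        df[col] = df[col].astype(int)
    return df.reset_index(drop=True)


def read_children(path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited child-record file into a validated DataFrame.

    A missing required column is a hard error; rows with an unparseable or
    out-of-range age/dmfs, an unknown birth class, or an empty parish are
    rejected with a logged warning naming the row.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    return _validate_frame(raw, source=str(path))


def write_children(df: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    df.loc[:, list(CHILD_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def records_from_rows(rows: Iterable[dict]) -> pd.DataFrame:
    """Build a validated child table from an iterable of dicts (test/fixture aid)."""
    return _validate_frame(pd.DataFrame(list(rows), columns=list(CHILD_COLUMNS)))


def filter_cohort(
    records: pd.DataFrame,
    *,
    year: int | None = None,
    age_min: int | None = None,
    age_max: int | None = None,
    birth_class: str = "all",
) -> pd.DataFrame:
    """Subset a cohort on exam year, age range and birth class.

    Predicates combine with AND; ``birth_class='all'`` disables that
    predicate.  Row order is preserved and an empty result is valid.
    """
    if age_min is not None and age_max is not None and age_min > age_max:
        raise ValueError(f"age_min ({age_min}) > age_max ({age_max})")
    if birth_class != "all" and birth_class not in BIRTH_CLASSES:
        raise ValueError(f"unknown birth_class {birth_class!r}")
    mask = pd.Series(True, index=records.index)
    if year is not None:
        mask &= records["exam_year"] == year
    if age_min is not None:
        mask &= records["age"] >= age_min
    if age_max is not None:
        mask &= records["age"] <= age_max
    if birth_class != "all":
        mask &= records["birth_class"] == birth_class
    return records.loc[mask]


def prevalence(records: pd.DataFrame) -> Prevalence:
    """Caries prevalence: share of children with dmfs > 0."""
    if len(records) == 0:
        raise PrevalenceUndefinedError("prevalence of an empty cohort is undefined")
    return Prevalence(cases=int((records["dmfs"] > 0).sum()), n=len(records))


def prevalence_ratio(group_a: pd.DataFrame, group_b: pd.DataFrame) -> PrevalenceRatio:
    """Prevalence ratio a/b with a two-proportion Pearson chi-square p-value.

    A zero prevalence in the denominator group yields ``ratio = inf`` with
    the ``infinite`` flag set rather than an exception.  The chi-square is
    the uncorrected Pearson statistic on the 2x2 case/non-case table.
    """
    pa, pb = prevalence(group_a), prevalence(group_b)
    table = np.array(
        [[pa.cases, pa.n - pa.cases], [pb.cases, pb.n - pb.cases]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():
        # a degenerate margin (e.g. no cases at all): no evidence of a difference
        p_value = 1.0
    else:
        p_value = float(stats.chi2_contingency(table, correction=False)[1])
    if pb.cases == 0:
        return PrevalenceRatio(float("inf"), p_value, pa, pb, infinite=True)
    return PrevalenceRatio(pa.proportion / pb.proportion, p_value, pa, pb)


def expected_counts(
    records: pd.DataFrame,
    *,
    sex_levels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Parish table of observed cases, internally standardized expected
    counts, and raw SMRs.

    E_i = sum over sex strata s of n_{i,s} * r_s, where r_s is the regional
    case rate in stratum s, so sum(E) equals sum(O) exactly (internal
    standardization).  ``sex_levels`` may pin the expected strata; a level
    with no children in the region is an error naming the stratum.
    """
    if len(records) == 0:
        raise ValueError("cannot standardize an empty cohort")
    levels = list(sex_levels) if sex_levels is not None else sorted(records["sex"].unique())
    rates = {}
    for s in levels:
        sub = records.loc[records["sex"] == s]
        if len(sub) == 0:
            raise ValueError(f"sex stratum {s!r} has zero regional children")
        rates[s] = (sub["dmfs"] > 0).mean()

    is_case = records["dmfs"] > 0
    grp = records.groupby("parish_id", sort=True)
    out = pd.DataFrame(
        {
            "n_children": grp.size(),
            "observed": is_case.groupby(records["parish_id"]).sum().astype(int),
        }
    )
    expected = pd.Series(0.0, index=out.index)
    for s in levels:
        n_is = (
            records.loc[records["sex"] == s]
            .groupby("parish_id")
            .size()
            .reindex(out.index, fill_value=0)
        )
        out[f"n_{s}"] = n_is.astype(int)
        expected = expected + n_is * rates[s]
    out["expected"] = expected
    with np.errstate(divide="ignore", invalid="ignore"):
        out["smr"] = np.where(out["expected"] > 0, out["observed"] / out["expected"], np.nan)
    return out.reset_index().rename(columns={"index": "parish_id"})


def write_parish_table(table: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    table.to_csv(path, sep=delimiter, index=False, float_format="%.10g")
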