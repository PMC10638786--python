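"""Pubertal phenotype scoring and covariate preparation.

The pubertal development scale (PDS) is the mean of five self-reported
ordinal puberty markers: growth spurt, body hair, skin changes,
breast development (girls) / voice change (boys), and menarche (girls) /
facial hair (boys). Items run 1-3 at the age-12 wave and 1-4 at the age-14
wave, except menarche (coded {1, 4}) and facial hair (coded 1-3), which keep
the age-12 coding at both waves. The score is the item sum divided by five;
records with any missing item are excluded.

Pubertal age (PA) is the self-reported age at menarche (girls) or voice
break (boys); respondents who report the event has not yet happened are
coded as the event occurring at age 17, and reports inconsistent with the
reporting age are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CELL_COLUMNS, SMOKING_LEVELS, TwinCohort

__all__ = [
    "PdsItems", "PaReport", "RecordExcluded", "MissingPdsItem",
    "compute_pds", "score_pds_table", "code_pubertal_age",
    "code_pubertal_age_table", "prepare_covariates", "NOT_YET_AGE",
]

NOT_YET_AGE = 17.0

_ITEM_NAMES = ("growth_spurt", "body_hair", "skin_changes", "breast_or_voice")


class RecordExcluded(Exception):
    """The record cannot be scored and is excluded (not an input error)."""


class MissingPdsItem(RecordExcluded):
    pass


@dataclass
class PdsItems:
    wave: int                      # 12 | 14
    sex: str                       # M | F
    growth_spurt: int | None
    body_hair: int | None
    skin_changes: int | None
    breast_or_voice: int | None
    menarche_or_facial_hair: int | None


@dataclass
class PaReport:
    sex: str
    report_age: float
    event_age: float | None = None   # None = missing
    not_yet: bool = False


def _item_range(wave: int) -> range:
    if wave == 12:
        return range(1, 4)
    if wave == 14:
        return range(1, 5)
    raise ValueError(f"wave must be 12 or 14, got {wave}")


def compute_pds(items: PdsItems) -> float:
    """PDS score = (sum of the five item codes) / 5.

    Raises :class:`MissingPdsItem` for any missing item (the record is
    excluded) and :class:`ValueError`, naming the item, for out-of-range
    codes.
    """
    rng = _item_range(items.wave)
    codes = []
    for name in _ITEM_NAMES:
        v = getattr(items, name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingPdsItem(name)
        if int(v) not in rng:
            raise ValueError(
                f"item {name!r} code {v} outside {rng.start}..{rng.stop - 1} "
                f"at wave {items.wave}")
        codes.append(int(v))
    mf = items.menarche_or_facial_hair
    if mf is None or (isinstance(mf, float) and np.isnan(mf)):
        raise MissingPdsItem("menarche_or_facial_hair")
    mf = int(mf)
    # menarche {1,4} and facial hair {1,2,3} keep the age-12 coding at both waves
    if items.sex == "F":
        if mf not in (1, 4):
            raise ValueError(f"item 'menarche' code {mf} not in {{1, 4}}")
    elif items.sex == "M":
        if mf not in (1, 2, 3):
            raise ValueError(f"item 'facial_hair' code {mf} not in {{1, 2, 3}}")
    else:
        raise ValueError(f"sex must be 'M' or 'F', got {items.sex!r}")
    codes.append(mf)
    return sum(codes) / 5.0


def score_pds_table(items: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Score a table of PDS items (columns as in :class:`PdsItems` plus
    ``individual_id``). Returns (scored rows, n_excluded); n_in = n_scored
    + n_excluded."""
    scores, excluded = [], 0
    for row in items.itertuples(index=False):
        rec = PdsItems(wave=int(row.wave), sex=row.sex,
                       growth_spurt=row.growth_spurt, body_hair=row.body_hair,
                       skin_changes=row.skin_changes,
                       breast_or_voice=row.breast_or_voice,
                       menarche_or_facial_hair=row.menarche_or_facial_hair)
        try:
            scores.append((row.individual_id, int(row.wave), compute_pds(rec)))
        except RecordExcluded:
            excluded += 1
    out = pd.DataFrame(scores, columns=["individual_id", "wave", "pds"])
    return out, excluded


def code_pubertal_age(report: PaReport) -> float:
    """Code one pubertal-age report.

    Numeric event ages pass through; "not yet" is coded as the event
    happening at age 17. Missing or inconsistent reports (event age later
    than the reporting age) raise :class:`RecordExcluded`.
    """
    if report.not_yet:
        return NOT_YET_AGE
    ev = report.event_age
    if ev is None or (isinstance(ev, float) and np.isnan(ev)):
        raise RecordExcluded("missing event age")
    if ev > report.report_age:
        raise RecordExcluded("event age exceeds report age")
    return float(ev)


def code_pubertal_age_table(reports: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Vector version over a PA report table (with ``individual_id``)."""
    coded, excluded = [], 0
    for row in reports.itertuples(index=False):
        rec = PaReport(sex=row.sex, report_age=float(row.report_age),
                       event_age=None if pd.isna(row.event_age)
                       else float(row.event_age),
                       not_yet=bool(row.not_yet))
        try:
            coded.append((row.individual_id, code_pubertal_age(rec)))
        except RecordExcluded:
            excluded += 1
    return pd.DataFrame(coded, columns=["individual_id", "pa"]), excluded


def prepare_covariates(cohort: TwinCohort, include_sex: bool = False,
                       include_cohort: bool = False) -> pd.DataFrame:
    """Deterministic covariate design table, one row per individual.

    Smoking is expanded to current/former indicators (never = reference),
    chip date and array row to indicators against their first level, and the
    six cell-type proportions enter with the last component dropped (they sum
    to one). Sex (M = 0) and cohort (FT12 = 0) indicators are added on
    request. Constant columns (e.g. smoking in an all-never cohort) are
    dropped with a warning.
    """
    s = cohort.samples
    out = pd.DataFrame(index=s.individual_id.values)
    out["age_at_sampling"] = s.age_at_sampling.values
    bad = set(s.smoking) - set(SMOKING_LEVELS)
    if bad:
        offender = s[s.smoking.isin(bad)].iloc[0]
        raise ValueError(
            f"unknown smoking level {offender.smoking!r} for sample "
            f"{offender.individual_id}")
    for level in SMOKING_LEVELS[1:]:
        out[f"smoking_{level}"] = (s.smoking.values == level).astype(float)
    out["alcohol_g_day"] = s.alcohol_g_day.values
    for col in CELL_COLUMNS[:-1]:   # drop the last: sum-to-one collinearity
        out[col] = s[col].values
    for field, prefix in (("chip_date", "chip"), ("array_row", "row")):
        levels = sorted(pd.unique(s[field]))
        for lev in levels[1:]:
            out[f"{prefix}_{lev}"] = (s[field].values == lev).astype(float)
    if include_sex:
        out["sex_f"] = (s.sex.values == "F").astype(float)
    if include_cohort:
        out["cohort_ft16"] = (s.cohort.values == "FT16").astype(float)
    constant = [c for c in out.columns if out[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate columns: {constant}",
                      UserWarning)
        out = out.drop(columns=constant)
    return out
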