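"""Variable derivation: raw survey fields to analysis categories.

Implements every categorisation rule used by the analysis (sitting-time bands,
the physical-activity partition, dichotomisations, tertiles, above-average
flags, climate bands, the 18-to-8 occupation collapse, ...) plus the
complete-case filter.  Missing inputs propagate as missing; values outside a
declared raw domain raise :class:`DomainError` naming the field and row.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import CategoricalDataset
from .schema import VariableSchema, default_survey_schema, schema_by_name
from .synthetic_data import COUNTRIES_BY_REGION, OCC18_TO_8, REL14_TO_FLAGS, SITTING10_TO_4

logger = logging.getLogger(__name__)

__all__ = [
    "DomainError",
    "RecodeMap",
    "derive_sitting",
    "derive_pa",
    "derive_netuse",
    "derive_education",
    "categorize_climate",
    "derive_household_size",
    "derive_migration",
    "tertile_split",
    "above_average_flag",
    "default_recode_maps",
    "passthrough_maps",
    "apply_recodes",
    "complete_case_filter",
]


class DomainError(ValueError):
    """A raw value fell outside its declared domain."""


COUNTRY_TO_REGION = {
    iso: region for region, isos in COUNTRIES_BY_REGION.items() for iso in isos
}

AGE_BANDS = ((15, 25, "15_25"), (26, 44, "26_44"), (45, 64, "45_64"), (65, None, "65plus"))


# --------------------------------------------------------------------------- #
# scalar derivation rules
# --------------------------------------------------------------------------- #

def derive_sitting(sitting_10cat: int) -> int:
    """Collapse the 10 IPAQ sitting-time categories into 4 bands (1..4)."""
    code = int(sitting_10cat)
    if code not in SITTING10_TO_4:
        raise DomainError(f"sitting_10cat must be in 1..10, got {sitting_10cat!r}")
    return SITTING10_TO_4[code]


def derive_pa(mpa_minutes: float, vpa_minutes: float) -> int:
    """Physical-activity class from weekly MPA/VPA minutes.

    Evaluated in precedence order highly(3) -> sufficiently(2) -> low(1) ->
    inactive(0); inactive requires both MPA and VPA to be exactly zero, which
    makes the four classes a partition.
    """
    if mpa_minutes < 0 or vpa_minutes < 0:
        raise DomainError(
            f"activity minutes must be >= 0, got ({mpa_minutes!r}, {vpa_minutes!r})"
        )
    if mpa_minutes >= 150 and vpa_minutes >= 75:
        return 3
    if mpa_minutes >= 150 or vpa_minutes >= 75:
        return 2
    if mpa_minutes > 0 or vpa_minutes > 0:
        return 1
    return 0


def derive_netuse(home: int, work: int, elsewhere: int) -> int:
    """Highest collapsed internet-use frequency over the three locations."""
    for label, value in (("home", home), ("work", work), ("elsewhere", elsewhere)):
        if value not in (0, 1, 2):
            raise DomainError(f"netuse frequency for {label} must be 0..2, got {value!r}")
    return max(home, work, elsewhere)


def derive_education(stop_age: float) -> int:
    """Education band from the age at which full-time education stopped."""
    if stop_age < 0:
        raise DomainError(f"education stop age must be >= 0, got {stop_age!r}")
    if stop_age <= 15:
        return 1
    if stop_age <= 19:
        return 2
    return 3


def categorize_climate(temp_max_avg: float, precip_daily_avg: float) -> tuple[str, str]:
    """Climate bands: temperature >15 hot, [10, 15] moderate, <10 cold;
    precipitation <0.2 dry, [0.2, 2] moderate, >2 wet."""
    for label, value in (("temperature", temp_max_avg), ("precipitation", precip_daily_avg)):
        if not math.isfinite(value):
            raise DomainError(f"{label} must be finite, got {value!r}")
    if temp_max_avg > 15:
        temp = "hot"
    elif temp_max_avg >= 10:
        temp = "moderate"
    else:
        temp = "cold"
    if precip_daily_avg < 0.2:
        precip = "dry"
    elif precip_daily_avg <= 2:
        precip = "moderate"
    else:
        precip = "wet"
    return temp, precip


def derive_household_size(n_under10: int, n_10to14: int, n_15plus: int) -> int:
    """Sum of the three household counts, capped at the '3 or more' class."""
    counts = (n_under10, n_10to14, n_15plus)
    if any(c < 0 for c in counts):
        raise DomainError(f"household counts must be >= 0, got {counts!r}")
    return min(int(sum(counts)), 3)


def derive_migration(nationality_iso: str, residence_iso: str) -> int:
    """1 iff nationality and residence country codes differ."""
    for label, code in (("nationality", nationality_iso), ("residence", residence_iso)):
        if code not in COUNTRY_TO_REGION:
            raise DomainError(f"unknown {label} ISO code {code!r}")
    return int(nationality_iso != residence_iso)


def tertile_split(values: Sequence[float]) -> np.ndarray:
    """Assign each entry to its empirical tertile (1..3); ties go lower.

    Cut points are the 1/3 and 2/3 empirical quantiles (linear interpolation);
    entries exactly at a cut point are assigned to the lower tertile.
    """
    arr = np.asarray(values, dtype=float)
    if np.unique(arr).size < 3:
        raise DomainError("tertile split needs at least 3 distinct values")
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])
    out = np.full(arr.shape, 3, dtype=np.int64)
    out[arr <= q2] = 2
    out[arr <= q1] = 1
    return out


def above_average_flag(values: Sequence[float], reference: float) -> np.ndarray:
    """1 iff value is strictly above the reference mean; ties map to 0."""
    arr = np.asarray(values, dtype=float)
    if not math.isfinite(reference):
        raise DomainError(f"reference must be finite, got {reference!r}")
    if not np.all(np.isfinite(arr)):
        raise DomainError("values must be finite")
    return (arr > reference).astype(np.int64)


def derive_age_group(age: float) -> str:
    if age < 15:
        raise DomainError(f"age must be >= 15, got {age!r}")
    for lo, hi, label in AGE_BANDS:
        if hi is None or age <= hi:
            if age >= lo:
                return label
    raise DomainError(f"age {age!r} outside all bands")  # pragma: no cover


# --------------------------------------------------------------------------- #
# recode maps
# --------------------------------------------------------------------------- #

@dataclasses.dataclass
class RecodeMap:
    """Derivation of one categorical analysis variable from raw fields."""

    target: str
    sources: tuple[str, ...]
    fn: Callable[[pd.DataFrame], pd.Series]

    def apply(self, table: pd.DataFrame) -> pd.Series:
        missing = [s for s in self.sources if s not in table.columns]
        if missing:
            raise DomainError(
                f"cannot derive {self.target!r}: missing source fields {missing}"
            )
        return self.fn(table)


def _check_domain(s: pd.Series, valid: set, field: str) -> None:
    obs = s.dropna()
    bad = ~obs.isin(valid)
    if bad.any():
        row = int(bad.idxmax())
        raise DomainError(
            f"field {field!r} has value {obs.loc[row]!r} outside its domain at row {row}"
        )


def _code_map(field: str, mapping: dict) -> Callable[[pd.DataFrame], pd.Series]:
    def fn(df: pd.DataFrame) -> pd.Series:
        s = df[field]
        _check_domain(s, set(mapping), field)
        return s.map(mapping)

    return fn


def _rowwise(
    fields: Sequence[str], scalar_fn: Callable, post: dict | None = None
) -> Callable[[pd.DataFrame], pd.Series]:
    """Lift a scalar derivation to a Series; missing inputs yield missing."""

    def fn(df: pd.DataFrame) -> pd.Series:
        cols = [df[f] for f in fields]
        out = []
        for i in range(len(df)):
            vals = [c.iloc[i] for c in cols]
            if any(pd.isna(v) for v in vals):
                out.append(np.nan)
                continue
            try:
                v = scalar_fn(*vals)
            except DomainError as exc:
                raise DomainError(f"{exc} (row {df.index[i]})") from None
            out.append(post[v] if post is not None else v)
        return pd.Series(out, index=df.index, dtype=object)

    return fn


def _region_level_frame(df: pd.DataFrame, field: str) -> pd.DataFrame:
    """One row per region (or per distinct value when no region id exists)."""
    key = "region_id" if "region_id" in df.columns else None
    if key is None:
        return df[[field]].drop_duplicates()
    return df[[key, field]].dropna().drop_duplicates(subset=[key])


def _tertile_map(field: str, levels: tuple[str, ...]) -> Callable:
    def fn(df: pd.DataFrame) -> pd.Series:
        regional = _region_level_frame(df, field)
        codes = tertile_split(regional[field].to_numpy())
        lookup = dict(zip(regional[field], (levels[c - 1] for c in codes)))
        return df[field].map(lookup)

    return fn


def _above_average_map(field: str, levels: tuple[str, ...]) -> Callable:
    def fn(df: pd.DataFrame) -> pd.Series:
        regional = _region_level_frame(df, field)
        ref = float(regional[field].mean())
        flags = above_average_flag(regional[field].to_numpy(), ref)
        lookup = dict(zip(regional[field], (levels[f] for f in flags)))
        return df[field].map(lookup)

    return fn


def _education_fn(df: pd.DataFrame) -> pd.Series:
    """Stop-age bands; still-studying (stop age 0) falls back on current age,
    or missing when no age is available."""
    levels = ("le15", "16_19", "ge20")
    out = []
    age = df["age"] if "age" in df.columns else None
    for i in range(len(df)):
        stop = df["education_stop_age"].iloc[i]
        if pd.isna(stop):
            out.append(np.nan)
            continue
        if stop < 0:
            raise DomainError(
                f"field 'education_stop_age' has negative value at row {df.index[i]}"
            )
        if stop == 0:  # still studying
            current = age.iloc[i] if age is not None else np.nan
            out.append(levels[derive_education(current) - 1] if pd.notna(current) else np.nan)
        else:
            out.append(levels[derive_education(stop) - 1])
    return pd.Series(out, index=df.index, dtype=object)


def _wealth_fn(df: pd.DataFrame) -> pd.Series:
    paid = df["own_home_paid"]
    paying = df["own_home_paying"]
    for field, s in (("own_home_paid", paid), ("own_home_paying", paying)):
        _check_domain(s, {0, 1}, field)
    out = pd.Series(np.where(paid == 1, "paid", np.where(paying == 1, "paying", "none")),
                    index=df.index, dtype=object)
    out[paid.isna() | paying.isna()] = np.nan
    return out


def _facility_fn(df: pd.DataFrame) -> pd.Series:
    i1, i2 = df["facility_item1_4"], df["facility_item2_4"]
    for field, s in (("facility_item1_4", i1), ("facility_item2_4", i2)):
        _check_domain(s, {1, 2, 3, 4}, field)
    agreed = (i1 <= 2) | (i2 <= 2)
    out = pd.Series(np.where(agreed, "high", "low"), index=df.index, dtype=object)
    out[i1.isna() | i2.isna()] = np.nan
    return out


def _partner_children_fn(which: int) -> Callable:
    mapping = {code: ("no", "yes")[flags[which]] for code, flags in REL14_TO_FLAGS.items()}
    field = "relationship_14"

    def fn(df: pd.DataFrame) -> pd.Series:
        s = df[field]
        _check_domain(s, set(mapping), field)
        return s.map(mapping)

    return fn


def _club_fn(df: pd.DataFrame) -> pd.Series:
    fields = ["club_health", "club_sport", "club_socio", "club_other"]
    for f in fields:
        _check_domain(df[f], {0, 1}, f)
    any_yes = df[fields].sum(axis=1) > 0
    out = pd.Series(np.where(any_yes, "yes", "no"), index=df.index, dtype=object)
    out[df[fields].isna().any(axis=1)] = np.nan
    return out


def _migration_fn(df: pd.DataFrame) -> pd.Series:
    nat, res = df["nationality_iso"], df["country_iso"]
    out = []
    for i in range(len(df)):
        a, b = nat.iloc[i], res.iloc[i]
        if pd.isna(a) or pd.isna(b):
            out.append(np.nan)
            continue
        out.append(("no", "yes")[derive_migration(a, b)])
    return pd.Series(out, index=df.index, dtype=object)


def _climate_fn(which: int) -> Callable:
    field = ("temp_max_avg", "precip_daily_avg")[which]

    def fn(df: pd.DataFrame) -> pd.Series:
        out = []
        for i in range(len(df)):
            v = df[field].iloc[i]
            if pd.isna(v):
                out.append(np.nan)
                continue
            pair = categorize_climate(
                v if which == 0 else 12.0, v if which == 1 else 1.0
            )
            out.append(pair[which])
        return pd.Series(out, index=df.index, dtype=object)

    return fn


def default_recode_maps() -> list[RecodeMap]:
    """The full derivation rule set, one map per analysis variable."""
    yn = {0: "no", 1: "yes"}
    sitting_levels = ("le2h30", "2h31_4h30", "4h31_7h30", "ge7h31")
    pa_levels = ("inactive", "low", "sufficient", "high")
    netuse_levels = ("never", "monthly", "daily")
    occ_levels = ("self_employed", "professional", "desk_travel", "manual_service",
                  "housework", "unemployed", "retired", "student")
    collapse6 = {1: 2, 2: 2, 3: 2, 4: 1, 5: 1, 6: 0}

    def netuse_fn(df: pd.DataFrame) -> pd.Series:
        fields = ["netuse_home_6", "netuse_work_6", "netuse_else_6"]
        for f in fields:
            _check_domain(df[f], set(collapse6), f)
        collapsed = [df[f].map(collapse6) for f in fields]
        m = pd.concat(collapsed, axis=1).max(axis=1)
        out = m.map(lambda v: netuse_levels[int(v)] if pd.notna(v) else np.nan)
        out[pd.concat(collapsed, axis=1).isna().any(axis=1)] = np.nan
        return out

    maps = [
        RecodeMap("sitting", ("sitting_10cat",),
                  _rowwise(["sitting_10cat"], derive_sitting,
                           {i + 1: lev for i, lev in enumerate(sitting_levels)})),
        RecodeMap("pa", ("mpa_minutes", "vpa_minutes"),
                  _rowwise(["mpa_minutes", "vpa_minutes"], derive_pa,
                           {i: lev for i, lev in enumerate(pa_levels)})),
        RecodeMap("life_satisfaction", ("life_satisfaction_4",),
                  _code_map("life_satisfaction_4", {1: "yes", 2: "yes", 3: "no", 4: "no"})),
        RecodeMap("netuse",
                  ("netuse_home_6", "netuse_work_6", "netuse_else_6"), netuse_fn),
        RecodeMap("occupation", ("occupation_18",),
                  _code_map("occupation_18",
                            {raw: occ_levels[cat - 1] for raw, cat in OCC18_TO_8.items()})),
        RecodeMap("education", ("education_stop_age",), _education_fn),
        RecodeMap("social_class", ("social_class_3",),
                  _code_map("social_class_3",
                            {1: "working", 2: "middle_higher", 3: "middle_higher"})),
        RecodeMap("financial_burden", ("financial_burden_3",),
                  _code_map("financial_burden_3", {1: "yes", 2: "yes", 3: "no"})),
        RecodeMap("wealth", ("own_home_paid", "own_home_paying"), _wealth_fn),
        RecodeMap("computer", ("own_computer",), _code_map("own_computer", yn)),
        RecodeMap("internet", ("own_internet",), _code_map("own_internet", yn)),
        RecodeMap("social_media", ("social_media_pct",),
                  _above_average_map("social_media_pct", ("below_avg", "above_avg"))),
        RecodeMap("healthcare_quality", ("healthcare_quality_4",),
                  _code_map("healthcare_quality_4",
                            {1: "good", 2: "good", 3: "bad", 4: "bad"})),
        RecodeMap("healthcare_provision", ("healthcare_personnel",),
                  _tertile_map("healthcare_personnel", ("t1", "t2", "t3"))),
        RecodeMap("chronic_disease", ("chronic_disease_pct",),
                  _above_average_map("chronic_disease_pct", ("below_avg", "above_avg"))),
        RecodeMap("urbanity", ("urbanity_3",),
                  _code_map("urbanity_3", {1: "rural", 2: "town", 3: "city"})),
        RecodeMap("facility", ("facility_item1_4", "facility_item2_4"), _facility_fn),
        RecodeMap("municipality", ("municipality_item_4",),
                  _code_map("municipality_item_4",
                            {1: "low", 2: "low", 3: "high", 4: "high"})),
        RecodeMap("region", ("country_iso",), _code_map("country_iso", COUNTRY_TO_REGION)),
        RecodeMap("temperature", ("temp_max_avg",), _climate_fn(0)),
        RecodeMap("precipitation", ("precip_daily_avg",), _climate_fn(1)),
        RecodeMap("household_size", ("n_under10", "n_10to14", "n_15plus"),
                  _rowwise(["n_under10", "n_10to14", "n_15plus"], derive_household_size,
                           {0: "0", 1: "1", 2: "2", 3: "3plus"})),
        RecodeMap("partner", ("relationship_14",), _partner_children_fn(0)),
        RecodeMap("children", ("relationship_14",), _partner_children_fn(1)),
        RecodeMap("club_member",
                  ("club_health", "club_sport", "club_socio", "club_other"), _club_fn),
        RecodeMap("eu_migration", ("nationality_iso", "country_iso"), _migration_fn),
        RecodeMap("car", ("own_car",), _code_map("own_car", yn)),
        RecodeMap("sb_guidelines", ("sb_guidelines_flag",), _code_map("sb_guidelines_flag", yn)),
        RecodeMap("pa_guidelines", ("pa_guidelines_flag",), _code_map("pa_guidelines_flag", yn)),
        RecodeMap("transport_policy", ("transport_policy_flag",),
                  _code_map("transport_policy_flag", yn)),
        RecodeMap("gdp", ("gdp_eur",), _tertile_map("gdp_eur", ("t1", "t2", "t3"))),
        RecodeMap("sex", ("sex",), _code_map("sex", {1: "female", 2: "male"})),
        RecodeMap("age_group", ("age",), _rowwise(["age"], derive_age_group)),
    ]
    return maps


def passthrough_maps(schema: Iterable[VariableSchema]) -> list[RecodeMap]:
    """Identity maps for data already simulated at the categorical level."""
    out = []
    for var in schema:
        mapping = {lev: lev for lev in var.levels}
        mapping.update({i: lev for i, lev in enumerate(var.levels)})
        out.append(RecodeMap(var.name, (var.name,), _code_map(var.name, mapping)))
    return out


def apply_recodes(
    table: pd.DataFrame,
    maps: Sequence[RecodeMap] | None = None,
    schema: Sequence[VariableSchema] | None = None,
) -> pd.DataFrame:
    """Derive every analysis variable; missing inputs propagate as missing.

    Applying the default maps to a table that already contains the categorical
    targets (but none of the raw sources) is a domain error rather than a
    silent re-mapping.
    """
    maps = list(maps) if maps is not None else default_recode_maps()
    schema = list(schema) if schema is not None else default_survey_schema()
    by_name = schema_by_name(schema)
    out = {}
    for rm in maps:
        if rm.target not in by_name:
            continue
        if rm.target in table.columns and not all(
            s in table.columns for s in rm.sources
        ):
            raise DomainError(
                f"input already contains categorical column {rm.target!r}; "
                "refusing to re-map"
            )
        series = rm.apply(table)
        declared = set(by_name[rm.target].levels)
        bad = series.dropna()[~series.dropna().isin(declared)]
        if len(bad):
            raise DomainError(
                f"derived value {bad.iloc[0]!r} for {rm.target!r} is not a declared level"
            )
        out[rm.target] = series
    result = pd.DataFrame(out, index=table.index)
    missing_targets = [v.name for v in schema if v.name not in result.columns]
    if missing_targets:
        raise DomainError(f"no recode map produced variables {missing_targets}")
    return result[[v.name for v in schema]]


def complete_case_filter(
    table: pd.DataFrame, schema: Sequence[VariableSchema] | None = None
) -> CategoricalDataset:
    """Drop rows with any missing analysis variable; log the retained count."""
    schema = list(schema) if schema is not None else default_survey_schema()
    cols = [v.name for v in schema]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise DomainError(f"table is missing analysis variables {missing_cols}")
    keep = table[cols].notna().all(axis=1)
    retained = table.loc[keep, cols]
    logger.info(
        "complete-case filter: retained %d of %d rows", len(retained), len(table)
    )
    return CategoricalDataset.from_frame(retained, schema)
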