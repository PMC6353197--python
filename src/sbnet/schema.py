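"""Variable schemas for the categorical survey analysis.

A :class:`VariableSchema` describes one analysis variable: its name, the
determinant cluster it belongs to, its ordered category levels and whether it
varies per respondent (``micro``) or is constant within a region (``macro``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

CLUSTERS = (
    "psychology_behaviour",
    "institutional_home",
    "physical_health",
    "built_natural",
    "social_cultural",
    "politics_economics",
    "demographic",
)

#: Name of the sedentary-behaviour (sitting time) variable.
SB_VARIABLE = "sitting"
#: Name of the physical-activity variable (excluded by default downstream).
PA_VARIABLE = "pa"

YES_NO = ("no", "yes")


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single categorical analysis variable."""

    name: str
    cluster: str
    levels: tuple[str, ...]
    scope: str = "micro"  # "micro" | "macro"

    def __post_init__(self) -> None:
        if self.cluster not in CLUSTERS:
            raise ValueError(
                f"unknown cluster {self.cluster!r} for variable {self.name!r}; "
                f"expected one of {CLUSTERS}"
            )
        if self.scope not in ("micro", "macro"):
            raise ValueError(f"scope must be 'micro' or 'macro', got {self.scope!r}")
        if len(self.levels) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"duplicate level labels in variable {self.name!r}")

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    def code_of(self, label: str) -> int:
        return self.levels.index(label)


def default_survey_schema() -> list[VariableSchema]:
    """The default roster of analysis variables.

    31 determinant variables across the six clusters plus sex and age group
    (33 columns in total).  Downstream analyses drop the physical-activity
    variable by default, giving a 32-node overall network (including sex and
    age) and 30-node stratum networks.
    """
    t3 = ("t1", "t2", "t3")
    ba = ("below_avg", "above_avg")
    spec: list[tuple[str, str, tuple[str, ...], str]] = [
        # psychology and behaviour
        ("sitting", "psychology_behaviour",
         ("le2h30", "2h31_4h30", "4h31_7h30", "ge7h31"), "micro"),
        ("pa", "psychology_behaviour",
         ("inactive", "low", "sufficient", "high"), "micro"),
        ("life_satisfaction", "psychology_behaviour", YES_NO, "micro"),
        ("netuse", "psychology_behaviour", ("never", "monthly", "daily"), "micro"),
        # institutional and home settings
        ("occupation", "institutional_home",
         ("self_employed", "professional", "desk_travel", "manual_service",
          "housework", "unemployed", "retired", "student"), "micro"),
        ("education", "institutional_home", ("le15", "16_19", "ge20"), "micro"),
        ("social_class", "institutional_home", ("working", "middle_higher"), "micro"),
        ("financial_burden", "institutional_home", YES_NO, "micro"),
        ("wealth", "institutional_home", ("none", "paying", "paid"), "micro"),
        ("computer", "institutional_home", YES_NO, "micro"),
        ("internet", "institutional_home", YES_NO, "micro"),
        ("social_media", "institutional_home", ba, "macro"),
        # physical health and wellbeing
        ("healthcare_quality", "physical_health", ("bad", "good"), "micro"),
        ("healthcare_provision", "physical_health", t3, "macro"),
        ("chronic_disease", "physical_health", ba, "macro"),
        # built and natural environment
        ("urbanity", "built_natural", ("rural", "town", "city"), "micro"),
        ("facility", "built_natural", ("low", "high"), "micro"),
        ("municipality", "built_natural", ("low", "high"), "micro"),
        ("region", "built_natural",
         ("western_central", "southern", "northern", "eastern"), "macro"),
        ("temperature", "built_natural", ("cold", "moderate", "hot"), "macro"),
        ("precipitation", "built_natural", ("dry", "moderate", "wet"), "macro"),
        # social and cultural context
        ("household_size", "social_cultural", ("0", "1", "2", "3plus"), "micro"),
        ("partner", "social_cultural", YES_NO, "micro"),
        ("children", "social_cultural", YES_NO, "micro"),
        ("club_member", "social_cultural", YES_NO, "micro"),
        ("eu_migration", "social_cultural", YES_NO, "micro"),
        # politics and economics
        ("car", "politics_economics", YES_NO, "micro"),
        ("sb_guidelines", "politics_economics", YES_NO, "macro"),
        ("pa_guidelines", "politics_economics", YES_NO, "macro"),
        ("transport_policy", "politics_economics", YES_NO, "macro"),
        ("gdp", "politics_economics", t3, "macro"),
        # demographics (stratification variables)
        ("sex", "demographic", ("female", "male"), "micro"),
        ("age_group", "demographic", ("15_25", "26_44", "45_64", "65plus"), "micro"),
    ]
    return [VariableSchema(n, c, lv, s) for n, c, lv, s in spec]


def schema_by_name(schema: Iterable[VariableSchema]) -> dict[str, VariableSchema]:
    out: dict[str, VariableSchema] = {}
    for var in schema:
        if var.name in out:
            raise ValueError(f"duplicate variable name {var.name!r}")
        out[var.name] = var
    return out


def validate_schema(schema: Iterable[VariableSchema], require_sb: bool = True) -> None:
    """Check cross-variable invariants of a schema set."""
    by_name = schema_by_name(schema)
    if require_sb:
        if SB_VARIABLE not in by_name:
            raise ValueError(f"schema must contain the {SB_VARIABLE!r} variable")
        if by_name[SB_VARIABLE].cardinality != 4:
            raise ValueError(f"{SB_VARIABLE!r} must have exactly 4 levels")
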