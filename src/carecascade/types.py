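"""Core domain types, schema constants and exceptions.

The package operates on survey microdata held in a :class:`pandas.DataFrame`
with one row per participant (columns listed in :data:`SCHEMA_COLUMNS`).
``SurveyIndividual`` is the record-level view of one row; the frame is the
working container throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Categorical domains
# ---------------------------------------------------------------------------

#: Care-initiative settings (operational districts), in the fixed order used
#: for deterministic fills and stratified output.
SETTINGS = [
    "coexistence",
    "community_based",
    "health_center_based",
    "health_center_with_context",
    "hospital_based",
]

AGE_GROUPS = ["40-49", "50-59", "60+"]
SEXES = ["male", "female"]
MARITAL_LEVELS = [
    "married_or_with_spouse",
    "widowed_or_not_with_spouse",
    "never",
]
EDUCATION_LEVELS = [
    "none_or_less_than_primary",
    "primary",
    "secondary_or_higher",
]
PROVIDERS = ["public", "private", "other", "none"]

N_ASSETS = 20
ASSET_COLUMNS = [f"asset_{i+1:02d}" for i in range(N_ASSETS)]

BOOL_COLUMNS = [
    "takes_t2d_drugs",
    "takes_insulin",
    "ever_tested_3y",
    "ever_told_t2d",
    "care_past_12m",
    "advice_diet",
    "advice_weight",
    "advice_smoking",
    "advice_exercise",
]

CATEGORICAL_DOMAINS = {
    "setting": SETTINGS,
    "age_group": AGE_GROUPS,
    "sex": SEXES,
    "education": EDUCATION_LEVELS,
    "marital": MARITAL_LEVELS,
    "provider_of_diagnosis": PROVIDERS,
}

#: Full microdata schema, in canonical column order.
SCHEMA_COLUMNS = (
    ["participant_id", "household_id", "setting", "age_years", "age_group",
     "sex", "education", "marital"]
    + ASSET_COLUMNS
    + ["fbg_mg_dl", "hba1c_pct"]
    + BOOL_COLUMNS
    + ["provider_of_diagnosis"]
)

#: Covariates accepted by the association module, in the fixed order used for
#: elimination tie-breaking.
ANALYSIS_COVARIATES = [
    "age_group",
    "sex",
    "marital",
    "education",
    "wealth_quintile",
    "setting",
]

#: Reference level per covariate block in the undiagnosed-status model.
REFERENCE_LEVELS = {
    "age_group": "60+",
    "sex": "female",
    "marital": "married_or_with_spouse",
    "education": "secondary_or_higher",
    "wealth_quintile": 5,
    "setting": "hospital_based",
}

CASCADE_STAGES = ["tested", "diagnosed", "in_care", "in_treatment", "under_control"]
CASCADE_BARS = ["prevalence"] + CASCADE_STAGES


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class CareCascadeError(Exception):
    """Base class for package errors."""


class ParameterError(CareCascadeError, ValueError):
    """Invalid user-supplied parameter."""


class SchemaError(CareCascadeError, ValueError):
    """Microdata does not conform to the schema (names a column/row)."""


class ConsistencyError(CareCascadeError, ValueError):
    """A fixture specification violates its internal constraints."""


class DegenerateInputError(CareCascadeError, ValueError):
    """Input is structurally valid but degenerate for the requested analysis."""


class SeparationError(CareCascadeError, RuntimeError):
    """Perfect separation in a logistic fit (names the offending level)."""


class ConvergenceError(CareCascadeError, RuntimeError):
    """Logistic fit failed to converge."""


# ---------------------------------------------------------------------------
# Records and configs
# ---------------------------------------------------------------------------

@dataclass
class SurveyIndividual:
    """One participant's covariates, biomarkers and self-report flags.

    ``fbg_mg_dl`` / ``hba1c_pct`` use ``None`` for a missing measurement.
    """

    participant_id: str
    household_id: str
    setting: str
    age_years: int
    age_group: str
    sex: str
    education: str
    marital: str
    assets: tuple
    fbg_mg_dl: Optional[float]
    hba1c_pct: Optional[float]
    takes_t2d_drugs: bool
    takes_insulin: bool
    ever_tested_3y: bool
    ever_told_t2d: bool
    care_past_12m: bool
    advice_diet: bool
    advice_weight: bool
    advice_smoking: bool
    advice_exercise: bool
    provider_of_diagnosis: str

    def validate(self) -> None:
        if self.age_years < 40:
            raise ParameterError(f"age_years must be >= 40, got {self.age_years}")
        expected = age_group_of(self.age_years)
        if self.age_group != expected:
            raise ParameterError(
                f"age_group {self.age_group!r} inconsistent with age_years "
                f"{self.age_years} (expected {expected!r})")
        if self.fbg_mg_dl is not None and not (30 < self.fbg_mg_dl < 600):
            raise ParameterError(f"fbg_mg_dl out of range: {self.fbg_mg_dl}")
        if self.hba1c_pct is not None and not (3 < self.hba1c_pct < 20):
            raise ParameterError(f"hba1c_pct out of range: {self.hba1c_pct}")
        if (self.provider_of_diagnosis != "none") != bool(self.ever_told_t2d):
            raise ParameterError(
                "provider_of_diagnosis must be 'none' exactly when "
                "ever_told_t2d is false")
        if len(self.assets) != N_ASSETS:
            raise ParameterError(f"assets must have {N_ASSETS} entries")


def age_group_of(age_years: int) -> str:
    if age_years < 50:
        return "40-49"
    if age_years < 60:
        return "50-59"
    return "60+"


def individuals_to_frame(individuals) -> pd.DataFrame:
    """Pack ``SurveyIndividual`` records into a schema-ordered DataFrame."""
    rows = []
    for ind in individuals:
        row = {f.name: getattr(ind, f.name) for f in fields(SurveyIndividual)
               if f.name != "assets"}
        row.update(dict(zip(ASSET_COLUMNS, ind.assets)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    for col in ("fbg_mg_dl", "hba1c_pct"):
        df[col] = df[col].astype(float)
    return df


def frame_to_individuals(df: pd.DataFrame) -> list:
    """Unpack a microdata frame into ``SurveyIndividual`` records."""
    out = []
    for _, row in df.iterrows():
        kwargs = {f.name: row[f.name] for f in fields(SurveyIndividual)
                  if f.name not in ("assets",)}
        for col in ("fbg_mg_dl", "hba1c_pct"):
            kwargs[col] = None if pd.isna(row[col]) else float(row[col])
        for col in BOOL_COLUMNS:
            kwargs[col] = bool(row[col])
        kwargs["age_years"] = int(row["age_years"])
        kwargs["assets"] = tuple(int(row[c]) for c in ASSET_COLUMNS)
        out.append(SurveyIndividual(**kwargs))
    return out


@dataclass
class CascadeConfig:
    """Thresholds and recall windows defining the cascade bars.

    FBG threshold 126 mg/dL with HbA1c >= 6.5% defines a biomarker case;
    treated cases with HbA1c below 8% count as under glycaemic control.
    """

    fbg_threshold: float = 126.0
    hba1c_case_threshold: float = 6.5
    hba1c_control_threshold: float = 8.0
    testing_window_years: int = 3
    care_window_months: int = 12
    treatment_window_weeks: int = 2
    denominator_mode: str = "fixed"

    def validate(self) -> None:
        if min(self.fbg_threshold, self.hba1c_case_threshold,
               self.hba1c_control_threshold) <= 0:
            raise ParameterError("all thresholds must be positive")
        if self.hba1c_control_threshold <= self.hba1c_case_threshold:
            raise ParameterError(
                "hba1c_control_threshold must exceed hba1c_case_threshold")
        if self.denominator_mode not in ("fixed", "conditional"):
            raise ParameterError(
                f"unknown denominator_mode {self.denominator_mode!r}")


# Stage retention defaults are the observed transition ratios of the surveyed
# cascade: 353/560 tested, 309/353 diagnosed, 279/309 in care, 273/279
# treated, 60/273 controlled; prevalence 560/5072.
@dataclass
class GeneratorParams:
    """Parameters of the synthetic-survey generator (see docs/methods.md)."""

    n_per_setting: int = 1015
    prevalence: float = 560 / 5072
    p_tested_given_case: float = 353 / 560
    p_diagnosed_given_tested: float = 309 / 353
    p_care_given_diagnosed: float = 279 / 309
    p_treated_given_care: float = 273 / 279
    p_control_given_treated: float = 60 / 273
    undiagnosed_logodds: dict = field(default_factory=lambda: dict(DEFAULT_UNDIAGNOSED_LOGODDS))
    background_tested_rate: float = 0.30
    p_advice_bundle_given_treated: float = 130 / 273
    p_missing_biomarker: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_setting < 1:
            raise ParameterError("n_per_setting must be >= 1")
        probs = {
            "prevalence": self.prevalence,
            "p_tested_given_case": self.p_tested_given_case,
            "p_diagnosed_given_tested": self.p_diagnosed_given_tested,
            "p_care_given_diagnosed": self.p_care_given_diagnosed,
            "p_treated_given_care": self.p_treated_given_care,
            "p_control_given_treated": self.p_control_given_treated,
            "background_tested_rate": self.background_tested_rate,
            "p_advice_bundle_given_treated": self.p_advice_bundle_given_treated,
            "p_missing_biomarker": self.p_missing_biomarker,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.undiagnosed_logodds) - set(UNDIAGNOSED_EFFECT_KEYS)
        if unknown:
            raise ParameterError(
                f"unknown undiagnosed_logodds keys: {sorted(unknown)}")


#: Covariate levels that may carry a planted log-odds offset on the
#: probability of remaining undiagnosed (reference levels carry none).
UNDIAGNOSED_EFFECT_KEYS = [
    "age_40_49",
    "age_50_59",
    "male",
    "poorest_quintile",
    "coexistence",
    "community_based",
    "health_center_based",
    "health_center_with_context",
]

#: Default planted effects: the adjusted odds ratios the survey analysis
#: reported for undiagnosed status (reference: age 60+, female, richest
#: quintile, hospital-based setting), on the log-odds scale.
DEFAULT_UNDIAGNOSED_LOGODDS = {
    "age_40_49": float(np.log(3.2)),
    "age_50_59": float(np.log(1.2)),
    "male": float(np.log(1.7)),
    "poorest_quintile": float(np.log(2.3)),
    "coexistence": float(np.log(1.9)),
    "community_based": float(np.log(1.9)),
    "health_center_based": float(np.log(2.1)),
    "health_center_with_context": float(np.log(1.2)),
}
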