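"""Cascade-of-care classification and fixed-denominator cascade assembly.

A participant is a T2D case when both biomarkers sit at or above the
diagnostic thresholds (FBG >= 126 mg/dL and HbA1c >= 6.5%, both measured)
or when they report taking antidiabetic drugs or insulin, irrespective of
biomarker values.  The five downstream stages are nested conjunctions —
tested, diagnosed, in care, in treatment, under control — and every
percentage is computed against the fixed prevalence-bar denominator, so
drops between bars show cumulative leakage along the care continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import CASCADE_STAGES, CascadeConfig, ParameterError, SETTINGS

ADVICE_COLUMNS = ["advice_diet", "advice_weight", "advice_smoking",
                  "advice_exercise"]


@dataclass
class CascadeResult:
    """Bar counts and fixed-denominator percentages for one stratum."""

    total_n: int
    denominator: int
    bars: list                  # [(stage, count, percent-of-denominator)]
    advice_bundle: tuple        # (count among treated, percent among treated)
    stratum: Optional[str] = None
    degenerate: bool = False    # true when the denominator is zero
    raw_flag_counts: dict = field(default_factory=dict)  # non-nested, diagnostic

    @property
    def prevalence_pct(self) -> float:
        return 100.0 * self.denominator / self.total_n if self.total_n else 0.0

    def bar_count(self, stage: str) -> int:
        for name, count, _ in self.bars:
            if name == stage:
                return count
        raise ParameterError(f"unknown stage {stage!r}")

    def bar_percent(self, stage: str) -> float:
        for name, _, pct in self.bars:
            if name == stage:
                return pct
        raise ParameterError(f"unknown stage {stage!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stratum": self.stratum or "overall", "stage": name,
                 "count": count, "percent": pct}
                for name, count, pct in self.bars]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum or "overall",
            "total_n": self.total_n,
            "denominator": self.denominator,
            "degenerate": self.degenerate,
            "bars": [{"stage": s, "count": c, "percent": p}
                     for s, c, p in self.bars],
            "advice_bundle": {"count": self.advice_bundle[0],
                              "percent_of_treated": self.advice_bundle[1]},
            "raw_flag_counts": self.raw_flag_counts,
        }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def case_mask(df: pd.DataFrame, config: CascadeConfig = None) -> pd.Series:
    """Vectorized T2D case definition.

    The biomarker clause requires both measurements present; a missing value
    fails the clause (no imputation).  Reported drug or insulin use
    classifies a participant as a case irrespective of biomarkers.
    """
    config = config or CascadeConfig()
    config.validate()
    fbg = df["fbg_mg_dl"]
    hba1c = df["hba1c_pct"]
    biomarker = (fbg.notna() & hba1c.notna()
                 & (fbg >= config.fbg_threshold)
                 & (hba1c >= config.hba1c_case_threshold))
    drugs = df["takes_t2d_drugs"].astype(bool) | df["takes_insulin"].astype(bool)
    return biomarker | drugs


def classify_case(individual, config: CascadeConfig = None) -> bool:
    """Scalar case classification for one record (Series or dataclass)."""
    return bool(case_mask(_as_frame(individual), config).iloc[0])


def stage_masks(df: pd.DataFrame, config: CascadeConfig = None) -> pd.DataFrame:
    """Nested stage membership for every row (regardless of case status).

    Each stage is the conjunction of its own flag with all preceding stages:
    a diagnosed-but-never-tested respondent does not count as diagnosed.
    """
    config = config or CascadeConfig()
    config.validate()
    drugs = df["takes_t2d_drugs"].astype(bool) | df["takes_insulin"].astype(bool)
    out = pd.DataFrame(index=df.index)
    out["tested"] = df["ever_tested_3y"].astype(bool)
    out["diagnosed"] = out["tested"] & df["ever_told_t2d"].astype(bool)
    out["in_care"] = out["diagnosed"] & df["care_past_12m"].astype(bool)
    out["in_treatment"] = out["in_care"] & drugs
    out["under_control"] = (out["in_treatment"] & df["hba1c_pct"].notna()
                            & (df["hba1c_pct"] < config.hba1c_control_threshold))
    return out


def classify_stage(individual, stage: str, config: CascadeConfig = None) -> bool:
    """Scalar nested-stage classification for one record."""
    if stage not in CASCADE_STAGES:
        raise ParameterError(
            f"unknown stage {stage!r}; expected one of {CASCADE_STAGES}")
    return bool(stage_masks(_as_frame(individual), config)[stage].iloc[0])


def advice_bundle_mask(df: pd.DataFrame) -> pd.Series:
    """True when all four lifestyle-advice flags are reported."""
    out = pd.Series(True, index=df.index)
    for col in ADVICE_COLUMNS:
        out &= df[col].astype(bool)
    return out


def advice_bundle(individual) -> bool:
    """Scalar advice-bundle indicator for one record."""
    return bool(advice_bundle_mask(_as_frame(individual)).iloc[0])


def _as_frame(individual) -> pd.DataFrame:
    if isinstance(individual, pd.Series):
        return individual.to_frame().T
    if isinstance(individual, pd.DataFrame):
        return individual
    from .types import individuals_to_frame
    return individuals_to_frame([individual])


# ---------------------------------------------------------------------------
# Cascade assembly
# ---------------------------------------------------------------------------

def build_cascade(df: pd.DataFrame, config: CascadeConfig = None,
                  stratify_by: Optional[str] = None):
    """Assemble the six-bar fixed-denominator cascade.

    With ``stratify_by`` (e.g. ``"setting"``) returns a list whose first
    element is the overall cascade followed by one result per stratum in
    canonical order; otherwise a single :class:`CascadeResult`.  A stratum
    with no cases is returned degenerate, with all-zero bars and percentages
    defined as 0.
    """
    if len(df) == 0:
        raise ParameterError("cannot build a cascade from an empty collection")
    config = config or CascadeConfig()
    config.validate()

    overall = _one_cascade(df, config, stratum=None)
    if stratify_by is None:
        return overall
    if stratify_by not in df.columns:
        raise ParameterError(f"unknown stratification column {stratify_by!r}")
    levels = (SETTINGS if stratify_by == "setting"
              else sorted(df[stratify_by].unique()))
    results = [overall]
    for level in levels:
        sub = df[df[stratify_by] == level]
        if len(sub):
            results.append(_one_cascade(sub, config, stratum=str(level)))
    return results


def _one_cascade(df: pd.DataFrame, config: CascadeConfig,
                 stratum) -> CascadeResult:
    cases = df[case_mask(df, config)]
    denom = len(cases)
    stages = stage_masks(cases, config)

    def pct(count, base):
        return 100.0 * count / base if base else 0.0

    bars = [("prevalence", denom, pct(denom, denom))]
    if config.denominator_mode == "fixed":
        for stage in CASCADE_STAGES:
            c = int(stages[stage].sum())
            bars.append((stage, c, pct(c, denom)))
    else:  # conditional denominators, diagnostic display only
        prev = denom
        for stage in CASCADE_STAGES:
            c = int(stages[stage].sum())
            bars.append((stage, c, pct(c, prev)))
            prev = c

    treated = cases[stages["in_treatment"]]
    n_bundle = int(advice_bundle_mask(treated).sum()) if len(treated) else 0
    raw = {
        "ever_tested_3y": int(cases["ever_tested_3y"].astype(bool).sum()),
        "ever_told_t2d": int(cases["ever_told_t2d"].astype(bool).sum()),
        "care_past_12m": int(cases["care_past_12m"].astype(bool).sum()),
        "takes_t2d_drugs_or_insulin": int(
            (cases["takes_t2d_drugs"].astype(bool)
             | cases["takes_insulin"].astype(bool)).sum()),
    }
    return CascadeResult(
        total_n=len(df),
        denominator=denom,
        bars=bars,
        advice_bundle=(n_bundle, pct(n_bundle, len(treated))),
        stratum=stratum,
        degenerate=(denom == 0),
        raw_flag_counts=raw,
    )


def undiagnosed_mask(df: pd.DataFrame, config: CascadeConfig = None) -> pd.Series:
    """Cases never told by a health worker that they have T2D."""
    return case_mask(df, config) & ~df["ever_told_t2d"].astype(bool)
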