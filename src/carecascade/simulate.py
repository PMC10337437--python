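"""Synthetic survey generation, fixture reconstruction, and microdata I/O.

Two ways to obtain individual-level data:

``generate_population``
    Draws a stochastic population of adults aged >=40 across the five
    care-initiative settings.  True T2D cases receive biomarkers above the
    diagnostic thresholds (or below them with the medication flag set, for
    treated-and-controlled cases) and move through the care continuum as a
    nested Markov chain; the probability of remaining undiagnosed depends on
    covariates through planted log-odds offsets.

``reconstruct_fixture``
    Deterministically builds an individual-level dataset from published
    summary counts (cascade bars, covariate-by-diagnosis-status tables,
    diagnosing-provider counts) such that re-running the cascade engine and
    the cross-tabulations reproduces every count exactly.  Biomarker values
    are synthetic representatives consistent with each record's stage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import (
    AGE_GROUPS,
    ANALYSIS_COVARIATES,
    ASSET_COLUMNS,
    BOOL_COLUMNS,
    CATEGORICAL_DOMAINS,
    ConsistencyError,
    EDUCATION_LEVELS,
    GeneratorParams,
    MARITAL_LEVELS,
    N_ASSETS,
    ParameterError,
    SCHEMA_COLUMNS,
    SETTINGS,
    SEXES,
    SchemaError,
)

# Representative biomarker values used by the deterministic fixture: any
# values satisfying each record's stage constraints are acceptable.
_FBG_CASE = 150.0
_FBG_RAISED_NONCASE = 150.0
_FBG_NORMAL = 95.0
_HBA1C_UNCONTROLLED = 9.0
_HBA1C_CONTROLLED = 7.5
_HBA1C_RAISED_NONCASE = 6.0
_HBA1C_NORMAL = 5.5

#: Nested asset-ownership counts per wealth quintile used by the fixture
#: (quintile q households own the first counts[q-1] items).
_FIXTURE_ASSET_COUNTS = [0, 5, 10, 15, 20]

_REPRESENTATIVE_AGE = {"40-49": 44, "50-59": 54, "60+": 67}


# ---------------------------------------------------------------------------
# Fixture specification
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Published summary counts from which a dataset is reconstructed."""

    total_n: int
    raised_fbg: int
    cascade: Mapping[str, int]          # cases, tested, ..., under_control
    advice_bundle: int
    covariate_tables: Mapping[str, Mapping[object, Sequence[int]]]
    provider_counts: Mapping[str, Sequence[int]]  # per setting [pub, priv, other]

    def validate(self) -> None:
        order = ["cases", "tested", "diagnosed", "in_care", "in_treatment",
                 "under_control"]
        missing = [k for k in order if k not in self.cascade]
        if missing:
            raise ConsistencyError(f"cascade counts missing {missing}")
        counts = [int(self.cascade[k]) for k in order]
        if any(c < 0 for c in counts):
            raise ConsistencyError("cascade counts must be non-negative")
        for prev, cur, name in zip(counts, counts[1:], order[1:]):
            if cur > prev:
                raise ConsistencyError(
                    f"cascade bar '{name}' ({cur}) exceeds its predecessor "
                    f"({prev}): bars must be non-increasing")
        cases, _, diagnosed = counts[0], counts[1], counts[2]
        if cases > self.total_n:
            raise ConsistencyError("cases exceed total_n")
        if self.raised_fbg < cases:
            raise ConsistencyError(
                "raised_fbg must be >= cases (every fixture case carries "
                "raised fasting glucose)")
        if self.raised_fbg > self.total_n:
            raise ConsistencyError("raised_fbg exceeds total_n")
        if self.advice_bundle > self.cascade["in_treatment"]:
            raise ConsistencyError("advice_bundle exceeds in_treatment")
        undiagnosed = cases - diagnosed
        for cov, table in self.covariate_tables.items():
            arr = np.array([list(map(int, v)) for v in table.values()])
            if (arr < 0).any():
                raise ConsistencyError(f"negative count in {cov} table")
            col = arr.sum(axis=0)
            if tuple(col) != (diagnosed, undiagnosed):
                raise ConsistencyError(
                    f"{cov} table columns sum to {tuple(col)}, expected "
                    f"({diagnosed}, {undiagnosed})")
        missing_tabs = [c for c in ANALYSIS_COVARIATES
                        if c not in self.covariate_tables]
        if missing_tabs:
            raise ConsistencyError(
                f"covariate_tables missing {missing_tabs}")
        setting_table = self.covariate_tables["setting"]
        prov_total = 0
        for setting, (d_count, _) in setting_table.items():
            prov = list(map(int, self.provider_counts.get(setting, (0, 0, 0))))
            if sum(prov) != int(d_count):
                raise ConsistencyError(
                    f"provider counts for {setting} sum to {sum(prov)}, "
                    f"expected {d_count} diagnosed")
            prov_total += sum(prov)
        if prov_total != diagnosed:
            raise ConsistencyError("provider counts do not sum to diagnosed")
        quintile_tab = self.covariate_tables.get("wealth_quintile")
        if quintile_tab is not None:
            targets = _quintile_sizes(self.total_n)
            for q, size in zip(sorted(quintile_tab), targets):
                if sum(quintile_tab[q]) > size:
                    raise ConsistencyError(
                        f"wealth quintile {q} case count exceeds the "
                        f"quintile's total size {size}")


def load_fixture_spec(path) -> FixtureSpec:
    """Load a :class:`FixtureSpec` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    spec = FixtureSpec(
        total_n=int(raw["total_n"]),
        raised_fbg=int(raw["raised_fbg"]),
        cascade={k: int(v) for k, v in raw["cascade"].items()},
        advice_bundle=int(raw["advice_bundle"]),
        covariate_tables=raw["covariate_tables"],
        provider_counts=raw["provider_counts"],
    )
    spec.validate()
    return spec


def paper_fixture_spec() -> FixtureSpec:
    """The packaged fixture transcribed from the published survey counts."""
    ref = (importlib.resources.files("carecascade")
           / "data" / "paper_fixture.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_fixture_spec(path)


def _quintile_sizes(n: int) -> list:
    """Sizes of the five rank-partition quintiles (first groups take the
    remainder), matching :func:`carecascade.wealth.compute_wealth_index`."""
    base, rem = divmod(n, 5)
    return [base + (1 if i < rem else 0) for i in range(5)]


# ---------------------------------------------------------------------------
# Deterministic reconstruction
# ---------------------------------------------------------------------------

def _block_fill(level_counts, n, fill=None):
    """Assign levels to n slots in contiguous blocks, in the given order."""
    out = np.empty(n, dtype=object)
    pos = 0
    for level, count in level_counts:
        out[pos:pos + count] = level
        pos += count
    if pos != n:
        if fill is None:
            raise ConsistencyError(
                f"block fill covers {pos} of {n} slots")
        out[pos:] = fill
    return out


def _table_column(spec: FixtureSpec, covariate: str, col: int, order) -> list:
    table = spec.covariate_tables[covariate]
    return [(level, int(table[level][col])) for level in order
            if level in table]


def reconstruct_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Build a deterministic individual-level dataset reproducing ``spec``.

    The allocation is a greedy block fill in a fixed covariate order
    (age, sex, marital, education, wealth, setting); only the margins present
    in the spec are guaranteed, not unprinted higher-order joints.
    Seed-free and idempotent.
    """
    spec.validate()
    cas = {k: int(v) for k, v in spec.cascade.items()}
    n_cases = cas["cases"]
    n_diag = cas["diagnosed"]
    n_undiag = n_cases - n_diag
    n_noncase = spec.total_n - n_cases

    df = pd.DataFrame(index=range(spec.total_n), columns=SCHEMA_COLUMNS)
    is_case = np.zeros(spec.total_n, dtype=bool)
    is_case[:n_cases] = True
    diag_sl = slice(0, n_diag)                 # cases ever told
    undiag_sl = slice(n_diag, n_cases)         # cases never told
    noncase_sl = slice(n_cases, spec.total_n)

    for col in BOOL_COLUMNS:
        df[col] = False
    df["provider_of_diagnosis"] = "none"

    # --- covariates among cases: independent block fills per status column
    for cov in ("age_group", "sex", "marital", "education"):
        order = CATEGORICAL_DOMAINS[cov] if cov != "age_group" else AGE_GROUPS
        df.loc[df.index[diag_sl], cov] = _block_fill(
            _table_column(spec, cov, 0, order), n_diag)
        df.loc[df.index[undiag_sl], cov] = _block_fill(
            _table_column(spec, cov, 1, order), n_undiag)

    # settings among cases
    setting_diag = _table_column(spec, "setting", 0, SETTINGS)
    setting_undiag = _table_column(spec, "setting", 1, SETTINGS)
    df.loc[df.index[diag_sl], "setting"] = _block_fill(setting_diag, n_diag)
    df.loc[df.index[undiag_sl], "setting"] = _block_fill(setting_undiag, n_undiag)

    # provider within each diagnosed setting block
    providers = []
    for setting, count in setting_diag:
        pub, priv, other = map(int, spec.provider_counts[setting])
        providers.extend(["public"] * pub + ["private"] * priv
                         + ["other"] * other)
    df.loc[df.index[diag_sl], "provider_of_diagnosis"] = providers

    # wealth quintile: cases by table, non-cases fill each quintile to its
    # rank-partition size so the PCA quintiles reproduce the table exactly
    quintile = np.empty(spec.total_n, dtype=int)
    q_diag = _table_column(spec, "wealth_quintile", 0, [1, 2, 3, 4, 5])
    q_undiag = _table_column(spec, "wealth_quintile", 1, [1, 2, 3, 4, 5])
    quintile[diag_sl] = _block_fill(q_diag, n_diag).astype(int)
    quintile[undiag_sl] = _block_fill(q_undiag, n_undiag).astype(int)
    sizes = _quintile_sizes(spec.total_n)
    case_per_q = {q: 0 for q in range(1, 6)}
    for q in quintile[:n_cases]:
        case_per_q[int(q)] += 1
    noncase_fill = [(q, sizes[q - 1] - case_per_q[q]) for q in range(1, 6)]
    quintile[noncase_sl] = _block_fill(noncase_fill, n_noncase).astype(int)

    # --- cascade stages among diagnosed cases (prefix nesting)
    idx = df.index
    df["ever_tested_3y"] = False
    df.loc[idx[:n_diag], "ever_tested_3y"] = True
    df.loc[idx[:n_diag], "ever_told_t2d"] = True
    df.loc[idx[:cas["in_care"]], "care_past_12m"] = True
    df.loc[idx[:cas["in_treatment"]], "takes_t2d_drugs"] = True
    n_bundle = int(spec.advice_bundle)
    for col in ("advice_diet", "advice_weight", "advice_smoking",
                "advice_exercise"):
        df.loc[idx[:n_bundle], col] = True
    # treated without the full bundle: partial advice only
    df.loc[idx[n_bundle:cas["in_treatment"]], "advice_diet"] = True
    df.loc[idx[n_bundle:cas["in_treatment"]], "advice_exercise"] = True
    # tested-but-never-told cases
    n_tested_untold = cas["tested"] - n_diag
    df.loc[idx[n_diag:n_diag + n_tested_untold], "ever_tested_3y"] = True

    # --- biomarkers
    fbg = np.full(spec.total_n, _FBG_NORMAL)
    hba1c = np.full(spec.total_n, _HBA1C_NORMAL)
    fbg[:n_cases] = _FBG_CASE
    hba1c[:n_cases] = _HBA1C_UNCONTROLLED
    hba1c[:cas["under_control"]] = _HBA1C_CONTROLLED
    extra_raised = spec.raised_fbg - n_cases
    fbg[n_cases:n_cases + extra_raised] = _FBG_RAISED_NONCASE
    hba1c[n_cases:n_cases + extra_raised] = _HBA1C_RAISED_NONCASE
    df["fbg_mg_dl"] = fbg
    df["hba1c_pct"] = hba1c

    # --- non-case covariates: deterministic cyclic fill
    if n_noncase:
        cyc = np.arange(n_noncase)
        df.loc[idx[noncase_sl], "age_group"] = np.array(AGE_GROUPS)[cyc % 3]
        df.loc[idx[noncase_sl], "sex"] = np.array(SEXES)[cyc % 2]
        df.loc[idx[noncase_sl], "marital"] = np.array(MARITAL_LEVELS)[cyc % 3]
        df.loc[idx[noncase_sl], "education"] = np.array(EDUCATION_LEVELS)[cyc % 3]
        per = _quintile_sizes(n_noncase)  # reuse near-even split across settings
        df.loc[idx[noncase_sl], "setting"] = _block_fill(
            list(zip(SETTINGS, per)), n_noncase)

    df["age_years"] = df["age_group"].map(_REPRESENTATIVE_AGE).astype(int)

    # assets: nested ownership pattern monotone in the assigned quintile
    counts = np.array(_FIXTURE_ASSET_COUNTS)[quintile - 1]
    asset_mat = (np.arange(N_ASSETS)[None, :] < counts[:, None]).astype(int)
    df[ASSET_COLUMNS] = asset_mat

    width = len(str(spec.total_n))
    df["participant_id"] = [f"P{i+1:0{width}d}" for i in range(spec.total_n)]
    df["household_id"] = [f"H{i+1:0{width}d}" for i in range(spec.total_n)]

    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    for col in ("fbg_mg_dl", "hba1c_pct"):
        df[col] = df[col].astype(float)
    return df[SCHEMA_COLUMNS]


# ---------------------------------------------------------------------------
# Stochastic generation
# ---------------------------------------------------------------------------

def _sample_covariates(rng, n):
    """Demographics of a rural Cambodian survey population aged >=40."""
    age_group = rng.choice(AGE_GROUPS, size=n, p=[0.38, 0.30, 0.32])
    lo = np.select([age_group == "40-49", age_group == "50-59"], [40, 50], 60)
    hi = np.select([age_group == "40-49", age_group == "50-59"], [50, 60], 81)
    age_years = rng.integers(lo, hi)
    sex = rng.choice(SEXES, size=n, p=[0.36, 0.64])
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.30, 0.55, 0.15])
    marital = rng.choice(MARITAL_LEVELS, size=n, p=[0.70, 0.27, 0.03])
    return age_group, age_years, sex, education, marital


def _sample_assets(rng, n):
    """20 binary asset items following a one-factor item-response model."""
    latent = rng.standard_normal(n)
    difficulty = np.linspace(-2.0, 2.0, N_ASSETS)
    p_own = expit(2.0 * (latent[:, None] - difficulty[None, :]))
    assets = (rng.random((n, N_ASSETS)) < p_own).astype(int)
    # sample-relative quintile of the latent wealth score (generator truth)
    order = np.argsort(latent, kind="stable")
    sizes = _quintile_sizes(n)
    quintile = np.empty(n, dtype=int)
    pos = 0
    for q, size in enumerate(sizes, start=1):
        quintile[order[pos:pos + size]] = q
        pos += size
    return assets, quintile


def _undiagnosed_linear_predictor(params, age_group, sex, quintile, setting):
    beta = params.undiagnosed_logodds
    lp = np.zeros(len(age_group))
    lp += np.where(age_group == "40-49", beta.get("age_40_49", 0.0), 0.0)
    lp += np.where(age_group == "50-59", beta.get("age_50_59", 0.0), 0.0)
    lp += np.where(sex == "male", beta.get("male", 0.0), 0.0)
    lp += np.where(quintile == 1, beta.get("poorest_quintile", 0.0), 0.0)
    for key in ("coexistence", "community_based", "health_center_based",
                "health_center_with_context"):
        lp += np.where(setting == key, beta.get(key, 0.0), 0.0)
    return lp


def _centered_probs(lp: np.ndarray, target: float) -> np.ndarray:
    """Probabilities expit(lp + c) with c solved so their mean equals target.

    Keeps the marginal stage-retention calibration exact while preserving the
    planted covariate log-odds (only the intercept moves).
    """
    if target <= 0.0:
        return np.zeros_like(lp)
    if target >= 1.0:
        return np.ones_like(lp)
    if np.allclose(lp, lp[0]):
        return np.full_like(lp, target)

    def gap(c):
        return expit(lp + c).mean() - target

    c = brentq(gap, -40.0, 40.0, xtol=1e-12)
    return expit(lp + c)


def generate_population(params: GeneratorParams) -> pd.DataFrame:
    """Draw a synthetic survey population under ``params``.

    Reproducible: identical params (including seed) yield identical output.
    """
    if not isinstance(params, GeneratorParams):
        raise ParameterError("params must be a GeneratorParams instance")
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_per_setting * len(SETTINGS)
    setting = np.repeat(np.array(SETTINGS, dtype=object), params.n_per_setting)

    age_group, age_years, sex, education, marital = _sample_covariates(rng, n)
    assets, quintile = _sample_assets(rng, n)

    case = rng.random(n) < params.prevalence

    told = np.zeros(n, dtype=bool)
    tested = np.zeros(n, dtype=bool)
    care = np.zeros(n, dtype=bool)
    treated = np.zeros(n, dtype=bool)
    controlled = np.zeros(n, dtype=bool)

    n_cases = int(case.sum())
    if n_cases:
        p_diag = params.p_tested_given_case * params.p_diagnosed_given_tested
        lp = _undiagnosed_linear_predictor(
            params, age_group[case], sex[case], quintile[case], setting[case])
        # planted log-odds raise the odds of remaining undiagnosed
        p_d = 1.0 - _centered_probs(lp, 1.0 - p_diag)
        told_c = rng.random(n_cases) < p_d
        # residual testing among the never-told keeps the marginal tested
        # rate at p_tested_given_case
        if p_diag < 1.0:
            resid = (params.p_tested_given_case
                     * (1.0 - params.p_diagnosed_given_tested) / (1.0 - p_diag))
        else:
            resid = 0.0
        tested_c = told_c | (rng.random(n_cases) < resid)
        care_c = told_c & (rng.random(n_cases) < params.p_care_given_diagnosed)
        treat_c = care_c & (rng.random(n_cases) < params.p_treated_given_care)
        ctrl_c = treat_c & (rng.random(n_cases) < params.p_control_given_treated)
        told[case], tested[case] = told_c, tested_c
        care[case], treated[case], controlled[case] = care_c, treat_c, ctrl_c

    tested |= (~case) & (rng.random(n) < params.background_tested_rate)

    # biomarkers
    fbg = np.clip(rng.normal(97.0, 13.0, n), 35.0, 125.0)
    hba1c = np.clip(rng.normal(5.4, 0.5, n), 3.5, 6.4)
    uncontrolled_case = case & ~controlled
    m = int(uncontrolled_case.sum())
    fbg[uncontrolled_case] = np.clip(rng.normal(165.0, 25.0, m), 126.0, 450.0)
    hba1c[uncontrolled_case] = np.clip(rng.normal(9.5, 1.5, m), 8.0, 16.0)
    m = int(controlled.sum())
    fbg[controlled] = np.clip(rng.normal(120.0, 20.0, m), 70.0, 250.0)
    hba1c[controlled] = np.clip(rng.normal(7.0, 0.4, m), 5.0, 7.9)

    if params.p_missing_biomarker > 0.0:
        # missingness may only strike records whose classification does not
        # depend on the biomarker clause (treated cases and non-cases)
        eligible = treated | ~case
        drop_f = eligible & (rng.random(n) < params.p_missing_biomarker)
        drop_h = (eligible & ~controlled
                  & (rng.random(n) < params.p_missing_biomarker))
        fbg[drop_f] = np.nan
        hba1c[drop_h] = np.nan

    takes_drugs = treated.copy()
    takes_insulin = treated & (rng.random(n) < 0.05)

    advice = np.zeros((n, 4), dtype=bool)
    if treated.any():
        t_idx = np.flatnonzero(treated)
        bundle = rng.random(t_idx.size) < params.p_advice_bundle_given_treated
        advice[t_idx[bundle]] = True
        partial = t_idx[~bundle]
        part = rng.random((partial.size, 4)) < 0.5
        full = part.all(axis=1)
        part[full, rng.integers(0, 4, int(full.sum()))] = False
        advice[partial] = part

    provider = np.full(n, "none", dtype=object)
    m = int(told.sum())
    if m:
        provider[told] = rng.choice(
            ["public", "private", "other"], size=m,
            p=[121 / 309, 177 / 309, 11 / 309])

    width = len(str(n))
    df = pd.DataFrame({
        "participant_id": [f"P{i+1:0{width}d}" for i in range(n)],
        "household_id": [f"H{i+1:0{width}d}" for i in range(n)],
        "setting": setting,
        "age_years": age_years.astype(int),
        "age_group": age_group,
        "sex": sex,
        "education": education,
        "marital": marital,
    })
    df[ASSET_COLUMNS] = assets
    df["fbg_mg_dl"] = fbg
    df["hba1c_pct"] = hba1c
    df["takes_t2d_drugs"] = takes_drugs
    df["takes_insulin"] = takes_insulin
    df["ever_tested_3y"] = tested
    df["ever_told_t2d"] = told
    df["care_past_12m"] = care
    df["advice_diet"] = advice[:, 0]
    df["advice_weight"] = advice[:, 1]
    df["advice_smoking"] = advice[:, 2]
    df["advice_exercise"] = advice[:, 3]
    df["provider_of_diagnosis"] = provider
    return df[SCHEMA_COLUMNS]


# ---------------------------------------------------------------------------
# Microdata I/O  (CSV, UTF-8, header row, "NA" for missing)
# ---------------------------------------------------------------------------

def write_microdata(df: pd.DataFrame, path) -> None:
    """Write microdata to CSV; booleans as 0/1, missing biomarkers as NA."""
    _check_columns(df.columns)
    out = df.copy()
    for col in BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, na_rep="NA", encoding="utf-8")


def read_microdata(path) -> pd.DataFrame:
    """Read and validate a microdata CSV written by :func:`write_microdata`.

    Raises :class:`SchemaError` naming the offending column and CSV row for
    unknown columns, out-of-domain categoricals or malformed numerics.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False,
                     dtype=str, encoding="utf-8")
    _check_columns(df.columns)
    df = df[SCHEMA_COLUMNS]

    def _bad_row(mask):
        return int(np.flatnonzero(mask)[0]) + 2  # 1-based + header line

    out = pd.DataFrame(index=df.index)
    out["participant_id"] = df["participant_id"]
    out["household_id"] = df["household_id"]
    for col, domain in CATEGORICAL_DOMAINS.items():
        vals = df[col]
        bad = ~vals.isin([str(v) for v in domain])
        if bad.any():
            raise SchemaError(
                f"column '{col}', row {_bad_row(bad)}: value "
                f"{vals[bad].iloc[0]!r} not in {domain}")
        out[col] = vals
    for col in ["age_years"] + ASSET_COLUMNS:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() | (num != num.round())
        if bad.any():
            raise SchemaError(
                f"column '{col}', row {_bad_row(bad)}: expected an integer, "
                f"got {df[col][bad].iloc[0]!r}")
        out[col] = num.astype(int)
    for col in ("fbg_mg_dl", "hba1c_pct"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"column '{col}', row {_bad_row(bad)}: malformed numeric "
                f"{df[col][bad].iloc[0]!r}")
        out[col] = num.astype(float)
    for col in BOOL_COLUMNS:
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            raise SchemaError(
                f"column '{col}', row {_bad_row(bad)}: expected 0/1, got "
                f"{df[col][bad].iloc[0]!r}")
        out[col] = df[col] == "1"
    return out[SCHEMA_COLUMNS]


def _check_columns(columns) -> None:
    cols = list(columns)
    missing = [c for c in SCHEMA_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    unknown = [c for c in cols if c not in SCHEMA_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")
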