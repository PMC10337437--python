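"""Bivariate contingency analysis and the undiagnosed-status logistic model.

Workflow: restrict to T2D cases, cross-tabulate diagnosed vs undiagnosed
status against each covariate (Pearson chi-square, no continuity
correction), then fit a multiple logistic regression of undiagnosed status
on all covariate blocks and prune it by backward elimination — the block
with the largest likelihood-ratio p-value is removed repeatedly until every
remaining block is significant at ``alpha``.  Adjusted odds ratios carry
Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cascade import case_mask, undiagnosed_mask
from .types import (
    ANALYSIS_COVARIATES,
    CATEGORICAL_DOMAINS,
    CascadeConfig,
    ConvergenceError,
    DegenerateInputError,
    ParameterError,
    REFERENCE_LEVELS,
    SeparationError,
)

_LEVEL_ORDERS = dict(CATEGORICAL_DOMAINS)
_LEVEL_ORDERS["wealth_quintile"] = [1, 2, 3, 4, 5]


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Covariate levels x (diagnosed, undiagnosed) counts among cases."""

    covariate: str
    table: pd.DataFrame     # index: levels; columns: diagnosed, undiagnosed

    @property
    def row_margins(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def column_margins(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.table.values.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        totals = self.column_margins
        for col in out.columns:
            denom = totals[col]
            out[f"{col}_pct"] = (100.0 * out[col] / denom) if denom else 0.0
        out.insert(0, "level", out.index)
        out.insert(0, "covariate", self.covariate)
        return out.reset_index(drop=True)


def crosstab(individuals: pd.DataFrame, covariate: str,
             config: CascadeConfig = None) -> ContingencyTable:
    """Cross-tabulate diagnosis status against one covariate, among cases."""
    allowed = ANALYSIS_COVARIATES + ["provider_of_diagnosis"]
    if covariate not in allowed:
        raise ParameterError(
            f"covariate must be one of {allowed}, got {covariate!r}")
    cases = individuals[case_mask(individuals, config)]
    if len(cases) == 0:
        raise DegenerateInputError("no cases to tabulate")
    undiag = undiagnosed_mask(cases, config)
    status = np.where(undiag, "undiagnosed", "diagnosed")
    tab = pd.crosstab(cases[covariate], pd.Series(status, index=cases.index))
    for col in ("diagnosed", "undiagnosed"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["diagnosed", "undiagnosed"]]
    order = [lv for lv in _LEVEL_ORDERS.get(covariate, list(tab.index))
             if lv in tab.index]
    tab = tab.loc[order]
    return ContingencyTable(covariate=covariate, table=tab)


def chi_square_test(table: ContingencyTable):
    """Pearson chi-square test of independence, without continuity
    correction; warns when any expected cell count is below 5."""
    obs = table.table.values
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateInputError(
            "chi-square requires at least 2 rows and 2 columns with "
            "positive margins")
    res = stats.chi2_contingency(obs, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn(
            f"{int((res.expected_freq < 5).sum())} expected cell count(s) "
            "below 5; the chi-square approximation may be poor",
            UserWarning, stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_test(table: ContingencyTable, n_resamples: int = 20_000,
                seed: int = 0) -> float:
    """Exact/permutation independence test for sparse tables.

    2x2 tables use Fisher's exact test; larger tables use a Monte Carlo
    permutation null of the Pearson statistic conditional on the margins.
    """
    obs = table.table.values
    if obs.shape == (2, 2):
        return float(stats.fisher_exact(obs).pvalue)
    stat, _, _ = chi_square_with_zeros(obs)
    rng = np.random.default_rng(seed)
    draws = stats.random_table(obs.sum(axis=1), obs.sum(axis=0)).rvs(
        n_resamples, random_state=rng)
    null_stats = _pearson_stat_batch(draws)
    return float((np.sum(null_stats >= stat - 1e-12) + 1) / (n_resamples + 1))


def chi_square_with_zeros(obs: np.ndarray):
    """Pearson statistic tolerating (skipping) zero-margin rows/columns."""
    obs = np.asarray(obs, dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _pearson_stat_batch(tables: np.ndarray) -> np.ndarray:
    tables = np.asarray(tables, dtype=float)
    row = tables.sum(axis=2, keepdims=True)
    col = tables.sum(axis=1, keepdims=True)
    n = tables.sum(axis=(1, 2), keepdims=True)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0,
                           (tables - expected) ** 2 / expected, 0.0)
    return contrib.sum(axis=(1, 2))


# ---------------------------------------------------------------------------
# Undiagnosed-status logistic model with block backward elimination
# ---------------------------------------------------------------------------

@dataclass
class UndiagnosedModelResult:
    """Final model after block-wise backward elimination."""

    retained_blocks: list
    estimates: pd.DataFrame     # covariate, level, aor, ci_low, ci_high, p, ref
    elimination_trace: list = field(default_factory=list)
    n_obs: int = 0
    llf: float = float("nan")

    def aor(self, covariate: str, level) -> float:
        rows = self.estimates
        hit = rows[(rows["covariate"] == covariate)
                   & (rows["level"].astype(str) == str(level))]
        if hit.empty:
            raise ParameterError(f"no estimate for {covariate}={level}")
        return float(hit["aor"].iloc[0])

    def ci(self, covariate: str, level):
        rows = self.estimates
        hit = rows[(rows["covariate"] == covariate)
                   & (rows["level"].astype(str) == str(level))]
        if hit.empty:
            raise ParameterError(f"no estimate for {covariate}={level}")
        return float(hit["ci_low"].iloc[0]), float(hit["ci_high"].iloc[0])


def _design_matrix(cases: pd.DataFrame, blocks: Sequence[str]):
    """Dummy-coded design with the documented reference levels dropped."""
    X = pd.DataFrame(index=cases.index)
    columns = []           # (covariate, level) for each non-reference column
    for cov in blocks:
        ref = REFERENCE_LEVELS[cov]
        levels = [lv for lv in _LEVEL_ORDERS[cov]
                  if lv in set(cases[cov])]
        for lv in levels:
            if lv == ref:
                continue
            X[f"{cov}[{lv}]"] = (cases[cov] == lv).astype(float)
            columns.append((cov, lv))
    X.insert(0, "const", 1.0)
    return X, columns


def _fit_logit(y: np.ndarray, X: pd.DataFrame, columns,
               check_separation: bool = True):
    """Binomial GLM fit by IRLS (log-likelihood tolerance 1e-8).

    ``check_separation=False`` skips the divergence check: likelihood-ratio
    comparisons remain valid when a level's MLE diverges, so intermediate
    elimination fits tolerate separation and only the final reported model
    must be estimable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            fit = model.fit(maxiter=200, tol=1e-8, scale=1.0)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular design in logistic fit: {exc}") from exc
    if not getattr(fit, "converged", True):
        raise ConvergenceError(
            "logistic fit did not converge after 200 IRLS iterations")
    if check_separation:
        se = np.asarray(fit.bse)
        coef = np.asarray(fit.params)
        bad = (np.abs(coef) > 15) | (se > 100) | ~np.isfinite(se)
        if bad[1:].any():
            cov, lv = columns[int(np.flatnonzero(bad[1:])[0])]
            raise SeparationError(
                f"perfect separation detected at level {cov}={lv}")
    return fit


def fit_undiagnosed_model(individuals: pd.DataFrame,
                          covariates: Optional[Sequence[str]] = None,
                          alpha: float = 0.05,
                          config: CascadeConfig = None,
                          test: str = "lrt") -> UndiagnosedModelResult:
    """Model undiagnosed status among cases; prune blocks backwards.

    Parameters
    ----------
    covariates
        Covariate blocks for the initial model (default: all of
        ``ANALYSIS_COVARIATES`` present in the data, regardless of their
        bivariate significance).
    alpha
        Retention threshold: elimination stops once every block's p-value is
        below ``alpha``.
    test
        ``"lrt"`` (default) removes blocks by likelihood-ratio test;
        ``"wald"`` uses the block Wald chi-square instead.
    """
    if test not in ("lrt", "wald"):
        raise ParameterError(f"test must be 'lrt' or 'wald', got {test!r}")
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if covariates is None:
        covariates = [c for c in ANALYSIS_COVARIATES
                      if c in individuals.columns]
    unknown = [c for c in covariates if c not in ANALYSIS_COVARIATES]
    if unknown:
        raise ParameterError(f"unknown covariate block(s): {unknown}")

    cases = individuals[case_mask(individuals, config)]
    if len(cases) == 0:
        raise DegenerateInputError("no cases to model")
    y = undiagnosed_mask(cases, config).to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateInputError(
            "undiagnosed status has no variation among cases")

    blocks = list(covariates)
    trace = []
    step = 0
    while True:
        X, columns = _design_matrix(cases, blocks)
        fit = _fit_logit(y, X, columns, check_separation=False)
        pvals = {}
        for cov in blocks:
            block_cols = [i for i, (c, _) in enumerate(columns) if c == cov]
            if not block_cols:
                pvals[cov] = 1.0   # block collapsed to its reference level
                continue
            if test == "lrt":
                reduced = [b for b in blocks if b != cov]
                Xr, colr = _design_matrix(cases, reduced)
                fit_r = _fit_logit(y, Xr, colr, check_separation=False)
                lr = 2.0 * (fit.llf - fit_r.llf)
                pvals[cov] = float(stats.chi2.sf(max(lr, 0.0), len(block_cols)))
            else:
                idx = [i + 1 for i in block_cols]  # offset for const
                coef = np.asarray(fit.params)[idx]
                cov_mat = np.asarray(fit.cov_params())[np.ix_(idx, idx)]
                w = float(coef @ np.linalg.solve(cov_mat, coef))
                pvals[cov] = float(stats.chi2.sf(w, len(idx)))
        worst = max(blocks, key=lambda c: pvals[c])  # first max wins ties
        if pvals[worst] < alpha:
            break
        step += 1
        trace.append({"step": step, "removed": worst,
                      "p_at_removal": pvals[worst], "test": test})
        blocks.remove(worst)
        if not blocks:
            break

    rows = []
    if blocks:
        X, columns = _design_matrix(cases, blocks)
        fit = _fit_logit(y, X, columns)
        coef = np.asarray(fit.params)
        se = np.asarray(fit.bse)
        pz = np.asarray(fit.pvalues)
        by_cov = {}
        for i, (cov, lv) in enumerate(columns):
            by_cov.setdefault(cov, []).append((i + 1, lv))
        for cov in blocks:
            for i, lv in by_cov.get(cov, []):
                rows.append({
                    "covariate": cov, "level": lv,
                    "aor": float(np.exp(coef[i])),
                    "ci_low": float(np.exp(coef[i] - 1.96 * se[i])),
                    "ci_high": float(np.exp(coef[i] + 1.96 * se[i])),
                    "p": float(pz[i]), "reference": False,
                })
            rows.append({
                "covariate": cov, "level": REFERENCE_LEVELS[cov],
                "aor": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "reference": True,
            })
        llf = float(fit.llf)
    else:
        llf = float("nan")
    estimates = pd.DataFrame(
        rows, columns=["covariate", "level", "aor", "ci_low", "ci_high",
                       "p", "reference"])
    return UndiagnosedModelResult(
        retained_blocks=blocks,
        estimates=estimates,
        elimination_trace=trace,
        n_obs=len(cases),
        llf=llf,
    )


def block_pvalues(individuals: pd.DataFrame,
                  covariates: Optional[Sequence[str]] = None,
                  config: CascadeConfig = None,
                  test: str = "lrt") -> dict:
    """Block p-values in the full (pre-elimination) model."""
    if covariates is None:
        covariates = [c for c in ANALYSIS_COVARIATES
                      if c in individuals.columns]
    cases = individuals[case_mask(individuals, config)]
    y = undiagnosed_mask(cases, config).to_numpy(dtype=float)
    X, columns = _design_matrix(cases, list(covariates))
    fit = _fit_logit(y, X, columns, check_separation=False)
    out = {}
    for cov in covariates:
        block_cols = [i for i, (c, _) in enumerate(columns) if c == cov]
        if not block_cols:
            out[cov] = 1.0
            continue
        if test == "lrt":
            reduced = [b for b in covariates if b != cov]
            Xr, colr = _design_matrix(cases, list(reduced))
            fit_r = _fit_logit(y, Xr, colr, check_separation=False)
            lr = 2.0 * (fit.llf - fit_r.llf)
            out[cov] = float(stats.chi2.sf(max(lr, 0.0), len(block_cols)))
        else:
            idx = [i + 1 for i in block_cols]
            coef = np.asarray(fit.params)[idx]
            cov_mat = np.asarray(fit.cov_params())[np.ix_(idx, idx)]
            w = float(coef @ np.linalg.solve(cov_mat, coef))
            out[cov] = float(stats.chi2.sf(w, len(idx)))
    return out
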