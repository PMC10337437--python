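"""Asset-based household wealth index and quintile assignment.

Follows the standard DHS construction: the index is the first principal
component of the standardized household asset-indicator matrix.  Scores are
oriented so that households owning more assets score positive, and quintiles
(1 = poorest .. 5 = richest) are assigned by rank with ties broken by
household identifier.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import (
    ASSET_COLUMNS,
    DegenerateInputError,
    ParameterError,
)


def compute_wealth_index(asset_matrix: pd.DataFrame,
                         household_ids=None) -> pd.DataFrame:
    """Score households on the first principal component of their assets.

    Parameters
    ----------
    asset_matrix
        One row per household, one column per binary/ordinal asset indicator
        (the microdata's ``asset_*`` columns, or any numeric indicators).
    household_ids
        Optional identifiers; defaults to ``asset_matrix.index``.

    Returns
    -------
    DataFrame with columns ``household_id``, ``score``, ``quintile`` in the
    input row order.  Scores are invariant to row ordering; quintile
    boundaries split the score ranking into five near-equal groups.
    """
    X = np.asarray(asset_matrix, dtype=float)
    if household_ids is None:
        household_ids = list(asset_matrix.index)
    household_ids = list(household_ids)
    n, _ = X.shape
    if n < 5:
        raise ParameterError(
            f"need at least 5 households to form quintiles, got {n}")

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError(
            "all asset indicators are constant; wealth index undefined")
    if not keep.all():
        dropped = [asset_matrix.columns[i] if hasattr(asset_matrix, "columns")
                   else i for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping constant asset indicator(s): {dropped}",
            UserWarning, stacklevel=2)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    corr = (Z.T @ Z) / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    loading = eigvecs[:, -1]           # leading eigenvector
    score = Z @ loading

    # orientation: households owning the most assets score positive
    total = X.sum(axis=1)
    cov = float(np.dot(score - score.mean(), total - total.mean()))
    if cov < 0 or (cov == 0 and loading.sum() < 0):
        score = -score

    quintile = _rank_quintiles(score, household_ids)
    return pd.DataFrame({
        "household_id": household_ids,
        "score": score,
        "quintile": quintile,
    })


def _rank_quintiles(score: np.ndarray, household_ids) -> np.ndarray:
    """Rank-based quintiles, ties broken by household_id order."""
    n = len(score)
    order = sorted(range(n), key=lambda i: (score[i], str(household_ids[i])))
    base, rem = divmod(n, 5)
    quintile = np.empty(n, dtype=int)
    pos = 0
    for q in range(1, 6):
        size = base + (1 if q <= rem else 0)
        for i in order[pos:pos + size]:
            quintile[i] = q
        pos += size
    return quintile


def attach_wealth_quintile(df: pd.DataFrame) -> pd.DataFrame:
    """Compute household quintiles from the microdata asset columns and
    join them back onto the individual-level frame as ``wealth_quintile``."""
    households = df.drop_duplicates("household_id").set_index("household_id")
    result = compute_wealth_index(households[ASSET_COLUMNS],
                                  households.index)
    mapping = result.set_index("household_id")["quintile"]
    out = df.copy()
    out["wealth_quintile"] = out["household_id"].map(mapping).astype(int)
    return out
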