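"""Associating potency with physicochemical descriptors.

Pearson correlations and backward stepwise ordinary least squares link the
per-endpoint potency exponents (signed) to particle-level properties such as
primary size (TEM), BET specific surface area, hydrodynamic size (DLS), zeta
potential and elemental contents.

Sign convention: correlations are computed against the *signed* exponent.
Potency tables often report absolute magnitudes; :func:`signed_beta` restores
the sign from the endpoint's known direction (viability endpoints decline with
dose, %LDH released rises).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateInputError,
    DesignError,
    ValidationError,
)
from .potency import ENDPOINT_DIRECTIONS, PotencyEstimate

logger = logging.getLogger(__name__)


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation with listwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return PearsonResult(float(r), float(p), int(n))


def signed_beta(estimate, endpoint: Optional[str] = None) -> float:
    """Signed potency exponent, restoring sign from endpoint direction if needed.

    Accepts a :class:`~nanopotency.potency.PotencyEstimate` (its own signed
    value is returned) or a bare absolute magnitude together with ``endpoint``:
    decreasing endpoints (ATP, CTB) are negated, increasing (%LDH) kept
    positive.
    """
    if isinstance(estimate, PotencyEstimate):
        return estimate.beta_signed
    beta_abs = float(estimate)
    direction = ENDPOINT_DIRECTIONS.get(endpoint)
    if direction is None:
        raise ValidationError(f"unknown endpoint direction for {endpoint!r}")
    if beta_abs == 0:
        return 0.0
    return -beta_abs if direction == "decreasing" else beta_abs


@dataclass
class AssociationResult:
    """Outcome of a backward stepwise regression for one response."""

    response: str
    retained: list[str]
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    n: int
    dropped: list[str] = field(default_factory=list)


def _ols_pvalues(X: pd.DataFrame, y: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    coefs = {c: float(fit.params[c]) for c in X.columns}
    pvals = {c: float(fit.pvalues[c]) for c in X.columns}
    return coefs, pvals


def backward_stepwise(
    X: pd.DataFrame,
    y: Sequence[float],
    alpha_remove: float = 0.10,
    *,
    response: str = "y",
    standardize: bool = True,
) -> AssociationResult:
    """Backward elimination OLS: drop the worst predictor until all p <= alpha.

    Starts from the full model (with intercept); at each step the predictor
    with the largest p-value above ``alpha_remove`` is removed. Rows with any
    missing value are dropped listwise; predictors are z-scored internally so
    coefficient scales are comparable (reported coefficients are on the
    standardized scale when ``standardize`` is true).
    """
    if not 0.0 <= alpha_remove <= 1.0:
        raise ValidationError("alpha_remove must be in [0, 1]")
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ValidationError("X and y lengths differ")
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    X, y = X.loc[keep].reset_index(drop=True), y[keep]
    n, p = X.shape
    if n < p + 2:
        raise DesignError(
            f"backward stepwise needs >= p + 2 = {p + 2} complete rows, got {n}; "
            "use pairwise correlation instead"
        )
    if standardize:
        sd = X.std(ddof=1)
        zero_var = sd[sd == 0].index.tolist()
        if zero_var:
            raise DegenerateInputError(f"zero-variance predictors: {zero_var}")
        X = (X - X.mean()) / sd
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()]))
    if rank < p + 1:
        aliased = _aliased_columns(X)
        raise CollinearityError(
            f"design matrix is rank deficient; aliased predictors: {aliased}",
            aliased=aliased,
        )

    current = list(X.columns)
    dropped: list[str] = []
    coefs: dict[str, float] = {}
    pvals: dict[str, float] = {}
    while current:
        coefs, pvals = _ols_pvalues(X[current], y)
        worst = max(current, key=lambda c: pvals[c])
        if pvals[worst] <= alpha_remove:
            break
        current.remove(worst)
        dropped.append(worst)
    if not current:
        coefs, pvals = {}, {}
    return AssociationResult(
        response=response,
        retained=current,
        coefficients={c: coefs[c] for c in current},
        pvalues={c: pvals[c] for c in current},
        n=n,
        dropped=dropped,
    )


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    # greedy scan: a column is aliased if it adds no rank to its predecessors
    cols = list(X.columns)
    base = np.ones((len(X), 1))
    aliased = []
    for c in cols:
        cand = np.column_stack([base, X[c].to_numpy()])
        if np.linalg.matrix_rank(cand) == base.shape[1]:
            aliased.append(c)
        else:
            base = cand
    return aliased


def pairwise_correlations(
    descriptors: pd.DataFrame,
    responses: pd.DataFrame,
) -> pd.DataFrame:
    """Tidy table of Pearson r for every descriptor x response pair.

    Both frames must be indexed by particle. Pairs with fewer than three
    complete observations are skipped with a logged notice.
    """
    rows = []
    joined = descriptors.join(responses, how="inner")
    for d, r in itertools.product(descriptors.columns, responses.columns):
        x = joined[d].to_numpy(dtype=float)
        y = joined[r].to_numpy(dtype=float)
        try:
            res = pearson_r(x, y)
        except (ValidationError, DegenerateInputError) as exc:
            logger.info("skipping %s vs %s: %s", d, r, exc)
            continue
        rows.append({"descriptor": d, "response": r, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
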