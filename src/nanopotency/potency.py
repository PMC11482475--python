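"""Power-law potency estimation and consensus ranking.

The dose-response model is

    FE = (Dose + 1)^beta

where FE is the fold effect relative to zero-dose controls and beta is the
potency estimate: its magnitude is the rate of change of log fold-effect per
log unit of (dose + 1), its sign the direction of the response. Viability
endpoints (ATP, CTB) decline with dose (beta < 0); %LDH released rises
(beta > 0). The +1 shift keeps the zero-dose anchor (FE = 1) informative and
finite in log space.

Consensus potency for a particle in a cell type is the mean of the absolute
betas across the three cytotoxicity endpoints; particles are ranked by it
(rank 1 = most potent).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import InsufficientDesignError, KeyingError, ValidationError

logger = logging.getLogger(__name__)

#: fixed direction metadata for the cytotoxicity endpoints
ENDPOINT_DIRECTIONS = {
    "ATP": "decreasing",
    "CTB": "decreasing",
    "LDH": "increasing",
}

#: search bounds for the one-parameter fit; generous vs. observed magnitudes
BETA_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class PotencyEstimate:
    """Fitted potency for one particle x cell type x endpoint."""

    particle: str
    cell_type: str
    endpoint: str
    beta_signed: float
    se_beta: float
    rss: float
    n_points: int

    @property
    def beta_abs(self) -> float:
        return abs(self.beta_signed)

    @property
    def direction(self) -> Optional[str]:
        return ENDPOINT_DIRECTIONS.get(self.endpoint)


@dataclass(frozen=True)
class ConsensusPotency:
    """Endpoint-averaged absolute potency for one particle x cell type."""

    particle: str
    cell_type: str
    beta_avg: float
    rank: Optional[int] = None


def _loglinear_beta(log_shift_dose: np.ndarray, log_fe: np.ndarray) -> float:
    # through-origin slope of ln FE on ln(dose + 1); origin is forced by FE(0)=1
    denom = float(np.dot(log_shift_dose, log_shift_dose))
    if denom == 0.0:
        raise InsufficientDesignError("all doses are zero; beta is unidentified")
    return float(np.dot(log_shift_dose, log_fe) / denom)


def fit_beta(
    doses: Sequence[float],
    fe: Sequence[float],
    method: str = "nls",
    *,
    particle: str = "",
    cell_type: str = "",
    endpoint: str = "",
) -> PotencyEstimate:
    """Fit FE = (dose + 1)^beta to fold-effect data.

    Parameters
    ----------
    doses, fe
        Paired dose (>= 0) and fold-effect (> 0) observations. At least three
        distinct doses, including zero, are required.
    method
        ``"nls"`` (default) minimizes squared error in FE space with a bounded
        one-dimensional search over beta; ``"loglinear"`` is the closed-form
        through-origin slope of ln FE on ln(dose + 1). On noise-free power-law
        data the two agree to high precision.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fe, dtype=float)
    if d.shape != f.shape or d.ndim != 1:
        raise ValidationError("doses and fe must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
        raise ValidationError("doses and fe must be finite")
    if np.any(d < 0):
        raise ValidationError("doses must be >= 0")
    if np.any(f <= 0):
        raise ValidationError("fold effects must be > 0")
    distinct = np.unique(d)
    if distinct.size < 3 or 0.0 not in distinct:
        raise InsufficientDesignError(
            "need >= 3 distinct doses including 0 to fit beta"
        )

    x = np.log1p(d)
    logf = np.log(f)
    beta_ll = _loglinear_beta(x, logf)

    if method == "loglinear":
        beta = beta_ll
    elif method == "nls":

        def sse(b: float) -> float:
            r = f - np.exp(b * x)
            return float(np.dot(r, r))

        res = minimize_scalar(
            sse, bounds=BETA_BOUNDS, method="bounded", options={"xatol": 1e-12}
        )
        beta = float(res.x)
        # Gauss-Newton polish: the bounded search stops on an x-tolerance,
        # a few Newton steps on the normal equation reach machine precision
        for _ in range(3):
            fitted = np.exp(beta * x)
            jac_ = x * fitted
            denom = float(np.dot(jac_, jac_))
            if denom == 0.0:
                break
            step = float(np.dot(jac_, f - fitted)) / denom
            cand = min(max(beta + step, BETA_BOUNDS[0]), BETA_BOUNDS[1])
            if sse(cand) <= sse(beta):
                beta = cand
            if abs(step) < 1e-14:
                break
    else:
        raise ValidationError(f"unknown fit method: {method!r}")

    resid = f - np.exp(beta * x)
    rss = float(np.dot(resid, resid))
    # Gauss-Newton standard error for the single parameter
    jac = x * np.exp(beta * x)
    jtj = float(np.dot(jac, jac))
    n = d.size
    if n > 1 and jtj > 0:
        se = math.sqrt(max(rss, 0.0) / (n - 1) / jtj)
    else:
        se = float("nan")
    return PotencyEstimate(
        particle=particle,
        cell_type=cell_type,
        endpoint=endpoint,
        beta_signed=beta,
        se_beta=se,
        rss=rss,
        n_points=int(n),
    )


def fit_all(fe_table: pd.DataFrame, method: str = "nls") -> pd.DataFrame:
    """Fit beta per (particle x cell type x endpoint) from a FoldEffectTable.

    Duplicate wells are first averaged per (experiment x dose); all experiments'
    per-dose means are then pooled into one fit with equal weights.
    """
    from .normalize import average_replicates

    pooled = average_replicates(fe_table)
    rows = []
    for (particle, cell_type, endpoint), grp in pooled.groupby(
        ["particle", "cell_type", "endpoint"]
    ):
        est = fit_beta(
            grp["dose"].to_numpy(),
            grp["fe"].to_numpy(),
            method=method,
            particle=particle,
            cell_type=cell_type,
            endpoint=endpoint,
        )
        rows.append(
            {
                "particle": particle,
                "cell_type": cell_type,
                "endpoint": endpoint,
                "beta_signed": est.beta_signed,
                "beta_abs": est.beta_abs,
                "se_beta": est.se_beta,
                "rss": est.rss,
                "n_points": est.n_points,
            }
        )
    return pd.DataFrame(rows)


def consensus_beta(
    b_atp: PotencyEstimate, b_ldh: PotencyEstimate, b_ctb: PotencyEstimate
) -> ConsensusPotency:
    """Average the absolute betas of the ATP, %LDH and CTB endpoints."""
    ests = (b_atp, b_ldh, b_ctb)
    keys = {(e.particle, e.cell_type) for e in ests}
    if len(keys) != 1:
        raise KeyingError(f"estimates do not share particle/cell type: {keys}")
    beta_avg = (b_atp.beta_abs + b_ldh.beta_abs + b_ctb.beta_abs) / 3.0
    particle, cell_type = keys.pop()
    return ConsensusPotency(particle=particle, cell_type=cell_type, beta_avg=beta_avg)


def rank_particles(
    consensus: Iterable[ConsensusPotency], cell_type: str
) -> list[ConsensusPotency]:
    """Rank particles of one cell type by consensus potency (1 = most potent).

    Ranking uses the full-precision beta_avg, never a rounded display value;
    exact ties are broken lexicographically by particle label with a logged
    notice.
    """
    entries = [c for c in consensus if c.cell_type == cell_type]
    labels = [c.particle for c in entries]
    if len(set(labels)) != len(labels):
        dupes = sorted({p for p in labels if labels.count(p) > 1})
        raise KeyingError(f"duplicate consensus entries for particles: {dupes}")
    order = sorted(entries, key=lambda c: (-c.beta_avg, c.particle))
    for a, b in zip(order, order[1:]):
        if a.beta_avg == b.beta_avg:
            logger.info(
                "tied consensus beta %.6g between %s and %s; broken by label",
                a.beta_avg,
                a.particle,
                b.particle,
            )
    ranked = {c.particle: i + 1 for i, c in enumerate(order)}
    return [replace(c, rank=ranked[c.particle]) for c in entries]


def consensus_table(potency: pd.DataFrame) -> pd.DataFrame:
    """Consensus beta and ranks from a tidy per-endpoint potency table.

    Expects columns particle, cell_type, endpoint, beta_abs with exactly the
    endpoints ATP, LDH, CTB per particle x cell type.
    """
    rows = []
    for cell_type, sub in potency.groupby("cell_type"):
        consensus = []
        for particle, grp in sub.groupby("particle"):
            by_ep = grp.set_index("endpoint")["beta_abs"]
            missing = {"ATP", "LDH", "CTB"} - set(by_ep.index)
            if missing:
                raise KeyingError(
                    f"{particle}/{cell_type} missing endpoints: {sorted(missing)}"
                )
            ests = {
                ep: PotencyEstimate(
                    particle=particle,
                    cell_type=cell_type,
                    endpoint=ep,
                    beta_signed=float(by_ep[ep]),
                    se_beta=float("nan"),
                    rss=float("nan"),
                    n_points=0,
                )
                for ep in ("ATP", "LDH", "CTB")
            }
            consensus.append(consensus_beta(ests["ATP"], ests["LDH"], ests["CTB"]))
        for c in rank_particles(consensus, cell_type):
            rows.append(
                {
                    "particle": c.particle,
                    "cell_type": c.cell_type,
                    "beta_avg": c.beta_avg,
                    "rank": c.rank,
                }
            )
    return pd.DataFrame(rows)
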