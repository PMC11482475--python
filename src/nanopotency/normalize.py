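"""Plate-assay normalization: blank correction, fold effects, %LDH released.

A raw assay table is a long-format :class:`pandas.DataFrame` with one row per
well and the columns

``experiment_id, cell_type, particle, dose, endpoint, role, replicate, signal``

where ``role`` is one of ``cells`` (exposed cells), ``no_cells`` (particle
suspension only, used to correct optical/chemical interference) and
``lysed_control`` (fully lysed untreated cells, the 100% reference for %LDH).

The fold effect (FE) of a well is its signal divided by the grand mean of all
zero-dose control signals within the same experiment, cell type and endpoint,
so FE = 1 means no change from control. Zero-dose wells are retained: their
mean FE is exactly 1 by construction, which anchors the power-law dose-response
fit downstream.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    KeyingError,
    NormalizationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

RAW_COLUMNS = [
    "experiment_id",
    "cell_type",
    "particle",
    "dose",
    "endpoint",
    "role",
    "replicate",
    "signal",
]

ROLES = ("cells", "no_cells", "lysed_control")

#: keys identifying a well group that shares one blank measurement
BLANK_KEYS = ["experiment_id", "cell_type", "particle", "dose", "endpoint"]

#: keys identifying one normalization stratum (grand mean of zero-dose controls)
CONTROL_KEYS = ["experiment_id", "cell_type", "endpoint"]

#: floor applied to non-positive fold effects so log-domain fits stay defined
FE_FLOOR = 1e-6


def blank_correct(cells_signal, no_cells_signal):
    """Subtract a no-cells (interference) reading from a cells reading.

    Negative results are floored at zero with a warning, since a corrected
    signal below zero has no physical meaning.
    """
    cells = np.asarray(cells_signal, dtype=float)
    blank = np.asarray(no_cells_signal, dtype=float)
    if not (np.all(np.isfinite(cells)) and np.all(np.isfinite(blank))):
        raise ValidationError("blank_correct requires finite signals")
    corrected = cells - blank
    floored = corrected < 0
    if np.any(floored):
        warnings.warn(
            "blank correction produced negative signal(s); floored at 0",
            stacklevel=2,
        )
        corrected = np.where(floored, 0.0, corrected)
    if np.ndim(cells_signal) == 0 and np.ndim(no_cells_signal) == 0:
        return float(corrected)
    return corrected


def validate_raw_table(raw: pd.DataFrame) -> None:
    """Check schema, finiteness and dose sign of a raw assay table."""
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"raw assay table missing columns: {missing}")
    bad_roles = set(raw["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown well roles: {sorted(bad_roles)}")
    dose = pd.to_numeric(raw["dose"], errors="coerce")
    signal = pd.to_numeric(raw["signal"], errors="coerce")
    if not np.isfinite(dose).all():
        raise ValidationError("doses must be finite numbers")
    if (dose < 0).any():
        raise ValidationError("doses must be >= 0")
    if not np.isfinite(signal).all():
        raise ValidationError("signals must be finite numbers")


def apply_blank_correction(raw: pd.DataFrame) -> pd.DataFrame:
    """Subtract matching no-cells blanks from cells wells, where present.

    Blanks are averaged per (experiment, cell type, particle, dose, endpoint)
    and subtracted from every cells well of that group. Groups without blanks
    pass through unchanged with a logged notice. Returns a table containing
    only ``cells`` and ``lysed_control`` rows.
    """
    validate_raw_table(raw)
    blanks = raw[raw["role"] == "no_cells"]
    out = raw[raw["role"] != "no_cells"].copy()
    if blanks.empty:
        logger.info("no no-cells blanks supplied; signals passed through")
        return out
    blank_means = blanks.groupby(BLANK_KEYS)["signal"].mean().rename("blank")
    cells_mask = out["role"] == "cells"
    cells = out[cells_mask].join(blank_means, on=BLANK_KEYS)
    n_unmatched = int(cells["blank"].isna().sum())
    if n_unmatched:
        logger.info("%d cells wells had no matching blank; passed through", n_unmatched)
    corrected = blank_correct(
        cells["signal"].to_numpy(), cells["blank"].fillna(0.0).to_numpy()
    )
    out.loc[cells_mask, "signal"] = corrected
    return out


def compute_fold_effect(
    raw: pd.DataFrame,
    *,
    subtract_blanks: bool = True,
    clip_floor: float = FE_FLOOR,
) -> pd.DataFrame:
    """Normalize signals to fold effects within each experiment.

    Each cells-role signal is divided by the grand mean of the zero-dose
    cells signals of the same (experiment, cell type, endpoint) stratum.
    No-cells blanks, when present and ``subtract_blanks`` is true, are
    subtracted first. Fold effects that are non-positive after correction are
    clipped to ``clip_floor`` with a warning.

    Returns a FoldEffectTable: columns ``experiment_id, cell_type, particle,
    dose, endpoint, replicate, fe``.
    """
    if subtract_blanks:
        table = apply_blank_correction(raw)
    else:
        validate_raw_table(raw)
        table = raw.copy()
    cells = table[table["role"] == "cells"].copy()
    if cells.empty:
        raise ValidationError("no cells-role wells in raw assay table")

    controls = cells[cells["dose"] == 0]
    grand = controls.groupby(CONTROL_KEYS)["signal"].mean().rename("grand_mean")
    missing = (
        cells.groupby(CONTROL_KEYS).size().index.difference(grand.index).tolist()
    )
    if missing:
        raise NormalizationError(
            f"groups lack zero-dose control wells: {missing}"
        )
    bad = grand[grand <= 0]
    if len(bad):
        raise DegenerateControlError(
            f"zero-dose control grand mean <= 0 for groups: {list(bad.index)}"
        )
    cells = cells.join(grand, on=CONTROL_KEYS)
    fe = cells["signal"].to_numpy(dtype=float) / cells["grand_mean"].to_numpy()
    clipped = fe <= 0
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} fold effect(s) <= 0 clipped to {clip_floor:g}",
            stacklevel=2,
        )
        fe = np.where(clipped, clip_floor, fe)
    cells["fe"] = fe
    keep = ["experiment_id", "cell_type", "particle", "dose", "endpoint", "replicate", "fe"]
    return cells[keep].reset_index(drop=True)


def average_replicates(fe_table: pd.DataFrame) -> pd.DataFrame:
    """Mean FE per (experiment x cell type x particle x endpoint x dose).

    Within-experiment duplicate wells are technical replicates; the unit of
    observation for model fitting is the experiment, so duplicates are
    averaged before any fit and n equals the number of independent experiments.
    """
    keys = ["experiment_id", "cell_type", "particle", "endpoint", "dose"]
    return fe_table.groupby(keys, as_index=False)["fe"].mean()


def compute_pct_ldh(released, lysed_totals) -> float:
    """Percent LDH released: 100 x released / mean(total LDH of lysed controls)."""
    totals = np.asarray(lysed_totals, dtype=float)
    if totals.size == 0:
        raise DegenerateControlError("no lysed-control totals supplied")
    mean_total = float(totals.mean())
    if not np.isfinite(mean_total) or mean_total <= 0:
        raise DegenerateControlError(
            f"mean lysed-control total must be positive, got {mean_total}"
        )
    released = np.asarray(released, dtype=float)
    if not np.all(np.isfinite(released)):
        raise ValidationError("released signal must be finite")
    out = 100.0 * released / mean_total
    return float(out) if out.ndim == 0 else out


def pct_ldh_table(raw: pd.DataFrame) -> pd.DataFrame:
    """%LDH released per LDH cells well, using lysed-control totals.

    Totals are pooled per (experiment, cell type): lysed controls are untreated,
    so they are shared across particles within an experiment.
    """
    validate_raw_table(raw)
    ldh = raw[raw["endpoint"] == "LDH"]
    lysed = ldh[ldh["role"] == "lysed_control"]
    cells = ldh[ldh["role"] == "cells"].copy()
    if lysed.empty:
        raise DegenerateControlError("no lysed-control wells for LDH")
    totals = (
        lysed.groupby(["experiment_id", "cell_type"])["signal"].mean().rename("total")
    )
    cells = cells.join(totals, on=["experiment_id", "cell_type"])
    if cells["total"].isna().any():
        missing = cells.loc[cells["total"].isna(), ["experiment_id", "cell_type"]]
        raise KeyingError(
            "LDH wells without matching lysed controls: "
            f"{missing.drop_duplicates().to_records(index=False).tolist()}"
        )
    if (cells["total"] <= 0).any():
        raise DegenerateControlError("lysed-control mean total <= 0")
    cells["pct_ldh"] = 100.0 * cells["signal"] / cells["total"]
    keep = ["experiment_id", "cell_type", "particle", "dose", "replicate", "pct_ldh"]
    return cells[keep].reset_index(drop=True)
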