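"""Pipeline orchestration: validate CSV inputs, run every stage, write reports.

The pipeline sequences the library stages over CSV files: fold-effect
normalization -> potency fitting -> consensus ranking -> descriptor
association -> group inference -> oxidative stress -> secretome filtering and
clustering. Outputs are plain CSV/JSON, written at full precision; a run log
records package version, configuration and seed so a run can be re-executed
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import backward_stepwise, pairwise_correlations, signed_beta
from .errors import DesignError, NanopotencyError, ValidationError
from .inference import one_way_anova, two_way_anova
from .normalize import RAW_COLUMNS, compute_fold_effect, validate_raw_table
from .potency import consensus_table, fit_all
from .stress import filter_responders, hierarchical_cluster, oxidative_stress_table

logger = logging.getLogger(__name__)

#: descriptor columns offered to the stepwise regression when present
DEFAULT_PREDICTORS = ["tem_size", "betsa", "dls_size", "zeta", "transition_metals"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for one pipeline run."""

    assay_path: Optional[str] = None
    descriptor_path: Optional[str] = None
    stress_path: Optional[str] = None
    secretome_path: Optional[str] = None
    outdir: str = "nanopotency_out"
    fit_method: str = "nls"
    alpha_remove: float = 0.10
    anova_transform: str = "auto"
    fc_cutoff: float = 1.5
    cluster_distance: str = "pearson"
    cluster_linkage: str = "average"
    stress_control: str = "control"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha_remove < 1.0:
            raise ValidationError("alpha_remove must be in (0, 1)")
        if self.fc_cutoff <= 1.0:
            raise ValidationError("fc_cutoff must be > 1")
        for p in (self.assay_path, self.descriptor_path, self.stress_path,
                  self.secretome_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Schema-check every provided CSV; return a machine-readable violation list.

    ``paths`` maps input kind (assay, descriptors, stress, secretome) to a CSV
    path. Each violation is a dict with keys ``input``, ``where``, ``message``.
    """
    violations: list[dict] = []

    def add(kind, where, message):
        violations.append({"input": kind, "where": where, "message": message})

    for kind, path in paths.items():
        try:
            df = pd.read_csv(path)
        except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
            add(kind, str(path), f"unreadable: {exc}")
            continue
        if kind == "assay":
            missing = [c for c in RAW_COLUMNS if c not in df.columns]
            if missing:
                add(kind, "header", f"missing columns: {missing}")
                continue
            dose = pd.to_numeric(df["dose"], errors="coerce")
            signal = pd.to_numeric(df["signal"], errors="coerce")
            for idx in df.index[dose.isna() | ~np.isfinite(dose)]:
                add(kind, f"row {idx}", "dose is not a finite number")
            for idx in df.index[dose < 0]:
                add(kind, f"row {idx}", f"negative dose {dose[idx]}")
            for idx in df.index[signal.isna() | ~np.isfinite(signal)]:
                add(kind, f"row {idx}", "signal is not a finite number")
            cells = df[(df["role"] == "cells") & (dose == 0)]
            have = set(map(tuple, cells[["experiment_id", "cell_type", "endpoint"]]
                           .drop_duplicates().to_numpy()))
            need = set(map(tuple, df[df["role"] == "cells"]
                           [["experiment_id", "cell_type", "endpoint"]]
                           .drop_duplicates().to_numpy()))
            for key in sorted(need - have):
                add(kind, f"experiment {key[0]}, cell_type {key[1]}, endpoint {key[2]}",
                    "no zero-dose control wells")
        elif kind == "stress":
            for col in ("treatment", "gsh", "gssg"):
                if col not in df.columns:
                    add(kind, "header", f"missing column {col!r}")
        elif kind == "secretome":
            numeric = df.select_dtypes(include=[np.number])
            if numeric.empty:
                add(kind, "header", "no numeric fold-change columns")
            elif (numeric <= 0).any().any():
                add(kind, "values", "fold changes must be > 0")
        elif kind == "descriptors":
            if "particle" not in df.columns and df.index.name != "particle":
                add(kind, "header", "missing 'particle' column")
    return violations


class StageError(NanopotencyError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage with available inputs; return the written file map.

    On any stage failure the partially written outputs of this run are removed
    and a :class:`StageError` naming the stage is raised.
    """
    config.validate()
    if config.assay_path is None:
        raise ValidationError("run_pipeline requires at least assay_path")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, **kwargs)
        written[name] = path

    stage = "validate"
    try:
        raw = pd.read_csv(config.assay_path)
        validate_raw_table(raw)

        stage = "normalize"
        fe = compute_fold_effect(raw)
        emit("fold_effect.csv", fe, index=False)

        stage = "potency"
        potency = fit_all(fe, method=config.fit_method)
        consensus = consensus_table(potency)
        wide = potency.pivot_table(
            index=["particle", "cell_type"], columns="endpoint",
            values="beta_abs", aggfunc="first",
        ).reset_index()
        report = wide.merge(consensus, on=["particle", "cell_type"])
        report = report.sort_values(["cell_type", "rank"])
        emit("potency.csv", potency, index=False)
        emit("consensus.csv", report, index=False)

        stage = "inference"
        anova_rows = []
        for (cell_type, endpoint), grp in fe.groupby(["cell_type", "endpoint"]):
            try:
                res = two_way_anova(grp, transform=config.anova_transform)
            except DesignError as exc:
                logger.info("ANOVA skipped for %s/%s: %s", cell_type, endpoint, exc)
                continue
            frame = res.to_frame()
            frame.insert(0, "endpoint", endpoint)
            frame.insert(0, "cell_type", cell_type)
            anova_rows.append(frame)
        if anova_rows:
            emit("anova.csv", pd.concat(anova_rows, ignore_index=True), index=False)

        if config.descriptor_path:
            stage = "associate"
            descriptors = pd.read_csv(config.descriptor_path).set_index("particle")
            assoc_csv, assoc_json = associate_potency(
                descriptors, potency, alpha_remove=config.alpha_remove
            )
            emit("association.csv", assoc_csv, index=False)
            path = outdir / "association.json"
            path.write_text(json.dumps(assoc_json, indent=2))
            written["association.json"] = path

        if config.stress_path:
            stage = "stress"
            stress_raw = pd.read_csv(config.stress_path)
            stress = oxidative_stress_table(stress_raw, control=config.stress_control)
            groups = [
                grp["gsh"].to_numpy() / grp["gssg"].to_numpy()
                for _, grp in stress_raw.groupby("treatment")
            ]
            if all(len(g) >= 2 for g in groups) and len(groups) >= 2:
                res = one_way_anova(groups)
                stress_anova = res.to_frame()
                emit("stress_anova.csv", stress_anova, index=False)
            emit("stress.csv", stress, index=False)

        if config.secretome_path:
            stage = "secretome"
            matrix = pd.read_csv(config.secretome_path, index_col=0)
            responders = filter_responders(matrix, cutoff=config.fc_cutoff)
            emit("responders.csv", responders)
            if responders.shape[0] >= 2 and responders.shape[1] >= 2:
                clusters = hierarchical_cluster(
                    responders,
                    distance=config.cluster_distance,
                    linkage=config.cluster_linkage,
                )
                emit("cluster_rows.csv", clusters.merge_table("rows"), index=False)
                emit("cluster_cols.csv", clusters.merge_table("cols"), index=False)
                order = pd.DataFrame(
                    {"axis": ["rows"] * len(clusters.row_order)
                             + ["cols"] * len(clusters.col_order),
                     "label": clusters.row_order + clusters.col_order}
                )
                emit("cluster_order.csv", order, index=False)

        stage = "log"
        log = {
            "package": "nanopotency",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "outputs": sorted(written),
        }
        log_path = outdir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
        written["run_log.json"] = log_path
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
    return written


def associate_potency(
    descriptors: pd.DataFrame,
    potency: pd.DataFrame,
    alpha_remove: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise correlations and stepwise regressions of signed beta on descriptors.

    Returns a tidy correlation table (descriptor, response, r, n, p) and a JSON-
    ready dict of stepwise results per response. Responses are the signed
    exponents per cell type x endpoint; stepwise fits are skipped (with a note)
    whenever fewer complete rows than predictors + 2 remain.
    """
    if "beta_signed" in potency.columns:
        betas = potency.copy()
    else:
        betas = potency.assign(
            beta_signed=[
                signed_beta(b, ep)
                for b, ep in zip(potency["beta_abs"], potency["endpoint"])
            ]
        )
    responses = betas.pivot_table(
        index="particle", columns=["cell_type", "endpoint"],
        values="beta_signed", aggfunc="first",
    )
    responses.columns = [f"beta_{ep}_{ct}" for ct, ep in responses.columns]
    numeric = descriptors.select_dtypes(include=[np.number])
    corr = pairwise_correlations(numeric, responses)

    predictors = [c for c in DEFAULT_PREDICTORS if c in numeric.columns]
    stepwise: dict[str, dict] = {}
    joined = numeric.join(responses, how="inner")
    for response in responses.columns:
        sub = joined[predictors + [response]].dropna()
        try:
            res = backward_stepwise(
                sub[predictors], sub[response].to_numpy(),
                alpha_remove=alpha_remove, response=response,
            )
        except (DesignError, NanopotencyError) as exc:
            stepwise[response] = {"skipped": str(exc), "n": int(len(sub))}
            continue
        stepwise[response] = {
            "retained": res.retained,
            "coefficients": res.coefficients,
            "pvalues": res.pvalues,
            "dropped": res.dropped,
            "n": res.n,
        }
    return corr, {"alpha_remove": alpha_remove, "stepwise": stepwise}
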