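"""Synthetic plate-assay, descriptor, stress and secretome generators.

These generators emit data with the structure of a multi-endpoint in vitro
nanoparticle screen — 8 particles x 2 cell types x 3 cytotoxicity endpoints,
a 7-point dose grid spanning 0-100 ug/cm2, 3 independent experiments with
duplicate wells — and a known ground truth, so every downstream stage
(normalization, potency fitting, association, inference, clustering) can be
tested end to end without any external data.

The generative model inverts the analysis model: each well's signal is

    signal = blank + L_e * (dose + 1)^beta_true * exp(eps)

where L_e is the experiment's control level, ``blank`` an additive
interference term measured by the no-cells wells, and eps ~ N(0, sigma^2)
multiplicative log-normal noise (assay CVs are roughly scale-proportional,
so noise is multiplicative; sigma = 0.1 approximates a typical 10% plate CV).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_DOSES = (0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 100.0)


def _default_betas() -> pd.DataFrame:
    from .datasets import zno_potency

    return zno_potency(signed=True)[
        ["particle", "cell_type", "endpoint", "beta_signed"]
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for the synthetic assay generator.

    ``betas`` holds the signed ground-truth exponents, one row per
    particle x cell type x endpoint (columns ``particle, cell_type, endpoint,
    beta_signed``); the default is the bundled reference screen's potency
    table with signs restored, so the simulated study spans realistic
    magnitudes (|beta| from ~0.001 to 1.6).
    """

    betas: pd.DataFrame = field(default_factory=_default_betas)
    doses: Sequence[float] = DEFAULT_DOSES
    n_experiments: int = 3
    duplicates: int = 2
    noise_sigma: float = 0.1
    control_signal_mean: float = 1000.0
    control_cv: float = 0.15
    blank_level: float = 20.0
    lysed_total_mean: float = 4000.0
    seed: int = 0

    def validate(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses.size < 3 or 0.0 not in doses or np.any(doses < 0):
            raise ValidationError("dose grid must include 0, be nonnegative, >= 3 points")
        if self.n_experiments < 1 or self.duplicates < 1:
            raise ValidationError("n_experiments and duplicates must be >= 1")
        if self.noise_sigma < 0 or self.control_cv < 0:
            raise ValidationError("noise_sigma and control_cv must be >= 0")
        if self.control_signal_mean <= 0 or self.lysed_total_mean <= 0:
            raise ValidationError("control and lysed means must be > 0")
        if self.blank_level < 0:
            raise ValidationError("blank_level must be >= 0")
        needed = {"particle", "cell_type", "endpoint", "beta_signed"}
        if not needed.issubset(self.betas.columns):
            raise ValidationError(f"betas table needs columns {sorted(needed)}")


def simulate_assay(config: SimulationConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a long-format raw assay table (RawAssayTable schema).

    Emits cells wells for every dose, no-cells blank wells measuring the
    additive interference term, and lysed-control wells for LDH totals.
    Identical (config, seed) pairs give bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    doses = np.asarray(config.doses, dtype=float)
    sigma = config.noise_sigma
    rows = []
    groups = config.betas.sort_values(
        ["cell_type", "particle", "endpoint"]
    ).itertuples(index=False)
    # control level varies by experiment (plate), shared by all particles of a
    # (cell type x endpoint) stratum -- mirrors one control group per plate
    levels: dict[tuple, float] = {}
    for g in groups:
        beta = float(g.beta_signed)
        for exp_i in range(1, config.n_experiments + 1):
            key = (g.cell_type, g.endpoint, exp_i)
            if key not in levels:
                levels[key] = config.control_signal_mean * float(
                    np.exp(rng.normal(0.0, config.control_cv))
                )
            level = levels[key]
            for dose in doses:
                expected = level * (dose + 1.0) ** beta
                for rep in range(1, config.duplicates + 1):
                    noise = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                    rows.append(
                        (f"E{exp_i}", g.cell_type, g.particle, dose, g.endpoint,
                         "cells", rep, config.blank_level + expected * noise)
                    )
                for rep in range(1, config.duplicates + 1):
                    noise = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                    rows.append(
                        (f"E{exp_i}", g.cell_type, g.particle, dose, g.endpoint,
                         "no_cells", rep, config.blank_level * noise)
                    )
            if g.endpoint == "LDH":
                for rep in range(1, config.duplicates + 1):
                    noise = float(np.exp(rng.normal(0.0, sigma))) if sigma else 1.0
                    rows.append(
                        (f"E{exp_i}", g.cell_type, g.particle, 0.0, "LDH",
                         "lysed_control", rep, config.lysed_total_mean * noise)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "experiment_id", "cell_type", "particle", "dose", "endpoint",
            "role", "replicate", "signal",
        ],
    )


def beta_recovery(
    true_beta: float,
    n_replicates: int,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    method: str = "nls",
) -> np.ndarray:
    """Fitted betas from repeated simulate -> normalize -> fit cycles.

    Each replicate simulates one particle x endpoint under the study design
    (dose grid, experiments, duplicates and noise from ``config``), normalizes
    to fold effects per experiment, averages duplicates, pools the
    per-experiment dose means and fits beta. The signal arithmetic mirrors
    :func:`nanopotency.normalize.compute_fold_effect` on blank-free wells; the
    fit is the production fitter.
    """
    from .potency import fit_beta

    base = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    doses = np.asarray(base.doses, dtype=float)
    growth = (doses + 1.0) ** true_beta  # (d,)
    n_exp, dup, sigma = base.n_experiments, base.duplicates, base.noise_sigma
    zero = doses == 0.0
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        levels = base.control_signal_mean * np.exp(
            rng.normal(0.0, base.control_cv, size=n_exp)
        )
        eps = rng.normal(0.0, sigma, size=(n_exp, doses.size, dup))
        signals = levels[:, None, None] * growth[None, :, None] * np.exp(eps)
        grand = signals[:, zero, :].reshape(n_exp, -1).mean(axis=1)
        fe = signals / grand[:, None, None]
        per_dose = fe.mean(axis=2)  # duplicate average per experiment x dose
        est = fit_beta(
            np.tile(doses, n_exp), per_dose.reshape(-1), method=method
        )
        out[i] = est.beta_signed
    return out


def simulate_descriptors(
    betas: Mapping[str, float] | pd.Series,
    coupling: Mapping[str, float],
    seed: int = 0,
    *,
    means: Optional[Mapping[str, float]] = None,
    scales: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Descriptor columns with a chosen population correlation to signed beta.

    Each descriptor is built in standardized space as
    ``r * z(beta) + sqrt(1 - r^2) * z_noise`` so its population correlation
    with the signed exponent equals the coupling target exactly, then shifted
    and scaled to the requested mean/scale (default 100 +/- 20). ``r = 0``
    gives an independent column; ``|r| = 1`` a noise-free linear transform.
    """
    s = pd.Series(betas, dtype=float)
    if s.size < 2:
        raise ValidationError("need >= 2 particles to simulate descriptors")
    for name, r in coupling.items():
        if not np.isfinite(r) or abs(r) > 1:
            raise ValidationError(
                f"coupling for {name!r} must be in [-1, 1], got {r}"
            )
    rng = np.random.default_rng(seed)
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValidationError("betas have zero variance; coupling is undefined")
    z_beta = (s - s.mean()) / sd
    out = {}
    for name, r in coupling.items():
        z_noise = rng.standard_normal(s.size)
        z = r * z_beta.to_numpy() + np.sqrt(1.0 - r * r) * z_noise
        mean = 100.0 if means is None else means.get(name, 100.0)
        scale = 20.0 if scales is None else scales.get(name, 20.0)
        out[name] = mean + scale * z
    df = pd.DataFrame(out, index=s.index)
    df.index.name = "particle"
    return df


def simulate_stress_and_proteins(
    treatments: Sequence[str],
    seed: int = 0,
    *,
    suppression: Optional[Mapping[str, float]] = None,
    n_replicates: int = 3,
    noise_sigma: float = 0.1,
    control_gsh: float = 800.0,
    control_gssg: float = 40.0,
    proteins: Optional[Sequence[str]] = None,
    responders: Optional[Mapping[str, Mapping[str, float]]] = None,
    blocks: Optional[Mapping[str, Sequence[str]]] = None,
    block_sd: float = 0.6,
    within_block_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Synthetic oxidative-stress readings and secreted-protein fold changes.

    Stress: per treatment, GSH is suppressed and GSSG inflated so that the
    GSH/GSSG ratio fold change equals the treatment's ``suppression`` factor
    (< 1 = oxidative stress; default 0.5 for every treatment), with
    multiplicative noise on each replicate reading.

    Secretome: a proteins x treatments fold-change matrix. ``responders`` pins
    chosen protein/treatment fold changes; all other entries are 1 before
    noise. When ``blocks`` assigns treatments to groups, each block shares one
    latent log2 profile (SD ``block_sd``) and members deviate from it by
    ``within_block_sd``, producing the tight within-block correlation that
    column clustering should recover.

    Returns (stress table, secretome matrix, ground-truth dict).
    """
    rng = np.random.default_rng(seed)
    treatments = list(treatments)
    supp = {t: 0.5 for t in treatments} if suppression is None else dict(suppression)
    for t, s_t in supp.items():
        if not np.isfinite(s_t) or s_t <= 0:
            raise ValidationError(f"suppression for {t!r} must be > 0")

    stress_rows = []
    for rep in range(1, n_replicates + 1):
        noise = np.exp(rng.normal(0.0, noise_sigma, size=2)) if noise_sigma else (1.0, 1.0)
        stress_rows.append(("control", rep, control_gsh * noise[0], control_gssg * noise[1]))
    for t in treatments:
        s_t = supp.get(t, 1.0)
        # split the ratio change evenly between GSH loss and GSSG gain
        gsh_t, gssg_t = control_gsh * np.sqrt(s_t), control_gssg / np.sqrt(s_t)
        for rep in range(1, n_replicates + 1):
            noise = np.exp(rng.normal(0.0, noise_sigma, size=2)) if noise_sigma else (1.0, 1.0)
            stress_rows.append((t, rep, gsh_t * noise[0], gssg_t * noise[1]))
    stress = pd.DataFrame(stress_rows, columns=["treatment", "replicate", "gsh", "gssg"])

    if proteins is None:
        proteins = [f"P{i:02d}" for i in range(1, 21)]
    proteins = list(proteins)
    log2fc = pd.DataFrame(0.0, index=proteins, columns=treatments)
    if blocks:
        for members in blocks.values():
            latent = rng.normal(0.0, block_sd, size=len(proteins))
            for t in members:
                if t not in log2fc.columns:
                    raise ValidationError(f"block member {t!r} not a treatment")
                log2fc[t] += latent + rng.normal(0.0, within_block_sd, size=len(proteins))
    if responders:
        for protein, per_treatment in responders.items():
            if protein not in log2fc.index:
                raise ValidationError(f"responder protein {protein!r} not in panel")
            for t, fc in per_treatment.items():
                log2fc.loc[protein, t] = np.log2(fc)
    if noise_sigma:
        log2fc += rng.normal(0.0, noise_sigma, size=log2fc.shape)
    secretome = (2.0 ** log2fc).astype(float)

    truth = {
        "suppression": supp,
        "responders": {k: dict(v) for k, v in (responders or {}).items()},
        "blocks": {k: list(v) for k, v in (blocks or {}).items()},
    }
    return stress, secretome, truth


def write_fixture_bundle(
    outdir,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> dict:
    """Emit the full synthetic fixture set (CSV) plus a ground-truth JSON.

    Files: assay.csv, descriptors.csv, stress.csv, secretome.csv, truth.json.
    Returns the ground-truth dictionary.
    """
    import json
    from pathlib import Path

    cfg = config or SimulationConfig()
    cfg = replace(cfg, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    assay = simulate_assay(cfg)
    assay.to_csv(outdir / "assay.csv", index=False)

    betas = cfg.betas
    atp = betas[(betas["endpoint"] == "ATP")].groupby("particle")["beta_signed"].mean()
    coupling = {"betsa": -0.9, "dls_size": -0.8, "tem_size": 0.0, "zn": 0.6}
    descriptors = simulate_descriptors(atp, coupling, seed=seed + 1)
    descriptors.to_csv(outdir / "descriptors.csv")

    particles = sorted(betas["particle"].unique())
    stress, secretome, truth_sp = simulate_stress_and_proteins(
        particles,
        seed=seed + 2,
        responders={"P01": {particles[0]: 2.0}, "P02": {particles[0]: 0.4}},
        blocks={"coated": particles[: len(particles) // 2],
                "uncoated": particles[len(particles) // 2:]},
    )
    stress.to_csv(outdir / "stress.csv", index=False)
    secretome.to_csv(outdir / "secretome.csv", index_label="protein")

    truth = {
        "seed": seed,
        "betas": {
            f"{r.particle}|{r.cell_type}|{r.endpoint}": r.beta_signed
            for r in betas.itertuples(index=False)
        },
        "descriptor_coupling": coupling,
        **truth_sp,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
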