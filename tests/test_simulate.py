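import numpy as np
import pandas as pd
import pytest

from nanopotency import (
    SimulationConfig,
    beta_recovery,
    compute_fold_effect,
    fit_all,
    pearson_r,
    filter_responders,
    gsh_gssg_fc,
    hierarchical_cluster,
    simulate_assay,
    simulate_descriptors,
    simulate_stress_and_proteins,
)
from nanopotency.errors import ValidationError


def small_betas():
    return pd.DataFrame(
        {
            "particle": ["NP1", "NP1", "NP2", "NP2"],
            "cell_type": ["CT", "CT", "CT", "CT"],
            "endpoint": ["ATP", "LDH", "ATP", "LDH"],
            "beta_signed": [-0.3, 0.15, -1.0, 0.05],
        }
    )


class TestSimulateAssay:
    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(betas=small_betas())
        a = simulate_assay(cfg, seed=9)
        b = simulate_assay(cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_roles_and_controls_present(self):
        cfg = SimulationConfig(betas=small_betas())
        raw = simulate_assay(cfg, seed=1)
        assert set(raw["role"]) == {"cells", "no_cells", "lysed_control"}
        zero = raw[(raw["role"] == "cells") & (raw["dose"] == 0)]
        assert not zero.empty
        assert (raw[raw["role"] == "lysed_control"]["endpoint"] == "LDH").all()

    def test_noise_free_round_trip_is_exact(self):
        cfg = SimulationConfig(betas=small_betas(), noise_sigma=0.0)
        fe = compute_fold_effect(simulate_assay(cfg, seed=2))
        est = fit_all(fe).set_index(["particle", "endpoint"])["beta_signed"]
        for row in small_betas().itertuples(index=False):
            assert est.loc[(row.particle, row.endpoint)] == pytest.approx(
                row.beta_signed, abs=1e-9
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(betas=small_betas(), doses=(5.0, 10.0, 20.0)).validate()
        with pytest.raises(ValidationError):
            SimulationConfig(betas=small_betas(), noise_sigma=-0.1).validate()

    def test_end_to_end_identifiability_across_beta_range(self):
        """Simulate -> normalize -> fit recovers the exponent across the
        magnitude range of real screens, zero included."""
        for true_beta in (-1.5, -0.3, 0.0, 0.2, 1.6):
            fits = beta_recovery(true_beta, n_replicates=200, seed=13)
            assert abs(fits.mean() - true_beta) < 0.03


class TestSimulateDescriptors:
    BETAS = pd.Series(
        {"NP1": -0.2, "NP2": -0.5, "NP3": -1.1, "NP4": -0.05, "NP5": -0.8}
    )

    def test_unit_coupling_is_noise_free_linear_transform(self):
        desc = simulate_descriptors(self.BETAS, {"betsa": 1.0}, seed=0)
        r = pearson_r(desc["betsa"], self.BETAS.loc[desc.index])
        assert round(r.r, 3) == 1.0

    def test_zero_coupling_is_independent(self):
        rng_betas = pd.Series(
            np.random.default_rng(0).normal(size=1000),
            index=[f"P{i}" for i in range(1000)],
        )
        desc = simulate_descriptors(rng_betas, {"d": 0.0}, seed=1)
        assert abs(pearson_r(desc["d"], rng_betas).r) < 0.1

    def test_negative_coupling_calibrated(self):
        betas = pd.Series(
            np.random.default_rng(5).normal(size=500),
            index=[f"P{i}" for i in range(500)],
        )
        rs = [
            pearson_r(
                simulate_descriptors(betas, {"d": -0.9}, seed=s)["d"], betas
            ).r
            for s in range(200)
        ]
        assert abs(np.mean(rs) - (-0.9)) < 0.03

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ValidationError):
            simulate_descriptors(self.BETAS, {"d": 1.2})

    def test_determinism(self):
        a = simulate_descriptors(self.BETAS, {"d": 0.5}, seed=3)
        b = simulate_descriptors(self.BETAS, {"d": 0.5}, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateStressAndProteins:
    def test_suppression_recovered_noise_free(self):
        stress, _, _ = simulate_stress_and_proteins(
            ["NP1"], suppression={"NP1": 0.5}, noise_sigma=0.0
        )
        by = stress.groupby("treatment")[["gsh", "gssg"]].mean()
        fc = gsh_gssg_fc(
            by.loc["NP1", "gsh"], by.loc["NP1", "gssg"],
            by.loc["control", "gsh"], by.loc["control", "gssg"],
        )
        assert fc == pytest.approx(0.5)

    def test_designated_responders_recovered_noise_free(self):
        _, matrix, _ = simulate_stress_and_proteins(
            ["NP1", "NP2"],
            noise_sigma=0.0,
            responders={"P01": {"NP1": 2.0}, "P05": {"NP2": 0.4}},
        )
        kept = filter_responders(matrix, cutoff=1.5)
        assert set(kept.index) == {"P01", "P05"}

    def test_treatment_blocks_split_at_top_merge(self):
        coated = ["c1", "c2", "c3"]
        uncoated = ["u1", "u2", "u3"]
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            _, matrix, _ = simulate_stress_and_proteins(
                coated + uncoated,
                seed=seed,
                blocks={"coated": coated, "uncoated": uncoated},
                noise_sigma=0.05,
            )
            res = hierarchical_cluster(matrix)
            left, right = res.top_split("cols")
            hits += {frozenset(left), frozenset(right)} == {
                frozenset(coated), frozenset(uncoated)
            }
        assert hits >= 0.95 * n_runs
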