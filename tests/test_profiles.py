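import numpy as np
import pandas as pd
import pytest

from cellrecap.datatypes import N_STRATA, PhylostratumMap
from cellrecap.profiles import (
    evolutionary_profile,
    ontogenetic_profile,
    slope_profile,
)
from cellrecap.simulate import (
    SimulationConfig,
    cc_signature_genes,
    simulate_expression,
)

FLAT = (0.0,) * N_STRATA


def noiseless_config(**kw):
    base = dict(n_genes_per_stratum=6, n_cells_per_population=30,
                noise_sd=0.0, n_background_genes=0, n_cc_genes=5, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSlopeProfile:
    def test_noiseless_recovery_is_exact(self):
        cfg = noiseless_config()
        matrix, strata, _ = simulate_expression(cfg)
        prof = slope_profile(matrix, strata, cc_signature_genes(cfg),
                             "reference", normalize=False, log_offset=0.0,
                             log_scale=True)
        np.testing.assert_allclose(prof.slopes, cfg.slope_profile, atol=1e-9)

    def test_noisy_sign_pattern(self):
        cfg = SimulationConfig(n_genes_per_stratum=30,
                               n_cells_per_population=150, seed=1)
        matrix, strata, _ = simulate_expression(cfg)
        prof = slope_profile(matrix, strata, cc_signature_genes(cfg),
                             "reference")
        slopes = np.asarray(prof.slopes)
        assert (slopes[:2] > 0).all()          # unicellular strata couple up
        assert (slopes[5:] < 0).all()          # post-Bilateria couple down

    def test_constant_signature_rejected(self):
        cfg = noiseless_config(
            cc_activity_params={"reference": (0.0, 0.0),
                                "contrast": (0.0, 0.0)})
        matrix, strata, _ = simulate_expression(cfg)
        with pytest.raises(ValueError, match="constant"):
            slope_profile(matrix, strata, cc_signature_genes(cfg),
                          "reference", normalize=False, log_offset=0.0)


class TestEvolutionaryProfile:
    def test_same_population_contrast_is_zero(self):
        cfg = noiseless_config(noise_sd=0.2)
        matrix, strata, _ = simulate_expression(cfg)
        prof = evolutionary_profile(matrix, strata, cc_signature_genes(cfg),
                                    "reference", "reference")
        deltas = prof.to_frame()["delta_intercept"]
        np.testing.assert_allclose(deltas, 0.0, atol=1e-9)

    def test_noiseless_log_scale_recovers_programmed_shifts(self):
        cfg = noiseless_config()
        matrix, strata, _ = simulate_expression(cfg)
        prof = evolutionary_profile(matrix, strata, cc_signature_genes(cfg),
                                    "contrast", "reference", normalize=False,
                                    log_offset=0.0, log_scale=True)
        deltas = prof.to_frame()["delta_intercept"].to_numpy()
        np.testing.assert_allclose(deltas, cfg.shift_profile, atol=1e-9)

    def test_sign_flip_between_strata_two_and_three(self):
        # the programmed three-phase profile flips sign at stratum 3
        cfg = SimulationConfig(n_genes_per_stratum=30,
                               n_cells_per_population=150, seed=2)
        matrix, strata, _ = simulate_expression(cfg)
        prof = evolutionary_profile(matrix, strata, cc_signature_genes(cfg),
                                    "contrast", "reference")
        deltas = prof.to_frame()["delta_intercept"].to_numpy()
        assert deltas[1] < 0 < deltas[2]

    def test_gene_and_cell_order_invariance(self):
        cfg = noiseless_config(noise_sd=0.3, seed=3)
        matrix, strata, _ = simulate_expression(cfg)
        base = evolutionary_profile(matrix, strata, cc_signature_genes(cfg),
                                    "contrast", "reference").to_frame()
        rng = np.random.default_rng(0)
        gperm = rng.permutation(len(matrix.gene_ids))
        cperm = rng.permutation(len(matrix.cell_ids))
        from cellrecap.datatypes import ExpressionMatrix
        shuffled = ExpressionMatrix(
            values=matrix.values.iloc[gperm, cperm],
            cell_labels=matrix.cell_labels.iloc[cperm])
        other = evolutionary_profile(shuffled, strata,
                                     cc_signature_genes(cfg),
                                     "contrast", "reference").to_frame()
        pd.testing.assert_frame_equal(base, other, atol=1e-9)

    def test_missing_stratum_flagged_not_dropped(self):
        cfg = noiseless_config(noise_sd=0.1)
        matrix, strata, _ = simulate_expression(cfg)
        pruned = PhylostratumMap(
            strata=strata.strata[strata.strata != 9])
        prof = evolutionary_profile(matrix, pruned, cc_signature_genes(cfg),
                                    "contrast", "reference")
        frame = prof.to_frame()
        assert len(frame) == N_STRATA
        assert frame.loc[frame["stratum"] == 9, "flag"].iloc[0] == "empty"
        assert frame.loc[frame["stratum"] == 9, "call"].iloc[0] == "empty"

    def test_cell_cycle_confound_is_removed(self):
        # no programmed shifts, but the contrast population has lower
        # cell-cycle activity: raw stratum-1 means differ between the
        # populations, while the intercept contrast stays near zero
        cfg = SimulationConfig(
            n_genes_per_stratum=40, n_cells_per_population=200,
            shift_profile=FLAT, seed=4,
            cc_activity_params={"reference": (0.4, 0.4),
                                "contrast": (-0.4, 0.4)})
        matrix, strata, _ = simulate_expression(cfg)
        s1 = sorted(strata.stratum_genes(1))
        raw_ref = matrix.values.loc[s1, matrix.cells_in("reference")].mean().mean()
        raw_con = matrix.values.loc[s1, matrix.cells_in("contrast")].mean().mean()
        raw_diff = abs(raw_con - raw_ref)
        prof = evolutionary_profile(matrix, strata, cc_signature_genes(cfg),
                                    "contrast", "reference", normalize=False)
        delta = abs(prof.contrasts[0].delta_intercept)
        assert raw_diff > 0.5
        assert delta < 0.25 * raw_diff


class TestOntogeneticProfile:
    def _staged(self, scales, seed=5, **kw):
        stages = tuple(f"s{i}" for i in range(len(scales)))
        cfg = SimulationConfig(
            n_genes_per_stratum=20, n_cells_per_population=80,
            populations=stages, population_shift_scales=tuple(scales),
            cc_activity_params={s: (0.0, 0.6) for s in stages},
            seed=seed, **kw)
        return cfg, stages

    def test_reference_stage_is_identically_zero(self):
        cfg, stages = self._staged([0.0, 1.0, 0.5])
        matrix, strata, _ = simulate_expression(cfg)
        prof = ontogenetic_profile(matrix, strata, cc_signature_genes(cfg),
                                   list(stages), reference_stage="s0")
        assert prof.contrasts[0].delta_intercept == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_identical_stages_give_zero_contrast(self):
        cfg, stages = self._staged([0.0, 0.0], noise_sd=0.2)
        matrix, strata, _ = simulate_expression(cfg)
        prof = ontogenetic_profile(matrix, strata, cc_signature_genes(cfg),
                                   list(stages), reference_stage="s0")
        assert prof.contrasts[1].call == "null"

    def test_programmed_peak_recovered(self):
        # UC shift peaks at stage 2 of 4 (scales on the negative UC shift
        # profile, so the *least negative* UC stage is the peak flipped in)
        shift = tuple([0.4, 0.4] + [0.0] * 15)
        cfg, stages = self._staged([0.0, 0.5, 1.0, 0.25],
                                   shift_profile=shift, seed=6)
        matrix, strata, _ = simulate_expression(cfg)
        prof = ontogenetic_profile(matrix, strata, cc_signature_genes(cfg),
                                   list(stages), reference_stage="s0")
        assert prof.peak_stage() == "s2"

    def test_unknown_stage_rejected(self):
        cfg, stages = self._staged([0.0, 1.0])
        matrix, strata, _ = simulate_expression(cfg)
        with pytest.raises(KeyError, match="nope"):
            ontogenetic_profile(matrix, strata, cc_signature_genes(cfg),
                                ["s0", "nope"], reference_stage="s0")


def test_profile_plot_writes_file(tmp_path):
    cfg = noiseless_config(noise_sd=0.2)
    matrix, strata, _ = simulate_expression(cfg)
    prof = evolutionary_profile(matrix, strata, cc_signature_genes(cfg),
                                "contrast", "reference")
    from cellrecap.profiles import plot_profile
    out = tmp_path / "profile.png"
    plot_profile(prof.to_frame(), str(out))
    assert out.stat().st_size > 0
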