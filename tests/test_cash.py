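"""CASh inference: bootstrap p-values, direction combination, end-to-end runs."""

import numpy as np
import pandas as pd
import pytest

from cashde.cash import (
    CASH_RESULT_COLUMNS,
    CashConfig,
    bootstrap_pvalues,
    combine_directions,
    fold_change,
    preselect_genes,
    run_cash,
    write_cash_results,
)
from cashde.errors import ValidationError
from cashde.games import OVER, control_reference, discretize, split_by_group
from cashde.simulate import SimulationConfig, generate_dataset

from .conftest import make_dataset
from .test_games import bool_mat


def _boolean_pair(case_bits, ctrl_bits):
    return bool_mat(case_bits), bool_mat(ctrl_bits)


class TestConfig:
    def test_paper_defaults(self):
        cfg = CashConfig()
        assert cfg.n_boot == 1000
        assert cfg.fc_threshold == 2.0
        assert cfg.fdr_alpha == 0.05
        assert cfg.preselect_alpha in (0.01, 0.05)

    @pytest.mark.parametrize(
        "kwargs", [{"n_boot": 0}, {"fc_threshold": 1.0}, {"preselect_alpha": 0.0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CashConfig(**kwargs)


class TestPreselect:
    def test_alpha_one_keeps_everything(self, tiny_dataset):
        assert preselect_genes(tiny_dataset, 1.0) == tiny_dataset.genes

    def test_alpha_below_minimum_empties(self, tiny_dataset):
        assert preselect_genes(tiny_dataset, 1e-12) == []

    def test_recovers_fully_penetrant_truth(self):
        cfg = SimulationConfig(
            n_genes=1000, frac_de=0.05, effect_size=2.0, penetrance=1.0, seed=31
        )
        ds, truth = generate_dataset(cfg)
        kept = set(preselect_genes(ds, 0.05))
        assert len(kept & set(truth.de_genes)) >= 45


class TestBootstrap:
    def test_zero_difference_gives_p_one(self):
        rng = np.random.default_rng(0)
        b_case, b_ctrl = _boolean_pair([[1, 0], [0, 1]], [[0, 1], [1, 0]])
        _, p = bootstrap_pvalues(b_case, b_ctrl, 50, rng)
        np.testing.assert_allclose(p, 1.0)

    def test_p_on_plus_one_grid(self):
        rng = np.random.default_rng(1)
        bits = (np.random.default_rng(2).random((5, 8)) < 0.5).astype(np.uint8)
        b_case, b_ctrl = bool_mat(bits[:, :4]), bool_mat(bits[:, 4:])
        B = 100
        _, p = bootstrap_pvalues(b_case, b_ctrl, B, rng)
        grid = np.arange(1, B + 2) / (B + 1)
        assert all(np.isclose(grid, x).any() for x in p)

    def test_identical_rows_share_statistic_and_p(self):
        """Genes with identical Boolean rows get identical d and p."""
        rng_bits = np.random.default_rng(3)
        bits = (rng_bits.random((10, 10)) < 0.4).astype(np.uint8)
        bits[7] = bits[2]
        b_case, b_ctrl = bool_mat(bits[:, :5]), bool_mat(bits[:, 5:])
        d, p = bootstrap_pvalues(b_case, b_ctrl, 300, np.random.default_rng(4))
        assert d[7] == d[2] and p[7] == p[2]

    def test_seed_determinism(self):
        bits = (np.random.default_rng(5).random((10, 12)) < 0.5).astype(np.uint8)
        b_case, b_ctrl = bool_mat(bits[:, :6]), bool_mat(bits[:, 6:])
        p1 = bootstrap_pvalues(b_case, b_ctrl, 200, np.random.default_rng(9))[1]
        p2 = bootstrap_pvalues(b_case, b_ctrl, 200, np.random.default_rng(9))[1]
        np.testing.assert_array_equal(p1, p2)

    def test_small_group_rejected(self):
        b_case, b_ctrl = _boolean_pair([[1]], [[1, 0]])
        with pytest.raises(ValidationError):
            bootstrap_pvalues(b_case, b_ctrl, 10, np.random.default_rng(0))


class TestCombineDirections:
    def test_minimizing_side_sets_direction(self):
        p, d = combine_directions([0.004], [0.8], [0.1], [0.01], [1.0])
        assert p[0] == pytest.approx(0.008) and d[0] == "up"

    def test_winning_under_game_with_negative_d_means_up(self):
        # cases LESS under-expressed than controls: evidence of up-regulation
        p, d = combine_directions([0.3], [0.01], [0.02], [-0.05], [1.5])
        assert p[0] == pytest.approx(0.02) and d[0] == "up"

    def test_tie_falls_back_to_delta_sign(self):
        p, d = combine_directions([0.5], [0.5], [0.0], [0.0], [-0.2])
        assert p[0] == 1.0 and d[0] == "down"
        p, d = combine_directions([0.5], [0.5], [0.0], [0.0], [0.0])
        assert d[0] == "up"

    def test_capped_at_one(self):
        p, _ = combine_directions([0.6], [0.7], [0.1], [0.1], [0.1])
        assert p[0] == 1.0


class TestFoldChange:
    @pytest.mark.parametrize(
        "delta, fc", [(1.0, 2.0), (-2.0, -4.0), (0.0, 1.0)]
    )
    def test_signed_convention(self, delta, fc):
        ds = make_dataset([[delta, delta]], [[0.0, 0.0]])
        res = fold_change(ds)
        assert res["fold_change"].iloc[0] == pytest.approx(fc)

    def test_threshold_is_strict(self):
        ds = make_dataset([[1.0, 1.0]], [[0.0, 0.0]])  # delta exactly 1 -> FC 2
        delta = fold_change(ds)["delta_log2"].iloc[0]
        assert not abs(delta) > np.log2(2.0)


class TestRunCash:
    def test_deterministic_given_seed(self, tmp_path):
        ds, _ = generate_dataset(
            SimulationConfig(n_genes=150, frac_de=0.2, effect_size=2.5, seed=6)
        )
        cfg = CashConfig(n_boot=100, seed=77)
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cash_results(run_cash(ds, cfg), out1)
        write_cash_results(run_cash(ds, cfg), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_empty_preselection_yields_empty_table(self, tiny_dataset):
        cfg = CashConfig(preselect_alpha=1e-9, n_boot=10, seed=0)
        res = run_cash(tiny_dataset, cfg)
        assert res.empty and list(res.columns) == CASH_RESULT_COLUMNS

    def test_flags_recomputable_from_stored_numbers(self):
        ds, _ = generate_dataset(
            SimulationConfig(n_genes=300, frac_de=0.2, effect_size=2.5, seed=10)
        )
        cfg = CashConfig(n_boot=100, seed=5)
        res = run_cash(ds, cfg)
        assert len(res) > 0
        np.testing.assert_array_equal(res["sig_raw"], res["p_gene"] < cfg.preselect_alpha)
        np.testing.assert_array_equal(res["sig_fdr"], res["q_gene"] < cfg.fdr_alpha)
        np.testing.assert_array_equal(
            res["passes_fc"], np.abs(res["delta_log2"]) > np.log2(cfg.fc_threshold)
        )
        np.testing.assert_allclose(res["d_over"], res["phi_case_over"] - res["phi_ctrl_over"], atol=1e-12)

    def test_degenerate_flat_dataset_all_p_one(self):
        """No value ever exceeds mean +/- sd: empty supports, p_gene = 1."""
        rng = np.random.default_rng(8)
        # controls (6,6,8,8): mean 7, sd 1.155 -> even the controls stay
        # strictly inside mean +/- sd, so every support is empty
        ctrl = np.tile([6.0, 6.0, 8.0, 8.0], (20, 1))
        case = np.full((20, 4), 7.0) + rng.uniform(-0.05, 0.05, (20, 4))
        ds = make_dataset(case, ctrl)
        cfg = CashConfig(preselect_alpha=1.0, n_boot=50, seed=1)
        res = run_cash(ds, cfg)
        np.testing.assert_allclose(res["p_gene"], 1.0)
        assert not res["sig_fdr"].any()

    def test_direction_matches_planted_truth(self):
        cfg = SimulationConfig(
            n_genes=400, frac_de=0.1, effect_size=4.0, penetrance=1.0, seed=23
        )
        ds, truth = generate_dataset(cfg)
        res = run_cash(ds, CashConfig(n_boot=200, seed=3)).set_index("gene")
        hits = res[res["sig_raw"]]
        true_dirs = truth.table.loc[truth.table["is_de"], "direction"]
        checked = 0
        for gene, row in hits.iterrows():
            if gene in true_dirs.index:
                assert row["direction"] == true_dirs[gene]
                checked += 1
        assert checked >= 10
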