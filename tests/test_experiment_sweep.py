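import numpy as np
import pandas as pd
import pytest

from ecovoi import (
    SweepGrid,
    build_parameter_grid,
    default_grid,
    fine_alpha_sweep,
    rank_feature_influence,
    run_case_study,
    run_sweep,
)
from ecovoi.configio import example_case_study_config
from ecovoi.experiment_sweep import FEATURE_COLUMNS


class TestParameterGrid:
    def test_default_grid_matches_the_factorial_design(self):
        grid = default_grid()
        assert grid.size == 10_368
        configs = build_parameter_grid(grid)
        assert len(configs) == 10_368

    def test_single_value_grids_give_one_config(self):
        grid = SweepGrid(
            motifs=("linear",), trophic_levels=(1,), alphas=(0.5,),
            p0s=(0.5,), bs=(0.5,),
        )
        assert len(build_parameter_grid(grid)) == 1

    def test_two_by_five_product(self, small_grid):
        assert len(build_parameter_grid(small_grid)) == 32

    def test_grid_values_outside_unit_interval_fail_at_build(self):
        grid = SweepGrid(alphas=(1.5,))
        with pytest.raises(ValueError):
            build_parameter_grid(grid)


class TestRunSweep:
    def test_sweep_rows_and_columns(self, small_grid):
        table = run_sweep(small_grid, objective="service")
        assert len(table) == 32
        assert list(table.columns[:5]) == FEATURE_COLUMNS
        assert (table["status"] == "ok").all()
        assert not table.duplicated(FEATURE_COLUMNS).any()

    def test_two_runs_are_byte_identical(self, small_grid, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        run_sweep(small_grid, objective="service", out=a)
        run_sweep(small_grid, objective="service", out=b)
        assert a.read_bytes() == b.read_bytes()

    def test_interrupted_and_resumed_equals_uninterrupted(self, small_grid, tmp_path):
        full = tmp_path / "full.csv"
        run_sweep(small_grid, objective="service", out=full)
        # simulate an interruption: keep the header and the first 10 rows
        partial = tmp_path / "partial.csv"
        lines = full.read_text().splitlines(keepends=True)
        partial.write_text("".join(lines[:11]))
        run_sweep(small_grid, objective="service", out=partial, resume=True)
        assert partial.read_bytes() == full.read_bytes()

    def test_empty_grid_gives_empty_table(self):
        table = run_sweep(SweepGrid(motifs=()), objective="service")
        assert table.empty

    def test_per_row_failures_are_recorded_not_raised(self):
        grid = SweepGrid(
            motifs=("linear",), trophic_levels=(1,), alphas=(0.5,),
            p0s=(0.5, 1.5), bs=(0.5,),  # p0=1.5 is invalid
        )
        table = run_sweep(grid, objective="service")
        assert list(table["status"]) == ["ok", "error"]
        assert "ValueError" in table.loc[1, "reason"]


@pytest.fixture(scope="module")
def omnivory_alpha_table():
    return fine_alpha_sweep(motifs=("omnivory",), trophic_levels=(1, 4))


@pytest.fixture(scope="module")
def coarse_case_config():
    cfg = example_case_study_config()
    cfg["alpha_grid"] = {"start": 0.2, "stop": 0.8, "step": 0.3}
    cfg["b_grid"] = {"start": 0.3, "stop": 0.9, "step": 0.3}
    return cfg


class TestFineAlphaSweep:
    def test_inclusive_alpha_count(self, omnivory_alpha_table):
        per_level = omnivory_alpha_table.groupby("trophic_level").size()
        assert (per_level == 71).all()

    def test_basal_provider_has_no_information_value(self, omnivory_alpha_table):
        basal = omnivory_alpha_table[omnivory_alpha_table["trophic_level"] == 1]
        assert basal["evpi_rel_pct"].abs().max() < 1e-9

    def test_top_provider_evpi_weakly_increases_with_alpha(self, omnivory_alpha_table):
        top = omnivory_alpha_table[
            omnivory_alpha_table["trophic_level"] == 4
        ].sort_values("alpha")
        diffs = np.diff(top["evpi_rel_pct"].to_numpy())
        assert diffs.min() > -1e-9


class TestFeatureRanking:
    @staticmethod
    def synthetic_table(response_fn):
        rows = []
        for motif in ("linear", "omnivory"):
            for tl in (1, 4):
                for alpha in (0.2, 0.5, 0.8):
                    for p0 in (0.4, 0.8):
                        for b in (0.3, 0.9):
                            rows.append(
                                dict(
                                    motif=motif, trophic_level=tl, alpha=alpha,
                                    p0=p0, b=b, status="ok",
                                    evpi_rel_pct=response_fn(motif, tl, alpha, p0, b),
                                )
                            )
        return pd.DataFrame(rows * 5)  # enough rows for the default leaf size

    def test_alpha_only_response_ranks_alpha_first(self):
        table = self.synthetic_table(lambda m, tl, a, p0, b: 10 * a)
        ranking = rank_feature_influence(table, min_samples_leaf=5)
        assert ranking.iloc[0]["feature"] == "alpha"
        others = ranking[ranking["feature"] != "alpha"]["importance"]
        assert (others == 0).all()

    def test_constant_response_gives_all_zero_importances(self):
        table = self.synthetic_table(lambda *args: 1.0)
        ranking = rank_feature_influence(table, min_samples_leaf=5)
        assert (ranking["importance"] == 0).all()

    def test_feature_without_variation_is_rejected(self):
        table = self.synthetic_table(lambda m, tl, a, p0, b: a)
        table["b"] = 0.5
        with pytest.raises(ValueError, match="distinct"):
            rank_feature_influence(table)


class TestCaseStudy:
    def test_one_row_per_motif_and_provider_level(self, coarse_case_config):
        table = run_case_study(coarse_case_config)
        assert len(table) == 4  # two motifs x two provider levels each
        assert set(table.columns) >= {
            "label", "motif", "trophic_level", "max_evpi_rel_pct",
            "argmax_alpha", "argmax_b",
        }

    def test_biodiversity_objective_values_stay_near_zero(self, coarse_case_config):
        cfg = dict(coarse_case_config, objective="biodiversity")
        table = run_case_study(cfg)
        assert table["max_evpi_rel_pct"].max() <= 1.0

    def test_basal_provider_never_beats_higher_providers(self, coarse_case_config):
        table = run_case_study(coarse_case_config)
        for _, group in table.groupby("label"):
            basal = group[group["trophic_level"] == 1]
            upper = group[group["trophic_level"] > 1]
            if len(basal) and len(upper):
                assert (
                    basal["max_evpi_rel_pct"].max()
                    <= upper["max_evpi_rel_pct"].min() + 1e-9
                )

    def test_missing_p0_is_an_error(self, coarse_case_config):
        bad = dict(coarse_case_config)
        bad["motifs"] = [{"motif": "linear", "providers": [1]}]
        with pytest.raises(KeyError, match="p0"):
            run_case_study(bad)
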