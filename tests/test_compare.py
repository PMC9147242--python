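import json

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from ascakit.compare import (
    coincidence_with_reference,
    profile_correlation,
    run_workflow,
    select_top_k,
    venn_partition,
)
from ascakit.exceptions import ConfigurationError


class TestSelectTopK:
    def test_k_equals_all_variables(self):
        sel = select_top_k([0.5, 0.2, 0.9], ["a", "b", "c"], "plsda_vip", k=3)
        assert sel.top_k == {"a", "b", "c"}

    def test_absolute_value_ranking_for_loadings(self):
        sel = select_top_k([0.9, -0.8, 0.1], ["v1", "v2", "v3"], "asca", k=2)
        assert sel.top_k == {"v1", "v2"}
        assert sel.ranking == ["v1", "v2", "v3"]

    def test_raw_value_ranking_for_vip(self):
        sel = select_top_k([0.9, -0.8, 0.1], ["v1", "v2", "v3"], "plsda_vip", k=2)
        assert sel.ranking == ["v1", "v3", "v2"]  # no absolute value

    def test_tie_broken_by_lower_index(self):
        sel = select_top_k([0.5, 0.7, 0.5], ["v1", "v2", "v3"], "plsda_vip", k=2)
        assert sel.top_k == {"v2", "v1"}  # v1 beats v3 on the tie

    def test_k_larger_than_p_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            sel = select_top_k([0.1, 0.2], ["a", "b"], "plsda_vip", k=5)
        assert sel.top_k == {"a", "b"}

    def test_k_validation(self):
        with pytest.raises(ConfigurationError):
            select_top_k([0.1], ["a"], "asca", k=0)


class TestVennPartition:
    def test_identical_sets(self):
        out = venn_partition({"A": {1, 2, 3}, "B": {1, 2, 3}})
        assert out[frozenset({"A", "B"})] == 3
        assert out[frozenset({"A"})] == 0
        assert out[frozenset({"B"})] == 0

    def test_disjoint_sets(self):
        out = venn_partition({"A": {1, 2}, "B": {3}})
        assert out[frozenset({"A"})] == 2
        assert out[frozenset({"B"})] == 1
        assert out[frozenset({"A", "B"})] == 0

    def test_four_sets_brute_force_oracle(self):
        sets = {
            "w": {1, 2, 3, 4},
            "x": {3, 4, 5},
            "y": {1, 4, 5, 6},
            "z": {7},
        }
        out = venn_partition(sets)
        # brute-force membership tabulation
        for sig, count in out.items():
            expected = sum(
                1
                for e in set().union(*sets.values())
                if {n for n in sets if e in sets[n]} == set(sig)
            )
            assert count == expected
        assert sum(out.values()) == len(set().union(*sets.values()))

    @settings(max_examples=30, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c"]),
            st.sets(st.integers(0, 20)),
            min_size=2,
            max_size=3,
        )
    )
    def test_region_counts_reconstruct_set_sizes(self, sets):
        out = venn_partition(sets)
        for name, s in sets.items():
            total = sum(c for sig, c in out.items() if name in sig)
            assert total == len(s)

    def test_set_count_validation(self):
        with pytest.raises(ConfigurationError):
            venn_partition({"A": {1}})


class TestProfileCorrelation:
    def test_self_correlation_one(self, rng):
        v = rng.normal(size=20)
        out = profile_correlation({"a": v, "b": v})
        assert out.loc["a", "b"] == pytest.approx(1.0)
        assert out.loc["a", "a"] == 1.0

    def test_negation_and_absolute(self, rng):
        v = rng.normal(size=20)
        out = profile_correlation({"a": v, "b": -v})
        assert out.loc["a", "b"] == pytest.approx(-1.0)
        out_abs = profile_correlation({"a": np.abs(v), "b": np.abs(-v)})
        assert out_abs.loc["a", "b"] == pytest.approx(1.0)

    def test_textbook_pearson_oracle(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        out = profile_correlation({"a": a, "b": b})
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert out.loc["a", "b"] == pytest.approx(expected)

    def test_zero_variance_profile_nan_with_warning(self, rng):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = profile_correlation({"a": np.ones(5), "b": rng.normal(size=5)})
        assert np.isnan(out.loc["a", "b"])

    def test_length_mismatch(self, rng):
        with pytest.raises(ConfigurationError):
            profile_correlation({"a": np.ones(4), "b": np.ones(5)})


class TestCoincidence:
    def test_reference_equals_itself_k(self):
        sets = {"plsda_vip": {1, 2, 3}, "asca": {1, 2, 3}}
        out = coincidence_with_reference(sets)
        assert out == {"asca": 3}

    def test_disjoint_zero(self):
        sets = {"plsda_vip": {1, 2}, "asca": {5, 6}}
        assert coincidence_with_reference(sets) == {"asca": 0}

    def test_symmetric_and_bounded(self, rng):
        a = set(rng.choice(100, 50, replace=False).tolist())
        b = set(rng.choice(100, 50, replace=False).tolist())
        ab = coincidence_with_reference({"plsda_vip": a, "m": b})["m"]
        ba = coincidence_with_reference({"plsda_vip": b, "m": a})["m"]
        assert ab == ba <= 50

    def test_missing_reference(self):
        with pytest.raises(ConfigurationError):
            coincidence_with_reference({"asca": {1}}, "plsda_vip")


class TestRunWorkflow:
    CONFIG = {
        "factor": "group",
        "synthetic": {
            "n_per_group": 5,
            "group_levels": ["A", "B"],
            "n_variables": 60,
            "n_markers": 10,
            "effect_size": 3.0,
            "n_internal_standards": 2,
            "drift_sd": 0.2,
            "seed": 3,
        },
        "k": 20,
        "n_permutations": 49,
        "seed": 5,
    }

    def test_shape_contract(self):
        report = run_workflow(self.CONFIG)
        assert set(report["p_values"]) == {"asca", "rmanova", "gasca"}
        assert len(report["top_k_sets"]) == 6
        assert all(len(s) == 20 for s in report["top_k_sets"].values())
        corr = report["profile_correlations"]
        assert len(corr) == 6 and all(len(row) == 6 for row in corr.values())
        assert set(report["coincidence_with_reference"]) == {
            "asca", "rmanova", "gasca", "plsda_sr", "univariate",
        }
        assert all(0 <= c <= 20 for c in report["coincidence_with_reference"].values())
        # venn regions containing a method reconstruct its set size
        # (univariate is excluded from the venn, which is capped at 5 sets)
        for m, s in report["top_k_sets"].items():
            if m == "univariate":
                continue
            total = sum(
                c for sig, c in report["venn"].items() if m in sig.split("+")
            )
            assert total == len(s)

    def test_missing_factor_fails_before_compute(self):
        cfg = dict(self.CONFIG)
        del cfg["factor"]
        with pytest.raises(ConfigurationError, match="factor"):
            run_workflow(cfg)

    def test_unknown_method_rejected(self):
        cfg = dict(self.CONFIG)
        cfg["methods"] = ["asca", "mystery"]
        with pytest.raises(ConfigurationError, match="mystery"):
            run_workflow(cfg)

    def test_rerun_byte_identical_report(self, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_workflow(self.CONFIG, output_dir=out1)
        run_workflow(self.CONFIG, output_dir=out2)
        assert (out1 / "report.json").read_bytes() == (out2 / "report.json").read_bytes()

    def test_config_file_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(self.CONFIG))
        report = run_workflow(path, output_dir=tmp_path / "out")
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "ranking_asca.csv").exists()
        assert (tmp_path / "out" / "log.txt").exists()
        on_disk = json.loads((tmp_path / "out" / "report.json").read_text())
        assert on_disk["p_values"] == report["p_values"]

    def test_strong_markers_dominate_selections(self):
        report = run_workflow(self.CONFIG)
        markers = {f"V{j + 1:04d}" for j in range(10)}
        for method, top in report["top_k_sets"].items():
            assert len(markers & set(top)) >= 8, method
        assert all(p <= 0.05 for p in report["p_values"].values())
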