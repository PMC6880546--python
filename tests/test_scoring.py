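"""Weighted-sum scoring: loader validation, arithmetic, and linear-algebra
properties (linearity, permutation invariance, nested decomposition)."""

import numpy as np
import pandas as pd
import pytest

from methalc.containers import MethylationMatrix
from methalc.scoring import (
    CoefficientSet,
    compute_score,
    load_coefficients,
)


def _write_coefs(path, rows):
    lines = ["cpg\tweight\tset"] + [f"{c}\t{w}\t{s}" for c, w, s in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoader:
    def test_minimal_nested_family(self, tmp_path):
        p = _write_coefs(tmp_path / "c.tsv", [("cg1", 1.0, "a"), ("cg1", 1.0, "b"), ("cg2", -2.0, "b")])
        fam = load_coefficients(p)
        assert fam.sizes == [1, 2]
        assert fam["b"].weights["cg2"] == -2.0

    def test_nesting_violation_names_cpg(self, tmp_path):
        p = _write_coefs(
            tmp_path / "c.tsv", [("cg1", 1.0, "a"), ("cg2", 1.0, "b"), ("cg3", 1.0, "b")]
        )
        with pytest.raises(ValueError, match="cg1"):
            load_coefficients(p)

    def test_duplicate_cpg_within_set(self, tmp_path):
        p = _write_coefs(tmp_path / "c.tsv", [("cg1", 1.0, "a"), ("cg1", 2.0, "a")])
        with pytest.raises(ValueError, match="duplicate"):
            load_coefficients(p)

    def test_non_numeric_weight_reports_line(self, tmp_path):
        p = _write_coefs(tmp_path / "c.tsv", [("cg1", 1.0, "a"), ("cg2", "oops", "a")])
        with pytest.raises(ValueError, match="line 3"):
            load_coefficients(p)

    def test_bundled_family_structure(self, family):
        assert family.sizes == [5, 23, 78, 144]
        # nested by construction; shared CpGs keep identical weights
        for smaller, larger in zip(family.sets[:-1], family.sets[1:]):
            for cpg, w in smaller.weights.items():
                assert larger.weights[cpg] == w

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            CoefficientSet("bad", {"cg1": 0.0})


class TestComputeScore:
    def test_forced_arithmetic(self):
        m = MethylationMatrix(
            pd.DataFrame({"cg01": [0.5], "cg02": [0.3]}, index=["s1"]), time_point="t"
        )
        cs = CoefficientSet("s", {"cg01": 2.0, "cg02": -1.0})
        sv = compute_score(m, cs)
        assert sv.scores["s1"] == pytest.approx(0.7, abs=1e-12)
        assert sv.coverage == 1.0

    def test_all_zero_methylation(self):
        m = MethylationMatrix(pd.DataFrame(np.zeros((3, 2)), columns=["cg01", "cg02"]))
        cs = CoefficientSet("s", {"cg01": 2.0, "cg02": -1.0})
        assert (compute_score(m, cs).scores == 0).all()

    def test_matches_elementwise_dot_product_oracle(self, rng, family):
        largest = family.largest
        cpgs = largest.cpgs
        vals = rng.uniform(0, 1, (200, len(cpgs)))
        m = MethylationMatrix(pd.DataFrame(vals, columns=cpgs))
        sv = compute_score(m, largest)
        for i in rng.choice(200, size=25, replace=False):
            expected = sum(largest.weights[c] * vals[i, j] for j, c in enumerate(cpgs))
            assert sv.scores.iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_linearity(self, rng, tiny_family):
        cs = tiny_family["tiny.4"]
        cols = cs.cpgs
        X = rng.uniform(0, 1, (15, 4))
        Y = rng.uniform(0, 1, (15, 4))
        a, b = 0.3, 0.6

        def score(arr, resid=False):
            m = MethylationMatrix(pd.DataFrame(arr, columns=cols), residualized=resid)
            return compute_score(m, cs).scores.to_numpy()

        combo = score(a * X + b * Y, resid=True)
        assert np.allclose(combo, a * score(X) + b * score(Y), atol=1e-10)

    def test_permutation_invariance(self, rng, tiny_family, make_matrix):
        cs = tiny_family["tiny.4"]
        m = make_matrix(30)
        base = compute_score(m, cs).scores
        perm = rng.permutation(30)
        m_rows = MethylationMatrix(m.values.iloc[perm], time_point="t0")
        assert (compute_score(m_rows, cs).scores == base.iloc[perm]).all()
        m_cols = MethylationMatrix(m.values[list(reversed(m.cpg_ids))], time_point="t0")
        assert np.allclose(compute_score(m_cols, cs).scores, base, atol=1e-12)

    def test_nested_decomposition(self, rng, family, make_matrix):
        small, large = family.sets[0], family.sets[1]
        m = make_matrix(25, cpgs=large.cpgs)
        s_small = compute_score(m, small).scores
        s_large = compute_score(m, large).scores
        extra_cpgs = [c for c in large.cpgs if c not in small.weights]
        extra = m.values[extra_cpgs] @ pd.Series({c: large.weights[c] for c in extra_cpgs})
        assert np.allclose(s_large, s_small + extra, atol=1e-12)

    def test_missing_policy(self, tiny_family, make_matrix):
        cs = tiny_family["tiny.4"]
        m = make_matrix(10, cpgs=("cg01", "cg02", "cg03"))  # cg04 missing
        with pytest.raises(ValueError, match="coverage"):
            compute_score(m, cs, missing_policy="error")
        sv = compute_score(m, cs, missing_policy="drop")
        assert sv.coverage == pytest.approx(0.75)
        with pytest.raises(ValueError, match="residualized"):
            compute_score(m, cs, missing_policy="impute-zero")

    def test_zero_coverage_is_hard_error(self, tiny_family, make_matrix):
        cs = tiny_family["tiny.2"]
        m = make_matrix(5, cpgs=("cgX",))
        with pytest.raises(ValueError, match="no CpG"):
            compute_score(m, cs, missing_policy="drop")


def test_raw_matrix_rejects_out_of_range():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        MethylationMatrix(pd.DataFrame({"cg01": [1.2]}))
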