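import subprocess
import sys
import textwrap

import numpy as np
import pytest

from cuvarp.ordination import rda_matrices
from cuvarp.varpart import (
    chisq_fraction_compare,
    subset_key,
    varpart2,
    varpart3,
)
from cuvarp.varpart import test_fractions as fraction_tests

from conftest import quant_table


def _tables(rng, n, shapes):
    ids = [f"s{i}" for i in range(n)]
    return [quant_table(rng.normal(size=(n, k)), ids=ids) for k in shapes]


class TestVarpart2:
    def test_closure_identity(self, rng):
        y, x1, x2 = _tables(rng, 30, (3, 2, 2))
        res = varpart2(y, x1, x2, labels=("E", "S"))
        total = sum(res.fractions.values()) + res.residual
        assert total == pytest.approx(1.0, abs=1e-12)
        a12 = rda_matrices(
            y.numeric(), np.hstack([x1.numeric(), x2.numeric()])
        ).adj_r2
        assert sum(res.fractions.values()) == pytest.approx(a12, abs=1e-12)

    def test_response_equal_to_one_predictor(self, rng):
        n = 100
        ids = [f"s{i}" for i in range(n)]
        x1 = quant_table(rng.normal(size=(n, 1)), ids=ids)
        x2 = quant_table(rng.normal(size=(n, 1)), ids=ids)
        res = varpart2(x1, x1, x2, labels=("A", "B"))
        assert res.fractions["A"] == pytest.approx(1.0, abs=0.05)
        assert abs(res.fractions["B"]) < 0.05
        assert abs(res.fractions["AB"]) < 0.05
        assert abs(res.residual) < 0.05

    def test_duplicated_predictor_matrix_is_all_shared(self, rng):
        y, x1 = _tables(rng, 25, (2, 2))
        res = varpart2(y, x1, x1, labels=("A", "B"))
        a1 = rda_matrices(y.numeric(), x1.numeric()).adj_r2
        assert res.fractions["A"] == pytest.approx(0.0, abs=1e-12)
        assert res.fractions["B"] == pytest.approx(0.0, abs=1e-12)
        assert res.fractions["AB"] == pytest.approx(a1, abs=1e-12)

    def test_variance_units_view(self, rng):
        y, x1, x2 = _tables(rng, 20, (2, 1, 1))
        res = varpart2(y, x1, x2)
        vu = res.in_variance_units()
        assert sum(vu.values()) == pytest.approx(res.total_variance, abs=1e-9)


class TestVarpart3:
    def test_closure_on_random_data(self, rng):
        y, x1, x2, x3 = _tables(rng, 30, (3, 2, 2, 2))
        res = varpart3(y, x1, x2, x3, labels=("A", "E", "S"))
        assert len(res.fractions) == 7
        assert sum(res.fractions.values()) + res.residual == pytest.approx(
            1.0, abs=1e-12
        )

    def test_unique_fractions_match_partial_model_subtraction(self, rng):
        y, x1, x2, x3 = _tables(rng, 40, (2, 2, 3, 2))
        res = varpart3(y, x1, x2, x3, labels=("A", "E", "S"))
        Y = y.numeric()
        Ms = [x1.numeric(), x2.numeric(), x3.numeric()]
        all3 = rda_matrices(Y, np.hstack(Ms)).adj_r2
        for i, lab in enumerate(("A", "E", "S")):
            others = np.hstack([Ms[j] for j in range(3) if j != i])
            unique = all3 - rda_matrices(Y, others).adj_r2
            assert res.fractions[lab] == pytest.approx(unique, abs=1e-12)

    def test_orthogonal_predictors_have_negligible_shared_fractions(self, rng):
        n = 300
        ids = [f"s{i}" for i in range(n)]
        # mutually orthogonal predictor blocks by QR construction
        Q, _ = np.linalg.qr(rng.normal(size=(n, 6)))
        x1, x2, x3 = Q[:, :2], Q[:, 2:4], Q[:, 4:6]
        y = Q[:, :6] @ rng.normal(size=(6, 2)) + 0.5 * rng.normal(size=(n, 2))
        res = varpart3(
            quant_table(y, ids=ids),
            quant_table(x1, ids=ids),
            quant_table(x2, ids=ids),
            quant_table(x3, ids=ids),
            labels=("A", "E", "S"),
        )
        for key in ("AE", "AS", "ES", "AES"):
            assert abs(res.fractions[key]) < 0.05

    def test_constant_response_rejected(self, rng):
        _, x1, x2, x3 = _tables(rng, 20, (1, 1, 1, 1))
        y = quant_table(np.ones((20, 2)), ids=x1.row_ids)
        with pytest.raises(ValueError, match="constant response"):
            varpart3(y, x1, x2, x3)

    def test_negative_fractions_are_preserved(self, rng):
        # suppressor-style configurations can push shared fractions negative;
        # scan a few seeds and check no clamping happened
        found = False
        for seed in range(40):
            r = np.random.default_rng(seed)
            y, x1, x2, x3 = _tables(r, 15, (1, 2, 2, 2))
            res = varpart3(y, x1, x2, x3)
            if any(v < 0 for v in res.fractions.values()):
                found = True
                assert sum(res.fractions.values()) + res.residual == pytest.approx(
                    1.0, abs=1e-12
                )
        assert found


class TestTestFractions:
    def test_shared_keys_absent_and_signal_detected(self, rng):
        n = 80
        ids = [f"s{i}" for i in range(n)]
        x1 = quant_table(rng.normal(size=(n, 2)), ids=ids)
        x2 = quant_table(rng.normal(size=(n, 2)), ids=ids)
        y = quant_table(
            x1.numeric() @ rng.normal(size=(2, 2)) + 0.2 * rng.normal(size=(n, 2)),
            ids=ids,
        )
        tests = fraction_tests(y, [x1, x2], labels=("A", "B"), n_perm=199, seed=1)
        assert set(tests) == {"simple:A", "simple:B", "A", "B"}
        assert "AB" not in tests
        assert tests["simple:A"].p_value == pytest.approx(1 / 200)
        assert tests["A"].p_value == pytest.approx(1 / 200)
        assert all(t.p_value >= 1 / 200 for t in tests.values())

    def test_null_predictor_conditional_effect_not_significant(self, rng):
        nonsig = 0
        for i in range(30):
            n = 50
            ids = [f"s{j}" for j in range(n)]
            x1 = quant_table(rng.normal(size=(n, 1)), ids=ids)
            x2 = quant_table(rng.normal(size=(n, 1)), ids=ids)
            y = quant_table(
                x1.numeric() + 0.5 * rng.normal(size=(n, 1)), ids=ids
            )
            tests = fraction_tests(y, [x1, x2], labels=("A", "B"), n_perm=99, seed=i)
            nonsig += tests["B"].p_value > 0.1
        assert nonsig >= 0.8 * 30


class TestChiSquare:
    def test_identical_distributions_give_zero(self):
        res = chisq_fraction_compare([25, 25, 25, 25], [25, 25, 25, 25])
        assert res.statistic == 0.0
        assert res.df == 3

    def test_hand_computed_statistic(self):
        res = chisq_fraction_compare([10, 20, 30, 40], [25, 25, 25, 25])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 3

    def test_zero_expected_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            chisq_fraction_compare([1, 2], [0, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chisq_fraction_compare([1, 2, 3], [1, 2])


def test_subset_key_layouts():
    assert subset_key(["E"]) == "E"
    assert subset_key(["E", "S"]) == "ES"
    assert subset_key(["env", "spa"]) == "env+spa"


def test_varpart_agrees_with_r_vegan_oracle(rng, tmp_path):
    """Independent cross-check of the fraction arithmetic against vegan::varpart."""
    n = 25
    ids = [f"s{i}" for i in range(n)]
    Y = rng.normal(size=(n, 3))
    X1 = rng.normal(size=(n, 2))
    X2 = rng.normal(size=(n, 2))
    res = varpart2(
        quant_table(Y, ids=ids), quant_table(X1, ids=ids), quant_table(X2, ids=ids),
        labels=("A", "B"),
    )
    np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
    np.savetxt(tmp_path / "X1.csv", X1, delimiter=",")
    np.savetxt(tmp_path / "X2.csv", X2, delimiter=",")
    script = textwrap.dedent(
        f"""
        suppressMessages(library(vegan))
        Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
        X1 <- as.matrix(read.csv("{tmp_path}/X1.csv", header=FALSE))
        X2 <- as.matrix(read.csv("{tmp_path}/X2.csv", header=FALSE))
        v <- varpart(Y, X1, X2)
        cat(v$part$indfract$Adj.R.square, sep=",")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    # vegan row order: [a]=X1|X2, [b]=X2|X1, [c]=shared, [d]=residuals
    a, b, c, d = [float(v) for v in out.stdout.strip().split(",")]
    assert res.fractions["A"] == pytest.approx(a, abs=1e-6)
    assert res.fractions["B"] == pytest.approx(b, abs=1e-6)
    assert res.fractions["AB"] == pytest.approx(c, abs=1e-6)
    assert res.residual == pytest.approx(d, abs=1e-6)
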