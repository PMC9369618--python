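"""Dempster-Shafer combination: worked values, algebra and the power-set oracle."""

import numpy as np
import pandas as pd
import pytest
from oracle import dempster_powerset, focal_to_singleton_vector, singleton_masses_to_focal

from conftest import random_mass
from dsscreen import (
    CombinationResult,
    FusionSpec,
    MassVector,
    ProbabilityMatrix,
    combine_evidences,
    combine_pair,
    conflict_coefficient,
    fuse_predictions,
)
from dsscreen.errors import ContractError, TotalConflictError

DS12 = FusionSpec((1, 2))
DS123 = FusionSpec((1, 2, 3))


def test_mass_vector_validation():
    MassVector([0.5, 0.5])
    with pytest.raises(ContractError):
        MassVector([0.7, 0.2])  # does not sum to 1
    with pytest.raises(ContractError):
        MassVector([1.2, -0.2])


def test_conflict_worked_examples():
    one_hot_3 = MassVector([0, 0, 1])
    assert conflict_coefficient(one_hot_3, one_hot_3) == pytest.approx(0.0, abs=1e-12)
    assert conflict_coefficient(MassVector([1, 0, 0]), MassVector([0, 1, 0])) == pytest.approx(1.0)
    m1, m2 = MassVector([0.6, 0.3, 0.1]), MassVector([0.5, 0.3, 0.2])
    assert conflict_coefficient(m1, m2) == pytest.approx(0.59, abs=1e-12)
    with pytest.raises(ContractError):
        conflict_coefficient(MassVector([0.5, 0.5]), m1)


def test_combine_pair_worked_example():
    m1, m2 = MassVector([0.6, 0.3, 0.1]), MassVector([0.5, 0.3, 0.2])
    res = combine_pair(m1, m2)
    assert res.fused.masses == pytest.approx([0.30 / 0.41, 0.09 / 0.41, 0.02 / 0.41], abs=1e-12)
    assert res.fused.masses == pytest.approx([0.7317, 0.2195, 0.0488], abs=1e-4)
    assert res.kc == pytest.approx(0.59)


def test_combine_pair_uniform_is_neutral_and_certainty_absorbs():
    m1 = MassVector([0.6, 0.3, 0.1])
    uniform = MassVector([1 / 3] * 3)
    assert combine_pair(m1, uniform).fused.masses == pytest.approx(m1.masses, abs=1e-12)
    hot = MassVector([0, 1, 0])
    res = combine_pair(hot, hot)
    assert res.fused.masses == pytest.approx([0, 1, 0], abs=1e-12)
    assert res.kc == pytest.approx(0.0, abs=1e-12)


def test_combine_pair_total_conflict_raises():
    with pytest.raises(TotalConflictError):
        combine_pair(MassVector([1, 0, 0]), MassVector([0, 1, 0]))


def test_combine_evidences_worked_triple():
    m = MassVector([0.6, 0.3, 0.1])
    res = combine_evidences([m, m, m], DS123)
    cubes = np.array([0.216, 0.027, 0.001])
    assert res.fused.masses == pytest.approx(cubes / cubes.sum(), abs=1e-9)
    assert res.fused.masses == pytest.approx([0.8852, 0.1107, 0.0041], abs=1e-4)
    assert not res.fallback_used


def test_combine_evidences_uniform_anywhere_is_neutral():
    rng = np.random.default_rng(0)
    m1, m2 = MassVector(random_mass(rng, 4)), MassVector(random_mass(rng, 4))
    uniform = MassVector([0.25] * 4)
    with_u = combine_evidences([m1, uniform, m2], DS123)
    without = combine_evidences([m1, m2], DS12)
    assert with_u.fused.masses == pytest.approx(without.fused.masses, abs=1e-9)


def test_fallback_mean_on_disjoint_one_hots():
    res = combine_evidences([MassVector([1, 0, 0, 0]), MassVector([0, 1, 0, 0])], DS12)
    assert res.fallback_used
    assert res.kc > 0.95
    assert res.fused.masses == pytest.approx([0.5, 0.5, 0, 0], abs=1e-9)


def test_combine_evidences_rejects_wrong_arity():
    m = MassVector([0.5, 0.5])
    with pytest.raises(ContractError):
        combine_evidences([m], DS12)
    with pytest.raises(ContractError):
        combine_evidences([m, m, m], DS12)


def test_commutativity_on_random_pairs():
    rng = np.random.default_rng(12)
    for _ in range(1000):
        c = int(rng.integers(2, 6))
        a, b = MassVector(random_mass(rng, c)), MassVector(random_mass(rng, c))
        ab = combine_pair(a, b).fused.masses
        ba = combine_pair(b, a).fused.masses
        assert np.allclose(ab, ba, atol=1e-12)


def test_order_invariance_without_fallback():
    rng = np.random.default_rng(13)
    checked = 0
    while checked < 200:
        masses = [MassVector(random_mass(rng, 4)) for _ in range(3)]
        results = []
        orders = [(0, 1, 2), (2, 0, 1), (1, 2, 0)]
        rs = [combine_evidences([masses[i] for i in o], DS123) for o in orders]
        if any(r.fallback_used for r in rs):
            continue
        checked += 1
        for r in rs[1:]:
            assert np.allclose(rs[0].fused.masses, r.fused.masses, atol=1e-10)


def test_argmax_preserved_when_evidences_agree():
    rng = np.random.default_rng(14)
    checked = 0
    while checked < 300:
        c = int(rng.integers(3, 6))
        a, b = random_mass(rng, c), random_mass(rng, c)
        if np.argmax(a) != np.argmax(b):
            continue
        checked += 1
        fused = combine_pair(MassVector(a), MassVector(b)).fused.masses
        assert np.argmax(fused) == np.argmax(a)


@pytest.mark.parametrize("c", [3, 4])
def test_powerset_oracle_equivalence(c):
    rng = np.random.default_rng(c)
    for _ in range(1000):
        a, b = random_mass(rng, c), random_mass(rng, c)
        oracle_m, oracle_k = dempster_powerset(
            singleton_masses_to_focal(a), singleton_masses_to_focal(b)
        )
        expected = focal_to_singleton_vector(oracle_m, c)
        res = combine_pair(MassVector(a), MassVector(b))
        assert np.allclose(res.fused.masses, expected, atol=1e-12)
        assert res.kc == pytest.approx(oracle_k, abs=1e-12)


def test_kc_zero_only_for_identical_one_hots():
    rng = np.random.default_rng(5)
    for _ in range(500):
        c = int(rng.integers(2, 5))
        a, b = random_mass(rng, c), random_mass(rng, c)
        kc = conflict_coefficient(MassVector(a), MassVector(b))
        assert 0.0 <= kc <= 1.0
        if kc == 0.0:
            assert np.allclose(sorted(a), [0] * (c - 1) + [1]) and np.allclose(a, b)


def test_fusion_spec_names():
    assert FusionSpec((1, 2)).name == "DS12"
    assert FusionSpec.from_name("DS1235").indices == (1, 2, 3, 5)
    assert FusionSpec.from_name("DS12345").kinds == ("RF", "SVM", "LR", "LDA", "ABT")
    for bad in ("DS", "DS1", "DS21", "DS99", "DS112", "RF"):
        with pytest.raises(ContractError):
            FusionSpec.from_name(bad)


def _pm(rows, ids=None, index=1):
    ids = ids or [f"r{i}" for i in range(len(rows))]
    return ProbabilityMatrix(
        pd.DataFrame(rows, index=ids, columns=["c1", "c2", "c3"]), classifier_index=index
    )


def test_fuse_predictions_matches_row_oracle():
    rng = np.random.default_rng(21)
    rows_a = [random_mass(rng, 3) for _ in range(3)]
    rows_b = [random_mass(rng, 3) for _ in range(3)]
    fused = fuse_predictions(DS12, [_pm(rows_a), _pm(rows_b, index=2)])
    for r in range(3):
        expected = combine_evidences([MassVector(rows_a[r]), MassVector(rows_b[r])], DS12)
        assert np.allclose(fused.data.iloc[r].to_numpy(), expected.fused.masses, atol=1e-12)
        assert fused.report.iloc[r]["kc"] == pytest.approx(expected.kc)
    assert np.allclose(fused.data.sum(axis=1), 1.0, atol=1e-9)


def test_fuse_predictions_identity_and_neutral_cases():
    hot = _pm([[1, 0, 0], [0, 0, 1]])
    fused = fuse_predictions(DS12, [hot, _pm([[1, 0, 0], [0, 0, 1]], index=2)])
    assert np.allclose(fused.data.to_numpy(), hot.data.to_numpy(), atol=1e-9)
    some = _pm([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]])
    uni = _pm([[1 / 3] * 3, [1 / 3] * 3], index=2)
    fused2 = fuse_predictions(DS12, [some, uni])
    assert np.allclose(fused2.data.to_numpy(), some.data.to_numpy(), atol=1e-9)


def test_fuse_predictions_rejects_misalignment():
    a = _pm([[0.5, 0.3, 0.2]])
    b = _pm([[0.5, 0.3, 0.2]], ids=["other"], index=2)
    with pytest.raises(ContractError):
        fuse_predictions(DS12, [a, b])
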