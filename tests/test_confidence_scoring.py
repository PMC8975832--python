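"""d0 normalization, piTM, interface-score, model scoring and ranking."""

import numpy as np
import pytest

from complexkit import (
    ConsistencyError,
    MetricInputs,
    ParameterError,
    ScoreReport,
    d0,
    find_interface,
    interface_score,
    interface_score_terms,
    pitm,
    rank_models,
    score_model,
)
from complexkit.types import InterfaceSet, PAEMatrix
from complexkit.synthetic_fixtures import (
    helix_pair_complex,
    ladder_complex,
    make_pae,
    separated_complex,
)

from conftest import brute_force_interface_score, brute_force_pitm


# ---------------------------------------------------------------------------
# d0
# ---------------------------------------------------------------------------


def test_d0_branch_values():
    # both sides of the piecewise break: the function is discontinuous at 22
    assert d0(22) == pytest.approx(1.24 * 7 ** (1 / 3) - 1.8, abs=1e-12)
    assert d0(22) == pytest.approx(0.5720346666377626, abs=1e-12)
    assert d0(21) == pytest.approx(0.42)
    assert d0(10) == pytest.approx(0.20)


def test_d0_domain():
    with pytest.raises(ParameterError):
        d0(0)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _iface_and_pae(n_per_chain, pae_values=None, seed=0):
    """Interface of n residues per chain (A1-Bk ladder pairing) plus a PAE
    over exactly those residues."""
    order = [("A", i + 1) for i in range(n_per_chain)] + [
        ("B", i + 1) for i in range(n_per_chain)
    ]
    iface = InterfaceSet.from_pairs(
        [(("A", i + 1), ("B", i + 1)) for i in range(n_per_chain)]
    )
    T = len(order)
    if pae_values is None:
        rng = np.random.default_rng(seed)
        pae_values = np.abs(rng.normal(8, 4, size=(T, T)))
    pae = PAEMatrix(values=pae_values, residue_order=order)
    return MetricInputs.build(pae, iface)


# ---------------------------------------------------------------------------
# piTM
# ---------------------------------------------------------------------------


def test_pitm_is_one_at_zero_pae():
    inputs = _iface_and_pae(5, pae_values=np.zeros((10, 10)))
    assert pitm(inputs) == pytest.approx(1.0)


def test_pitm_constant_pae_closed_form():
    # constant e over a 22-residue interface: piTM = 1/(1 + (e/d0(22))^2);
    # e = d0(22) gives exactly 0.5
    e = d0(22)
    inputs = _iface_and_pae(11, pae_values=np.full((22, 22), e))
    assert pitm(inputs) == pytest.approx(0.5, abs=1e-12)


def test_pitm_three_residue_asymmetric_oracle():
    order = [("A", 1), ("A", 2), ("B", 1)]
    values = np.array([[0.0, 3.0, 7.0], [2.0, 0.0, 1.0], [9.0, 4.0, 0.5]])
    pae = PAEMatrix(values=values, residue_order=order)
    iface = InterfaceSet.from_pairs([(("A", 1), ("B", 1)), (("A", 2), ("B", 1))])
    inputs = MetricInputs.build(pae, iface)
    expected = brute_force_pitm(
        values, pae.index_map(), iface.interface_residues, d0(3)
    )
    assert pitm(inputs) == pytest.approx(expected, abs=1e-12)


def test_pitm_empty_interface_is_zero():
    order = [("A", 1), ("B", 1)]
    pae = PAEMatrix(values=np.zeros((2, 2)), residue_order=order)
    inputs = MetricInputs.build(pae, InterfaceSet.from_pairs([]))
    assert pitm(inputs) == 0.0


def test_pitm_missing_residue_in_pae_is_error():
    order = [("A", 1), ("B", 1)]
    pae = PAEMatrix(values=np.zeros((2, 2)), residue_order=order)
    iface = InterfaceSet.from_pairs([(("A", 1), ("B", 9))])
    with pytest.raises(ConsistencyError):
        pitm(MetricInputs.build(pae, iface))


def test_pitm_oracle_equivalence_small_interfaces(rng):
    """Exhaustive reference-frame enumeration for interfaces up to 12
    residues agrees to 1e-12."""
    for trial in range(20):
        n = int(rng.integers(1, 7))  # up to 12 interface residues
        inputs = _iface_and_pae(n, seed=trial)
        expected = brute_force_pitm(
            inputs.pae.values,
            inputs.index_map,
            inputs.iface.interface_residues,
            d0(2 * n),
        )
        assert pitm(inputs) == pytest.approx(expected, abs=1e-12)


def test_pitm_bounds_and_monotone_decrease(rng):
    inputs = _iface_and_pae(6, seed=42)
    base = pitm(inputs)
    assert 0 <= base <= 1
    # increasing any single PAE entry between interface residues never
    # increases the score
    idx = [inputs.index_map[r] for r in sorted(inputs.iface.interface_residues)]
    for _ in range(10):
        i, j = rng.choice(idx, size=2)
        bumped = inputs.pae.values.copy()
        bumped[i, j] += 5.0
        worse = pitm(
            MetricInputs.build(
                PAEMatrix(bumped, inputs.pae.residue_order), inputs.iface
            )
        )
        assert worse <= base + 1e-12


# ---------------------------------------------------------------------------
# interface-score
# ---------------------------------------------------------------------------


def test_interface_score_is_one_at_zero_pae():
    inputs = _iface_and_pae(5, pae_values=np.zeros((10, 10)))
    assert interface_score(inputs) == pytest.approx(1.0)
    # per-chain terms sum to S and split as I_p / I
    terms = dict(interface_score_terms(inputs))
    assert terms["A"] == pytest.approx(0.5) and terms["B"] == pytest.approx(0.5)


def test_interface_score_two_chain_oracle(rng):
    """Brute-force enumeration over all allowed reference frames on a
    2+2-residue interface with random PAE."""
    for trial in range(20):
        inputs = _iface_and_pae(2, seed=100 + trial)
        expected = brute_force_interface_score(
            inputs.pae.values,
            inputs.index_map,
            inputs.iface.interface_residues,
            d0(4),
        )
        assert interface_score(inputs) == pytest.approx(expected, abs=1e-12)


def test_interface_score_inert_chain_contributes_zero():
    # chain C present in the complex but absent from the interface
    order = [("A", 1), ("A", 2), ("B", 1), ("B", 2), ("C", 1)]
    rng = np.random.default_rng(5)
    values5 = np.abs(rng.normal(6, 3, size=(5, 5)))
    iface = InterfaceSet.from_pairs(
        [(("A", 1), ("B", 1)), (("A", 2), ("B", 2))]
    )
    pae5 = PAEMatrix(values=values5, residue_order=order)
    with_c = MetricInputs.build(pae5, iface)
    terms = dict(interface_score_terms(with_c))
    assert terms["C"] == 0.0

    pae4 = PAEMatrix(values=values5[:4, :4], residue_order=order[:4])
    without_c = MetricInputs.build(pae4, iface)
    assert interface_score(with_c) == pytest.approx(
        interface_score(without_c), abs=1e-12
    )


def test_interface_score_bounds_random(rng):
    for trial in range(15):
        inputs = _iface_and_pae(int(rng.integers(1, 8)), seed=200 + trial)
        s = interface_score(inputs)
        assert 0 <= s <= 1


# ---------------------------------------------------------------------------
# score_model
# ---------------------------------------------------------------------------


def test_perfect_dimer_scores_one():
    model, _ = helix_pair_complex(n_res=15)
    pae = make_pae(model.residue_order(), model="zero")
    report = score_model(model, pae, model_id="perfect")
    assert report.pitm == pytest.approx(1.0)
    assert report.interface_score == pytest.approx(1.0)
    assert report.interface_size > 0
    assert report.clash_indicator is not None


def test_huge_pae_scores_near_zero():
    model, _ = helix_pair_complex(n_res=15)
    pae = make_pae(model.residue_order(), model="constant", e=30.0, ceiling=30.0)
    report = score_model(model, pae)
    I = report.interface_size
    closed_form = 1.0 / (1.0 + (30.0 / d0(I)) ** 2)
    assert report.pitm == pytest.approx(closed_form, abs=1e-12)
    assert report.pitm < 0.01 and report.interface_score < 0.01


def test_single_chain_model_convention():
    model, _ = separated_complex()
    # keep only chain A
    from complexkit.types import StructureModel

    single = StructureModel([model.chains[0]])
    pae = make_pae(single.residue_order(), model="zero")
    report = score_model(single, pae, model_id="mono")
    assert report.pitm == 0.0
    assert report.interface_score == 0.0
    assert report.clash_indicator is None


def test_score_model_order_mismatch_is_error():
    model, _ = ladder_complex(k=3)
    wrong_order = list(reversed(model.residue_order()))
    pae = make_pae(wrong_order, model="zero")
    with pytest.raises(ConsistencyError):
        score_model(model, pae)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _report(mid, s, p=0.5):
    return ScoreReport(
        model_id=mid,
        pitm=p,
        interface_score=s,
        clash_indicator=1.0,
        interface_size=10,
        n_contacts=8,
    )


def test_rank_descending_by_interface_score():
    ranked = rank_models([_report("a", 0.2), _report("b", 0.9), _report("c", 0.5)])
    assert [r.model_id for r in ranked] == ["b", "c", "a"]


def test_rank_tie_breaks_by_pitm_then_id():
    ranked = rank_models(
        [_report("a", 0.5, p=0.3), _report("b", 0.5, p=0.4), _report("c", 0.5, p=0.4)]
    )
    assert [r.model_id for r in ranked] == ["b", "c", "a"]


def test_rank_selects_single_top_of_fifteen(rng):
    # three runs x five models, as in repeated prediction protocols
    reports = [
        _report(f"run{r}_model{m}", float(rng.uniform(0, 1)))
        for r in range(3)
        for m in range(5)
    ]
    ranked = rank_models(reports)
    assert len(ranked) == 15
    best = max(reports, key=lambda x: x.interface_score)
    assert ranked[0].model_id == best.model_id
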