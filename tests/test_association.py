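"""Axis binning, chi-square/Cramér's V and the character-axis report."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from morphodisp import (
    CharacterMatrix,
    CharacterSpec,
    MISSING,
    associate_all,
    bin_axis,
    chi_square_p,
    cramers_v,
    gower_matrix,
    pcoa,
    retain_axes,
)
from morphodisp.errors import (
    ContinuousCharacterError,
    DegenerateAxisError,
    MorphodispError,
)

from oracles import chi2_by_hand, cramers_v_by_hand


class TestBinAxis:
    def test_four_bins_example(self):
        assert list(bin_axis([0.0, 0.2, 0.5, 1.0], 4)) == [1, 1, 3, 4]

    def test_interior_boundary_opens_next_bin(self):
        assert list(bin_axis([0.0, 0.25, 1.0], 4)) == [1, 2, 4]

    def test_max_lands_in_last_closed_bin(self):
        bins = bin_axis(np.linspace(-3, 5, 17), 4)
        assert bins.max() == 4 and bins.min() == 1

    def test_constant_axis_rejected(self):
        with pytest.raises(DegenerateAxisError):
            bin_axis([1.0, 1.0, 1.0], 4)

    def test_every_score_assigned_one_bin(self, rng):
        scores = rng.normal(size=50)
        bins = bin_axis(scores, 6)
        assert bins.shape == scores.shape
        assert set(np.unique(bins)) <= set(range(1, 7))


class TestChiSquare:
    def test_independent_table(self):
        chi2, df, p = chi_square_p([[5, 5], [5, 5]])
        assert (chi2, df, p) == (0.0, 1, 1.0)

    def test_diagonal_table(self):
        chi2, df, p = chi_square_p([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(float(chi2_dist.sf(20.0, 1)), rel=1e-9)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_zero_margin_column_collapses_to_undefined(self):
        assert chi_square_p([[3, 0], [2, 0]]) is None

    def test_invalid_table_rejected(self):
        with pytest.raises(MorphodispError):
            chi_square_p([[-1, 2], [3, 4]])


class TestCramersV:
    def test_complete_association(self):
        assert cramers_v([[5, 0], [0, 5]]) == pytest.approx(1.0)

    def test_independence(self):
        assert cramers_v([[5, 5], [5, 5]]) == pytest.approx(0.0)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(30):
            table = rng.integers(0, 12, size=(3, 4))
            if table.sum() == 0:
                continue
            ours = cramers_v(table)
            t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            if t.shape[0] < 2 or t.shape[1] < 2:
                assert ours is None
                continue
            assert ours == pytest.approx(cramers_v_by_hand(table), abs=1e-12)
            chi2, df, p = chi_square_p(table)
            o_chi2, o_df, o_p = chi2_by_hand(table)
            assert chi2 == pytest.approx(o_chi2, abs=1e-10)
            assert (df, p) == (o_df, pytest.approx(o_p, abs=1e-12))


def _ordination_of(matrix, n_axes=2):
    return retain_axes(pcoa(gower_matrix(matrix)), n_axes=n_axes)


def test_constant_character_is_undefined_everywhere(reference,
                                                    reference_ordination):
    matrix, _, _ = reference
    const = CharacterMatrix(
        taxa=list(matrix.taxa),
        specs=list(matrix.specs) + [CharacterSpec("flat", "nominal", ("u", "v"))],
        states=[row + ["u"] for row in matrix.states],
    )
    # ordination taxa must match; recompute on the extended matrix
    o = _ordination_of(const, n_axes=4)
    rep = associate_all(const, o)
    for axis in range(1, 5):
        assert rep.cell("flat", axis).v is None
        assert not rep.cell("flat", axis).significant


def test_gradient_character_loads_on_axis_one(reference_ordination, reference):
    """A character that increases monotonically along axis 1 must associate
    more strongly with axis 1 than axis 2."""
    matrix, _, _ = reference
    axis1 = reference_ordination.retained[:, 0]
    quartile = bin_axis(axis1, 4)
    grad = CharacterMatrix(
        taxa=list(matrix.taxa),
        specs=list(matrix.specs)
        + [CharacterSpec("grad", "ordinal", ("1", "2", "3", "4"))],
        states=[row + [str(q)] for row, q in zip(matrix.states, quartile)],
    )
    o = _ordination_of(grad, n_axes=4)
    rep = associate_all(grad, o)
    assert rep.cell("grad", 1).v > rep.cell("grad", 2).v


def test_missing_states_dropped_pairwise(reference, reference_ordination):
    matrix, _, _ = reference
    rep = associate_all(matrix, reference_ordination)
    for spec in matrix.specs:
        n_obs = sum(
            1 for row in matrix.states
            if row[[s.name for s in matrix.specs].index(spec.name)] is not MISSING
        )
        assert rep.cell(spec.name, 1).n_used == n_obs


def test_axis_reflection_invariance(reference, reference_ordination):
    """Reflecting any axis permutes bin labels only: V and p are unchanged."""
    import dataclasses

    matrix, _, _ = reference
    base = associate_all(matrix, reference_ordination)
    flipped = dataclasses.replace(
        reference_ordination,
        coordinates=reference_ordination.coordinates * -1.0,
    )
    rep = associate_all(matrix, flipped)
    for c_base, c_flip in zip(base.cells, rep.cells):
        if c_base.v is None:
            assert c_flip.v is None
        else:
            assert c_flip.v == pytest.approx(c_base.v, abs=1e-12)
            assert c_flip.p == pytest.approx(c_base.p, abs=1e-12)


def test_state_label_permutation_invariance(reference, reference_ordination):
    matrix, _, _ = reference
    base = associate_all(matrix, reference_ordination)
    j = [s.name for s in matrix.specs].index("orientation")
    spec = matrix.specs[j]
    relabel = dict(zip(spec.levels, reversed(spec.levels)))
    permuted = CharacterMatrix(
        taxa=list(matrix.taxa),
        specs=[
            CharacterSpec(s.name, s.kind, s.levels, s.description) if i != j
            else CharacterSpec(s.name, s.kind, tuple(reversed(s.levels)))
            for i, s in enumerate(matrix.specs)
        ],
        states=[
            [relabel[v] if (i == j and v is not MISSING) else v
             for i, v in enumerate(row)]
            for row in matrix.states
        ],
    )
    rep = associate_all(permuted, reference_ordination)
    for axis in range(1, 5):
        assert rep.cell("orientation", axis).v == pytest.approx(
            base.cell("orientation", axis).v, abs=1e-12
        )


def test_high_v_can_be_nonsignificant():
    """V and the significance flag are independent columns: a tiny sample
    yields V = 1 with p > 0.05."""
    table = [[2, 0], [0, 1]]
    v = cramers_v(table)
    _, _, p = chi_square_p(table)
    assert v == pytest.approx(1.0)
    assert p > 0.05


def test_continuous_numeric_character_rejected(reference_ordination, reference):
    matrix, _, _ = reference
    cont = CharacterMatrix(
        taxa=list(matrix.taxa),
        specs=list(matrix.specs) + [CharacterSpec("len", "numeric")],
        states=[row + [0.5 + 0.01 * i] for i, row in enumerate(matrix.states)],
    )
    o = _ordination_of(cont, n_axes=4)
    with pytest.raises(ContinuousCharacterError):
        associate_all(cont, o)


def test_holm_correction_is_more_conservative(reference, reference_ordination):
    matrix, _, _ = reference
    raw = associate_all(matrix, reference_ordination, correction="none")
    holm = associate_all(matrix, reference_ordination, correction="holm")
    n_raw = sum(c.significant for c in raw.cells)
    n_holm = sum(c.significant for c in holm.cells)
    assert n_holm <= n_raw
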