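"""Matrix/spec/group parsing, validation and report serialization."""

import math

import pytest

from morphodisp import (
    EXCLUDED,
    MISSING,
    CharacterMatrix,
    CharacterSpec,
    GroupScheme,
    read_groups,
    read_matrix,
    read_report,
    write_matrix,
    write_report,
)
from morphodisp.errors import (
    DuplicateTaxonError,
    EmptyColumnError,
    InvalidStateError,
    SpecMismatchError,
    UnknownTaxonError,
    ValidationError,
)
from morphodisp.matrix_io import write_groups
from morphodisp.synthetic import SyntheticSpec, generate_matrix

SPEC_YAML = """\
- name: claws
  kind: binary_symmetric
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_minimal_binary_matrix(tmp_path):
    mp = _write(tmp_path, "m.tsv", "taxon\tclaws\nA\t0\nB\t1\n")
    sp = _write(tmp_path, "s.yaml", SPEC_YAML)
    m = read_matrix(mp, sp)
    assert (m.n_taxa, m.n_characters) == (2, 1)
    assert m.states[0][0] == "0" and m.states[1][0] == "1"


def test_missing_tokens_map_to_missing(tmp_path):
    mp = _write(tmp_path, "m.tsv", "taxon\tclaws\nA\t?\nB\t1\n")
    sp = _write(tmp_path, "s.yaml", SPEC_YAML)
    m = read_matrix(mp, sp)
    assert m.states[0][0] is MISSING


@pytest.mark.parametrize(
    "matrix_text,err",
    [
        ("taxon\tclaws\nA\t0\nA\t1\n", DuplicateTaxonError),
        ("taxon\tclaws\nA\t2\nB\t1\n", InvalidStateError),
        ("taxon\twrong\nA\t0\nB\t1\n", SpecMismatchError),
        ("taxon\tclaws\nA\t0\t1\nB\t1\n", ValidationError),
        ("taxon\tclaws\nA\t?\nB\t?\n", EmptyColumnError),
    ],
    ids=["duplicate-taxon", "bad-level", "header-mismatch", "ragged-row",
         "all-missing-column"],
)
def test_corrupted_fixtures_rejected(tmp_path, matrix_text, err):
    mp = _write(tmp_path, "m.tsv", matrix_text)
    sp = _write(tmp_path, "s.yaml", SPEC_YAML)
    with pytest.raises(err):
        read_matrix(mp, sp)


def test_spec_requires_levels_for_ordinal():
    with pytest.raises(ValidationError):
        CharacterSpec("x", "ordinal")
    with pytest.raises(ValidationError):
        CharacterSpec("x", "nominal", ("a",))
    with pytest.raises(ValidationError):
        CharacterSpec("x", "ranked")


def test_read_write_read_roundtrip(tmp_path):
    spec = SyntheticSpec(
        n_taxa=12,
        char_counts={"numeric": 2, "ordinal": 2, "nominal": 2,
                     "binary_symmetric": 1, "binary_asymmetric": 1},
        n_groups=3,
        separation=2.0,
        missing_rate=0.2,
        seed=5,
    )
    m, _ = generate_matrix(spec)
    write_matrix(m, tmp_path / "m.tsv", tmp_path / "s.yaml")
    m2 = read_matrix(tmp_path / "m.tsv", tmp_path / "s.yaml")
    assert m2.taxa == m.taxa
    assert m2.specs == m.specs
    assert m2.states == m.states


def test_groups_roundtrip_and_exclusion(tmp_path, reference):
    matrix, body_plan, _ = reference
    gp = tmp_path / "g.tsv"
    write_groups(body_plan, gp)
    scheme = read_groups(gp, matrix)
    assert scheme.assignment == body_plan.assignment
    # the problematica taxon is carried but flagged, not grouped
    assert "hur04" in scheme.excluded()
    assert all("hur04" not in members for members in scheme.groups().values())


def test_groups_small_scheme(tmp_path):
    m = CharacterMatrix(
        taxa=["a", "b", "c", "d", "e"],
        specs=[CharacterSpec("claws", "binary_symmetric")],
        states=[["0"], ["1"], ["0"], ["1"], ["0"]],
    )
    gp = _write(tmp_path, "g.tsv", "a\tA\nb\tA\nc\tA\nd\tB\ne\tB\n")
    scheme = read_groups(gp, m)
    assert {g: len(t) for g, t in scheme.groups().items()} == {"A": 3, "B": 2}


def test_groups_unknown_taxon_rejected(tmp_path):
    m = CharacterMatrix(
        taxa=["a", "b"],
        specs=[CharacterSpec("claws", "binary_symmetric")],
        states=[["0"], ["1"]],
    )
    gp = _write(tmp_path, "g.tsv", "a\tA\nb\tA\nghost\tB\n")
    with pytest.raises(UnknownTaxonError, match="ghost"):
        read_groups(gp, m)


def test_report_roundtrip_association(tmp_path, reference, reference_ordination):
    from morphodisp import associate_all

    matrix, _, _ = reference
    rep = associate_all(matrix, reference_ordination)
    write_report(rep, tmp_path / "assoc.json")
    back = read_report(tmp_path / "assoc.json")
    cells = back["cells"]
    assert len(cells) == matrix.n_characters * 4
    for cell, orig in zip(cells, rep.cells):
        assert cell["character"] == orig.character
        assert cell["v"] == orig.v and cell["p"] == orig.p  # lossless floats


def test_report_roundtrip_disparity_with_null_group(tmp_path, reference,
                                                    reference_ordination):
    from morphodisp import disparity_summary, group_axis_variances

    matrix, _, _ = reference
    scheme = GroupScheme(
        name="tiny",
        assignment={t: ("solo" if t == matrix.taxa[0] else "rest")
                    for t in matrix.taxa},
    )
    rep = disparity_summary(group_axis_variances(reference_ordination, scheme),
                            scheme)
    write_report(rep, tmp_path / "disp.json")
    back = read_report(tmp_path / "disp.json")
    assert back["per_group"]["solo"]["axis_variances"] is None
    assert back["per_group"]["rest"]["median_v"] == rep.per_group["rest"].median_v


def test_report_roundtrip_cascade(tmp_path, reference_ordination):
    from morphodisp import cascade_select

    cas = cascade_select(reference_ordination.retained, 3, 7, restarts=10, seed=1)
    write_report(cas, tmp_path / "cascade.json")
    back = read_report(tmp_path / "cascade.json")
    assert sorted(back["partitions"]) == ["3", "4", "5", "6", "7"]
    assert back["chosen_k"] == cas.chosen_k
    for k, p in cas.partitions.items():
        assert back["partitions"][str(k)]["ch"] == pytest.approx(p.ch)


def test_infinity_roundtrips(tmp_path):
    from morphodisp.clustering import PartitionResult

    p = PartitionResult(k=2, assignment=[0, 0, 1, 1], within_ss=0.0, ch=math.inf)
    write_report(p, tmp_path / "p.json")
    assert read_report(tmp_path / "p.json")["ch"] == math.inf
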