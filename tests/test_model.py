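"""Domain types: GPR logic, model validation, S matrix, balance audits."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cljflux.errors import DanglingReferenceError, DuplicateIdError
from cljflux.gpr import GPR, parse_gpr
from cljflux.model import (
    Metabolite,
    Reaction,
    build_model,
    check_balance,
    evaluate_gpr,
    formula_from_string,
    formula_to_string,
    stoichiometric_matrix,
)
from conftest import make_chain_model

GENES = ["g0", "g1", "g2", "g3", "g4", "g5"]


# -- GPR ------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule, ko, expected",
    [
        ("gA and gB", {"gA"}, False),
        ("gA or gB", {"gA"}, True),
        ("", {"anything"}, True),
        ("gA and (gB or gC)", {"gB"}, True),
        ("gA and (gB or gC)", {"gB", "gC"}, False),
        ("(gA and gB) or (gA and gC)", {"gC"}, True),
    ],
)
def test_gpr_evaluation(rule, ko, expected):
    assert evaluate_gpr(rule, ko) is expected


def test_gpr_string_round_trip():
    rule = "gA and (gB or gC)"
    assert parse_gpr(parse_gpr(rule).to_string()).to_string() == parse_gpr(rule).to_string()
    assert parse_gpr("gA AND gB").genes() == {"gA", "gB"}


@pytest.mark.parametrize("bad", ["gA and", "(gA or gB", "and gA", "gA gB"])
def test_gpr_parse_errors(bad):
    with pytest.raises(ValueError):
        parse_gpr(bad)


@st.composite
def gpr_trees(draw, depth=0):
    if depth >= 4 or draw(st.booleans()):
        return GPR(op="gene", gene=draw(st.sampled_from(GENES)))
    op = draw(st.sampled_from(["and", "or"]))
    kids = tuple(
        draw(gpr_trees(depth=depth + 1))
        for _ in range(draw(st.integers(min_value=2, max_value=3)))
    )
    return GPR(op=op, children=kids)


def _truth_table_eval(tree: GPR, active: dict[str, bool]) -> bool:
    """Independent evaluation via Python's own boolean operators."""
    if tree.op == "gene":
        return active[tree.gene]
    vals = [_truth_table_eval(c, active) for c in tree.children]
    return all(vals) if tree.op == "and" else any(vals)


@given(tree=gpr_trees(), ko=st.sets(st.sampled_from(GENES)))
@settings(max_examples=200, derandomize=True)
def test_gpr_agrees_with_truth_table(tree, ko):
    active = {g: g not in ko for g in GENES}
    assert tree.evaluate(ko) == _truth_table_eval(tree, active)


# -- model construction ---------------------------------------------------

def test_empty_model():
    m = build_model([], [], [], None)
    assert m.shape == (0, 0)
    assert stoichiometric_matrix(m).shape == (0, 0)


def test_chain_model_shape():
    m = make_chain_model()
    assert m.shape == (2, 3)
    S = stoichiometric_matrix(m)
    j = m.reaction_index("AB")
    assert S[0, j] == -1 and S[1, j] == 1


def test_duplicate_ids_rejected():
    mets = [Metabolite(id="x_c"), Metabolite(id="x_c")]
    with pytest.raises(DuplicateIdError):
        build_model(mets, [], [], None)
    with pytest.raises(DuplicateIdError):
        build_model([], [Reaction(id="R"), Reaction(id="R")], [], None)


def test_dangling_metabolite_rejected():
    with pytest.raises(DanglingReferenceError):
        build_model([], [Reaction(id="R", stoichiometry={"x_c": -1.0})], [], None)


def test_dangling_objective_rejected():
    with pytest.raises(DanglingReferenceError):
        build_model([], [], [], "BIOMASS")


def test_exchange_must_be_extracellular():
    mets = [Metabolite(id="x_c", compartment="c")]
    rxn = Reaction(id="EX_x", stoichiometry={"x_c": -1.0}, is_exchange=True)
    with pytest.raises(ValueError):
        build_model(mets, [rxn], [], None)


def test_bad_bounds_rejected():
    with pytest.raises(ValueError):
        Reaction(id="R", lower_bound=1.0, upper_bound=0.0)


# -- stoichiometric matrix ------------------------------------------------

def test_matrix_is_lossless(core_model):
    """Columns of S reproduce every reaction's stoichiometry map exactly."""
    S = stoichiometric_matrix(core_model)
    for j, r in enumerate(core_model.reactions):
        rebuilt = {
            core_model.metabolites[i].id: S[i, j]
            for i in range(S.shape[0])
            if S[i, j] != 0
        }
        assert rebuilt == {k: float(v) for k, v in r.stoichiometry.items()}


# -- balance audits -------------------------------------------------------

def test_ptar_balances_by_hand(core_model, metabolite_table):
    """Phosphotransacetylase: C23H34N7O17P3S(4-) + HO4P(2-) <->
    C2H3O5P(2-) + C21H32N7O16P3S(4-); every element and the charge net
    to zero (checked by hand from the standard formulas)."""
    res = check_balance(core_model.reaction("PTAr"), metabolite_table)
    assert res.status == "balanced"
    assert res.imbalance == {}


def test_constructed_hydrogen_imbalance():
    mets = {
        "a_c": Metabolite(id="a_c", formula={"C": 1, "H": 2}),
        "b_c": Metabolite(id="b_c", formula={"C": 1, "H": 3}),
    }
    r = Reaction(id="R", stoichiometry={"a_c": -1.0, "b_c": 1.0})
    res = check_balance(r, mets)
    assert res.status == "unbalanced"
    assert res.imbalance == {"H": 1.0}


def test_exchange_and_biomass_exempt(core_model, metabolite_table):
    assert check_balance(core_model.reaction("EX_ac"), metabolite_table).status == "exempt"
    assert check_balance(core_model.reaction("BIOMASS"), metabolite_table).status == "exempt"


def test_lumped_participant_skipped_with_warning(core_model, metabolite_table):
    with pytest.warns(UserWarning, match="lumped"):
        res = check_balance(core_model.reaction("METR"), metabolite_table)
    assert res.status == "skipped"


# -- formula helpers ------------------------------------------------------

@pytest.mark.parametrize(
    "s, parsed",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("HO4P", {"H": 1, "O": 4, "P": 1}),
        ("Fe2S2", {"Fe": 2, "S": 2}),
    ],
)
def test_formula_round_trip(s, parsed):
    assert formula_from_string(s) == parsed
    assert formula_from_string(formula_to_string(parsed)) == parsed
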