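"""Fold-change protocol arithmetic, GPR mapping, consistency, full pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxkit.core import Metabolite, Model, Reaction
from fluxkit.fixtures import (
    SyntheticOmicsSpec,
    ToyModelSpec,
    make_omics_dataset,
    make_toy_core_model,
)
from fluxkit.gpr import parse_gpr
from fluxkit.omics import (
    FCProtocolConfig,
    GeneFCTable,
    ReactionFCRecord,
    find_consistent_reactions,
    floor_value,
    fva_center,
    is_consistent,
    map_gene_fc_to_reactions,
    run_fc_protocol,
    simulated_fc,
)

EPS = 0.0001


# ------------------------------------------------------------- flooring

@pytest.mark.parametrize(
    "x, expected",
    [
        (0.00005, 0.00015),  # small positive: pushed up
        (-0.00005, -0.00015),  # small negative: pushed down
        (0.5, 0.5),  # unchanged
        (-0.5, -0.5),
        (0.0, EPS),  # zero convention: continuous extension of + branch
        (EPS, EPS),  # boundary: untouched
    ],
)
def test_floor_value(x, expected):
    assert floor_value(x, EPS) == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------ simulated FCs

@pytest.mark.parametrize(
    "v_mut, v_wt, up_mut, up_wt, expected",
    [
        (2.0, 1.0, 2.0, 2.0, 1.0),  # log2(1) - log2(0.5)
        (0.0, 0.0, 5.0, 5.0, 0.0),  # both floor to +eps
        (1.0, 1.0, 2.0, 2.0, 0.0),  # identical ratios
        (4.0, 1.0, 8.0, 4.0, 1.0),  # normalisation by |uptake|
    ],
)
def test_simulated_fc_values(v_mut, v_wt, up_mut, up_wt, expected):
    fc, _ = simulated_fc(v_mut, v_wt, up_mut, up_wt, EPS)
    assert fc == pytest.approx(expected, abs=1e-12)


def test_simulated_fc_zero_uptake_rejected():
    with pytest.raises(ValueError):
        simulated_fc(1.0, 1.0, 0.0, 2.0)


def test_simulated_fc_sign_reversal_flagged():
    fc, flags = simulated_fc(-2.0, 2.0, 2.0, 2.0)
    assert "sign_reversal" in flags
    assert fc == pytest.approx(0.0)  # same magnitude, opposite sign


@settings(max_examples=300, derandomize=True)
@given(
    a=st.floats(-5, 5, allow_nan=False),
    b=st.floats(-5, 5, allow_nan=False),
    up=st.floats(1, 20),
)
def test_simulated_fc_antisymmetry(a, b, up):
    """FC(a,b) = -FC(b,a) whenever no normalised flux sits in the floored band."""
    if abs(a / up) <= EPS or abs(b / up) <= EPS:
        return
    fc_ab, _ = simulated_fc(a, b, up, up, EPS)
    fc_ba, _ = simulated_fc(b, a, up, up, EPS)
    assert fc_ab == pytest.approx(-fc_ba, abs=1e-9)


@pytest.mark.parametrize(
    "vmin, vmax, expected", [(-1, 3, 1.0), (2, 2, 2.0), (-3, 3, 0.0)]
)
def test_fva_center(vmin, vmax, expected):
    assert fva_center(vmin, vmax) == expected


@settings(max_examples=100, derandomize=True)
@given(
    lo=st.floats(-100, 100, allow_nan=False),
    width=st.floats(0, 100, allow_nan=False),
)
def test_fva_center_within_range(lo, width):
    c = fva_center(lo, lo + width)
    assert lo - 1e-9 <= c <= lo + width + 1e-9


# -------------------------------------------------------------- mapping

def _tiny_model():
    model = Model(id="tiny")
    model.add_metabolite(Metabolite("m_c"))
    model.add_metabolite(Metabolite("n_c"))
    model.add_reaction(
        Reaction("R1", stoichiometry={"m_c": -1, "n_c": 1},
                 gpr=parse_gpr("g1 or g2 or g3"))
    )
    model.add_reaction(
        Reaction("R2", stoichiometry={"n_c": -1, "m_c": 1},
                 gpr=parse_gpr("g4 and g5"))
    )
    model.add_reaction(Reaction("R3", stoichiometry={"m_c": -2, "n_c": 2}))
    return model


def test_mapping_mean_over_nonzero_genes():
    table = GeneFCTable({"g1": 2.0, "g2": 0.0, "g3": -1.0})
    mapped = map_gene_fc_to_reactions(_tiny_model(), table)
    fc, genes = mapped["R1"]
    assert fc == pytest.approx(0.5)  # mean of {2, -1}; g2 excluded
    assert genes == ("g1", "g3")
    assert mapped["R2"] == (None, ())  # all genes unmeasured
    assert mapped["R3"] == (None, ())  # no GPR: never mapped


def test_mapping_zero_fc_gene_is_inert():
    base = map_gene_fc_to_reactions(
        _tiny_model(), GeneFCTable({"g1": 2.0, "g3": -1.0})
    )
    with_zero = map_gene_fc_to_reactions(
        _tiny_model(), GeneFCTable({"g1": 2.0, "g2": 0.0, "g3": -1.0})
    )
    assert base["R1"][0] == with_zero["R1"][0]


# ---------------------------------------------------------- consistency

@pytest.mark.parametrize(
    "meas, pfba, fva_fc, expected",
    [
        (1.0, -0.5, 0.2, True),  # FVA branch saves it
        (1.0, -0.5, -0.2, False),  # both sims opposite
        (0.0, 1.0, 1.0, False),  # zero measured never qualifies
        (-1.0, -0.3, 0.4, True),
        (-1.0, 0.0, 0.0, False),  # zero sims never qualify
    ],
)
def test_consistency_rule(meas, pfba, fva_fc, expected):
    assert is_consistent(meas, pfba, fva_fc) is expected


def test_consistency_matches_brute_force_sign_table():
    """Membership equals an exhaustive sign-table oracle on random records."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(1000):
        vals = rng.choice([-1.5, -0.2, 0.0, 0.3, 2.0], size=3)
        records.append(
            ReactionFCRecord(
                reaction_id=f"r{i}", fc_meas=vals[0], fc_pfba=vals[1],
                fc_fva=vals[2], mapped=True, consistent=False,
            )
        )
    got = find_consistent_reactions(records)

    def oracle(r):  # literal sign-table transcription
        neg = (r.fc_pfba < 0 or r.fc_fva < 0) and r.fc_meas < 0
        pos = (r.fc_pfba > 0 or r.fc_fva > 0) and r.fc_meas > 0
        return neg or pos

    assert got == {r.reaction_id for r in records if oracle(r)}


# ------------------------------------------------------------- pipeline

@pytest.fixture(scope="module")
def redox():
    return make_toy_core_model(ToyModelSpec(include_redox=True))


def test_null_case_identical_conditions(redox):
    """Same condition on both sides, all gene FCs zero: no signal anywhere."""
    gene_fc, wt, mut, _ = make_omics_dataset(
        redox,
        SyntheticOmicsSpec(deleted_genes=(), up_reactions=(), down_reactions=()),
    )
    report = run_fc_protocol(
        redox, wt, wt, (), GeneFCTable({g: 0.0 for g in redox.genes}),
        FCProtocolConfig(loopless=False),
    )
    assert report.n_consistent == 0
    assert all(abs(r.fc_pfba) < 1e-6 for r in report.records)
    assert report.consistent_set == set()


def test_planted_truth_recovered_exactly(redox):
    gene_fc, wt, mut, expected = make_omics_dataset(redox, SyntheticOmicsSpec())
    report = run_fc_protocol(
        redox, wt, mut, ["hydG", "ech"], gene_fc, FCProtocolConfig(loopless=True)
    )
    assert report.consistent_set == expected
    assert expected  # the fixture must plant a nonempty signal
    assert report.pearson_pfba == pytest.approx(1.0, abs=1e-6)


def test_sign_flipped_branch_excluded(redox):
    flipped = SyntheticOmicsSpec(sign_flip_reactions=("ALCD",))
    gene_fc, wt, mut, expected = make_omics_dataset(redox, flipped)
    report = run_fc_protocol(
        redox, wt, mut, ["hydG", "ech"], gene_fc, FCProtocolConfig(loopless=True)
    )
    assert "ALCD" not in expected
    assert "ALCD" not in report.consistent_set
    assert report.consistent_set == expected


def test_unmeasured_genes_leave_reactions_unmapped(redox):
    spec = SyntheticOmicsSpec(
        up_reactions=(), down_reactions=(), unmeasured_fraction=1.0
    )
    gene_fc, wt, mut, expected = make_omics_dataset(redox, spec)
    assert gene_fc.values == {}
    report = run_fc_protocol(
        redox, wt, mut, ["hydG", "ech"], gene_fc, FCProtocolConfig(loopless=False)
    )
    assert report.n_mapped == 0 and report.n_consistent == 0


def test_report_count_invariants_and_outputs(redox):
    gene_fc, wt, mut, _ = make_omics_dataset(redox, SyntheticOmicsSpec())
    report = run_fc_protocol(
        redox, wt, mut, ["hydG", "ech"], gene_fc, FCProtocolConfig(loopless=False)
    )
    assert report.n_consistent <= report.n_mapped <= report.n_total
    frame = report.to_frame()
    assert len(frame) == report.n_total
    escher = report.escher_table()
    assert set(escher["reaction_id"]) == report.consistent_set
    assert list(escher.columns) == ["reaction_id", "fc"]
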