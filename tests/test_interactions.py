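import dataclasses

import numpy as np
import pytest

from thermoring.interactions import (GeometricCriteria, InteractionSet,
                                     InteractionType,
                                     assign_energy_equivalents,
                                     detect_interactions, detect_intersubunit)
from thermoring.structure import StructureModel, select_pathway
from thermoring.synthetic import (generate_intersubunit_fixture,
                                  generate_structure_fixture)

ALL_TYPES = [t.value for t in InteractionType]


def _detected(model, start=1, end=200, criteria=None):
    sel = select_pathway(model, "A", start, end)
    return detect_interactions(sel, criteria)


def test_all_posed_interactions_recovered_and_no_decoys(
        geometry_model, geometry_blueprint):
    """Each planted pose fires with its type; decoy pairs stay silent."""
    iset = _detected(geometry_model)
    found = {(ia.pair, ia.itype.value) for ia in iset.interactions}
    expected = set()
    seq = 1
    for pose in geometry_blueprint.poses:
        expected.add(((seq, seq + 1), pose["itype"]))
        seq += 2
    assert found == expected  # exactly the poses, nothing from decoys


def test_detection_is_rigid_motion_invariant(geometry_model):
    """A rotation + translation of all coordinates leaves the set identical."""
    ref = _detected(geometry_model)
    # seeded random rotation matrix via QR
    rng = np.random.default_rng(7)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    shift = np.array([123.4, -56.7, 89.0])
    moved = StructureModel(
        geometry_model.structure_id,
        [dataclasses.replace(
            ch,
            residues=[
                dataclasses.replace(
                    res,
                    atoms=[dataclasses.replace(a, position=q @ a.position
                                               + shift)
                           for a in res.atoms])
                for res in ch.residues
            ])
         for ch in geometry_model.chains],
    )
    new = _detected(moved)
    assert [(ia.pair, ia.itype, round(ia.distance, 6))
            for ia in new.interactions] == \
           [(ia.pair, ia.itype, round(ia.distance, 6))
            for ia in ref.interactions]


def test_enlarging_cutoffs_never_removes_interactions(geometry_model):
    base = _detected(geometry_model)
    wide = GeometricCriteria(
        hbond_max_distance=4.5, salt_bridge_max_distance=5.0,
        pi_pi_max_parallel_distance=6.5, pi_pi_max_tshaped_distance=7.0,
        cation_pi_max_distance=7.0, ch_pi_max_distance=5.5,
        lone_pair_pi_max_distance=5.0, prefilter_distance=10.0)
    wider = _detected(geometry_model, criteria=wide)
    assert {(ia.pair, ia.itype) for ia in base.interactions} <= \
           {(ia.pair, ia.itype) for ia in wider.interactions}


def test_salt_bridge_suppresses_duplicate_hbond(geometry_model):
    """An Arg-Asp pair qualifying as both is recorded once, as salt bridge."""
    iset = _detected(geometry_model)
    arg_asp = [ia for ia in iset.interactions if ia.pair == (3, 4)]
    assert len(arg_asp) == 1
    assert arg_asp[0].itype is InteractionType.salt_bridge


def test_pair_at_nine_angstroms_detects_nothing(geometry_model):
    """Decoy pairs (the second half of the fixture) are all beyond cutoff."""
    iset = _detected(geometry_model, start=13, end=200)
    assert iset.interactions == []


def test_intersubunit_pose_detected_and_labeled():
    model = generate_intersubunit_fixture(separation=4.2)
    iset = detect_intersubunit(model)
    hits = [ia for ia in iset.interactions
            if ia.itype is InteractionType.cation_pi]
    assert len(hits) == 1
    assert hits[0].intersubunit
    assert hits[0].pair == (10, 20)
    # intersubunit records never count toward intra-pathway N
    assert iset.n_interactions == 0


def test_distant_chains_yield_empty_set():
    model = generate_intersubunit_fixture(separation=15.0)
    assert detect_intersubunit(model).interactions == []


def test_single_chain_model_yields_empty_intersubunit(geometry_model):
    assert detect_intersubunit(geometry_model).interactions == []


def test_energy_overrides_win_and_unknown_pairs_raise(geometry_model):
    iset = _detected(geometry_model)
    out = assign_energy_equivalents(iset, pair_overrides={(1, 2): 2.0})
    by_pair = {ia.pair: ia.energy_equiv for ia in out.interactions}
    assert by_pair[(1, 2)] == 2.0
    with pytest.raises(ValueError):
        assign_energy_equivalents(iset, pair_overrides={(999, 1000): 1.0})
    with pytest.raises(ValueError):
        assign_energy_equivalents(iset, grid_overrides={((999, 1000),): 3.0})


def test_grid_override_recorded():
    model = generate_structure_fixture()
    iset = _detected(model)
    out = assign_energy_equivalents(
        iset, grid_overrides={((1, 2), (3, 4)): 3.0})
    assert out.grid_energy_overrides[frozenset({(1, 2), (3, 4)})] == 3.0


def test_tsv_round_trip(tmp_path, geometry_model):
    iset = _detected(geometry_model)
    path = tmp_path / "interactions.tsv"
    iset.to_tsv(path)
    back = InteractionSet.from_tsv(path)
    assert [(ia.pair, ia.itype, ia.energy_equiv)
            for ia in back.interactions] == \
           [(ia.pair, ia.itype, ia.energy_equiv)
            for ia in iset.interactions]


def test_criteria_yaml_round_trip(tmp_path):
    crit = GeometricCriteria(hbond_max_distance=3.2, ch_pi_max_distance=4.0)
    path = tmp_path / "criteria.yaml"
    crit.to_yaml(path)
    assert GeometricCriteria.from_yaml(path) == crit
    path.write_text("no_such_cutoff: 1.0\n")
    with pytest.raises(ValueError):
        GeometricCriteria.from_yaml(path)


def test_detection_deterministic_order(geometry_model):
    a = _detected(geometry_model).interactions
    b = _detected(geometry_model).interactions
    assert a == b
    pairs = [ia.pair for ia in a]
    assert pairs == sorted(pairs)
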