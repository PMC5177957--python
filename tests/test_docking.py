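"""Monte-Carlo docking, SA refinement, ranking, and interaction energies."""

from types import SimpleNamespace

import numpy as np
import pytest

from curcumetry import (
    DockingConfig, DockingEngine, PeptideField, SARefineConfig,
    heptad_scan, mc_generate, rank_complexes, sa_refine,
    superimpose_ligand, interaction_energy,
)
from curcumetry.docking import DockedComplex, _COULOMB, _pair_energy

_FAST_CFG = dict(max_complexes=4, attempts_per_complex=6, seed=3)


@pytest.fixture(scope="module")
def engine(cyc_top, cyc_mini_ensemble, abeta_helix):
    match = heptad_scan(abeta_helix)[0]
    posed, _rmsd = superimpose_ligand(cyc_mini_ensemble.global_minimum,
                                      cyc_top, match)
    return DockingEngine(cyc_top, PeptideField(abeta_helix), posed,
                         DockingConfig(**_FAST_CFG))


@pytest.fixture(scope="module")
def complexes(engine):
    return mc_generate(engine)


def test_mc_generate_respects_all_acceptance_rules(engine, complexes):
    cfg = engine.cfg
    assert 1 <= len(complexes) <= cfg.max_complexes
    energies = [c.conformational_energy for c in complexes]
    best = min(energies)
    assert all(e <= best + cfg.energy_window for e in energies)
    for i, a in enumerate(complexes):
        for b in complexes[i + 1:]:
            diff = a.ligand_coordinates[engine.lig_heavy] \
                - b.ligand_coordinates[engine.lig_heavy]
            rms = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
            assert rms >= cfg.similarity_rms


def test_mc_generate_is_seed_deterministic(cyc_top, cyc_mini_ensemble,
                                           abeta_helix):
    match = heptad_scan(abeta_helix)[0]
    posed, _ = superimpose_ligand(cyc_mini_ensemble.global_minimum,
                                  cyc_top, match)
    cfg = DockingConfig(max_complexes=2, attempts_per_complex=4, seed=17)
    runs = []
    for _ in range(2):
        eng = DockingEngine(cyc_top, PeptideField(abeta_helix), posed, cfg)
        runs.append(mc_generate(eng, cfg))
    e1 = [c.conformational_energy for c in runs[0]]
    e2 = [c.conformational_energy for c in runs[1]]
    assert e1 == pytest.approx(e2, abs=1e-9)
    np.testing.assert_allclose(runs[0][-1].ligand_coordinates,
                               runs[1][-1].ligand_coordinates, atol=1e-9)


def test_interaction_energy_vanishes_at_separation(engine, complexes):
    engine.set_coords(complexes[0].ligand_coordinates + 200.0)
    assert interaction_energy(engine) == pytest.approx(0.0, abs=1e-6)
    engine.set_coords(complexes[0].ligand_coordinates)
    assert interaction_energy(engine) < 0.0  # bound pose is attractive


def test_coulomb_closed_form_distance_dependent_dielectric():
    """Two opposite unit charges at 3.33 A with eps = 2*r give
    -332.0637 / (2 * 3.33^2) kcal/mol; doubling charges quadruples it."""
    field = SimpleNamespace(
        coords=np.array([[3.33, 0.0, 0.0]]),
        charges=np.array([-1.0]),
        x_ii=np.array([1.0]), d_ii=np.array([0.0]),
        res_index=np.array([0]),
        res_centers=np.array([[3.33, 0.0, 0.0]]),
        heavy_mask=np.array([True]))
    lig = np.array([[0.0, 0.0, 0.0]])
    e1 = _pair_energy(lig, np.array([1.0]), np.array([1.0]),
                      np.array([0.0]), field, eps_scale=2.0)
    assert e1 == pytest.approx(-_COULOMB / (2.0 * 3.33 ** 2), rel=1e-9)
    e2 = _pair_energy(lig, np.array([2.0]), np.array([1.0]),
                      np.array([0.0]),
                      SimpleNamespace(**{**field.__dict__,
                                         "charges": np.array([-2.0])}),
                      eps_scale=2.0)
    assert e2 == pytest.approx(4.0 * e1, rel=1e-9)


def test_sa_stage_schedule():
    cfg = SARefineConfig()
    temps = cfg.stage_temperatures()
    assert temps[0] == 500.0 and temps[-1] == 300.0
    assert np.all(np.diff(temps) < 0)
    scales = cfg.stage_nb_scales()
    assert scales[0] == 0.1 and scales[-1] == 1.0
    assert cfg.total_ps == pytest.approx(5.0)
    assert cfg.steps_per_stage == 100
    with pytest.raises(ValueError):
        SARefineConfig(t_start=300.0, t_end=500.0)


def test_sa_refine_flags_and_restraints(engine, complexes):
    fast = SARefineConfig(n_stages=5, stage_fs=20.0)
    refined = sa_refine(engine, complexes[0], fast, seed=5)
    assert np.isfinite(refined.conformational_energy)
    assert refined.bound or not refined.stable     # stable => bound
    # rigid-helix backbone H-bond donors stay within 2.5 A + tolerance
    for dist in refined.restraint_distances.values():
        assert dist <= 2.5 + 0.2


def test_far_ligand_is_unbound_after_refinement(engine, complexes):
    engine.set_coords(complexes[0].ligand_coordinates + 200.0)
    far = engine.snapshot()
    assert not far.bound
    fast = SARefineConfig(n_stages=3, stage_fs=10.0)
    refined = sa_refine(engine, far, fast, seed=2)
    assert not refined.bound
    assert not refined.stable
    # beyond the group-based cutoff the interaction vanishes identically
    assert refined.interaction_energy == pytest.approx(0.0, abs=1e-6)


def _dummy(conf_e, inter_e):
    return DockedComplex(ligand_coordinates=np.zeros((1, 3)), torsions={},
                         conformational_energy=conf_e,
                         interaction_energy=inter_e)


def test_rank_complexes_ordering_and_representative():
    cx = [_dummy(3.0, -1.0), _dummy(1.0, -5.0), _dummy(2.0, -2.0)]
    ordered, rep = rank_complexes(cx)
    assert [c.conformational_energy for c in ordered] == [1.0, 2.0, 3.0]
    assert rep.conformational_energy == 1.0      # lowest on both records
    # tie on conformational energy: lower interaction energy wins
    cx = [_dummy(1.0, -1.0), _dummy(1.0, -4.0)]
    _ordered, rep = rank_complexes(cx)
    assert rep.interaction_energy == -4.0
    single = [_dummy(2.0, -2.0)]
    _o, rep = rank_complexes(single)
    assert rep is single[0]
    with pytest.raises(ValueError):
        rank_complexes([])


def test_stable_implies_bound_invariant():
    with pytest.raises(ValueError):
        DockedComplex(ligand_coordinates=np.zeros((1, 3)), torsions={},
                      conformational_energy=0.0, interaction_energy=0.0,
                      stable=True, bound=False)
    with pytest.raises(ValueError):
        DockedComplex(ligand_coordinates=np.zeros((1, 3)), torsions={},
                      conformational_energy=float("nan"),
                      interaction_energy=0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        DockingConfig(initial_nb_scale=0.0)
    with pytest.raises(ValueError):
        DockingConfig(max_complexes=0)
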