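"""Ideal helix construction, heptad scanning, and rigid superimposition."""

import numpy as np
import pytest

from curcumetry import (
    HeptadMatch, build_ideal_helix, heptad_scan, read_pdb,
    sidechain_centroid, superimpose_ligand, write_pdb,
)
from curcumetry.helix import HYDROPHOBIC, kabsch

# DERIVED oracle constants, frozen from the ideal-helix construction
# (phi = -57, psi = -47, CCD default rotamers)
POLY_LEU_I_I7_CENTROID = 11.05   # A
IDEAL_I_I4_CA = 6.40             # A


def test_abeta_helix_geometry(abeta_helix):
    assert abeta_helix.sequence == "GSNKGAIIGLM"
    assert len(abeta_helix) == 11
    assert abeta_helix.backbone_complete()
    assert [r.number for r in abeta_helix.residues] == list(range(25, 36))
    ca = [r.atoms["CA"] for r in abeta_helix.residues]
    assert np.linalg.norm(ca[0] - ca[4]) == pytest.approx(IDEAL_I_I4_CA,
                                                          abs=0.05)


def test_helical_backbone_hbonds(abeta_helix):
    """Interior O(i)...N(i+4) below 3.5 A — the alpha-helical H-bond."""
    res = abeta_helix.residues
    for i in range(len(res) - 4):
        d = np.linalg.norm(res[i].atoms["O"] - res[i + 4].atoms["N"])
        assert d < 3.5, (i, d)


def test_single_residue_helix():
    pep = build_ideal_helix("A")
    assert len(pep) == 1
    assert {"N", "CA", "C", "O", "CB"} <= set(pep.residues[0].atoms)


def test_unknown_residue_letter():
    with pytest.raises(ValueError, match="unknown residue"):
        build_ideal_helix("AXA")


def test_sidechain_centroids():
    pep = build_ideal_helix("GAL")
    gly, ala, leu = pep.residues
    with pytest.raises(ValueError):
        sidechain_centroid(gly)
    np.testing.assert_allclose(sidechain_centroid(ala), ala.atoms["CB"])
    expect = np.mean([leu.atoms[n] for n in ("CB", "CG", "CD1", "CD2")],
                     axis=0)
    np.testing.assert_allclose(sidechain_centroid(leu), expect)


def _brute_force_triples(seq: str):
    out = []
    for i in range(len(seq) - 7):
        letters = (seq[i], seq[i + 4], seq[i + 7])
        if sum(1 for x in letters if x == "N") > 1:
            continue
        if any(x not in HYDROPHOBIC and x != "N" for x in letters):
            continue
        if "G" in letters:   # Gly has no side-chain centroid
            continue
        out.append(i)
    return out


@pytest.mark.parametrize("seq", [
    "GSNKGAIIGLM", "LLLLLLLLLL", "AVNAVLAIVL", "GGGGGGGGGG", "KRDEKRDEKR",
])
def test_heptad_scan_matches_brute_force(seq):
    pep = build_ideal_helix(seq)
    matches = heptad_scan(pep)
    assert [m.residue_numbers[0] - 1 for m in matches] \
        == _brute_force_triples(seq)
    for m in matches:
        i, j, k = m.residue_numbers
        assert (j - i, k - i) == (4, 7)


def test_abeta_heptad_is_N27_I31_L34(abeta_helix):
    matches = heptad_scan(abeta_helix)
    assert any(m.residue_numbers == (27, 31, 34)
               and m.residue_names == ("ASN", "ILE", "LEU")
               for m in matches)


def test_polyleucine_i_i7_centroid_distance():
    pep = build_ideal_helix("LLLLLLLLLL")
    m = heptad_scan(pep)[0]
    assert m.distances["i_i7"] == pytest.approx(POLY_LEU_I_I7_CENTROID,
                                                abs=0.05)


def test_heptad_spacing_validation():
    with pytest.raises(ValueError):
        HeptadMatch(residue_numbers=(1, 4, 8), residue_names=("L", "L", "L"),
                    centroids=np.zeros((3, 3)), distances={})


def test_superimpose_identity_and_rigidity(cyc_top, cyc_mini_ensemble):
    from curcumetry.helix import _ligand_pharmacophore_points
    gm = cyc_mini_ensemble.global_minimum
    pts = _ligand_pharmacophore_points(gm, cyc_top)
    match = HeptadMatch(residue_numbers=(1, 5, 8),
                        residue_names=("X", "Y", "Z"),
                        centroids=pts.copy(), distances={})
    posed, rmsd = superimpose_ligand(gm, cyc_top, match)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(posed.coordinates, gm.coordinates,
                               atol=1e-9)


def test_superimpose_preserves_internal_distances(cyc_top,
                                                  cyc_mini_ensemble,
                                                  abeta_helix):
    from curcumetry import compute_d1
    gm = cyc_mini_ensemble.global_minimum
    match = heptad_scan(abeta_helix)[0]
    posed, rmsd = superimpose_ligand(gm, cyc_top, match)
    assert rmsd >= 0.0 and np.isfinite(rmsd)
    d_before = np.linalg.norm(
        gm.coordinates[:, None] - gm.coordinates[None, :], axis=-1)
    d_after = np.linalg.norm(
        posed.coordinates[:, None] - posed.coordinates[None, :], axis=-1)
    assert np.max(np.abs(d_before - d_after)) < 1e-9
    assert compute_d1(posed, cyc_top) \
        == pytest.approx(compute_d1(gm, cyc_top), abs=1e-9)


def test_superimpose_uses_proper_rotations_only(cyc_top,
                                                cyc_mini_ensemble):
    """A mirror-image target cannot be matched by reflection: the fit RMSD
    stays strictly positive."""
    from curcumetry.helix import _ligand_pharmacophore_points
    gm = cyc_mini_ensemble.global_minimum
    pts = _ligand_pharmacophore_points(gm, cyc_top)
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    # make sure the mirrored triple is not trivially superposable
    match = HeptadMatch(residue_numbers=(1, 5, 8),
                        residue_names=("X", "Y", "Z"),
                        centroids=mirrored, distances={})
    rot, _t = kabsch(pts, mirrored)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


def test_superimpose_rejects_collinear_targets(cyc_top,
                                               cyc_mini_ensemble):
    gm = cyc_mini_ensemble.global_minimum
    match = HeptadMatch(residue_numbers=(1, 5, 8),
                        residue_names=("X", "Y", "Z"),
                        centroids=np.array([[0.0, 0, 0], [1.0, 0, 0],
                                            [2.0, 0, 0]]),
                        distances={})
    with pytest.raises(ValueError, match="collinear"):
        superimpose_ligand(gm, cyc_top, match)


def test_pdb_round_trip(abeta_helix, tmp_path):
    path = tmp_path / "abeta.pdb"
    write_pdb(abeta_helix, str(path))
    back = read_pdb(str(path))
    assert back.sequence == abeta_helix.sequence
    assert len(back) == 11
    assert back.residues[0].number == 25
    with pytest.raises(ValueError, match="chain"):
        read_pdb(str(path), chain="Z")
    with pytest.raises(ValueError):
        read_pdb(str(path), res_range=(90, 99))
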