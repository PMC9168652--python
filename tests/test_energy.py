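import numpy as np
import pytest

from butterflymd.datasets import load_residue_energy_benchmark
from butterflymd.energy import (
    Atom,
    GBSettings,
    OBC_I,
    OBC_II,
    ParameterizedStructure,
    ResidueEnergyRow,
    effective_born_radii,
    gb_cross_energy,
    pairwise_nonbonded_energy,
    per_residue_decomposition,
    rank_alanine_candidates,
)
from butterflymd.sasa import shrake_rupley, sphere_points
from conftest import make_toy_structure
from oracles import hct_integral_mc, two_sphere_sasa

SETTINGS = GBSettings()


# ---------------------------------------------------------------------------
# pairwise terms

def test_coulomb_with_interior_dielectric():
    a1 = Atom((0, 0, 0), 1.0, 1.5, 0.1)
    a2 = Atom((3, 0, 0), -1.0, 1.5, 0.1)
    e = pairwise_nonbonded_energy(a1, a2, SETTINGS)
    assert e.ele == pytest.approx(332.0637 * -1.0 / (3.0 * 3.0), abs=1e-4)
    assert e.ele == pytest.approx(-36.896, abs=1e-3)


def test_neutral_pair_has_zero_electrostatics():
    a1 = Atom((0, 0, 0), 0.0, 1.5, 0.1)
    a2 = Atom((3, 0, 0), 0.0, 1.5, 0.1)
    assert pairwise_nonbonded_energy(a1, a2, SETTINGS).ele == 0.0


def test_lj_minimum_depth_is_combined_epsilon():
    """At r = rmin the LJ term equals -sqrt(eps1 eps2) (Lorentz–Berthelot)."""
    a1 = Atom((0, 0, 0), 0.0, 1.6, 0.09)
    a2 = Atom((1.6 + 1.8, 0, 0), 0.0, 1.8, 0.16)
    assert pairwise_nonbonded_energy(a1, a2, SETTINGS).vdw == pytest.approx(-np.sqrt(0.09 * 0.16))


def test_coincident_atoms_rejected():
    a = Atom((0, 0, 0), 0.1, 1.5, 0.1)
    with pytest.raises(ValueError):
        pairwise_nonbonded_energy(a, a, SETTINGS)


# ---------------------------------------------------------------------------
# Born radii

def _single_atom(radius=1.5):
    return ParameterizedStructure(
        np.zeros((1, 3)), [0.0], [1.9], [0.1], [radius], [1], ["LIG"], [True]
    )


def test_isolated_atom_effective_radius_is_reduced_radius():
    r = effective_born_radii(_single_atom(1.5), SETTINGS)
    assert r[0] == pytest.approx(1.5 - SETTINGS.gb_offset)


def test_homonuclear_dimer_symmetric_radii():
    st = ParameterizedStructure(
        np.array([[0.0, 0, 0], [3.2, 0, 0]]), [0.0, 0.0], [1.9, 1.9], [0.1, 0.1],
        [1.5, 1.5], [1, 1], ["LIG", "LIG"], [True, True],
    )
    r = effective_born_radii(st, SETTINGS)
    assert r[0] == pytest.approx(r[1], rel=1e-12)
    assert r[0] > 1.5 - SETTINGS.gb_offset  # descreening enlarges the effective radius


def test_obc_radii_match_quadrature_oracle():
    """Effective radii from the analytic descreening agree with a numeric
    integration of the r^-4 shell integral on a 3-atom toy."""
    coords = np.array([[0.0, 0, 0], [3.1, 0, 0], [1.4, 2.8, 0]])
    radii = np.array([1.5, 1.7, 1.4])
    screen = np.full(3, 0.8)
    st = ParameterizedStructure(coords, [0] * 3, [1.9] * 3, [0.1] * 3, radii,
                                [1] * 3, ["LIG"] * 3, [True] * 3, screen=screen)
    analytic = effective_born_radii(st, SETTINGS)
    rho = radii - SETTINGS.gb_offset
    a, b, g = SETTINGS.obc_parameters
    for i in range(3):
        I = sum(
            hct_integral_mc(coords[i], rho[i], coords[j], screen[j] * rho[j], seed=13 + j)
            for j in range(3) if j != i
        )
        psi = rho[i] * I
        inv = 1.0 / rho[i] - np.tanh(a * psi - b * psi**2 + g * psi**3) / radii[i]
        assert analytic[i] == pytest.approx(1.0 / inv, rel=0.05)


def test_obc_parameter_sets():
    assert GBSettings.obc1().obc_parameters == OBC_I
    assert GBSettings.obc2().obc_parameters == OBC_II
    assert SETTINGS.obc_parameters == OBC_I  # analysis default


def test_gb_pair_approaches_coulomb_screening_limit():
    """As ionic strength -> 0 and r -> infinity the GB cross term tends to
    -(1/eps_in - 1/eps_solv) k q1 q2 / r."""
    s = GBSettings(ionic_strength=0.0)
    got = float(gb_cross_energy(0.5, -0.4, 50.0, 1.6, 1.4, s))
    want = -(1 / s.interior_dielectric - 1 / s.solvent_dielectric) * 332.0637 * 0.5 * -0.4 / 50.0
    assert got == pytest.approx(want, rel=0.01)


def test_salt_strengthens_reaction_field_term():
    """Mobile ions damp the solvent term exp(-kappa f)/eps_solv, pushing the GB
    prefactor toward 1/eps_in, so the cross term grows in magnitude with ionic
    strength (Debye–Hückel screened GB)."""
    salty = float(gb_cross_energy(0.5, -0.4, 10.0, 1.6, 1.4, GBSettings(ionic_strength=0.1)))
    fresh = float(gb_cross_energy(0.5, -0.4, 10.0, 1.6, 1.4, GBSettings(ionic_strength=0.0)))
    assert abs(salty) > abs(fresh)
    assert np.sign(salty) == np.sign(fresh)


# ---------------------------------------------------------------------------
# SASA

def test_isolated_sphere_sasa_closed_form():
    sasa = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), probe_radius=1.4, n_points=500)
    assert sasa[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2)


@pytest.mark.parametrize("d", [2.0, 2.8, 3.6, 5.0])
def test_two_sphere_sasa_matches_cap_formula(d):
    R1, R2, probe = 1.7, 1.5, 1.4
    sasa = shrake_rupley(np.array([[0, 0, 0], [d, 0, 0.0]]), np.array([R1, R2]), probe, 4000)
    assert sasa[0] == pytest.approx(two_sphere_sasa(R1, R2, d, probe), rel=0.02)


def test_sphere_points_on_unit_sphere():
    pts = sphere_points(128)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.linalg.norm(pts.mean(axis=0)) < 0.02  # near-uniform coverage


# ---------------------------------------------------------------------------
# per-residue decomposition

def test_conservation_against_direct_double_loop(rng):
    """Per-residue vdw/ele/gb sums equal a naive ligand x receptor double loop."""
    st = make_toy_structure(rng)
    res = per_residue_decomposition([st], SETTINGS)
    born = effective_born_radii(st, SETTINGS)
    lig = np.flatnonzero(st.is_ligand)
    rec = np.flatnonzero(~st.is_ligand)
    direct_vdw = direct_ele = direct_gb = 0.0
    for i in lig:
        for j in rec:
            pe = pairwise_nonbonded_energy(
                Atom(tuple(st.coords[i]), st.charges[i], st.rmin_half[i], st.epsilon[i]),
                Atom(tuple(st.coords[j]), st.charges[j], st.rmin_half[j], st.epsilon[j]),
                SETTINGS,
            )
            direct_vdw += pe.vdw
            direct_ele += pe.ele
            r = np.linalg.norm(st.coords[i] - st.coords[j])
            direct_gb += float(gb_cross_energy(st.charges[i], st.charges[j], r, born[i], born[j], SETTINGS))
    assert sum(r.vdw for r in res.rows) == pytest.approx(direct_vdw, abs=1e-6)
    assert sum(r.ele for r in res.rows) == pytest.approx(direct_ele, abs=1e-6)
    assert sum(r.gb for r in res.rows) == pytest.approx(direct_gb, abs=1e-6)
    assert res.all_row.tot == pytest.approx(sum(r.tot for r in res.rows), abs=1e-9)


def test_row_total_is_component_sum(rng):
    res = per_residue_decomposition([make_toy_structure(rng)], SETTINGS)
    for row in res.rows + [res.all_row]:
        assert row.tot == pytest.approx(row.vdw + row.ele + row.gb + row.np_, abs=1e-9)


def test_symmetric_residues_get_identical_rows():
    """Ligand flanked by two identical single-atom residues: identical rows,
    All row equals twice either row."""
    st = ParameterizedStructure(
        np.array([[0.0, 0, 0], [4.0, 0, 0], [-4.0, 0, 0]]),
        [0.3, -0.2, -0.2], [1.8, 1.7, 1.7], [0.12, 0.1, 0.1], [1.5, 1.5, 1.5],
        [9, 1, 2], ["STY", "Leu", "Leu"], [True, False, False],
    )
    res = per_residue_decomposition([st], SETTINGS)
    r1, r2 = res.rows
    for attr in ("vdw", "ele", "gb", "np_", "tot"):
        assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-9)
        assert getattr(res.all_row, attr) == pytest.approx(2 * getattr(r1, attr), abs=1e-9)


def test_distant_residue_contributes_nothing(rng):
    st = make_toy_structure(rng)
    far = st.coords.copy()
    moved_res = st.resid[~st.is_ligand][0]
    far[(st.resid == moved_res) & ~st.is_ligand] += 50.0
    res = per_residue_decomposition([st.with_coords(far)], SETTINGS)
    (row,) = [r for r in res.rows if r.residue.startswith(str(moved_res))]
    assert abs(row.tot) < 0.01


def test_decomposition_invariant_under_rigid_transform(rng):
    st = make_toy_structure(rng)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = st.with_coords(st.coords @ q.T + rng.normal(0, 20, 3))
    res0 = per_residue_decomposition([st], SETTINGS)
    res1 = per_residue_decomposition([moved], SETTINGS)
    for a, b in zip(res0.rows, res1.rows):
        assert a.residue == b.residue
        # SASA quadrature is orientation-dependent at finite point count,
        # so the NP term (and hence tot) matches only to quadrature noise.
        assert a.vdw == pytest.approx(b.vdw, abs=1e-9)
        assert a.ele == pytest.approx(b.ele, abs=1e-9)
        assert a.gb == pytest.approx(b.gb, abs=1e-9)
        assert a.tot == pytest.approx(b.tot, abs=1e-3)


def test_frame_averages_match_naive_recomputation(rng):
    """Means and sds over frames equal per-frame single-frame decompositions."""
    st = make_toy_structure(rng)
    frames = [st.with_coords(st.coords + rng.normal(0, 0.05, st.coords.shape)) for _ in range(4)]
    res = per_residue_decomposition(frames, SETTINGS)
    singles = [per_residue_decomposition([f], SETTINGS) for f in frames]
    for row in res.rows:
        per_frame = [next(r for r in s.rows if r.residue == row.residue) for s in singles]
        tots = np.array([r.tot for r in per_frame])
        assert row.tot == pytest.approx(tots.mean(), abs=1e-9)
        assert row.tot_sd == pytest.approx(tots.std(ddof=1), abs=1e-9)


def test_frame_window_selects_tail(rng):
    st = make_toy_structure(rng)
    frames = [st.with_coords(st.coords + 0.02 * k) for k in range(5)]
    tail = per_residue_decomposition(frames, SETTINGS, frame_window=slice(-2, None))
    direct = per_residue_decomposition(frames[-2:], SETTINGS)
    for a, b in zip(tail.rows, direct.rows):
        assert a.tot == pytest.approx(b.tot, abs=1e-12)


def test_errors_no_ligand_and_topology_mismatch(rng):
    st = make_toy_structure(rng)
    no_lig = ParameterizedStructure(
        st.coords, st.charges, st.rmin_half, st.epsilon, st.gb_radius,
        st.resid, st.resname, np.zeros(st.n_atoms, bool), st.screen,
    )
    with pytest.raises(ValueError, match="ligand"):
        per_residue_decomposition([no_lig], SETTINGS)
    smaller = make_toy_structure(np.random.default_rng(1), n_receptor_residues=3)
    with pytest.raises(ValueError, match="atom-count"):
        per_residue_decomposition([st, smaller], SETTINGS)


def test_structure_table_roundtrip(tmp_path, rng):
    st = make_toy_structure(rng)
    p = tmp_path / "struct.tsv"
    st.to_table(p)
    back = ParameterizedStructure.from_table(p)
    np.testing.assert_allclose(back.coords, st.coords)
    np.testing.assert_array_equal(back.is_ligand, st.is_ligand)
    np.testing.assert_allclose(back.screen, st.screen)


# ---------------------------------------------------------------------------
# mutation-candidate ranking

def test_ranking_reproduces_published_order():
    rows = load_residue_energy_benchmark()
    cands = rank_alanine_candidates(rows, 10)
    assert [c.residue for c in cands] == [
        "279Ala", "123Ile", "329Trp", "97Leu", "278Val",
        "275Ala", "429Phe", "211Trp", "276Ile", "283Thr",
    ]
    assert cands[0].substitution == "A→G"  # alanines go to glycine
    assert cands[1].substitution == "Ile→A"


def _row(label, tot):
    return ResidueEnergyRow(label, tot, 0, 0, 0, tot)


def test_tie_broken_by_residue_number():
    cands = rank_alanine_candidates([_row("300Leu", -0.5), _row("42Phe", -0.5)], 2)
    assert [c.residue for c in cands] == ["42Phe", "300Leu"]


def test_glycines_excluded_with_warning():
    with pytest.warns(UserWarning, match="glycine"):
        cands = rank_alanine_candidates([_row("10Gly", -2.0), _row("11Leu", -0.1)], 5)
    assert [c.residue for c in cands] == ["11Leu"]
    with pytest.warns(UserWarning):
        assert rank_alanine_candidates([_row("10Gly", -2.0)], 3) == []


def test_ranking_rejects_bad_top_n():
    with pytest.raises(ValueError):
        rank_alanine_candidates([_row("11Leu", -0.1)], 0)
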