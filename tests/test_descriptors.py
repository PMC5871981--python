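"""Descriptor schemes against brute-force oracles and invariance properties."""

import io
import math

import numpy as np
import pytest

from sfbench.descriptors import (
    DEFAULT_RADIUS,
    LIGAND_ELEMENTS,
    PROTEIN_ELEMENTS,
    VDW_RADII,
    load_descriptor_table,
    rf_v1_counts,
    rf_v3_descriptors,
    vina_terms,
    write_descriptor_table,
    xscore_like_terms,
)
from sfbench.structio import AtomRecord, MolecularStructure


def make_mol(elements, coords, role="protein", bonds=None):
    atoms = [AtomRecord(el, tuple(float(v) for v in xyz), k)
             for k, (el, xyz) in enumerate(zip(elements, coords))]
    return MolecularStructure(atoms=atoms, role=role,
                              bonds=[] if bonds is None else bonds)


def random_complex(rng, n_protein=50, n_ligand=12, spread=8.0):
    pel = rng.choice(PROTEIN_ELEMENTS + ("ZN",), size=n_protein,
                     p=[0.5, 0.2, 0.2, 0.08, 0.02])
    lel = rng.choice(LIGAND_ELEMENTS + ("B",), size=n_ligand)
    pco = rng.normal(scale=spread, size=(n_protein, 3))
    lco = rng.normal(scale=3.0, size=(n_ligand, 3))
    protein = make_mol(pel, pco)
    ligand = make_mol(lel, lco, role="ligand",
                      bonds=[(k, k + 1, 1) for k in range(n_ligand - 1)])
    return protein, ligand


def radius(el):
    return VDW_RADII.get(el, DEFAULT_RADIUS)


# --- brute-force oracles: explicit python double loops -------------------

def brute_rf_v1(protein, ligand, cutoff):
    counts = {(le, pe): 0 for le in LIGAND_ELEMENTS for pe in PROTEIN_ELEMENTS}
    for pa in protein.atoms:
        for la in ligand.atoms:
            if (la.element, pa.element) not in counts:
                continue
            d2 = sum((a - b) ** 2 for a, b in zip(pa.coords, la.coords))
            if d2 <= cutoff * cutoff:
                counts[(la.element, pa.element)] += 1
    return np.array([counts[(le, pe)] for le in LIGAND_ELEMENTS for pe in PROTEIN_ELEMENTS],
                    dtype=float)


def brute_vina(protein, ligand, nrot):
    g1 = g2 = rep = hyd = hb = 0.0
    for pa in protein.atoms:
        for la in ligand.atoms:
            r = math.dist(pa.coords, la.coords)
            if r > 8.0:
                continue
            d = r - radius(pa.element) - radius(la.element)
            g1 += math.exp(-((d / 0.5) ** 2))
            g2 += math.exp(-(((d - 3.0) / 2.0) ** 2))
            if d < 0:
                rep += d * d
            if pa.element == "C" and la.element == "C":
                hyd += min(1.0, max(0.0, (1.5 - d) / 1.0))
            if pa.element in ("N", "O") and la.element in ("N", "O"):
                hb += min(1.0, max(0.0, -d / 0.7))
    return np.array([g1, g2, rep, hyd, hb, float(nrot)])


def brute_xscore(protein, ligand, nrot):
    vdw = hb = hyd = 0.0
    for pa in protein.atoms:
        for la in ligand.atoms:
            r = math.dist(pa.coords, la.coords)
            if r <= 8.0:
                d0 = radius(pa.element) + radius(la.element)
                ratio4 = (d0 / r) ** 4 if r > 0 else math.inf
                vdw += min(10.0, max(-1.0, ratio4 * ratio4 - 2 * ratio4))
            if pa.element in ("N", "O") and la.element in ("N", "O") and r <= 3.5:
                hb += 1
            if pa.element == "C" and la.element == "C" and r <= 4.5:
                hyd += 1
    return np.array([vdw, hb, hyd, float(nrot)])


class TestRfV1Counts:
    def test_no_eligible_elements_gives_zero_vector(self):
        protein = make_mol(["C"], [(0, 0, 0)])
        ligand = make_mol(["B"], [(1, 0, 0)], role="ligand")
        assert rf_v1_counts(protein, ligand).values.sum() == 0

    def test_single_cc_pair(self):
        protein = make_mol(["C"], [(5, 0, 0)])
        ligand = make_mol(["C"], [(0, 0, 0)], role="ligand")
        vec = rf_v1_counts(protein, ligand, cutoff=12)
        assert vec.as_series()["C_C"] == 1
        assert vec.values.sum() == 1

    def test_nonpositive_cutoff_rejected(self):
        protein = make_mol(["C"], [(0, 0, 0)])
        ligand = make_mol(["C"], [(1, 0, 0)], role="ligand")
        with pytest.raises(ValueError):
            rf_v1_counts(protein, ligand, cutoff=0)

    def test_equals_bruteforce_on_random_complexes(self, rng):
        for _ in range(15):
            protein, ligand = random_complex(rng)
            got = rf_v1_counts(protein, ligand, 12.0).values
            np.testing.assert_array_equal(got, brute_rf_v1(protein, ligand, 12.0))

    def test_cutoff_monotonicity(self, rng):
        protein, ligand = random_complex(rng)
        prev = rf_v1_counts(protein, ligand, 4.0).values
        for cutoff in (6.0, 8.0, 12.0, 20.0):
            cur = rf_v1_counts(protein, ligand, cutoff).values
            assert (cur >= prev).all()
            prev = cur

    def test_boundary_is_closed(self):
        protein = make_mol(["C"], [(12.0, 0, 0)])
        ligand = make_mol(["C"], [(0, 0, 0)], role="ligand")
        assert rf_v1_counts(protein, ligand, cutoff=12.0).values.sum() == 1


class TestVinaTerms:
    def test_surface_contact_gauss1_is_one(self):
        # centre distance exactly R(C)+R(C): surface distance d=0
        protein = make_mol(["C"], [(3.8, 0, 0)])
        ligand = make_mol(["C"], [(0, 0, 0)], role="ligand")
        vec = vina_terms(protein, ligand).as_series()
        assert vec["gauss1"] == pytest.approx(1.0)
        assert vec["repulsion"] == 0.0

    def test_gauss2_peak_at_three_angstrom_surface_distance(self):
        protein = make_mol(["C"], [(6.8, 0, 0)])  # d = 6.8 - 3.8 = 3.0
        ligand = make_mol(["C"], [(0, 0, 0)], role="ligand")
        assert vina_terms(protein, ligand).as_series()["gauss2"] == pytest.approx(1.0)

    def test_equals_bruteforce_on_random_complexes(self, rng):
        from sfbench.structio import count_rotatable_bonds

        for _ in range(15):
            protein, ligand = random_complex(rng)
            got = vina_terms(protein, ligand).values
            want = brute_vina(protein, ligand, count_rotatable_bonds(ligand))
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)


class TestXScoreTerms:
    def test_empty_contact_shell(self):
        protein = make_mol(["C"], [(50, 0, 0)])
        ligand = make_mol(["C", "C", "C"], [(0, 0, 0), (1.5, 0, 0), (3.0, 0, 0)],
                          role="ligand", bonds=[(0, 1, 1), (1, 2, 1)])
        np.testing.assert_array_equal(xscore_like_terms(protein, ligand).values,
                                      [0.0, 0.0, 0.0, 0.0])

    def test_vdw_minimum_at_equilibrium_distance(self):
        protein = make_mol(["C"], [(3.8, 0, 0)])  # r = d0 exactly
        ligand = make_mol(["C"], [(0, 0, 0)], role="ligand")
        vec = xscore_like_terms(protein, ligand).as_series()
        assert vec["vdw"] == pytest.approx(-1.0)

    def test_equals_bruteforce_on_random_complexes(self, rng):
        from sfbench.structio import count_rotatable_bonds

        for _ in range(15):
            protein, ligand = random_complex(rng)
            got = xscore_like_terms(protein, ligand).values
            want = brute_xscore(protein, ligand, count_rotatable_bonds(ligand))
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)


class TestRfV3:
    def test_concatenation_contract(self, rng):
        protein, ligand = random_complex(rng)
        v3 = rf_v3_descriptors(protein, ligand)
        assert len(v3.values) == 42
        np.testing.assert_array_equal(v3.values[:36], rf_v1_counts(protein, ligand).values)
        np.testing.assert_array_equal(v3.values[36:], vina_terms(protein, ligand).values)


def rigid_transform(mol, R, t):
    coords = mol.coords_array() @ R.T + t
    atoms = [AtomRecord(a.element, tuple(c), a.source_index)
             for a, c in zip(mol.atoms, coords)]
    return MolecularStructure(atoms=atoms, role=mol.role, bonds=list(mol.bonds))


def permute(mol, perm):
    atoms = [mol.atoms[p] for p in perm]
    inv = {p: k for k, p in enumerate(perm)}
    bonds = [(inv[a], inv[b], o) for a, b, o in mol.bonds]
    return MolecularStructure(atoms=atoms, role=mol.role, bonds=bonds)


class TestInvariances:
    def test_rigid_motion_leaves_all_schemes_unchanged(self, rng):
        from scipy.stats import special_ortho_group

        protein, ligand = random_complex(rng)
        R = special_ortho_group.rvs(3, random_state=12345)
        t = np.array([3.0, -7.0, 11.0])
        pro2, lig2 = rigid_transform(protein, R, t), rigid_transform(ligand, R, t)
        np.testing.assert_array_equal(
            rf_v1_counts(protein, ligand).values, rf_v1_counts(pro2, lig2).values)
        np.testing.assert_allclose(
            vina_terms(protein, ligand).values, vina_terms(pro2, lig2).values, atol=1e-9)
        np.testing.assert_allclose(
            xscore_like_terms(protein, ligand).values,
            xscore_like_terms(pro2, lig2).values, atol=1e-9)

    def test_atom_permutation_leaves_all_schemes_unchanged(self, rng):
        protein, ligand = random_complex(rng)
        pro2 = permute(protein, list(rng.permutation(len(protein))))
        lig2 = permute(ligand, list(rng.permutation(len(ligand))))
        np.testing.assert_array_equal(
            rf_v1_counts(protein, ligand).values, rf_v1_counts(pro2, lig2).values)
        np.testing.assert_allclose(
            vina_terms(protein, ligand).values, vina_terms(pro2, lig2).values, atol=1e-12)
        np.testing.assert_allclose(
            xscore_like_terms(protein, ligand).values,
            xscore_like_terms(pro2, lig2).values, atol=1e-12)

    def test_count_conservation(self, rng):
        """Sum of the 36 counts = number of eligible cross pairs in range."""
        protein, ligand = random_complex(rng)
        total = rf_v1_counts(protein, ligand, 12.0).values.sum()
        brute = brute_rf_v1(protein, ligand, 12.0).sum()
        assert total == brute


class TestDescriptorTable:
    CSV = "id,vdw,hbond,hydrophobic,rotor\nc1,-2.5,3,10,4\nc2,-1.25,0,2,0\nc3,0.5,1,7,2\n"

    def test_ingest_three_rows(self):
        table = load_descriptor_table(self.CSV, scheme="xscore4")
        assert len(table) == 3
        assert table.feature_names == ("vdw", "hbond", "hydrophobic", "rotor")
        assert table.frame.loc["c2", "vdw"] == -1.25

    def test_duplicate_id_rejected(self):
        bad = self.CSV + "c1,0,0,0,0\n"
        with pytest.raises(ValueError, match="c1"):
            load_descriptor_table(bad, scheme="xscore4")

    def test_non_numeric_cell_names_row_and_column(self):
        bad = "id,vdw,hbond,hydrophobic,rotor\nc1,-2.5,x,10,4\n"
        with pytest.raises(ValueError, match=r"c1.*hbond"):
            load_descriptor_table(bad, scheme="xscore4")

    def test_write_read_round_trip(self):
        table = load_descriptor_table(self.CSV, scheme="xscore4")
        buf = io.StringIO()
        write_descriptor_table(table, buf)
        back = load_descriptor_table(buf.getvalue(), scheme="xscore4")
        np.testing.assert_allclose(back.features().to_numpy(),
                                   table.features().to_numpy(), rtol=1e-6)
        assert back.ids == table.ids
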