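"""3D conformer descriptors against brute-force and Monte-Carlo oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protacprofiler.config import ATOMIC_MASSES, BONDI_RADII
from protacprofiler.conformers import (
    Conformer,
    RadiiTable,
    describe_conformer,
    find_imhb,
    golden_spiral_points,
    polar_atom_indices,
    psa_3d,
    radius_of_gyration,
    shrake_rupley_sasa,
)
from protacprofiler.errors import NoTopologyError, UnknownElementError


def mc_sasa_total(elements, coords, probe, n=1_000_000, seed=0):
    """Independent Monte-Carlo occlusion oracle: random surface points per
    atom, accessible when outside every other inflated sphere."""
    r = np.array([BONDI_RADII[e] for e in elements]) + probe
    gen = np.random.default_rng(seed)
    total = 0.0
    for i in range(len(elements)):
        pts = gen.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + r[i] * pts
        accessible = np.ones(n, dtype=bool)
        for j in range(len(elements)):
            if j == i:
                continue
            accessible &= ((pts - coords[j]) ** 2).sum(axis=1) >= r[j] ** 2
        total += 4 * math.pi * r[i] ** 2 * accessible.mean()
    return total


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        c = Conformer(elements=["C"], coords=[[1.0, 2.0, 3.0]])
        assert radius_of_gyration(c) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_dumbbell(self):
        c = Conformer(elements=["C", "C"], coords=[[0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(c) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mass_weighted", [True, False])
    def test_matches_brute_force_definition(self, rng, mass_weighted):
        elements = list(rng.choice(["C", "N", "O", "H", "S"], size=50))
        coords = rng.normal(scale=5.0, size=(50, 3))
        c = Conformer(elements=elements, coords=coords)
        w = np.array(
            [ATOMIC_MASSES[e] if mass_weighted else 1.0 for e in elements]
        )
        centroid = (w[:, None] * coords).sum(0) / w.sum()
        expected = math.sqrt(
            sum(
                wi * float(((ri - centroid) ** 2).sum())
                for wi, ri in zip(w, coords)
            )
            / w.sum()
        )
        assert radius_of_gyration(c, mass_weighted=mass_weighted) == pytest.approx(
            expected, abs=1e-10
        )

    def test_translation_invariance(self, random_conformer):
        r0 = radius_of_gyration(random_conformer)
        shifted = Conformer(
            elements=random_conformer.elements,
            coords=random_conformer.coords + np.array([10.0, -5.0, 3.0]),
        )
        assert radius_of_gyration(shifted) == pytest.approx(r0, abs=1e-12)

    def test_unknown_element_rejected(self):
        c = Conformer(elements=["Xx"], coords=[[0, 0, 0]])
        with pytest.raises(UnknownElementError):
            radius_of_gyration(c)


class TestShrakeRupley:
    def test_isolated_atom_closed_form(self):
        c = Conformer(elements=["O"], coords=[[0, 0, 0]])
        for probe, r in ((1.4, 2.92), (0.0, 1.52)):
            area = shrake_rupley_sasa(c, probe, 960)[0]
            exact = 4 * math.pi * r**2
            assert area == pytest.approx(exact, rel=0.01)

    def test_buried_atom_has_zero_area(self):
        # surround a carbon with a tight shell of carbons on a sphere
        shell = 1.2 * golden_spiral_points(40)
        c = Conformer(
            elements=["C"] * 41,
            coords=np.vstack([[0.0, 0.0, 0.0], shell]),
        )
        assert shrake_rupley_sasa(c, 1.4, 960)[0] == 0.0

    def test_area_non_increasing_as_neighbor_approaches(self):
        areas = []
        for d in (6.0, 4.0, 3.0, 2.5):
            c = Conformer(elements=["C", "C"], coords=[[0, 0, 0], [d, 0, 0]])
            areas.append(shrake_rupley_sasa(c, 1.4, 960)[0])
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_multi_atom_within_2pct_of_monte_carlo_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 9))
            elements = list(rng.choice(["C", "N", "O", "S"], size=n))
            coords = rng.normal(scale=1.8, size=(n, 3))
            c = Conformer(elements=elements, coords=coords)
            mine = shrake_rupley_sasa(c, 1.4, 960).sum()
            oracle = mc_sasa_total(elements, coords, 1.4, n=1_000_000,
                                   seed=int(rng.integers(0, 2**31)))
            assert mine == pytest.approx(oracle, rel=0.02)

    def test_rigid_motion_invariance(self, random_conformer):
        base = shrake_rupley_sasa(random_conformer, 1.4, 960)
        for k in range(3):
            R = Rotation.random(random_state=k).as_matrix()
            moved = Conformer(
                elements=random_conformer.elements,
                coords=random_conformer.coords @ R.T + np.array([5.0, -2.0, 9.0]),
            )
            assert np.abs(shrake_rupley_sasa(moved, 1.4, 960) - base).max() < 1e-8

    def test_convergence_toward_dense_oracle(self, rng):
        elements = ["C", "O", "N", "C", "S", "O"]
        coords = np.random.default_rng(7).normal(scale=1.5, size=(6, 3))
        c = Conformer(elements=elements, coords=coords)
        oracle = mc_sasa_total(elements, coords, 1.4, n=1_000_000, seed=3)
        errs = [
            abs(shrake_rupley_sasa(c, 1.4, npts).sum() - oracle)
            for npts in (240, 960, 3840)
        ]
        assert errs[-1] < errs[0]
        assert errs[-1] / oracle < 0.005

    def test_cross_check_against_biopython(self, tmp_path, rng):
        """Independent library implementation agrees on the same radii."""
        Bio = pytest.importorskip("Bio.PDB")
        from Bio.PDB.SASA import ShrakeRupley

        from protacprofiler.io import write_pdb_multimodel

        elements = ["C", "N", "O", "C", "O", "C"]
        coords = rng.normal(scale=1.8, size=(6, 3))
        c = Conformer(elements=elements, coords=coords)
        path = tmp_path / "mol.pdb"
        write_pdb_multimodel([c], path)
        structure = Bio.PDBParser(QUIET=True).get_structure("m", str(path))
        calc = ShrakeRupley(probe_radius=1.4, n_points=960,
                            radii_dict=BONDI_RADII)
        calc.compute(structure[0], level="A")
        reference = sum(a.sasa for a in structure.get_atoms())
        mine = shrake_rupley_sasa(c, 1.4, 960).sum()
        assert mine == pytest.approx(reference, rel=0.02)

    def test_bit_reproducibility(self, random_conformer):
        a = shrake_rupley_sasa(random_conformer, 1.4, 960)
        b = shrake_rupley_sasa(random_conformer, 1.4, 960)
        assert np.array_equal(a, b)


WATER = dict(
    elements=["O", "H", "H"],
    coords=[[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]],
    bonds=[(0, 1), (0, 2)],
)


class TestPsa3d:
    def test_hydrocarbon_has_zero_psa(self):
        c = Conformer(
            elements=["C", "C", "H"],
            coords=[[0, 0, 0], [1.5, 0, 0], [2.2, 0.8, 0]],
            bonds=[(0, 1), (1, 2)],
        )
        for probe in (0.0, 1.4):
            assert psa_3d(c, probe) == 0.0

    def test_water_like_molecule_matches_oracle(self):
        c = Conformer(**WATER)
        mine = psa_3d(c, 1.4, 960)
        # every atom is polar (O plus two H bonded to O): PSA == total SASA
        oracle = mc_sasa_total(c.elements, np.asarray(c.coords), 1.4)
        assert mine == pytest.approx(oracle, rel=0.01)

    def test_polar_atom_set_requires_h_on_n_or_o(self):
        c = Conformer(
            elements=["C", "H", "O", "H", "S"],
            coords=np.array(
                [[0, 0, 0], [1.1, 0, 0], [3, 0, 0], [3.96, 0, 0], [6, 0, 0]],
                dtype=float,
            ),
            bonds=[(0, 1), (2, 3)],
        )
        # O and its H are polar; C, its H, and S are not
        assert polar_atom_indices(c) == [2, 3]

    def test_folded_buries_polarity_relative_to_extended(self):
        # same composition: O atoms along a line vs clustered tightly
        elements = ["O"] * 6
        extended = Conformer(
            elements=elements,
            coords=np.array([[3.0 * i, 0, 0] for i in range(6)]),
        )
        folded = Conformer(
            elements=elements,
            coords=1.6 * golden_spiral_points(6),
        )
        assert psa_3d(folded, 1.4) < psa_3d(extended, 1.4)

    def test_psa_never_exceeds_total_sasa(self, random_conformer):
        sasa = shrake_rupley_sasa(random_conformer, 1.4, 960)
        assert psa_3d(random_conformer, 1.4, sasa=sasa) <= sasa.sum() + 1e-9


class TestImhb:
    def _ohO(self, d_ha, angle_deg):
        """Donor O-H ... acceptor O with given H-acceptor distance/angle."""
        theta = math.radians(180.0 - angle_deg)
        acceptor = [
            0.96 + d_ha * math.cos(theta),
            d_ha * math.sin(theta),
            0.0,
        ]
        return Conformer(
            elements=["O", "H", "O"],
            coords=[[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], acceptor],
            bonds=[(0, 1)],
        )

    def test_ideal_linear_bond_detected(self):
        assert find_imhb(self._ohO(1.9, 180.0)) == [(0, 1, 2)]

    def test_stretched_geometry_rejected(self):
        assert find_imhb(self._ohO(3.5, 180.0)) == []

    def test_bent_geometry_rejected(self):
        assert find_imhb(self._ohO(1.9, 90.0)) == []

    def test_covalently_bonded_pair_not_counted(self):
        c = Conformer(**WATER)
        assert find_imhb(c) == []

    def test_missing_topology_raises(self):
        c = Conformer(elements=["N", "O"], coords=[[0, 0, 0], [2.8, 0, 0]])
        with pytest.raises(NoTopologyError):
            find_imhb(c)


class TestDescribeConformer:
    def test_block_is_consistent(self):
        c = Conformer(**WATER)
        d = describe_conformer(c, n_points=240)
        assert d.psa_14 == pytest.approx(d.sasa_total, rel=1e-9)
        assert d.psa_0 >= 0 and d.r_gyr > 0 and d.n_imhb == 0

    def test_custom_radii_table(self):
        table = RadiiTable(radii={"C": 2.0}, masses={"C": 12.0})
        c = Conformer(elements=["C"], coords=[[0, 0, 0]])
        area = shrake_rupley_sasa(c, 0.0, 960, radii_table=table)[0]
        assert area == pytest.approx(4 * math.pi * 4.0, rel=0.01)
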