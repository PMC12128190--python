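"""Bond-probe electric fields: constants, projection, decomposition."""

import numpy as np
import pytest
import scipy.constants as const

from fepath.constants import COULOMB_KCAL_A_E2, KCAL_MOL_E_A_TO_MV_CM
from fepath.electric_field import (
    FieldProbe,
    atom_field,
    define_probe,
    field_decomposition,
    field_report,
)
from fepath.errors import GeometryError, InvalidParameterError, SelectionError
from fepath.structures import ChargedStructure
from fepath.toy_systems import make_toy_complex


def _probe_z():
    return FieldProbe(position=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))


class TestConstants:
    """Unit constants re-derived from CODATA values (via scipy.constants)."""

    def test_coulomb_constant_kcal_angstrom(self):
        ke = (const.e**2 / (4 * np.pi * const.epsilon_0)  # J·m
              * const.Avogadro / (const.calorie * 1e3) * 1e10)  # kcal·Å/mol
        assert COULOMB_KCAL_A_E2 == pytest.approx(ke, rel=1e-5)

    def test_field_conversion_mv_per_cm(self):
        # 1 kcal/(mol·e·Å) in MV/cm
        v_per_m = const.calorie * 1e3 / const.Avogadro / const.e / 1e-10
        mv_per_cm = v_per_m / 1e6 / 100
        assert KCAL_MOL_E_A_TO_MV_CM == pytest.approx(mv_per_cm, rel=1e-5)


class TestProbe:
    def test_midpoint_and_direction(self, toy_complex):
        s = ChargedStructure(
            [1, 2], ["OD1", "CG"], ["LIG", "LIG"], ["A", "A"], [1, 1],
            [[0, 0, 0], [0, 0, 2.0]], [-0.5, 0.5], [1.5, 1.7], [False, False],
        )
        probe = define_probe(s, "LIG:OD1", "LIG:CG")
        assert np.allclose(probe.position, [0, 0, 1.0])
        assert np.allclose(probe.direction, [0, 0, 1.0])

    def test_swapped_order_negates_direction(self, toy_complex):
        s = toy_complex.structure
        p1 = define_probe(s, "LIG:OD1", "LIG:CG")
        p2 = define_probe(s, "LIG:CG", "LIG:OD1")
        assert np.allclose(p1.position, p2.position)
        assert np.allclose(p1.direction, -p2.direction)

    def test_ambiguous_selection_rejected(self, toy_complex):
        with pytest.raises(SelectionError):
            define_probe(toy_complex.structure, "RES:A1", "LIG:CG")

    def test_unit_direction_enforced(self):
        probe = FieldProbe(np.zeros(3), np.array([0.0, 3.0, 4.0]))
        assert np.linalg.norm(probe.direction) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(InvalidParameterError):
            FieldProbe(np.zeros(3), np.zeros(3))


class TestAtomField:
    def test_unit_charge_on_axis_at_10A(self):
        """+1 e placed 10 Å behind the probe along −direction projects to
        k_e/100 kcal/(mol·e·Å) = +14.40 MV/cm."""
        val = atom_field([0.0, 0.0, -10.0], 1.0, _probe_z())
        assert val == pytest.approx(COULOMB_KCAL_A_E2 / 100 *
                                    KCAL_MOL_E_A_TO_MV_CM, rel=1e-12)
        assert val == pytest.approx(14.40, abs=0.005)

    def test_perpendicular_charge_projects_to_zero(self):
        assert atom_field([5.0, 0.0, 0.0], 1.0, _probe_z()) == pytest.approx(
            0.0, abs=1e-12)

    def test_zero_charge(self):
        assert atom_field([1.0, 2.0, 3.0], 0.0, _probe_z()) == 0.0

    def test_singularity_rejected(self):
        with pytest.raises(GeometryError):
            atom_field([0.0, 0.0, 0.05], 1.0, _probe_z())

    def test_positive_field_stabilises_negative_charge_at_oxygen(self):
        """A cation placed behind the oxygen of an O→C probe stabilises
        negative charge developing on O; its field at the probe points
        along O→C, i.e. the projection is positive.  A field along O→C
        also pushes electron density toward O (force on an electron is
        −E)."""
        probe = FieldProbe.from_atom_pair([-0.6, 0, 0], [0.6, 0, 0])  # O→C
        assert atom_field([-3.0, 0.0, 0.0], +1.0, probe) > 0
        # a cation beyond the carbon side destabilises a negative O
        assert atom_field([3.0, 0.0, 0.0], +1.0, probe) < 0


class TestDecomposition:
    def test_superposition_matches_per_atom_loop(self, toy_complex):
        s = toy_complex.structure
        probe = define_probe(s, *toy_complex.probe_pair)
        rec = field_decomposition(s, probe, solvent_cutoff=15.0)
        brute = 0.0
        for i in range(s.n_atoms):
            if s.resname[i] == "LIG":
                continue
            if s.is_solvent[i] and np.linalg.norm(
                    s.coords[i] - probe.position) > 15.0:
                continue
            brute += atom_field(s.coords[i], s.charge[i], probe)
        assert rec["field"].sum() == pytest.approx(brute, abs=1e-10)

    def test_solvent_cutoff_semantics(self):
        """A solvent atom at 16 Å contributes nothing; the same atom
        relabelled solute contributes its Coulomb term."""
        def build(is_solvent):
            return ChargedStructure(
                [1, 2, 3], ["OD1", "CG", "O"], ["LIG", "LIG", "HOH"],
                ["A", "A", "W"], [1, 1, 2],
                [[-0.6, 0, 0], [0.6, 0, 0], [16.0, 0, 0]],
                [-0.5, 0.5, -0.8], [1.5, 1.7, 1.4], [False, False, is_solvent],
            )
        probe = define_probe(build(True), "LIG:OD1", "LIG:CG")
        rec_solv = field_decomposition(build(True), probe)
        rec_solu = field_decomposition(build(False), probe)
        assert rec_solv["field"].iloc[0] == 0.0
        expected = atom_field([16.0, 0, 0], -0.8, probe)
        assert rec_solu["field"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_two_frame_mean_and_stderr(self, toy_complex):
        """Per-frame fields ±1 MV/cm give mean 0 and stderr 1."""
        s = ChargedStructure(
            [1, 2, 3], ["OD1", "CG", "Q"], ["LIG", "LIG", "RES"],
            ["A", "A", "A"], [1, 1, 2],
            [[0, 0, -0.6], [0, 0, 0.6], [0, 0, -10.0]],
            [-0.5, 0.5, 1.0], [1.5, 1.7, 1.6], [False] * 3,
        )
        base = s.coords.copy()
        flipped = base.copy()
        flipped[2, 2] = +10.0  # move charge to the other side
        probe = define_probe(s, "LIG:OD1", "LIG:CG")
        traj = np.stack([base, flipped])
        rec = field_decomposition(s, probe, traj=traj)
        f0 = atom_field([0, 0, -10.0], 1.0, probe)
        assert rec["field"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        # sd of (+f, −f) is f√2; stderr = f√2/√2 = f
        assert rec["err"].iloc[0] == pytest.approx(abs(f0), rel=1e-12)

    def test_rigid_motion_equivariance(self, toy_complex, rng):
        s = toy_complex.structure
        probe = define_probe(s, *toy_complex.probe_pair)
        rec = field_decomposition(s, probe)
        # random rotation + translation applied to everything
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(size=3) * 5
        s2 = s.with_coords(s.coords @ q.T + shift)
        probe2 = define_probe(s2, *toy_complex.probe_pair)
        rec2 = field_decomposition(s2, probe2)
        assert np.allclose(rec["field"], rec2["field"], atol=1e-9)

    def test_motif_records_sum_member_residues(self, toy_complex):
        s = toy_complex.structure
        probe = define_probe(s, *toy_complex.probe_pair)
        by_res = field_decomposition(s, probe).set_index("group")["field"]
        by_motif = field_decomposition(s, probe, grouping="motif")
        for _, row in by_motif.iterrows():
            keys = s.motifs[row["group"]]
            expected = sum(by_res[s.residue_label(k)] for k in keys)
            assert row["field"] == pytest.approx(expected, abs=1e-10)

    def test_frame_average_commutes_with_grouping(self, toy_complex, rng):
        s = toy_complex.structure
        probe = define_probe(s, *toy_complex.probe_pair)
        # jitter only non-probe atoms so the probe geometry stays fixed
        traj = np.stack([s.coords + 0.0, s.coords + 0.0, s.coords + 0.0])
        jitter = 0.05 * rng.normal(size=traj.shape)
        jitter[:, :2, :] = 0.0
        traj = traj + jitter
        rec = field_decomposition(s, probe, traj=traj)
        per_frame = [
            field_decomposition(s.with_coords(traj[f]), probe)["field"]
            for f in range(3)
        ]
        assert np.allclose(rec["field"], np.mean(per_frame, axis=0),
                           atol=1e-10)


class TestFieldReport:
    def test_threshold_zero_keeps_all(self, toy_complex):
        s = toy_complex.structure
        probe = define_probe(s, *toy_complex.probe_pair)
        rec = field_decomposition(s, probe)
        assert len(field_report(rec, 0.0)) == (rec["field"] != 0).sum()

    def test_filter_and_sort(self):
        import pandas as pd

        rec = pd.DataFrame({"group": ["a", "b", "c"],
                            "field": [3.0, -1.5, -2.5],
                            "err": [0.0, 0.0, 0.0]})
        out = field_report(rec, 2.0)
        assert list(out["group"]) == ["a", "c"]

    def test_empty_input(self):
        import pandas as pd

        empty = pd.DataFrame({"group": [], "field": [], "err": []})
        assert len(field_report(empty, 2.0)) == 0
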