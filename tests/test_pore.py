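"""Probe-radius profiling, constriction detection and hydrophobicity."""

import numpy as np
import pytest

from ionpore.core import Atom, Structure, StructureError
from ionpore.pore import (
    HYDROPHOBICITY_SCALES, PoreProfile, PoreSample, VDW_RADII,
    compute_pore_profile, hydrophobicity_annotation, min_constriction,
)
from tests.conftest import make_ring


AXIS = dict(axis_origin=[0.0, 0.0, 0.0], axis_direction=[0.0, 0.0, 1.0])


def stacked_rings(radius, z_values, resnames=None):
    atoms = []
    for j, z in enumerate(z_values):
        resname = resnames[j] if resnames else "LEU"
        for i in range(12):
            angle = 2 * np.pi * i / 12 + 0.2 * j
            atoms.append(Atom(
                element="C", atom_name=f"C{i + 1}", residue_name=resname,
                residue_number=30 + j, chain_id="A",
                position=np.array([radius * np.cos(angle),
                                   radius * np.sin(angle), z])))
    return Structure(atoms=atoms)


class TestProfiler:
    @pytest.mark.parametrize("ring_radius", [3.0, 4.2, 5.0, 6.5, 8.0])
    def test_ring_oracle(self, ring_radius):
        """Analytic clearance of a single ring: radius - vdW(C)."""
        structure = make_ring(ring_radius, n=12)
        profile = compute_pore_profile(structure, z_range=(0.0, 0.1), step=0.5,
                                       seed=0, **AXIS)
        assert profile.samples[0].radius == pytest.approx(
            ring_radius - VDW_RADII["C"], abs=0.05)

    def test_cylinder_constant_profile(self):
        structure = stacked_rings(5.0, np.arange(-6, 6.5, 1.0))
        profile = compute_pore_profile(structure, z_range=(-4, 4), step=0.5,
                                       seed=0, **AXIS)
        radii = profile.radius
        assert np.all(np.abs(radii - radii.mean()) < 0.05)
        assert radii.mean() == pytest.approx(5.0 - VDW_RADII["C"], abs=0.05)

    def test_vdw_shrink_monotonicity(self):
        """Replacing C (vdW 1.70) by O (vdW 1.52) widens the pore by exactly
        the radius difference for a centred symmetric ring."""
        delta = VDW_RADII["C"] - VDW_RADII["O"]
        carbon = make_ring(5.0, n=12)
        oxygen = Structure(atoms=[
            Atom(element="O", atom_name=a.atom_name, residue_name=a.residue_name,
                 residue_number=a.residue_number, chain_id=a.chain_id,
                 position=a.position)
            for a in carbon.atoms])
        r_c = compute_pore_profile(carbon, z_range=(0, 0.1), seed=0, **AXIS).samples[0].radius
        r_o = compute_pore_profile(oxygen, z_range=(0, 0.1), seed=0, **AXIS).samples[0].radius
        assert r_o - r_c == pytest.approx(delta, abs=0.02)

    def test_probe_never_overlaps_obstacles(self, toy_channel):
        structure, _ = toy_channel
        profile = compute_pore_profile(structure, z_range=(-15, 15), step=1.0,
                                       seed=3, **AXIS)
        coords = structure.coordinates()
        radii = np.array([VDW_RADII.get(a.element, 1.7) for a in structure.atoms])
        for sample in profile.samples:
            gap = np.min(np.linalg.norm(coords - sample.center, axis=1) - radii)
            assert gap - sample.radius >= -1e-6

    def test_seed_determinism(self, toy_channel):
        structure, _ = toy_channel
        kwargs = dict(z_range=(-10, 10), step=1.0, seed=11, **AXIS)
        p1 = compute_pore_profile(structure, **kwargs)
        p2 = compute_pore_profile(structure, **kwargs)
        np.testing.assert_array_equal(p1.radius, p2.radius)
        for a, b in zip(p1.samples, p2.samples):
            np.testing.assert_array_equal(a.center, b.center)

    def test_open_plane_is_capped(self):
        structure = make_ring(5.0, n=12, z=0.0)
        profile = compute_pore_profile(structure, z_range=(0, 30), step=10.0,
                                       seed=0, **AXIS)
        far = profile.samples[-1]
        assert far.capped and far.radius == pytest.approx(10.0)

    def test_waters_and_ions_excluded_from_obstacles(self):
        ring = make_ring(5.0, n=12)
        blocked = Structure(atoms=ring.atoms + [
            Atom(element="O", atom_name="O", residue_name="HOH", residue_number=900,
                 chain_id="W", position=np.zeros(3)),
            Atom(element="K", atom_name="K", residue_name="K", residue_number=901,
                 chain_id="I", position=np.array([0.0, 0.0, 0.5]))])
        profile = compute_pore_profile(blocked, z_range=(0, 0.1), seed=0, **AXIS)
        assert profile.samples[0].radius == pytest.approx(5.0 - 1.7, abs=0.05)

    def test_no_protein_raises(self):
        water_only = Structure(atoms=[
            Atom(element="O", atom_name="O", residue_name="HOH", residue_number=1,
                 chain_id="W", position=np.zeros(3))])
        with pytest.raises(StructureError):
            compute_pore_profile(water_only, z_range=(0, 1), seed=0, **AXIS)

    def test_step_must_be_positive(self, toy_channel):
        with pytest.raises(ValueError):
            compute_pore_profile(toy_channel[0], step=0.0, seed=0, **AXIS)


class TestMinConstriction:
    @staticmethod
    def profile_from_radii(radii):
        samples = [PoreSample(z=float(i), center=np.array([0.0, 0.0, float(i)]),
                              radius=float(r),
                              lining_residues=[("A", 30 + i, "LEU")])
                   for i, r in enumerate(radii)]
        return PoreProfile(axis_origin=np.zeros(3),
                           axis_direction=np.array([0.0, 0.0, 1.0]),
                           samples=samples)

    def test_v_shape_vertex(self):
        profile = self.profile_from_radii([5, 4, 3, 1.2, 3, 4, 5])
        z, radius, lining = min_constriction(profile)
        assert (z, radius) == (3.0, 1.2)
        assert lining == [("A", 33, "LEU")]

    def test_tie_breaks_toward_smaller_z(self):
        profile = self.profile_from_radii([5, 2, 4, 2, 5])
        z, radius, _ = min_constriction(profile)
        assert (z, radius) == (1.0, 2.0)

    def test_window_restricts_search(self):
        profile = self.profile_from_radii([1, 5, 4, 3, 5])
        z, radius, _ = min_constriction(profile, z_window=(2, 4))
        assert (z, radius) == (3.0, 3.0)

    def test_empty_window_raises(self):
        profile = self.profile_from_radii([1, 2, 3])
        with pytest.raises(ValueError):
            min_constriction(profile, z_window=(50, 60))

    def test_constriction_lining_names_the_gate(self, toy_channel):
        """The toy channel's narrowest ring is built from ILE residues."""
        structure, truth = toy_channel
        profile = compute_pore_profile(structure, z_range=(-4, 4), step=0.5,
                                       seed=0, **AXIS)
        _, radius, lining = min_constriction(profile)
        assert radius == pytest.approx(truth.constriction_radius, abs=0.05)
        assert any(resname == "ILE" for _, _, resname in lining)


class TestHydrophobicity:
    def test_uniform_leucine_lining(self):
        structure = stacked_rings(5.0, np.arange(-3, 3.5, 1.0))
        profile = compute_pore_profile(structure, z_range=(-2, 2), step=1.0,
                                       seed=0, **AXIS)
        hydrophobicity_annotation(structure, profile, lining_cutoff=8.0)
        leu = HYDROPHOBICITY_SCALES["kyte-doolittle"]["LEU"]
        assert all(s.hydrophobicity == pytest.approx(leu) for s in profile.samples)

    def test_alternating_ser_leu_mean(self):
        """Planes seeing both ring types score the mean of the two values."""
        names = ["SER", "LEU", "SER", "LEU", "SER", "LEU", "SER"]
        structure = stacked_rings(5.0, np.arange(-3, 3.5, 1.0), resnames=names)
        profile = compute_pore_profile(structure, z_range=(0, 0.1), step=1.0,
                                       seed=0, **AXIS)
        hydrophobicity_annotation(structure, profile, lining_cutoff=6.2)
        table = HYDROPHOBICITY_SCALES["kyte-doolittle"]
        # cutoff 6.2 from the axis reaches rings at |dz| <= ~3.6: 4 SER + 3 LEU
        expected = (4 * table["SER"] + 3 * table["LEU"]) / 7
        assert profile.samples[0].hydrophobicity == pytest.approx(expected)

    def test_unknown_residue_neutral_with_warning(self):
        structure = stacked_rings(5.0, [0.0], resnames=["XYZ"])
        # bypass record-class lookup: force the odd residue to count as protein
        structure = Structure(atoms=[
            Atom(element="C", atom_name=a.atom_name, residue_name="XYZ",
                 residue_number=a.residue_number, chain_id=a.chain_id,
                 position=a.position, record_class=a.record_class.__class__("protein"))
            for a in structure.atoms])
        profile = compute_pore_profile(structure, z_range=(0, 0.1), seed=0, **AXIS)
        with pytest.warns(UserWarning, match="XYZ"):
            hydrophobicity_annotation(structure, profile, lining_cutoff=8.0)
        assert profile.samples[0].hydrophobicity == pytest.approx(0.0)

    def test_vestibule_more_hydrophobic_than_entrance(self):
        """A LEU/ILE-lined segment outscores a SER/THR-lined one."""
        names = ["SER", "THR", "SER", "GLY", "ILE", "LEU", "LEU", "ILE"]
        structure = stacked_rings(5.0, np.arange(-4, 4.0, 1.0), resnames=names)
        profile = compute_pore_profile(structure, z_range=(-3.5, 3.0), step=0.5,
                                       seed=0, **AXIS)
        hydrophobicity_annotation(structure, profile, lining_cutoff=2.5 + 5.0 - 1.7)
        entrance = [s.hydrophobicity for s in profile.samples if s.z <= -2]
        vestibule = [s.hydrophobicity for s in profile.samples if s.z >= 1]
        assert np.mean(vestibule) > np.mean(entrance)
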