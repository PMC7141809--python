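"""Non-protein peak extraction, cross-map matching and ion/water classification."""

import numpy as np
import pytest

from ionpore.core import Atom, DensityMap, MapError, Structure, sigma_scale
from ionpore.sites import (
    CylinderMask, DensityPeak, IonSiteAssignment, classify_sites,
    find_nonprotein_peaks, match_peaks, site_geometry_report,
)


def blob_map(centers, amplitudes, shape=(32, 32, 32), voxel=1.0, width=1.2,
             origin=(0.0, 0.0, 0.0)):
    grid = np.zeros(shape)
    axes = [np.arange(n) * voxel + o for n, o in zip(shape, origin)]
    for center, amp in zip(centers, amplitudes):
        dx2 = ((axes[0][:, None, None] - center[0]) ** 2
               + (axes[1][None, :, None] - center[1]) ** 2
               + (axes[2][None, None, :] - center[2]) ** 2)
        grid += amp * np.exp(-dx2 / (2 * width ** 2))
    return sigma_scale(DensityMap(grid=grid, voxel_size=[voxel] * 3, origin=origin))


def peak_at(center, sigma=20.0, voxels=None):
    return DensityPeak(centroid=np.asarray(center, float), max_sigma=sigma,
                       max_raw=sigma, volume=1.0, nearest_protein_atom=5.0,
                       voxel_set=frozenset(voxels or []))


class TestFindPeaks:
    def test_single_blob_centroid_accuracy(self):
        truth = np.array([15.3, 16.8, 14.1])
        density = blob_map([truth], [10.0])
        peaks = find_nonprotein_peaks(density, None, threshold=8.0)
        assert len(peaks) == 1
        assert np.linalg.norm(peaks[0].centroid - truth) < 0.5

    def test_threshold_above_maximum_gives_empty(self):
        density = blob_map([[16, 16, 16]], [5.0])
        assert find_nonprotein_peaks(density, None, threshold=1e6) == []

    def test_unscaled_map_rejected(self):
        raw = DensityMap(grid=np.random.default_rng(0).normal(size=(8, 8, 8)),
                         voxel_size=[1] * 3, origin=[0] * 3)
        with pytest.raises(MapError, match="sigma-scaled"):
            find_nonprotein_peaks(raw, None, threshold=5.0)

    def test_exclusion_radius_removes_protein_density(self):
        centers = [[10.0, 16.0, 16.0], [22.0, 16.0, 16.0]]
        density = blob_map(centers, [10.0, 10.0])
        model = Structure(atoms=[
            Atom(element="C", atom_name="CA", residue_name="ALA", residue_number=1,
                 chain_id="A", position=np.array(centers[0]))])
        peaks = find_nonprotein_peaks(density, model, threshold=8.0,
                                      exclusion_radius=3.0)
        assert len(peaks) == 1
        assert np.linalg.norm(peaks[0].centroid - centers[1]) < 0.5

    def test_threshold_monotonicity(self):
        density = blob_map([[10, 16, 16], [22, 16, 16]], [8.0, 15.0])
        low = find_nonprotein_peaks(density, None, threshold=6.0)
        high = find_nonprotein_peaks(density, None, threshold=12.0)
        assert len(high) <= len(low)
        assert sum(p.n_voxels for p in high) <= sum(p.n_voxels for p in low)

    def test_sorted_by_max_sigma(self):
        density = blob_map([[10, 16, 16], [22, 16, 16]], [6.0, 15.0])
        peaks = find_nonprotein_peaks(density, None, threshold=5.0)
        sigmas = [p.max_sigma for p in peaks]
        assert sigmas == sorted(sigmas, reverse=True)

    def test_region_mask_restricts_peaks(self):
        density = blob_map([[16, 16, 8], [16, 16, 24], [4, 4, 16]], [10, 10, 10])
        mask = CylinderMask(axis_origin=np.array([16.0, 16.0, 16.0]),
                            axis_direction=np.array([0.0, 0.0, 1.0]), radius=5.0)
        peaks = find_nonprotein_peaks(density, None, threshold=8.0, region=mask)
        assert len(peaks) == 2

    def test_frame_invariance(self):
        """Translating map origin and model together leaves world centroids fixed."""
        truth = [12.0, 20.0, 16.0]
        base = blob_map([truth], [10.0])
        shifted = blob_map([np.add(truth, 50.0)], [10.0], origin=(50.0, 50.0, 50.0))
        p0 = find_nonprotein_peaks(base, None, threshold=8.0)[0]
        p1 = find_nonprotein_peaks(shifted, None, threshold=8.0)[0]
        np.testing.assert_allclose(p1.centroid - 50.0, p0.centroid, atol=1e-9)


class TestMatchPeaks:
    def test_identical_lists_match_at_zero(self):
        peaks = [peak_at([5, 5, 5], voxels=[(5, 5, 5)]),
                 peak_at([9, 9, 9], voxels=[(9, 9, 9)])]
        pairs, ua, ub = match_peaks(peaks, list(peaks), criterion="centroid_distance")
        assert len(pairs) == 2 and not ua and not ub
        assert all(np.allclose(a.centroid, b.centroid) for a, b in pairs)

    def test_displaced_beyond_cutoff_no_match(self):
        a = [peak_at([0, 0, 0])]
        b = [peak_at([0, 0, 4.0])]
        pairs, ua, ub = match_peaks(a, b, criterion="centroid_distance", cutoff=1.5)
        assert not pairs and len(ua) == 1 and len(ub) == 1

    def test_voxel_overlap_requires_shared_voxel(self):
        a = [peak_at([5, 5, 5], voxels=[(5, 5, 5), (5, 5, 6)])]
        b_hit = [peak_at([5.4, 5, 5], voxels=[(5, 5, 6), (5, 5, 7)])]
        b_miss = [peak_at([5.4, 5, 5], voxels=[(8, 8, 8)])]
        assert len(match_peaks(a, b_hit)[0]) == 1
        assert len(match_peaks(a, b_miss)[0]) == 0

    def test_count_conservation_and_injectivity(self):
        rng = np.random.default_rng(4)
        a = [peak_at(rng.uniform(0, 30, 3)) for _ in range(8)]
        b = [peak_at(rng.uniform(0, 30, 3)) for _ in range(5)]
        pairs, ua, ub = match_peaks(a, b, criterion="centroid_distance", cutoff=10.0)
        assert len(pairs) + len(ua) == len(a)
        assert len(pairs) + len(ub) == len(b)
        matched_a = [id(p) for p, _ in pairs]
        matched_b = [id(q) for _, q in pairs]
        assert len(set(matched_a)) == len(matched_a)
        assert len(set(matched_b)) == len(matched_b)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = [peak_at(rng.uniform(0, 20, 3)) for _ in range(6)]
        b = [peak_at(rng.uniform(0, 20, 3)) for _ in range(6)]
        fwd, _, _ = match_peaks(a, b, criterion="centroid_distance", cutoff=6.0)
        rev, _, _ = match_peaks(b, a, criterion="centroid_distance", cutoff=6.0)
        fwd_set = {(id(x), id(y)) for x, y in fwd}
        rev_set = {(id(y), id(x)) for x, y in rev}
        assert fwd_set == rev_set

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([], [], cutoff=-1.0)


class TestClassification:
    def test_counts_conserved(self):
        matches = [(peak_at([0, 0, z]), peak_at([0, 0, z])) for z in range(4)]
        unmatched = [peak_at([1, 1, z]) for z in range(10)]
        assignments = classify_sites(matches, unmatched)
        assert sum(a.classification == "ion" for a in assignments) == 4
        assert sum(a.classification == "water" for a in assignments) == 10

    def test_empty_matches_all_water(self):
        assignments = classify_sites([], [peak_at([0, 0, 0]), peak_at([0, 0, 3])])
        assert all(a.classification == "water" for a in assignments)

    def test_labels_ordered_along_axis(self):
        matches = [(peak_at([0, 0, 9.0]), peak_at([0, 0, 9.0])),
                   (peak_at([0, 0, -5.0]), peak_at([0, 0, -5.0]))]
        assignments = classify_sites(matches, [])
        assert assignments[0].label == "K1"
        assert assignments[0].peak_primary.centroid[2] == -5.0

    def test_amplitude_ratio_from_raw_amplitudes(self):
        primary = peak_at([0, 0, 0], sigma=20.0)
        partner = DensityPeak(centroid=np.zeros(3), max_sigma=10.0, max_raw=60.0,
                              volume=1.0, nearest_protein_atom=5.0)
        (assignment,) = classify_sites([(primary, partner)], [])
        assert assignment.amplitude_ratio == pytest.approx(60.0 / 20.0)

    def test_invariant_partner_iff_ion(self):
        with pytest.raises(ValueError):
            IonSiteAssignment(label="K1", classification="ion",
                              peak_primary=peak_at([0, 0, 0]), peak_partner=None)


class TestSiteGeometry:
    def test_constructed_contact_distance(self):
        model = Structure(atoms=[
            Atom(element="K", atom_name="K", residue_name="K", residue_number=1,
                 chain_id="I", position=np.zeros(3)),
            Atom(element="O", atom_name="O", residue_name="HOH", residue_number=2,
                 chain_id="W", position=np.array([2.8, 0.0, 0.0])),
        ])
        (assignment,) = classify_sites(
            [(peak_at([0, 0, 0], voxels=[(0, 0, 0)]), peak_at([0, 0, 0]))], [])
        report = site_geometry_report([assignment], model, shell=4.0)
        assert len(report) == 1
        assert report.loc[0, "distance"] == pytest.approx(2.8)
        assert report.loc[0, "contact_type"] == "solvent-mediated"

    def test_empty_shell_empty_table(self):
        model = Structure(atoms=[
            Atom(element="O", atom_name="O", residue_name="HOH", residue_number=2,
                 chain_id="W", position=np.array([50.0, 0.0, 0.0]))])
        (assignment,) = classify_sites([], [peak_at([0, 0, 0])])
        report = site_geometry_report([assignment], model, shell=4.0)
        assert len(report) == 0


class TestEndToEndRecovery:
    def test_default_scenario_perfect_classification(self, paired_maps):
        """4 ions + 12 waters with 3x partner amplitude: precision = recall = 1."""
        from ionpore.synthetic import DEFAULT_SIGMA_PARTNER, DEFAULT_SIGMA_PRIMARY
        map_primary, map_partner, truth, structure = paired_maps
        peaks_primary = find_nonprotein_peaks(map_primary, structure,
                                              DEFAULT_SIGMA_PRIMARY)
        peaks_partner = find_nonprotein_peaks(map_partner, structure,
                                              DEFAULT_SIGMA_PARTNER)
        pairs, unmatched, _ = match_peaks(peaks_primary, peaks_partner)
        assignments = classify_sites(pairs, unmatched)
        ions = [a for a in assignments if a.classification == "ion"]
        waters = [a for a in assignments if a.classification == "water"]
        assert len(ions) == len(truth.ion_positions) == 4
        assert len(waters) == len(truth.water_positions) == 12
        for group, positions in ((ions, truth.ion_positions),
                                 (waters, truth.water_positions)):
            truth_arr = np.array(positions)
            for a in group:
                d = np.linalg.norm(truth_arr - a.peak_primary.centroid, axis=1).min()
                assert d < 1.0

    def test_overlap_classification_independent_of_ratio(self, toy_channel):
        """With amplitude ratio 1 ions still match by voxel overlap."""
        from ionpore.synthetic import paired_ion_maps
        structure, _ = toy_channel
        mp, mq, truth = paired_ion_maps(structure, amplitude_ratio=1.0,
                                        n_ions=3, n_waters=4, seed=2,
                                        partner_noise_sd=0.3)
        sp, sq = sigma_scale(mp), sigma_scale(mq)
        pk = find_nonprotein_peaks(sp, structure, 12.0)
        pc = find_nonprotein_peaks(sq, structure, 12.0)
        pairs, _, _ = match_peaks(pk, pc)
        assignments = classify_sites(pairs, [])
        ratios = [a.amplitude_ratio for a in assignments]
        # equal-amplitude partner: everything overlaps, ratios near 1
        assert len(pairs) == 7
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)
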