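#!/usr/bin/env python
"""Optional integration checks against the deposited structures and maps.

These checks need externally downloaded files (PDB 6WC9/6WCA/6WCB and the
EMDB 21603/21605 volumes) and therefore do not run in the offline test
suite.  Given the files, the script recomputes:

* minimum pore radius of the open (class 1, ~1.7 Å) and closed
  (class 2, ~0.5 Å) K+ models;
* the repeat I vs repeat II superposed RMSD (~1.7 Å) using a residue-offset
  pairing between the two 6-helix repeats;
* the class 1 vs class 2 all-atom (protein) RMSD (~0.9 Å) and the
  K+ vs Cs+ class 1 RMSD (~0.2 Å);
* overlapping non-protein pore peaks at 12 sigma (K+) / 8 sigma (Cs+);
* the separation of symmetry-related K1 sites (~3.0 Å).

Usage:
    python scripts/deposition_checks.py --class1-k 6wc9.pdb --class2-k 6wca.pdb \
        --class1-cs 6wcb.pdb --map-k emd_21603.map --map-cs emd_21605.map
"""

from __future__ import annotations

import argparse
import json

import numpy as np

from ionpore.core import read_map, read_structure, select_atoms, sigma_scale
from ionpore.geometry import point_distance, rmsd_between_models
from ionpore.pore import compute_pore_profile, min_constriction
from ionpore.sites import CylinderMask, find_nonprotein_peaks, match_peaks

# repeat I (TM1-TM4, residues 30-173) onto repeat II (TM7-TM10); the two
# 6-helix repeats are related by an internal duplication with ~23% identity,
# so the pairing falls back to C-alpha atoms wherever residue types differ.
DEFAULT_REPEAT_MAP = [("A", 30, 173, "A", 254)]


def pore_minimum(structure, seed=0):
    coords = select_atoms(structure, "record_class == 'protein'").coordinates()
    center = coords.mean(axis=0)
    profile = compute_pore_profile(
        structure, axis_origin=center, axis_direction=[0.0, 0.0, 1.0],
        z_range=(-22.0, 22.0), step=0.5, seed=seed)
    z, radius, lining = min_constriction(profile, z_window=(-8.0, 8.0))
    return radius, lining


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--class1-k", help="class 1 K+ coordinates (6WC9)")
    parser.add_argument("--class2-k", help="class 2 K+ coordinates (6WCA)")
    parser.add_argument("--class1-cs", help="class 1 Cs+ coordinates (6WCB)")
    parser.add_argument("--map-k", help="class 1 K+ volume (EMD-21603)")
    parser.add_argument("--map-cs", help="class 1 Cs+ volume (EMD-21605)")
    parser.add_argument("--sigma-k", type=float, default=12.0)
    parser.add_argument("--sigma-cs", type=float, default=8.0)
    args = parser.parse_args()
    results = {}

    class1 = read_structure(args.class1_k) if args.class1_k else None
    if class1 is not None:
        radius, lining = pore_minimum(class1)
        results["class1_min_pore_radius_A"] = radius  # expect ~1.7
        results["class1_constriction_residues"] = [f"{c}/{r}/{n}" for c, r, n in lining]
        results["repeat_I_vs_II_rmsd_A"] = rmsd_between_models(
            class1, class1, pairing="by_sequence_map",
            residue_map=DEFAULT_REPEAT_MAP)  # expect ~1.7

        ions = select_atoms(class1, "record_class == 'ion'")
        if len(ions.atoms) >= 2:
            pos = ions.coordinates()
            order = np.argsort(pos[:, 2])
            k1_pair = pos[order[:2]]
            results["K1_pair_separation_A"] = point_distance(*k1_pair)  # expect ~3.0

    if args.class2_k and class1 is not None:
        class2 = read_structure(args.class2_k)
        results["class2_min_pore_radius_A"] = pore_minimum(class2)[0]  # expect ~0.5
        results["class1_vs_class2_rmsd_A"] = rmsd_between_models(class1, class2)  # ~0.9

    if args.class1_cs and class1 is not None:
        class1_cs = read_structure(args.class1_cs)
        results["K_vs_Cs_class1_rmsd_A"] = rmsd_between_models(class1, class1_cs)  # ~0.2

    if args.map_k and args.map_cs and class1 is not None:
        map_k = sigma_scale(read_map(args.map_k))
        map_cs = sigma_scale(read_map(args.map_cs))
        coords = select_atoms(class1, "record_class == 'protein'").coordinates()
        pore = CylinderMask(axis_origin=coords.mean(axis=0),
                            axis_direction=np.array([0.0, 0.0, 1.0]), radius=8.0)
        peaks_k = find_nonprotein_peaks(map_k, class1, args.sigma_k, region=pore)
        peaks_cs = find_nonprotein_peaks(map_cs, class1, args.sigma_cs, region=pore)
        pairs, _, _ = match_peaks(peaks_k, peaks_cs, criterion="centroid_distance",
                                  cutoff=1.5)
        results["n_pore_peaks_K"] = len(peaks_k)
        results["n_pore_peaks_Cs"] = len(peaks_cs)
        results["n_overlapping_pore_peaks"] = len(pairs)  # expect 4

    print(json.dumps(results, indent=2, default=float))


if __name__ == "__main__":
    main()
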