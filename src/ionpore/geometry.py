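"""Rigid-body superposition and RMSD for comparing channel models.

Least-squares superposition (Kabsch) underlies two comparisons: the internal
repeat-domain alignment (repeat I vs repeat II of one protomer) and the
open-vs-closed conformational comparison between 3D classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Atom, RecordClass, Structure

__all__ = [
    "Superposition",
    "SuperpositionError",
    "PairingError",
    "kabsch_superpose",
    "rmsd_between_models",
    "point_distance",
    "pair_by_identity",
    "pair_by_sequence_map",
]


class SuperpositionError(ValueError):
    """Underdetermined superposition (too few or degenerate points)."""


class PairingError(ValueError):
    """Atom pairing between two models produced no usable pairs."""


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mapping mobile onto reference.

    ``apply(x) = x @ rotation.T + translation`` minimises the least-squares
    deviation from the reference; ``rmsd`` is the minimised value in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise SuperpositionError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise SuperpositionError("rmsd must be non-negative")
        if self.n_pairs < 3:
            raise SuperpositionError("superposition needs at least 3 pairs")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired coordinates (Kabsch).

    Parameters
    ----------
    mobile, reference:
        (N, 3) arrays of paired positions, N >= 3, not collinear.

    Returns
    -------
    Superposition
        Proper rotation + translation minimising RMSD, with the minimised
        RMSD and the pair count.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise SuperpositionError(f"paired (N, 3) arrays required, got {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 pairs, got {n}")
    mob_center = mob.mean(axis=0)
    ref_center = ref.mean(axis=0)
    p = mob - mob_center
    q = ref - ref_center
    # collinear clouds leave a free rotation about the common axis
    singulars = np.linalg.svd(p, compute_uv=False)
    scale = singulars[0] if singulars[0] > 0 else 1.0
    if singulars[1] / scale < 1e-8:
        raise SuperpositionError("degenerate (collinear) coordinates")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_center - rotation @ mob_center
    moved = p @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd, n_pairs=n)


def point_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance in Å between two points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("points must be finite")
    return float(np.linalg.norm(a - b))


def pair_by_identity(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms sharing the same (chain, residue number, atom name) key."""
    index_b = {atom.key: atom for atom in b.atoms}
    pa, pb = [], []
    for atom in a.atoms:
        partner = index_b.get(atom.key)
        if partner is not None:
            pa.append(atom.position)
            pb.append(partner.position)
    if not pa:
        raise PairingError("no atoms share (chain, residue, name) keys")
    return np.array(pa), np.array(pb)


def pair_by_sequence_map(
    a: Structure,
    b: Structure,
    residue_map: Sequence[tuple[str, int, int, str, int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms through an explicit residue-range correspondence.

    ``residue_map`` rows are ``(chain_a, start_a, end_a, chain_b, start_b)``:
    residue ``start_a + i`` of chain_a pairs with ``start_b + i`` of chain_b
    for ``i in [0, end_a - start_a]``.  Within a residue pair, atoms sharing
    a name are paired when the residue types match; otherwise pairing falls
    back to the Cα atom alone (homologous residues of different type).
    """
    res_a: dict[tuple[str, int], list[Atom]] = {}
    for atom in a.atoms:
        res_a.setdefault((atom.chain_id, atom.residue_number), []).append(atom)
    res_b: dict[tuple[str, int], list[Atom]] = {}
    for atom in b.atoms:
        res_b.setdefault((atom.chain_id, atom.residue_number), []).append(atom)
    pa, pb = [], []
    for chain_a, start_a, end_a, chain_b, start_b in residue_map:
        for i in range(end_a - start_a + 1):
            atoms_a = res_a.get((chain_a, start_a + i))
            atoms_b = res_b.get((chain_b, start_b + i))
            if not atoms_a or not atoms_b:
                continue
            same_type = atoms_a[0].residue_name == atoms_b[0].residue_name
            lookup = {atom.atom_name: atom for atom in atoms_b}
            names = [x.atom_name for x in atoms_a] if same_type else ["CA"]
            for name in names:
                atom_a = next((x for x in atoms_a if x.atom_name == name), None)
                atom_b = lookup.get(name)
                if atom_a is not None and atom_b is not None:
                    pa.append(atom_a.position)
                    pb.append(atom_b.position)
    if not pa:
        raise PairingError("residue map produced no atom pairs")
    return np.array(pa), np.array(pb)


def rmsd_between_models(
    a: Structure,
    b: Structure,
    pairing: str = "by_identity",
    atom_scope: str = "record_class == 'protein'",
    residue_map: Sequence[tuple[str, int, int, str, int]] | None = None,
) -> float:
    """Superposed RMSD (Å) between two models over paired, scoped atoms.

    The default scope restricts to protein atoms ("all-atom" in the
    crystallographic sense: waters and ions excluded, since solvent placement
    is not comparable between independently built models).  Symmetric in its
    arguments to numerical precision.
    """
    from .core import select_atoms

    sa = select_atoms(a, atom_scope)
    sb = select_atoms(b, atom_scope)
    if not sa.atoms or not sb.atoms:
        raise PairingError("atom scope removed all atoms from one model")
    if pairing == "by_identity":
        pa, pb = pair_by_identity(sa, sb)
    elif pairing == "by_sequence_map":
        if residue_map is None:
            raise ValueError("pairing='by_sequence_map' requires residue_map")
        pa, pb = pair_by_sequence_map(sa, sb, residue_map)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if len(pa) < 3:
        raise PairingError(f"only {len(pa)} atom pairs; need at least 3")
    return kabsch_superpose(pa, pb).rmsd
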