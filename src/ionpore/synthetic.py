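"""Synthetic study inputs with recorded ground truth.

Three generators emulate the study's data so every pipeline stage can be
tested without downloads:

* :func:`make_toy_channel` — a pseudo-symmetric two- or four-chain ring
  bundle whose analytic minimum pore radius is a parameter (1.7 Å mimics
  the open-state isoleucine constriction, 0.5 Å the closed state);
* :func:`paired_ion_maps` — a K+-like / Cs+-like density-map pair sharing
  solvent positions, with ion blobs ~3x stronger in the partner map
  (differential cation scattering) and water blobs equal, the partner map
  noisier (as the lower-resolution Cs+ reconstructions were);
* :func:`simulate_iv` — whole-cell I-V families from a known permeability
  ratio via the bi-ionic GHK relation with multiplicative noise.

Every generator is deterministic for a fixed seed and returns a
:class:`ScenarioTruth` recording the generating parameters verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Atom, DensityMap, Structure
from .selectivity import (
    PROTOCOL_VOLTAGES, BiIonicCondition, IVFamily, IVRecord,
)

__all__ = [
    "ScenarioTruth",
    "GeometryError",
    "PlacementError",
    "make_toy_channel",
    "paired_ion_maps",
    "simulate_iv",
    "DEFAULT_SIGMA_PRIMARY",
    "DEFAULT_SIGMA_PARTNER",
]

# Peak-detection thresholds matched to the default map regime: waters sit
# near 15-22 sigma in the primary map and near 9 sigma in the noisier
# partner map, ions near 20 sigma (primary) and 25-36 sigma (partner).
DEFAULT_SIGMA_PRIMARY = 12.0
DEFAULT_SIGMA_PARTNER = 14.0

_CARBON_VDW = 1.70
_RING_SPACING = 2.0     # Å between obstacle rings along the axis
_ARC_SPACING = 2.0      # Å between adjacent atoms around a ring


class GeometryError(ValueError):
    """Requested toy-channel geometry is impossible."""


class PlacementError(ValueError):
    """Solvent blobs cannot be placed inside the pore / grid."""


@dataclass
class ScenarioTruth:
    """Ground truth recorded alongside every generated artifact."""

    seed: int
    ion_positions: list[np.ndarray] = field(default_factory=list)
    water_positions: list[np.ndarray] = field(default_factory=list)
    amplitude_ratio: float | None = None
    constriction_radius: float | None = None
    true_erev: float | None = None     # mV

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "ion_positions": [list(map(float, p)) for p in self.ion_positions],
            "water_positions": [list(map(float, p)) for p in self.water_positions],
            "amplitude_ratio": self.amplitude_ratio,
            "constriction_radius": self.constriction_radius,
            "true_erev": self.true_erev,
        }


def _pore_radius(z: float, constriction: float, flare: float) -> float:
    return constriction + flare * z * z


def make_toy_channel(
    n_chains: int = 2,
    constriction_radius: float = 1.7,
    length: float = 45.0,
    seed: int = 0,
    flare_height: float = 4.5,
) -> tuple[Structure, ScenarioTruth]:
    """Ring-bundle channel with an exact analytic minimum pore radius.

    Carbon obstacle atoms are arranged on rings around the z axis; the ring
    at z = 0 has radius ``constriction_radius + vdW(C)``, so the largest
    probe sphere centred on the axis there has radius exactly
    ``constriction_radius``.  Rings widen quadratically toward the mouths
    by ``flare_height`` Å.  Atoms are grouped into ``n_chains`` chains by
    angular sector, giving exact n-fold rotational symmetry.
    """
    if n_chains not in (2, 4):
        raise GeometryError(f"n_chains must be 2 or 4, got {n_chains}")
    if constriction_radius < 0:
        raise GeometryError("constriction_radius must be non-negative")
    if constriction_radius > 8.0:
        raise GeometryError(f"constriction_radius {constriction_radius} Å exceeds the bundle")
    half = length / 2.0
    flare = flare_height / (half * half)
    n_half_rings = int(np.floor(half / _RING_SPACING))
    ring_z = np.arange(-n_half_rings, n_half_rings + 1) * _RING_SPACING

    atoms: list[Atom] = []
    for ring_index, z in enumerate(ring_z):
        wall_radius = _pore_radius(z, constriction_radius, flare) + _CARBON_VDW
        per_chain = max(4, int(np.ceil(2 * np.pi * wall_radius / _ARC_SPACING / n_chains)))
        n_atoms = per_chain * n_chains
        twist = 0.3 * ring_index  # deterministic helical wind
        resname = "ILE" if abs(z) <= 1.0 else "LEU"
        for k in range(n_atoms):
            angle = twist + 2 * np.pi * k / n_atoms
            chain = chr(ord("A") + (k // per_chain))
            atoms.append(Atom(
                element="C",
                atom_name=f"C{k % per_chain + 1}",
                residue_name=resname,
                residue_number=30 + ring_index,
                chain_id=chain,
                position=np.array([wall_radius * np.cos(angle),
                                   wall_radius * np.sin(angle), z]),
                occupancy=1.0,
                b_factor=30.0,
            ))
    structure = Structure(
        atoms=atoms,
        label=f"toy-channel-r{constriction_radius:g}",
        condition="synthetic",
        repeat_annotations={("A", 30, 30 + 2 * n_half_rings): "repeatI"},
    )
    truth = ScenarioTruth(seed=seed, constriction_radius=constriction_radius)
    return structure, truth


def _solvent_positions(
    n_ions: int,
    n_waters: int,
    constriction: float,
    flare: float,
    length: float,
    rng: np.random.Generator,
    min_separation: float = 3.0,
    clearance_margin: float = 0.8,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Deterministic non-overlapping solvent placement inside the pore.

    Ions sit on (or very near) the axis, evenly spread along the central
    half of the pore; waters fill vestibule candidates (rings of four in
    the wide mouths, lateral singles elsewhere) greedily, keeping at least
    ``min_separation`` Å between any two blobs and ``clearance_margin`` +
    exclusion reach away from the wall.  Mirrors the study's layout: ions
    along the conduction axis, ordered waters layered around them.
    """
    half = length / 2.0
    span = 0.55 * length / 2.0
    if n_ions == 0:
        ion_z = np.array([])
    elif n_ions == 1:
        ion_z = np.array([0.0])
    else:
        ion_z = np.linspace(-span, span, n_ions)
    ions = []
    for z in ion_z:
        jitter = rng.uniform(-0.3, 0.3, size=2)
        ions.append(np.array([jitter[0], jitter[1], z]))

    chosen: list[np.ndarray] = list(ions)

    def admissible(p: np.ndarray) -> bool:
        return all(np.linalg.norm(p - q) >= min_separation for q in chosen)

    # candidate list ordered from the roomy mouths inward
    candidates: list[np.ndarray] = []
    z_grid = np.arange(np.floor(0.85 * half), -np.floor(0.85 * half) - 0.5, -1.0)
    z_grid = z_grid[np.argsort(-np.abs(z_grid), kind="stable")]
    for iz, z in enumerate(z_grid):
        # maximal radial offset keeping the blob core clear of wall carving
        rho_max = _pore_radius(z, constriction, flare) - clearance_margin
        if rho_max >= 2.2:
            phase = rng.uniform(0, 2 * np.pi)
            for k in range(4):
                angle = phase + k * np.pi / 2
                candidates.append(np.array([2.2 * np.cos(angle), 2.2 * np.sin(angle), z]))
        elif rho_max >= 0.9:
            angle = rng.uniform(0, 2 * np.pi)
            sign = 1 if iz % 2 == 0 else -1
            candidates.append(np.array([sign * 0.9 * np.cos(angle),
                                        sign * 0.9 * np.sin(angle), z]))
        elif rho_max >= 0.0:
            candidates.append(np.array([0.0, 0.0, z]))
    waters: list[np.ndarray] = []
    for cand in candidates:
        if len(waters) == n_waters:
            break
        if admissible(cand):
            waters.append(cand)
            chosen.append(cand)
    if len(waters) < n_waters:
        raise PlacementError(
            f"could only place {len(waters)} of {n_waters} waters inside the pore; "
            f"widen the channel or reduce n_waters")
    return ions, waters


def _render_blobs(
    grid: np.ndarray,
    origin: np.ndarray,
    voxel: float,
    centers: Sequence[np.ndarray],
    amplitudes: Sequence[float],
    width: float,
) -> None:
    """Add Gaussian blobs (peak height = amplitude) in place."""
    n = np.array(grid.shape)
    reach = int(np.ceil(4 * width / voxel))
    for center, amp in zip(centers, amplitudes):
        idx = (np.asarray(center) - origin) / voxel
        lo = np.maximum(np.floor(idx).astype(int) - reach, 0)
        hi = np.minimum(np.floor(idx).astype(int) + reach + 1, n)
        if np.any(lo >= n) or np.any(hi <= 0):
            raise PlacementError(f"blob at {center} lies outside the grid")
        ax = [np.arange(lo[d], hi[d]) * voxel + origin[d] - center[d] for d in range(3)]
        dx2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(-dx2 / (2 * width * width))


def paired_ion_maps(
    structure: Structure | None = None,
    n_ions: int = 4,
    n_waters: int = 12,
    amplitude_ratio: float = 3.0,
    voxel: float = 0.6,
    blob_width: float = 0.6,
    noise_sd: float = 0.3,
    partner_noise_sd: float = 2.0,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (80, 80, 80),
    protein_amplitude: float = 0.6,
    water_amplitude: float = 1.0,
    ion_amplitude: float = 1.3,
) -> tuple[DensityMap, DensityMap, ScenarioTruth]:
    """Paired density maps in two cation conditions with shared solvent sites.

    Both maps contain identical Gaussian protein density and blobs at the
    same solvent positions; ion blobs are ``amplitude_ratio`` times taller
    in the partner map (Cs+-like condition) while water blobs are equal.
    ``noise_sd`` / ``partner_noise_sd`` set additive Gaussian noise as a
    fraction of each map's noiseless standard deviation — the partner map
    is noisier by default, emulating its lower-resolution reconstruction,
    which is what pushes waters below the partner detection threshold
    while ions remain far above it.
    """
    if n_ions < 0 or n_waters < 0:
        raise ValueError("n_ions and n_waters must be non-negative")
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    if amplitude_ratio <= 0:
        raise ValueError("amplitude_ratio must be positive")
    rng = np.random.default_rng(seed)
    if structure is None:
        structure, _ = make_toy_channel(seed=seed)
    coords = structure.coordinates()
    center = coords.mean(axis=0)
    n = np.array(grid_shape)
    origin = center - (n - 1) * voxel / 2.0

    # pore geometry of the default toy channel, used for solvent placement
    length = float(coords[:, 2].max() - coords[:, 2].min())
    radial = np.linalg.norm(coords[:, :2] - center[None, :2], axis=1)
    constriction = float(radial.min() - _CARBON_VDW)
    flare_height = float(radial.max() - _CARBON_VDW - constriction)
    flare = flare_height / (length / 2.0) ** 2
    ions, waters = _solvent_positions(n_ions, n_waters, constriction, flare, length, rng)
    ions = [p + center for p in ions]
    waters = [p + center for p in waters]

    base = np.zeros(tuple(n), dtype=np.float64)
    _render_blobs(base, origin, voxel, coords, [protein_amplitude] * len(coords), blob_width)
    _render_blobs(base, origin, voxel, waters, [water_amplitude] * len(waters), blob_width)

    primary = base.copy()
    _render_blobs(primary, origin, voxel, ions, [ion_amplitude] * len(ions), blob_width)
    partner = base.copy()
    _render_blobs(partner, origin, voxel, ions,
                  [ion_amplitude * amplitude_ratio] * len(ions), blob_width)

    rng_primary, rng_partner = rng.spawn(2)
    primary += rng_primary.normal(0.0, noise_sd * primary.std(), size=primary.shape)
    partner += rng_partner.normal(0.0, partner_noise_sd * partner.std(), size=partner.shape)

    voxel3 = np.full(3, voxel)
    map_primary = DensityMap(grid=primary, voxel_size=voxel3, origin=origin)
    map_partner = DensityMap(grid=partner, voxel_size=voxel3, origin=origin)
    truth = ScenarioTruth(
        seed=seed,
        ion_positions=ions,
        water_positions=waters,
        amplitude_ratio=amplitude_ratio,
        constriction_radius=constriction,
    )
    return map_primary, map_partner, truth


def simulate_iv(
    condition: BiIonicCondition | None = None,
    true_ratio: float = 9.0,
    conductance: float = 10.0,
    noise_frac: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    label: str = "synthetic",
) -> tuple[IVFamily, ScenarioTruth]:
    """I-V family from a known permeability ratio via the bi-ionic relation.

    The true reversal potential is ``-(RT/F) ln(ratio * [X]int / [Y]ext)``
    and currents follow a linear conductance model
    ``I(V) = g_r (V - Erev)(1 + eps)`` with per-point multiplicative noise
    of relative sd ``noise_frac`` and a per-replicate conductance spread of
    ~20%, sampled at the 11-step protocol (-100..+100 mV in 20 mV steps).

    ``conductance`` is pA/mV (so ~1.5 nA at +100 mV for an Erev of -55 mV).
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if condition is None:
        condition = BiIonicCondition()
    rng = np.random.default_rng(seed)
    erev_true = -condition.thermal_voltage_mV * np.log(
        true_ratio * condition.conc_internal / condition.conc_external)
    records = []
    for rep in range(1, n_replicates + 1):
        g = conductance * rng.lognormal(mean=0.0, sigma=0.2)
        for v in PROTOCOL_VOLTAGES:
            eps = rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0
            current = g * (v - erev_true) * (1.0 + eps)
            records.append(IVRecord(voltage=float(v), current=float(current), replicate=rep))
    family = IVFamily(condition=condition, records=records, label=label)
    truth = ScenarioTruth(seed=seed, amplitude_ratio=None, true_erev=float(erev_true))
    return family, truth
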