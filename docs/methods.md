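# Methods

`ionpore` implements three analyses that together characterise how an ion
channel conducts and selects cations, plus generators that emulate their
inputs with known ground truth.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish about real data.

## Pore geometry: probe-radius profiling

The pore radius at a position *z* along a chosen channel axis is defined as
the radius of the largest sphere, centred in the plane perpendicular to the
axis at *z*, that overlaps no protein van der Waals sphere (the HOLE/CHAP
convention).  Waters and ions are excluded from the obstacle set, so the
profile describes the protein-walled pore.  Formally the radius at *z* is

    r(z) = max_{c in plane(z)}  min_i ( |c - x_i| - rho_i )

with atom centres `x_i` and vdW radii `rho_i` (Bondi-style table shipped in
`ionpore.pore.VDW_RADII`; carbon 1.70 Å, default 1.70 Å for unlisted
elements).

The in-plane maximisation uses Nelder–Mead from multiple starts: the
previous plane's centre, the axis point, and `n_starts` (default 8)
seeded-random offsets within `max_offset` (2 Å).  Convergence tolerance is
0.01 Å in the centre position.  A quadratic penalty keeps the centre within
`max_center_offset` (3 Å) of the axis — without it the search can escape
between wall atoms into bulk solvent, where the clearance is larger than
anywhere in the pore.  This bound also means the profiler reports the
*axial* pore; channels whose conduction path meanders more than ~3 Å off
the supplied axis need a piecewise axis.  Clearances above `radius_cap`
(10 Å) are reported as the cap with a `capped` flag: they mark bulk solvent,
not a measured pore radius.  For a fixed seed the profile is fully
deterministic.

On analytic geometries (rings, stacked cylinders) the profiler agrees with
the closed-form clearance `ring radius − vdW` to well under 0.05 Å (the
test suite checks 20 such cases).  Agreement with published CHAP profiles
of real structures is expected at the ~0.2 Å level, not bit-exact, because
the exact vdW table and annealing schedule of CHAP are not reproduced here.

Hydrophobicity annotation assigns each profile sample the mean
Kyte–Doolittle hydropathy of residues having any atom within
`lining_cutoff` (default 6 Å) of the probe centre; residues missing from
the scale score 0.0 with a warning.  `min_constriction` returns the global
radius minimum in a window, breaking ties toward smaller *z* (the
cytoplasmic end under this package's axis convention).

## Ion-site assignment by differential cation scattering

Cs⁺ scatters electrons roughly three times more strongly than K⁺.  If a
channel binds the two ions at the same sites, a density feature present in
maps determined in *both* cation conditions — and stronger in Cs⁺ — is an
ion-binding site, while a feature present only in the K⁺ map is an ordered
water.  The pipeline operationalises this:

1. **σ-scaling.** Each map is standardised over the full grid
   (EMDB visualisation convention, no masking): value → (value − mean)/sd.
   Raw statistics are kept so peak amplitudes can be reported in raw units.
2. **Peak extraction.** Voxels ≥ threshold are kept, voxels within
   `exclusion_radius` (default 1.8 Å) of any protein atom are removed, an
   optional cylindrical mask (default radius 8 Å around the pore axis)
   restricts the analysis to the permeation pathway, and 26-connected
   components become `DensityPeak`s with intensity-weighted centroids.
3. **Matching.** One-to-one across the two maps, by shared suprathreshold
   voxels (`voxel_overlap`, the default, requiring a common grid) or by
   mutual-nearest centroids within 1.5 Å.  Ties resolve by larger overlap /
   smaller distance, then higher partner peak height.
4. **Classification.** Matched → ion (labels K1… ordered along the axis);
   unmatched primary-map peaks → water.  Each ion site carries an amplitude
   ratio: partner peak raw amplitude over primary peak raw amplitude, ~3
   for a genuine cation site in a K⁺/Cs⁺ pair.

Whether an elongated feature is one peak or two depends on the threshold;
the pipeline reports the component count at the given threshold rather than
deciding occupancy.

## Bi-ionic selectivity

With cation X inside at `[X]int` and cation Y outside at `[Y]ext`, the
reversal potential fixes the permeability ratio through the bi-ionic form
of the GHK voltage equation:

    P_X / P_Y = ([Y]ext / [X]int) · exp( −E_rev · F / (R·T) )

Erev is estimated per replicate as the zero-crossing of the I-V relation,
linearly interpolated between the two bracketing voltage steps of the
−100…+100 mV / 20 mV protocol; the family value is the replicate mean ± sem.
Linear interpolation (not spline fitting) is deliberate: it is robust on an
11-point protocol and cannot overshoot.  No sign change raises an error and
the construct is flagged non-functional in `selectivity_table` rather than
dropped; multiple crossings raise an ambiguity error listing them.
Normalisation divides each replicate by its own +100 mV current.

The recording temperature defaults to 298.15 K (RT/F ≈ 25.69 mV) and is a
parameter; at any room temperature in 293–300 K, −55 mV maps to a ratio
rounding to 9 and −65 mV to 13.  No background-current subtraction is
performed: endogenous currents therefore make measured ratios *lower*
bounds on channel selectivity, a known limitation of the whole-cell
configuration.

## Rigid superposition

`kabsch_superpose` solves the least-squares superposition by SVD of the
3×3 covariance, with the determinant correction that forbids reflections;
collinear inputs (second singular value ≈ 0) are rejected as
underdetermined.  `rmsd_between_models` defaults to protein atoms only —
solvent placement is not comparable between independently built models —
paired by identical (chain, residue, atom name) keys, or through an
explicit residue-range offset map for internal-repeat comparisons, falling
back to Cα atoms where the paired residues differ in type.

## Synthetic data: what it emulates and what it does not

**Toy channel.** Carbon rings stacked every 2 Å along z, ring radius
`constriction + flare·z²` + vdW, so the analytic minimum pore radius *is*
the `constriction_radius` parameter (1.7 Å mimics the open isoleucine gate,
0.5 Å the closed one).  Atoms are grouped into 2 or 4 chains by angular
sector, giving exact rotational symmetry; the constriction ring is typed
ILE and the rest LEU so lining reports name the gate.

**Paired maps.** Gaussian density (peak amplitude: protein 0.6, water 1.0,
ion 1.3; width 0.6 Å) on an 80³ grid of 0.6 Å voxels.  Ion blobs are
scaled ×3 in the partner map; water blobs are identical in both.  Additive
Gaussian noise is 0.3× the structural sd in the primary map and 2.0× in the
partner map, reflecting the lower-resolution second-condition
reconstruction.  The voxel size matters: at 1 Å voxels the sub-voxel
attenuation of 0.6 Å-wide peaks varies by ~35%, smearing the water and ion
σ-bands into each other; at 0.6 Å the bands are cleanly separated — waters
sit near 15–22σ in the primary map and near 9σ in the noisier partner,
ions near 20–27σ and 25–35σ.  The bundled default thresholds
(12σ primary / 14σ partner) sit in the gaps with multi-sigma noise margins;
for real deposited map pairs the thresholds are whatever the maps warrant
and the CLI defaults to the conventional 12/8.  Solvent positions are
placed deterministically (ions near-axis, waters in vestibule rings and
lateral singles) with ≥3 Å mutual separation and clearance from the wall
carving — comparable to the ~3.1–3.4 Å ion-water distances seen in real
channel pores.

Not emulated: CTF effects, radiation damage, B-factor heterogeneity,
conformational mixing, or solvent disorder.  Passing the recovery tests
therefore demonstrates the *logic* of the dual-map procedure (extraction,
matching, classification, amplitude recovery) under controlled SNR, not
performance on experimental maps; the deposition checks script exists for
that purpose.

**I-V families.** Linear conductance `I = g_r (V − Erev)(1+ε)` with
`Erev = −(RT/F) ln(ratio·[X]int/[Y]ext)`, per-point multiplicative noise
(default 5% relative sd), and a ~20% lognormal conductance spread across
replicates.  Real bi-ionic curves rectify (GHK curvature); a linear model
exercises zero-crossing estimation identically and keeps the truth in
closed form.  Recovery across true ratios {1, 3, 9, 13, 36} with 3
replicates and 5% noise shows median relative ratio errors well under 10%
(the error grows with |Erev| because the ratio is exponential in it —
recovering a ratio of 36 to 10% needs Erev to ~2.4 mV).

## Problem sizes and determinism

Default problem sizes — 80³ voxel maps, ~400-atom toy channels, 21–90-plane
profiles, 11-point I-V protocols — run the full test suite in seconds.
Every stochastic component (probe restarts, map noise, I-V noise, jitter)
draws from a `numpy` Generator seeded from a single user-visible seed, and
identical seeds reproduce byte-identical PDB/MRC/CSV/JSON artifacts;
re-running a pipeline config is a no-op diff apart from nothing at all
(reports carry no timestamps).

## Known limitations

* The profiler's axis must be supplied or estimated; the built-in estimate
  (principal covariance axis) assumes the bundle is longer along the pore
  than across it, which holds for membrane channels but not generally.
* Voxel-overlap matching requires both maps on the same grid; use centroid
  matching (after superposing the models) otherwise.
* Altloc handling keeps only the highest-occupancy conformer; multi-model
  files use the first model.
* No liquid-junction correction, leak subtraction, or GHK current fitting.
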