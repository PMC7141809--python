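"""Bi-ionic whole-cell I-V analysis: normalisation, reversal potential, permeability.

Under bi-ionic conditions (cation X inside at [X]int, cation Y outside at
[Y]ext) the zero-current voltage Erev fixes the relative permeability via
the bi-ionic form of the Goldman-Hodgkin-Katz voltage equation:

    P_X / P_Y = ([Y]ext / [X]int) * exp(-Erev * F / (R * T))

A channel preferring the internal cation X reverses at negative voltages,
giving a ratio above 1.  With equal 150 mM concentrations at room
temperature, Erev = -55 mV corresponds to P_X/P_Y ~ 9 and -65 mV to ~ 13.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants

__all__ = [
    "BiIonicCondition",
    "IVFamily",
    "IVRecord",
    "SelectivityResult",
    "NormalizationError",
    "ReversalEstimationError",
    "normalize_iv",
    "estimate_erev",
    "permeability_ratio",
    "selectivity_table",
    "read_iv_table",
    "PROTOCOL_VOLTAGES",
]

FARADAY = constants.value("Faraday constant")          # C/mol
GAS_CONSTANT = constants.R                              # J/(mol K)

#: Voltage-step protocol: -100 to +100 mV in 20 mV increments (11 steps).
PROTOCOL_VOLTAGES = tuple(range(-100, 101, 20))

_REFERENCE_VOLTAGE = 100.0  # mV; normalisation reference step


class NormalizationError(ValueError):
    """A replicate is missing or has a degenerate +100 mV reference current."""


class ReversalEstimationError(ValueError):
    """No or ambiguous zero-crossing in a replicate's I-V relation."""


@dataclass(frozen=True)
class BiIonicCondition:
    """Bi-ionic recording configuration: X inside, Y outside."""

    species_internal: str = "K"
    species_external: str = "Na"
    conc_internal: float = 150.0   # mM
    conc_external: float = 150.0   # mM
    temperature: float = 298.15    # K

    def __post_init__(self) -> None:
        if self.conc_internal <= 0 or self.conc_external <= 0:
            raise ValueError("concentrations must be positive")
        if not 250.0 <= self.temperature <= 330.0:
            raise ValueError(f"temperature {self.temperature} K outside the plausible "
                             f"recording range [250, 330]")

    @property
    def thermal_voltage_mV(self) -> float:
        """RT/F in millivolts (~25.7 mV at 298.15 K)."""
        return 1000.0 * GAS_CONSTANT * self.temperature / FARADAY


@dataclass(frozen=True)
class IVRecord:
    voltage: float     # mV
    current: float     # pA (or normalised units)
    replicate: int


@dataclass
class IVFamily:
    """Voltage-clamp records for one construct under one bi-ionic condition."""

    condition: BiIonicCondition
    records: list[IVRecord]
    normalized: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        voltages = {r.voltage for r in self.records}
        if len(voltages) < 2:
            raise ValueError("an I-V family needs at least 2 distinct voltages")
        if any(abs(v) > 150 for v in voltages):
            raise ValueError("voltages outside [-150, +150] mV")

    @property
    def replicates(self) -> list[int]:
        return sorted({r.replicate for r in self.records})

    def replicate_curve(self, replicate: int) -> tuple[np.ndarray, np.ndarray]:
        recs = sorted((r for r in self.records if r.replicate == replicate),
                      key=lambda r: r.voltage)
        return (np.array([r.voltage for r in recs]),
                np.array([r.current for r in recs]))


@dataclass(frozen=True)
class SelectivityResult:
    label: str
    erev: float | None           # mV
    erev_sem: float | None       # mV
    ratio: float | None          # P_int / P_ext
    n_replicates: int
    functional: bool = True


def normalize_iv(family: IVFamily) -> IVFamily:
    """Divide each replicate's currents by its own +100 mV current.

    Matches the convention of normalising each experiment to its maximum
    current at the +100 mV step; replicates are scaled independently.
    """
    scale: dict[int, float] = {}
    for rep in family.replicates:
        refs = [r.current for r in family.records
                if r.replicate == rep and math.isclose(r.voltage, _REFERENCE_VOLTAGE)]
        if not refs:
            raise NormalizationError(f"replicate {rep}: no +100 mV record")
        if refs[0] == 0:
            raise NormalizationError(f"replicate {rep}: zero current at +100 mV")
        scale[rep] = refs[0]
    records = [replace(r, current=r.current / scale[r.replicate]) for r in family.records]
    return IVFamily(condition=family.condition, records=records,
                    normalized=True, label=family.label)


def _replicate_erev(voltages: np.ndarray, currents: np.ndarray, replicate: int) -> float:
    """Zero-crossing of one replicate by linear interpolation between steps."""
    crossings = []
    for i in range(len(voltages) - 1):
        i0, i1 = currents[i], currents[i + 1]
        if i0 == 0.0:
            crossings.append(float(voltages[i]))
        elif i0 * i1 < 0:
            frac = -i0 / (i1 - i0)
            crossings.append(float(voltages[i] + frac * (voltages[i + 1] - voltages[i])))
    if currents[-1] == 0.0:
        crossings.append(float(voltages[-1]))
    if not crossings:
        raise ReversalEstimationError(
            f"replicate {replicate}: current does not change sign in "
            f"[{voltages.min():g}, {voltages.max():g}] mV")
    if len(crossings) > 1:
        raise ReversalEstimationError(
            f"replicate {replicate}: multiple zero crossings at "
            f"{', '.join(f'{c:.1f}' for c in crossings)} mV")
    return crossings[0]


def estimate_erev(family: IVFamily) -> tuple[float, float]:
    """Reversal potential of a family: mean of per-replicate zero-crossings.

    Each replicate's Erev is the linear interpolation between the two
    voltage steps bracketing the sign change; the family value is the mean
    across replicates with its standard error (0 for a single replicate).
    """
    per_replicate = []
    for rep in family.replicates:
        voltages, currents = family.replicate_curve(rep)
        per_replicate.append(_replicate_erev(voltages, currents, rep))
    values = np.array(per_replicate)
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(values.mean()), sem


def permeability_ratio(erev_mV: float, condition: BiIonicCondition) -> float:
    """P_X/P_Y from the reversal potential (bi-ionic GHK voltage relation).

    ratio = ([Y]ext / [X]int) * exp(-Erev * F / (R * T)), Erev in volts
    internally.  Swapping species/concentrations and negating Erev returns
    the reciprocal.
    """
    exponent = -(erev_mV / 1000.0) * FARADAY / (GAS_CONSTANT * condition.temperature)
    return (condition.conc_external / condition.conc_internal) * math.exp(exponent)


def selectivity_table(
    families: Sequence[IVFamily],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per construct: Erev +/- sem, permeability ratio, replicate count.

    Families whose current never reverses within the protocol (e.g. flat
    near-zero traces from non-transfected cells) are flagged non-functional
    rather than dropped.
    """
    if not families:
        raise ValueError("selectivity_table needs at least one family")
    if labels is not None and len(labels) != len(families):
        raise ValueError("labels and families must have equal length")
    rows = []
    for i, family in enumerate(families):
        label = labels[i] if labels is not None else (family.label or f"family{i + 1}")
        try:
            erev, sem = estimate_erev(family)
            ratio = permeability_ratio(erev, family.condition)
            result = SelectivityResult(label, erev, sem, ratio,
                                       len(family.replicates), functional=True)
        except ReversalEstimationError:
            result = SelectivityResult(label, None, None, None,
                                       len(family.replicates), functional=False)
        rows.append({
            "construct": result.label,
            "erev_mV": result.erev,
            "erev_sem_mV": result.erev_sem,
            "permeability_ratio": result.ratio,
            "n_replicates": result.n_replicates,
            "functional": result.functional,
        })
    return pd.DataFrame(rows)


def read_iv_table(path: str | Path, condition: BiIonicCondition) -> dict[str, IVFamily]:
    """Read delimited I-V recordings into per-construct families.

    Expects columns ``voltage_mV, current_pA, replicate`` and optionally
    ``construct`` (defaults to a single unnamed construct).  Delimiter is
    sniffed by pandas (comma or whitespace).
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    required = {"voltage_mV", "current_pA", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "construct" not in frame.columns:
        frame["construct"] = "construct"
    families = {}
    for construct, group in frame.groupby("construct", sort=False):
        records = [IVRecord(voltage=float(r.voltage_mV), current=float(r.current_pA),
                            replicate=int(r.replicate))
                   for r in group.itertuples()]
        families[str(construct)] = IVFamily(condition=condition, records=records,
                                            label=str(construct))
    return families
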