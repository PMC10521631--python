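"""Mobility-to-CCS conversion, feature deduplication with multimodality
handling, and linear dataset alignment.

Trapped ion mobility instruments report the inverse reduced mobility 1/K0;
kinetic theory (the Mason–Schamp relation) links it to the collisional
cross-section given ion mass, charge, drift-gas mass and temperature.

Repeated identifications of one (sequence, charge) feature are fused into a
single aggregated feature. Observations farther than twice the
occurrence-weighted standard deviation from the main feature (the CCS
instance with the highest occurrence) indicate a second gas-phase
conformation: they are counted as extra modes and dropped, keeping only the
main conformer for regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import Dataset

# physical constants (SI)
_ELEMENTARY_CHARGE = 1.602176634e-19  # C
_BOLTZMANN = 1.380649e-23  # J/K
_LOSCHMIDT = 2.6867811e25  # m^-3, gas number density at 0 °C / 1 atm
_DA_TO_KG = 1.66053906660e-27


@dataclass(frozen=True)
class MobilityConstants:
    """Drift-gas context for the mobility <-> CCS conversion.

    Defaults follow timsTOF convention: nitrogen drift gas, 305 K.
    """

    gas_mass: float = 28.013  # Da
    temperature: float = 305.0  # K

    def __post_init__(self):
        if self.gas_mass <= 0 or self.temperature <= 0:
            raise ValueError("gas_mass and temperature must be positive")


@dataclass(frozen=True)
class AggregatedIon:
    """Deduplicated (sequence, charge) feature with fused CCS."""

    sequence: str
    charge: int
    mz: float
    ccs: float
    occurrence: int
    modality: str  # "unimodal" | "multimodal"
    n_modes: int
    dropped_occurrence: int = 0  # occurrence mass of secondary modes

    def __post_init__(self):
        if self.occurrence < 1 or self.n_modes < 1:
            raise ValueError("occurrence and n_modes must be >= 1")
        if (self.modality == "multimodal") != (self.n_modes >= 2):
            raise ValueError("modality label inconsistent with n_modes")


@dataclass(frozen=True)
class AlignmentShift:
    """Additive CCS shift aligning a target dataset onto a reference."""

    reference_id: str
    target_id: str
    shift: float  # Å²
    n_matched: int

    def __post_init__(self):
        if self.n_matched < 1:
            raise ValueError("shift undefined without matched pairs")


def _coefficient(charge: int, ion_mass: float, consts: MobilityConstants) -> float:
    # Mason-Schamp: CCS = 3ze/(16 N0) * sqrt(2π / (μ kB T)) * 1/K0
    mu = ion_mass * consts.gas_mass / (ion_mass + consts.gas_mass) * _DA_TO_KG
    return (
        3.0
        * charge
        * _ELEMENTARY_CHARGE
        / (16.0 * _LOSCHMIDT)
        * math.sqrt(2.0 * math.pi / (mu * _BOLTZMANN * consts.temperature))
    )


def k0_to_ccs(
    inv_k0: float, charge: int, ion_mass: float, consts: MobilityConstants | None = None
) -> float:
    """Convert inverse reduced mobility (Vs/cm²) to CCS (Å²).

    Linear in 1/K0 at fixed charge and mass; ``ccs_to_k0`` is the exact
    inverse.
    """
    if inv_k0 <= 0 or charge < 1 or ion_mass <= 0:
        raise ValueError("inv_k0, charge and ion_mass must be positive")
    consts = consts or MobilityConstants()
    # 1/K0 in Vs/cm² -> Vs/m² (1e4); CCS in m² -> Å² (1e20)
    return _coefficient(charge, ion_mass, consts) * inv_k0 * 1e4 * 1e20


def ccs_to_k0(
    ccs: float, charge: int, ion_mass: float, consts: MobilityConstants | None = None
) -> float:
    """Inverse of :func:`k0_to_ccs`: CCS (Å²) to 1/K0 (Vs/cm²)."""
    if ccs <= 0 or charge < 1 or ion_mass <= 0:
        raise ValueError("ccs, charge and ion_mass must be positive")
    consts = consts or MobilityConstants()
    return ccs / (_coefficient(charge, ion_mass, consts) * 1e4 * 1e20)


def aggregate_group(group: list[tuple[float, int]]) -> tuple[float, int, str, int, int]:
    """Fuse the CCS instances of one (sequence, charge) feature.

    ``group`` is a list of (ccs, occurrence) instances. The main feature is
    the instance with the highest occurrence (ties broken toward the lower
    CCS). Instances within 2σ of it — σ being the occurrence-weighted
    population standard deviation of the whole group — are fused into an
    occurrence-weighted mean; the remainder form additional modes and are
    dropped.

    Returns (fused ccs, fused occurrence, modality, n_modes,
    dropped occurrence mass).
    """
    if not group:
        raise ValueError("empty group")
    ccs = np.array([c for c, _ in group], dtype=float)
    occ = np.array([o for _, o in group], dtype=float)
    if np.any(ccs <= 0) or np.any(occ < 1):
        raise ValueError("ccs must be positive and occurrences >= 1")

    mean = np.average(ccs, weights=occ)
    sigma = math.sqrt(np.average((ccs - mean) ** 2, weights=occ))
    # exact-boundary cases (|Δ| = 2σ, e.g. an equal-occurrence pair) must
    # fuse; guard the ≤ comparison against representation noise
    cutoff = 2.0 * sigma * (1.0 + 1e-12) + 1e-12

    def fuse(idx: np.ndarray) -> tuple[np.ndarray, float, int]:
        # main instance among idx: highest occurrence, tie -> lower ccs
        order = sorted(idx, key=lambda i: (-occ[i], ccs[i]))
        main = order[0]
        members = idx[np.abs(ccs[idx] - ccs[main]) <= cutoff]
        fused_ccs = np.average(ccs[members], weights=occ[members])
        fused_occ = int(occ[members].sum())
        rest = np.setdiff1d(idx, members)
        return rest, float(fused_ccs), fused_occ

    remaining = np.arange(len(group))
    remaining, main_ccs, main_occ = fuse(remaining)
    n_modes = 1
    dropped = 0
    while remaining.size:
        remaining, _, mode_occ = fuse(remaining)
        n_modes += 1
        dropped += mode_occ
    modality = "multimodal" if n_modes >= 2 else "unimodal"
    return main_ccs, main_occ, modality, n_modes, dropped


def deduplicate(ds: Dataset) -> Dataset:
    """Aggregate records into one :class:`AggregatedIon` per (sequence, charge).

    Identical (sequence, charge, ccs) instances are first merged with summed
    occurrences, then the 2σ main-feature rule fuses measurement scatter and
    flags multimodal features. Total occurrence is conserved across fused and
    dropped modes.
    """
    groups: dict[tuple[str, int], dict[float, int]] = {}
    mzs: dict[tuple[str, int], float] = {}
    order: list[tuple[str, int]] = []
    for rec in ds.records:
        if rec.ccs is None:
            raise ValueError("deduplicate requires CCS on every record")
        key = (rec.sequence, rec.charge)
        if key not in groups:
            groups[key] = {}
            mzs[key] = rec.mz
            order.append(key)
        groups[key][rec.ccs] = groups[key].get(rec.ccs, 0) + rec.occurrence

    out = Dataset(
        source_id=ds.source_id,
        drift_gas=ds.drift_gas,
        temperature=ds.temperature,
        alignment_shift=ds.alignment_shift,
    )
    for key in order:
        instances = list(groups[key].items())
        ccs, occ, modality, n_modes, dropped = aggregate_group(instances)
        out.records.append(
            AggregatedIon(
                sequence=key[0],
                charge=key[1],
                mz=mzs[key],
                ccs=ccs,
                occurrence=occ,
                modality=modality,
                n_modes=n_modes,
                dropped_occurrence=dropped,
            )
        )
    return out


def multimodal_fraction(ds: Dataset) -> float:
    """Fraction of aggregated features flagged multimodal."""
    if not ds.records:
        return 0.0
    flagged = sum(1 for r in ds.records if getattr(r, "modality", "") == "multimodal")
    return flagged / len(ds.records)


def align_datasets(
    target: Dataset, reference: Dataset, weighted: bool = False
) -> tuple[AlignmentShift, Dataset]:
    """Align a target dataset onto a reference by an additive CCS shift.

    The shift is the mean difference (reference − target) of per-key mean CCS
    over (sequence, charge) pairs present in both datasets; with
    ``weighted=True`` pairs are weighted by their target occurrence. Every
    target CCS is incremented by the shift.
    """

    def key_means(ds: Dataset) -> dict[tuple[str, int], tuple[float, float]]:
        acc: dict[tuple[str, int], list[float]] = {}
        for rec in ds.records:
            if rec.ccs is None:
                continue
            acc.setdefault((rec.sequence, rec.charge), []).append(
                (rec.ccs, rec.occurrence)
            )
        return {
            k: (
                float(np.average([c for c, _ in v], weights=[o for _, o in v])),
                float(sum(o for _, o in v)),
            )
            for k, v in acc.items()
        }

    tgt, ref = key_means(target), key_means(reference)
    matched = sorted(set(tgt) & set(ref))
    if not matched:
        raise ValueError("no (sequence, charge) pairs shared between datasets")
    diffs = np.array([ref[k][0] - tgt[k][0] for k in matched])
    weights = np.array([tgt[k][1] for k in matched]) if weighted else None
    shift = float(np.average(diffs, weights=weights))

    shifted = Dataset(
        source_id=target.source_id,
        drift_gas=target.drift_gas,
        temperature=target.temperature,
        alignment_shift=target.alignment_shift + shift,
    )
    for rec in target.records:
        shifted.records.append(
            replace(rec, ccs=rec.ccs + shift if rec.ccs is not None else None)
        )
    return (
        AlignmentShift(
            reference_id=reference.source_id,
            target_id=target.source_id,
            shift=shift,
            n_matched=len(matched),
        ),
        shifted,
    )
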