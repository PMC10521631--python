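"""Seedable synthetic peptide-ion datasets with known ground truth.

Every generated cross-section follows the same structural decomposition the
predictor assumes:

    ccs = w_c * sqrt(mz) + b_c + Σ_token effect(token) + N(0, σ)

so parameter and sign recovery by the downstream modules is checkable against
recorded truth. Defaults emulate timsTOF-like tryptic data: per-charge
square-root curves with slope growing with charge, a few Å² of measurement
noise, occurrence counts of a handful of PSMs per feature, and a small
fraction of features carrying a second gas-phase conformation.

The phospho token effect defaults to −25 Å². The net observed difference
between a phosphopeptide and its unmodified counterpart also includes the
baseline increase from the +80 Da mass (≈ +13…15 Å² at charges 2–4), so the
net decrease lands in the few-percent range reported for real
phosphopeptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .io_formats import Dataset, IonRecord

RESIDUE_TOKENS = tuple(chem.AMINO_ACIDS) + chem.MODIFIED_RESIDUES


def _default_sqrt_params() -> dict[int, tuple[float, float]]:
    return {1: (14.0, 80.0), 2: (17.0, 40.0), 3: (21.0, 15.0), 4: (25.0, 0.0)}


def _default_effects() -> dict[str, float]:
    return {
        "S-ph": -25.0,
        "T-ph": -25.0,
        "Y-ph": -25.0,
        "M-ox": -4.0,
        "C-cam": -2.0,
        "C-cys": -5.0,
        "<START-ac>": -3.0,
        "G": -2.5,
        "P": -3.0,
        "W": 4.0,
        "F": 3.0,
        "L": 2.5,
        "I": 2.5,
        "K": 2.0,
        "R": 2.0,
    }


def _default_charge_probs() -> dict[int, float]:
    return {1: 0.1, 2: 0.5, 3: 0.3, 4: 0.1}


@dataclass
class SyntheticTruth:
    """Generator parameters; the recorded ground truth of a synthetic run."""

    sqrt_params: dict[int, tuple[float, float]] = field(default_factory=_default_sqrt_params)
    token_effects: dict[str, float] = field(default_factory=_default_effects)
    noise_sigma: float = 5.0  # Å²
    length_range: tuple[int, int] = (7, 30)
    charge_probs: dict[int, float] = field(default_factory=_default_charge_probs)
    acetyl_prob: float = 0.1
    occurrence_range: tuple[int, int] = (2, 12)
    multimodal_fraction: float = 0.0
    mode_separation: float = 30.0  # Å²
    secondary_occurrence_ratio: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.multimodal_fraction <= 1.0:
            raise ValueError("multimodal_fraction must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate(truth: SyntheticTruth, n: int) -> tuple[Dataset, pd.DataFrame]:
    """Draw ``n`` synthetic ions and their per-ion ground-truth components.

    Sequences are drawn uniformly over the residue vocabulary within the
    stated length range; mass and m/z come from :mod:`ccspred.chem`. The
    returned frame carries per-ion baseline, summed token effect and noise.
    The same seed reproduces the same output exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(truth.seed)
    charges_avail = sorted(truth.charge_probs)
    probs = np.array([truth.charge_probs[c] for c in charges_avail], dtype=float)
    probs = probs / probs.sum()

    ds = Dataset(source_id="synthetic")
    rows = []
    lo, hi = truth.length_range
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = list(rng.choice(RESIDUE_TOKENS, size=length))
        start = chem.START_AC if rng.random() < truth.acetyl_prob else chem.START
        tokens = [start] + residues + [chem.END]
        sequence = " ".join(tokens)
        charge = int(rng.choice(charges_avail, p=probs))
        mass = chem.monoisotopic_mass(sequence)
        mz = chem.mz(mass, charge)
        w, b = truth.sqrt_params[charge]
        baseline = w * np.sqrt(mz) + b
        effect = sum(truth.token_effects.get(t, 0.0) for t in tokens)
        noise = float(rng.normal(0.0, truth.noise_sigma)) if truth.noise_sigma else 0.0
        occurrence = int(rng.integers(*truth.occurrence_range, endpoint=True))
        ds.records.append(
            IonRecord(
                sequence=sequence,
                charge=charge,
                mz=mz,
                ccs=baseline + effect + noise,
                occurrence=occurrence,
                source_id="synthetic",
            )
        )
        rows.append(
            {
                "sequence": sequence,
                "charge": charge,
                "mz": mz,
                "baseline": baseline,
                "effect": effect,
                "noise": noise,
                "ccs": baseline + effect + noise,
                "occurrence": occurrence,
            }
        )
    components = pd.DataFrame(rows)
    if truth.multimodal_fraction > 0:
        ds, injected = inject_multimodality(
            ds,
            truth.multimodal_fraction,
            truth.mode_separation,
            seed=truth.seed + 1,
            occurrence_ratio=truth.secondary_occurrence_ratio,
        )
        components.attrs["injected_keys"] = injected
    return ds, components


def inject_multimodality(
    ds: Dataset,
    fraction: float,
    separation: float,
    seed: int,
    occurrence_ratio: float = 0.3,
) -> tuple[Dataset, list[tuple[str, int]]]:
    """Give a random subset of (sequence, charge) keys a second conformer.

    Selected keys gain a duplicate record at ccs + separation whose occurrence
    is strictly below the main mode's. Returns the new dataset and the list of
    injected keys as recorded ground truth.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    out = Dataset(
        source_id=ds.source_id,
        drift_gas=ds.drift_gas,
        temperature=ds.temperature,
        alignment_shift=ds.alignment_shift,
    )
    out.records = list(ds.records)
    n_inject = int(round(fraction * len(ds.records)))
    idx = rng.choice(len(ds.records), size=n_inject, replace=False)
    injected = []
    for i in sorted(idx):
        rec = ds.records[i]
        sec_occ = max(1, int(round(occurrence_ratio * rec.occurrence)))
        sec_occ = min(sec_occ, rec.occurrence - 1) if rec.occurrence > 1 else 1
        out.records.append(
            IonRecord(
                sequence=rec.sequence,
                charge=rec.charge,
                mz=rec.mz,
                ccs=rec.ccs + separation,
                occurrence=sec_occ,
                source_id=rec.source_id,
            )
        )
        injected.append((rec.sequence, rec.charge))
    return out, injected


def emit_search_table(ds: Dataset, dialect: str, path) -> None:
    """Write a dataset as a search-engine style identification table.

    One output row per PSM observation: a record with occurrence k becomes k
    identical rows, as in real evidence tables. ``read_search_results``
    recovers sequences, charges and CCS to 6 decimals, and the deduplication
    step recovers the occurrence counts.
    """
    import csv

    if dialect == "maxquant":
        header = ["Modified sequence", "Charge", "m/z", "CCS", "1/K0", "Intensity"]
        delim = "\t"
    elif dialect == "peaks":
        header = ["Peptide", "Z", "m/z", "CCS", "1/K0", "Intensity"]
        delim = ","
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    from .preprocess import MobilityConstants, ccs_to_k0

    consts = MobilityConstants(temperature=ds.temperature)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(header)
        for rec in ds.records:
            mass = rec.mz * rec.charge - rec.charge * chem.PROTON_MASS
            inv_k0 = (
                ccs_to_k0(rec.ccs, rec.charge, mass, consts)
                if rec.ccs is not None
                else None
            )
            row = [
                chem.render(rec.sequence, dialect),
                rec.charge,
                f"{rec.mz:.6f}",
                f"{rec.ccs:.6f}" if rec.ccs is not None else "",
                f"{inv_k0:.6f}" if inv_k0 is not None else "",
                "",
            ]
            for _ in range(rec.occurrence):
                writer.writerow(row)
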