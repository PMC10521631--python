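"""Evaluation metrics: signed relative error, median absolute percent error
(overall and per charge), and correlations of sequence residuals with the
nine additive scalar descriptors.

The headline accuracy metric is the median absolute percent error (MAPE):
the spread of CCS values within a charge state grows with ion mass, so a
percent-scale, outlier-robust summary compares models more faithfully than a
mean absolute error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import chem


def relative_error(pred, obs):
    """Signed percent error 100·(pred − obs)/obs; ``obs`` must be positive."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed CCS must be positive")
    return 100.0 * (pred - obs) / obs


def mape(preds, obs) -> float:
    """Median absolute percent error."""
    preds = np.atleast_1d(np.asarray(preds, dtype=float))
    if preds.size == 0:
        raise ValueError("empty input")
    return float(np.median(np.abs(relative_error(preds, obs))))


def mape_per_charge(charges, preds, obs) -> dict[int, float]:
    """MAPE within each charge stratum."""
    charges = np.asarray(charges)
    preds = np.asarray(preds, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if not (len(charges) == len(preds) == len(obs)):
        raise ValueError("length mismatch")
    return {int(c): mape(preds[charges == c], obs[charges == c]) for c in np.unique(charges)}


def correlate_residual_descriptors(
    residuals, sequences, table=None
) -> dict[str, float]:
    """Pearson r between per-sequence residuals and each scalar descriptor.

    A zero-variance descriptor yields ``nan`` as the undefined-correlation
    marker.
    """
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(sequences):
        raise ValueError("length mismatch")
    if len(residuals) < 3:
        raise ValueError("need at least 3 sequences")
    rows = [chem.scalar_descriptors(s, table) for s in sequences]
    out = {}
    for name in chem.SCALE_NAMES:
        x = np.array([r[name] for r in rows])
        if np.std(x) == 0.0 or np.std(residuals) == 0.0:
            out[name] = float("nan")
        else:
            out[name] = float(np.corrcoef(residuals, x)[0, 1])
    return out


@dataclass
class EvalReport:
    overall_mape: float
    per_charge_mape: dict[int, float]
    relative_errors: list[float] = field(default_factory=list, repr=False)
    descriptor_correlations: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "overall_mape": self.overall_mape,
            "per_charge_mape": {str(k): v for k, v in self.per_charge_mape.items()},
            "descriptor_correlations": self.descriptor_correlations,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_predictions(charges, preds, obs, residuals=None, sequences=None) -> EvalReport:
    """Assemble the full evaluation report for a set of predictions."""
    rel = relative_error(preds, obs)
    report = EvalReport(
        overall_mape=mape(preds, obs),
        per_charge_mape=mape_per_charge(charges, preds, obs),
        relative_errors=[float(x) for x in rel],
    )
    if residuals is not None and sequences is not None:
        report.descriptor_correlations = correlate_residual_descriptors(
            residuals, sequences
        )
    return report
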