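"""Per-charge square-root CCS baseline.

For every modeled charge state c, CCS is projected from m/z alone as

    ccs_init(mz, c) = w_c * sqrt(mz) + b_c

with (w_c, b_c) obtained by closed-form linear least squares on the
transformed regressor sqrt(mz). The projection captures the dominant
mass/charge trend of peptide cross-sections; the recurrent model predicts
only the sequence-specific residual on top of it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Dataset


class FitError(ValueError):
    """Raised when a charge stratum cannot be fit."""


@dataclass
class SqrtFitParams:
    """Per-charge slope/intercept of the square-root baseline plus fit metadata."""

    w: dict[int, float] = field(default_factory=dict)  # Å² Th^-1/2
    b: dict[int, float] = field(default_factory=dict)  # Å²
    n: dict[int, int] = field(default_factory=dict)
    mae: dict[int, float] = field(default_factory=dict)

    @property
    def charges(self) -> list[int]:
        return sorted(self.w)

    def to_json(self, path) -> None:
        payload = {
            str(c): {"w": self.w[c], "b": self.b[c], "n": self.n[c], "mae": self.mae[c]}
            for c in self.charges
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SqrtFitParams":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        params = cls()
        for c, d in payload.items():
            charge = int(c)
            params.w[charge] = float(d["w"])
            params.b[charge] = float(d["b"])
            params.n[charge] = int(d.get("n", 0))
            params.mae[charge] = float(d.get("mae", 0.0))
        return params


def fit_sqrt(ds: Dataset, max_charge: int = 4) -> SqrtFitParams:
    """Fit (w_c, b_c) separately for each charge state up to ``max_charge``.

    Charges above ``max_charge`` are excluded. A charge present with fewer
    than two points cannot determine a line and raises :class:`FitError`.
    """
    by_charge: dict[int, list[tuple[float, float]]] = {}
    for rec in ds.records:
        if rec.ccs is None:
            raise ValueError("fit_sqrt requires CCS on every record")
        if rec.charge <= max_charge:
            by_charge.setdefault(rec.charge, []).append((rec.mz, rec.ccs))

    if not by_charge:
        raise FitError("no records with charge <= max_charge")

    params = SqrtFitParams()
    for charge in sorted(by_charge):
        pts = by_charge[charge]
        if len(pts) < 2:
            raise FitError(f"charge {charge}: need >= 2 points, got {len(pts)}")
        x = np.sqrt([mz for mz, _ in pts])
        y = np.array([ccs for _, ccs in pts])
        design = np.column_stack([x, np.ones_like(x)])
        (w, b), *_ = np.linalg.lstsq(design, y, rcond=None)
        if w <= 0:
            warnings.warn(
                f"charge {charge}: non-positive slope {w:.3g}; fit is not physically sensible",
                stacklevel=2,
            )
        params.w[charge] = float(w)
        params.b[charge] = float(b)
        params.n[charge] = len(pts)
        params.mae[charge] = float(np.mean(np.abs(design @ np.array([w, b]) - y)))
    return params


def predict_init(mz, charge: int, params: SqrtFitParams):
    """Baseline CCS projection w_c·sqrt(mz) + b_c.

    ``mz`` may be a scalar or array; ``charge`` must have fitted parameters.
    """
    if charge not in params.w:
        raise ValueError(f"no fitted baseline for charge {charge}")
    return params.w[charge] * np.sqrt(mz) + params.b[charge]
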