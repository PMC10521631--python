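"""CCS feature computation for PSM rescoring and percolator PIN augmentation.

Five features quantify the agreement between the observed and the predicted
cross-section of a PSM: both values themselves, their signed difference, its
absolute value, and the signed percent error. They are appended to the PIN
feature block immediately before the Peptide column; percolator then weighs
them against the search-engine scores during semi-supervised rescoring.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import PinTable

FEATURE_COLUMNS = (
    "ccs_observed",
    "ccs_predicted",
    "ccs_error",
    "ccs_abs_error",
    "ccs_perc_error",
)


@dataclass(frozen=True)
class CcsFeatureRow:
    ccs_observed: float
    ccs_predicted: float
    ccs_error: float  # observed − predicted, Å²
    ccs_abs_error: float
    ccs_perc_error: float  # signed, percent of observed

    def as_fields(self) -> list[str]:
        return [f"{getattr(self, c):.6f}" for c in FEATURE_COLUMNS]


def ccs_features(observed: float, predicted: float) -> CcsFeatureRow:
    """The five rescoring features for one observed/predicted CCS pair."""
    if observed <= 0:
        raise ValueError(f"observed CCS must be positive, got {observed}")
    error = observed - predicted
    return CcsFeatureRow(
        ccs_observed=observed,
        ccs_predicted=predicted,
        ccs_error=error,
        ccs_abs_error=abs(error),
        ccs_perc_error=100.0 * error / observed,
    )


def augment_pin(
    pin: PinTable,
    predictions: dict[tuple[str, int], tuple[float, float]],
    peptide_column: str = "Peptide",
    charge_column: str = "Charge",
    max_charge: int = 4,
) -> tuple[PinTable, dict[str, int]]:
    """Append the five CCS feature columns to a PIN table.

    ``predictions`` maps (peptide, charge) to (observed ccs, predicted ccs);
    the observed value comes from the identification table join, since PIN
    files carry no mobility. Rows with charge above ``max_charge`` are removed
    (the predictor is not trained for them), as are rows without a matching
    prediction; both counts are reported. Untouched columns are preserved
    byte-for-byte.
    """
    for col in FEATURE_COLUMNS:
        if col in pin.header:
            raise ValueError(f"PIN already carries CCS feature column {col!r}")
    if peptide_column not in pin.header or charge_column not in pin.header:
        raise ValueError(f"PIN lacks {peptide_column!r} or {charge_column!r} column")
    pep_i = pin.header.index(peptide_column)
    chg_i = pin.header.index(charge_column)

    header = pin.header[:pep_i] + list(FEATURE_COLUMNS) + pin.header[pep_i:]
    direction = None
    if pin.direction_row is not None:
        direction = (
            pin.direction_row[:pep_i] + ["0"] * 5 + pin.direction_row[pep_i:]
        )

    rows = []
    report = {"charge_filtered": 0, "unmatched": 0, "rows_out": 0}
    for row in pin.rows:
        charge = int(float(row[chg_i]))
        if charge > max_charge:
            report["charge_filtered"] += 1
            continue
        key = (row[pep_i], charge)
        if key not in predictions:
            report["unmatched"] += 1
            continue
        observed, predicted = predictions[key]
        features = ccs_features(observed, predicted).as_fields()
        rows.append(row[:pep_i] + features + row[pep_i:])
    report["rows_out"] = len(rows)
    return PinTable(header=header, rows=rows, direction_row=direction), report
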