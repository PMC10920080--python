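"""Immunohistochemistry scoring: per-sample protein status and Ki67 index.

Thresholds: p53 is lost below 5% nuclear positivity and overexpressed at or
above 30%; p16 is lost when nuclear staining is absent irrespective of
cytoplasmic staining; SMAD4 is lost only when neither nuclear nor
cytoplasmic labelling is seen. The Ki67 labelling index is banded at 10%
(low, inclusive) and 50% (high, exclusive upper bound of intermediate).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

MARKERS = ("p16", "p53", "SMAD4", "Ki67")

P53_LOSS_BELOW = 5.0
P53_OVEREXPRESSED_AT = 30.0
KI67_LOW_MAX = 10.0
KI67_HIGH_ABOVE = 50.0
KI67_MIN_CELLS = 500

#: statuses that count a sample as altered, per marker
ALTERED_STATUSES = {
    "p16": {"lost"},
    "p53": {"lost", "overexpressed"},
    "SMAD4": {"lost"},
}


@dataclass(frozen=True)
class IHCMeasurement:
    sample_id: str
    marker: str
    percent_positive: Optional[float] = None
    nuclear_stain_present: Optional[bool] = None
    cytoplasmic_stain_present: Optional[bool] = None
    positive_cells: Optional[int] = None
    cells_counted: Optional[int] = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.percent_positive is not None and not (
            0.0 <= self.percent_positive <= 100.0
        ):
            raise ValueError(f"percent_positive {self.percent_positive} outside [0, 100]")
        if self.cells_counted is not None and self.cells_counted < 0:
            raise ValueError("cells_counted must be >= 0")


@dataclass(frozen=True)
class ProteinStatus:
    sample_id: str
    marker: str
    status: str  # lost | overexpressed | normal | retained
    ki67_percent: Optional[float] = None
    ki67_band: Optional[str] = None  # low | intermediate | high

    @property
    def altered(self) -> bool:
        return self.status in ALTERED_STATUSES.get(self.marker, set())


def classify_p53(percent_positive: float) -> str:
    """< 5% nuclear immunoreactivity -> lost; >= 30% -> overexpressed.

    The [5, 30) band is reported as normal; note the region between 20% and
    30% is a convention here (sub-20% accumulation reads as normal, the band
    up to 30% is treated the same way).
    """
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError(f"percent_positive {percent_positive} outside [0, 100]")
    if percent_positive < P53_LOSS_BELOW:
        return "lost"
    if percent_positive >= P53_OVEREXPRESSED_AT:
        return "overexpressed"
    return "normal"


def classify_p16(nuclear_stain_present: bool, cytoplasmic_stain_present: bool) -> str:
    """Absent nuclear staining -> lost, irrespective of cytoplasmic staining."""
    del cytoplasmic_stain_present
    return "retained" if nuclear_stain_present else "lost"


def classify_smad4(nuclear_stain_present: bool, cytoplasmic_stain_present: bool) -> str:
    """Lost only when neither cytoplasmic nor nuclear labelling is seen."""
    if not nuclear_stain_present and not cytoplasmic_stain_present:
        return "lost"
    return "retained"


def ki67_index(positive_cells: int, cells_counted: int) -> tuple[float, str]:
    """Labelling index (percent of counted cells) and its band.

    Bands: <= 10% low, > 50% high, otherwise intermediate. A warning is
    emitted when fewer than 500 cells were counted.
    """
    if cells_counted == 0:
        raise ValueError("cells_counted must be positive")
    if not 0 <= positive_cells <= cells_counted:
        raise ValueError("need 0 <= positive_cells <= cells_counted")
    if cells_counted < KI67_MIN_CELLS:
        warnings.warn(
            f"only {cells_counted} cells counted (< {KI67_MIN_CELLS})", stacklevel=2
        )
    percent = 100.0 * positive_cells / cells_counted
    if percent <= KI67_LOW_MAX:
        band = "low"
    elif percent > KI67_HIGH_ABOVE:
        band = "high"
    else:
        band = "intermediate"
    return percent, band


def classify_measurement(m: IHCMeasurement) -> ProteinStatus:
    """Dispatch one measurement to the marker-specific rule."""
    if m.marker == "p53":
        if m.percent_positive is None:
            raise ValueError(f"{m.sample_id}: p53 needs percent_positive")
        return ProteinStatus(m.sample_id, "p53", classify_p53(m.percent_positive))
    if m.marker == "p16":
        if m.nuclear_stain_present is None:
            raise ValueError(f"{m.sample_id}: p16 needs staining flags")
        return ProteinStatus(
            m.sample_id,
            "p16",
            classify_p16(m.nuclear_stain_present, bool(m.cytoplasmic_stain_present)),
        )
    if m.marker == "SMAD4":
        if m.nuclear_stain_present is None or m.cytoplasmic_stain_present is None:
            raise ValueError(f"{m.sample_id}: SMAD4 needs both staining flags")
        return ProteinStatus(
            m.sample_id,
            "SMAD4",
            classify_smad4(m.nuclear_stain_present, m.cytoplasmic_stain_present),
        )
    if m.marker == "Ki67":
        if m.positive_cells is None or m.cells_counted is None:
            raise ValueError(f"{m.sample_id}: Ki67 needs cell counts")
        percent, band = ki67_index(m.positive_cells, m.cells_counted)
        return ProteinStatus(
            m.sample_id, "Ki67", "assessed", ki67_percent=percent, ki67_band=band
        )
    raise ValueError(f"unknown marker {m.marker!r}")


def patient_protein_status(
    statuses: Iterable[ProteinStatus], marker: str
) -> tuple[bool, bool]:
    """Patient-level (altered, discordant) for one marker.

    A patient counts as altered when ANY tumour sample is altered for the
    marker; discordance between samples is surfaced rather than hidden.
    """
    statuses = [s for s in statuses if s.marker == marker]
    if not statuses:
        raise ValueError(f"no tumour-sample statuses for marker {marker}")
    flags = [s.altered for s in statuses]
    return any(flags), len(set(flags)) > 1


def _parse_bool(value: str) -> Optional[bool]:
    if value in ("", ".", None):
        return None
    if value.lower() in {"1", "true", "yes", "y"}:
        return True
    if value.lower() in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_ihc_table(path: str | Path) -> list[IHCMeasurement]:
    """Read the IHC results TSV.

    Columns: sample_id, marker, percent_positive, nuclear_stain_present,
    cytoplasmic_stain_present, positive_cells, cells_counted (blank or '.'
    for not-applicable fields).
    """
    measurements = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample_id", "marker"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: IHC table needs columns {sorted(required)}")
        for row in reader:
            try:
                measurements.append(
                    IHCMeasurement(
                        sample_id=row["sample_id"],
                        marker=row["marker"],
                        percent_positive=(
                            float(row["percent_positive"])
                            if row.get("percent_positive") not in (None, "", ".")
                            else None
                        ),
                        nuclear_stain_present=_parse_bool(
                            row.get("nuclear_stain_present", "")
                        ),
                        cytoplasmic_stain_present=_parse_bool(
                            row.get("cytoplasmic_stain_present", "")
                        ),
                        positive_cells=(
                            int(row["positive_cells"])
                            if row.get("positive_cells") not in (None, "", ".")
                            else None
                        ),
                        cells_counted=(
                            int(row["cells_counted"])
                            if row.get("cells_counted") not in (None, "", ".")
                            else None
                        ),
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed IHC record at line {reader.line_num}: {exc}"
                ) from exc
    return measurements


def score_cohort(
    measurements: Iterable[IHCMeasurement],
    sample_sheet: dict[str, dict],
) -> tuple[list[ProteinStatus], dict[str, dict[str, dict]]]:
    """Score every measurement and aggregate to patient level.

    Returns (per-sample statuses, per-patient nested dict
    patient -> marker -> {altered, discordant, n_samples}). Normal-tissue
    samples are excluded from patient aggregation.
    """
    per_sample = [classify_measurement(m) for m in measurements]
    by_patient: dict[str, dict[str, list[ProteinStatus]]] = {}
    for status in per_sample:
        meta = sample_sheet.get(status.sample_id)
        if meta is None or meta["tissue_class"] == "normal":
            continue
        if status.marker == "Ki67":
            continue
        by_patient.setdefault(meta["patient_id"], {}).setdefault(
            status.marker, []
        ).append(status)
    patients: dict[str, dict[str, dict]] = {}
    for patient_id, by_marker in sorted(by_patient.items()):
        patients[patient_id] = {}
        for marker, statuses in sorted(by_marker.items()):
            altered, discordant = patient_protein_status(statuses, marker)
            patients[patient_id][marker] = {
                "altered": altered,
                "discordant": discordant,
                "n_samples": len(statuses),
            }
    return per_sample, patients
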