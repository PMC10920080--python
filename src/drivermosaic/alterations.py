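"""Patient x gene driver-alteration calls and cohort summary tabulations.

Integrates counted somatic mutations (distinct identity keys pooled across a
patient's tumour samples) with patient-level IHC protein status into a
combined alteration call per driver, then tabulates the cohort: per-gene
alteration counts for each source and the distribution of patients by number
of altered drivers with a per-combination breakdown.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .variants import (
    COUNTED_CONSEQUENCES,
    SampleRecord,
    identity_key,
)

DRIVER_GENES = ("KRAS", "CDKN2A", "TP53", "SMAD4")

#: IHC marker informing each gene (KRAS has no IHC readout)
MARKER_FOR_GENE = {"CDKN2A": "p16", "TP53": "p53", "SMAD4": "SMAD4"}


@dataclass(frozen=True)
class AlterationCall:
    """Per patient x gene: mutation, IHC and combined alteration status."""

    patient_id: str
    gene: str
    mutated: bool
    n_mutations: int
    mut_assessed: bool
    ihc_altered: Optional[bool]  # None = not assessed
    ihc_discordant: bool = False

    @property
    def combined_altered(self) -> bool:
        return self.mutated or bool(self.ihc_altered)

    @property
    def ihc_assessed(self) -> bool:
        return self.ihc_altered is not None


def gene_mutation_status(
    records: Iterable[SampleRecord],
    gene: str,
    ddpcr_calls: Iterable[dict] = (),
    key_mode: str = "genomic",
) -> tuple[bool, int]:
    """(mutated, n distinct mutations) for one gene across a patient's
    tumour samples.

    Counts distinct identity keys with a counted consequence (synonymous and
    intronic never count). For KRAS a positive ddPCR assay alone also sets
    ``mutated`` (with no genomic key to count).
    """
    if gene not in DRIVER_GENES:
        raise ValueError(f"unknown driver gene {gene!r}")
    keys = set()
    for record in records:
        if record.is_normal:
            continue
        for v in record.variants:
            if v.gene == gene and v.consequence in COUNTED_CONSEQUENCES:
                keys.add(identity_key(v, key_mode))
    ddpcr_positive = gene == "KRAS" and any(
        row["result"] == "positive" for row in ddpcr_calls
    )
    return (bool(keys) or ddpcr_positive, len(keys))


def build_alteration_calls(
    records_by_patient: dict[str, list[SampleRecord]],
    ihc_by_patient: Optional[dict[str, dict[str, dict]]] = None,
    ddpcr_rows: Iterable[dict] = (),
    key_mode: str = "genomic",
) -> list[AlterationCall]:
    """One AlterationCall per patient x driver gene.

    ``ihc_by_patient`` is the patient -> marker -> {altered, discordant}
    mapping from :func:`drivermosaic.ihc.score_cohort`; patients absent from
    it (or markers not stained) are marked not-assessed. Patients appearing
    only in the IHC data still receive calls (mutation side not assessed).
    """
    ihc_by_patient = ihc_by_patient or {}
    ddpcr_by_patient: dict[str, list[dict]] = {}
    for row in ddpcr_rows:
        ddpcr_by_patient.setdefault(row["patient_id"], []).append(row)

    patient_ids = sorted(set(records_by_patient) | set(ihc_by_patient))
    calls = []
    for patient_id in patient_ids:
        records = records_by_patient.get(patient_id, [])
        sequenced = any(not r.is_normal for r in records)
        ihc = ihc_by_patient.get(patient_id, {})
        for gene in DRIVER_GENES:
            if sequenced:
                mutated, n = gene_mutation_status(
                    records, gene, ddpcr_by_patient.get(patient_id, ()), key_mode
                )
            else:
                mutated, n = False, 0
            marker = MARKER_FOR_GENE.get(gene)
            marker_info = ihc.get(marker) if marker else None
            calls.append(
                AlterationCall(
                    patient_id=patient_id,
                    gene=gene,
                    mutated=mutated,
                    n_mutations=n,
                    mut_assessed=sequenced,
                    ihc_altered=None if marker_info is None else marker_info["altered"],
                    ihc_discordant=bool(marker_info and marker_info["discordant"]),
                )
            )
    return calls


def _altered_for_source(call: AlterationCall, source: str) -> Optional[bool]:
    """Alteration flag under a source, or None when the patient is not
    assessable for that gene/source (excluded from the denominator)."""
    if source == "mutation":
        return call.mutated if call.mut_assessed else None
    if source == "ihc":
        return call.ihc_altered
    if source == "combined":
        if not call.mut_assessed and not call.ihc_assessed:
            return None
        return call.combined_altered
    raise ValueError(f"unknown source {source!r}")


@dataclass
class CohortSummary:
    source: str
    n_patients: int
    gene_counts: dict[str, dict]  # gene -> {altered, n, percent}
    distribution: dict[int, dict]  # k -> {count, percent, combinations}

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "n_patients": self.n_patients,
            "genes": self.gene_counts,
            "n_altered_drivers": {
                str(k): v for k, v in sorted(self.distribution.items(), reverse=True)
            },
        }


def driver_count_distribution(
    calls: Iterable[AlterationCall], source: str = "mutation"
) -> CohortSummary:
    """Cohort summary under one source: per-gene rates plus the distribution
    of patients by number of altered drivers (4/3/2/1/0) with per-combination
    breakdown. Percentages use the source-specific denominators.
    """
    by_patient: dict[str, dict[str, Optional[bool]]] = {}
    for call in calls:
        by_patient.setdefault(call.patient_id, {})[call.gene] = _altered_for_source(
            call, source
        )

    # distribution denominator: patients assessable for at least one gene
    assessable = {
        p: flags
        for p, flags in by_patient.items()
        if any(f is not None for f in flags.values())
    }
    n_patients = len(assessable)

    gene_counts: dict[str, dict] = {}
    for gene in DRIVER_GENES:
        flags = [f[gene] for f in by_patient.values() if f.get(gene) is not None]
        denom = len(flags)
        altered = sum(flags)
        gene_counts[gene] = {
            "altered": altered,
            "n": denom,
            "percent": round(100.0 * altered / denom, 1) if denom else None,
        }

    distribution: dict[int, dict] = {
        k: {"count": 0, "percent": 0.0, "combinations": {}} for k in range(5)
    }
    for flags in assessable.values():
        altered_genes = tuple(g for g in DRIVER_GENES if flags.get(g))
        k = len(altered_genes)
        entry = distribution[k]
        entry["count"] += 1
        label = "+".join(altered_genes) if altered_genes else "none"
        entry["combinations"][label] = entry["combinations"].get(label, 0) + 1
    for entry in distribution.values():
        entry["percent"] = (
            round(100.0 * entry["count"] / n_patients, 1) if n_patients else 0.0
        )
    return CohortSummary(source, n_patients, gene_counts, distribution)


def summarize_cohort(calls: list[AlterationCall]) -> dict:
    """All three source summaries as one JSON-ready dict."""
    return {
        source: driver_count_distribution(calls, source).to_dict()
        for source in ("mutation", "ihc", "combined")
    }


# ---------------------------------------------------------------------------
# matrix rendering
# ---------------------------------------------------------------------------

_CLASS_ORDER = {
    "primary_tumour": 0,
    "abdominal_wall_met": 1,
    "liver_met": 2,
    "lymph_node_met": 3,
    "omental_met": 4,
    "peritoneal_met": 5,
    "normal": 6,
}

MATRIX_ROWS = (
    "KRAS:mut",
    "CDKN2A:mut",
    "TP53:mut",
    "SMAD4:mut",
    "p16:ihc",
    "p53:ihc",
    "SMAD4:ihc",
)


def render_matrix(
    records_by_patient: dict[str, list[SampleRecord]],
    sample_statuses: Iterable = (),
    path: str | Path | None = None,
    key_mode: str = "genomic",
) -> list[list[str]]:
    """Gene x (patient, sample) alteration matrix.

    Rows are the four mutation tracks then the three IHC tracks; columns are
    patient sample sub-columns, primary tumours first then metastases by
    tissue class, alphabetical within a class. Mutation cells hold the
    per-sample counted-mutation count, IHC cells the status code
    (lost/overexpressed/normal/retained), '.' when not assessed.
    Returns the table as rows of strings; writes TSV when ``path`` given.
    """
    ihc_by_sample: dict[str, dict[str, str]] = {}
    for status in sample_statuses:
        ihc_by_sample.setdefault(status.sample_id, {})[status.marker] = status.status

    columns: list[tuple[str, SampleRecord]] = []
    for patient_id in sorted(records_by_patient):
        samples = [r for r in records_by_patient[patient_id] if not r.is_normal]
        samples.sort(
            key=lambda r: (_CLASS_ORDER.get(r.tissue_class or "", 9), r.sample_id)
        )
        columns.extend((patient_id, r) for r in samples)

    header = ["track"] + [f"{p}:{r.sample_id}" for p, r in columns]
    class_row = ["tissue_class"] + [
        {
            "primary_tumour": "PT",
            "lymph_node_met": "LNM",
            "liver_met": "LM",
            "peritoneal_met": "PM",
            "omental_met": "OM",
            "abdominal_wall_met": "AWM",
            "normal": "N",
        }.get(r.tissue_class or "", "?")
        for _, r in columns
    ]
    rows = [header, class_row]
    for track in MATRIX_ROWS:
        name, kind = track.split(":")
        row = [track]
        for _, record in columns:
            if kind == "mut":
                keys = {
                    identity_key(v, key_mode)
                    for v in record.variants
                    if v.gene == name and v.consequence in COUNTED_CONSEQUENCES
                }
                row.append(str(len(keys)))
            else:
                row.append(ihc_by_sample.get(record.sample_id, {}).get(name, "."))
        rows.append(row)

    if path is not None:
        with open(path, "w", newline="") as handle:
            csv.writer(handle, delimiter="\t", lineterminator="\n").writerows(rows)
    return rows


def write_summary_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
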