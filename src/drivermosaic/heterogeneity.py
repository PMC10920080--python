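"""Intra- and inter-tumoural heterogeneity via the Jaccard index.

The Jaccard index of two variant sets is the ratio of shared variants to the
total of all variants (|A ∩ B| / |A ∪ B|), ranging 0 (complete heterogeneity)
to 1 (complete similarity). For sample groups the median over every possible
pairwise comparison is taken.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Optional

from .variants import (
    COUNTED_CONSEQUENCES,
    SampleRecord,
    Variant,
    identity_key,
)

SCOPES = ("intra_primary", "primary_vs_met", "inter_patient")


@dataclass
class JaccardResult:
    scope: str
    unit_id: str  # patient id or gene symbol
    #: (sample_a, sample_b, shared_count, union_count, jaccard or None)
    pairs: list[tuple[str, str, int, int, Optional[float]]] = field(
        default_factory=list
    )

    @property
    def median_jaccard(self) -> Optional[float]:
        defined = [p[4] for p in self.pairs if p[4] is not None]
        if not defined:
            return None
        return statistics.median(defined)


def jaccard(set_a: set, set_b: set, strict: bool = False) -> Optional[float]:
    """|A ∩ B| / |A ∪ B|; None (NA) when both sets are empty.

    ``strict=True`` raises on the empty/empty case instead.
    """
    union = set_a | set_b
    if not union:
        if strict:
            raise ValueError("Jaccard undefined for two empty sets")
        return None
    return len(set_a & set_b) / len(union)


def select_jaccard_geneset(
    genes: Iterable[str] = ("KRAS", "CDKN2A", "TP53", "SMAD4"),
    consequences: Iterable[str] = COUNTED_CONSEQUENCES,
    include_synonymous: bool = False,
) -> Callable[[Variant], bool]:
    """Predicate deciding which variants enter the Jaccard sets.

    Default: the four driver genes, counted consequence classes only.
    ddPCR-only calls never enter (they carry no genomic key). Synonymous
    variants can be opted in.
    """
    from .alterations import DRIVER_GENES

    genes = set(genes)
    unknown = genes - set(DRIVER_GENES)
    if unknown:
        raise ValueError(f"unknown gene name(s): {sorted(unknown)}")
    consequences = set(consequences)
    if include_synonymous:
        consequences |= {"synonymous"}

    def predicate(v: Variant) -> bool:
        return v.gene in genes and v.consequence in consequences

    return predicate


def _sample_keys(
    record: SampleRecord,
    predicate: Optional[Callable[[Variant], bool]],
    key_mode: str,
) -> set:
    return {
        identity_key(v, key_mode)
        for v in record.variants
        if predicate is None or predicate(v)
    }


def _pairwise(
    pairs: Iterable[tuple[SampleRecord, SampleRecord]],
    predicate,
    key_mode: str,
) -> list[tuple[str, str, int, int, Optional[float]]]:
    out = []
    for a, b in pairs:
        ka = _sample_keys(a, predicate, key_mode)
        kb = _sample_keys(b, predicate, key_mode)
        shared, union = len(ka & kb), len(ka | kb)
        out.append(
            (a.sample_id, b.sample_id, shared, union, jaccard(ka, kb))
        )
    return out


def patient_median_jaccard(
    records: list[SampleRecord],
    scope: str,
    patient_id: Optional[str] = None,
    predicate: Optional[Callable[[Variant], bool]] = None,
    key_mode: str = "genomic",
) -> JaccardResult:
    """Median pairwise Jaccard for one patient's samples under a scope.

    ``intra_primary`` compares all unordered primary-tumour pairs;
    ``primary_vs_met`` compares every primary-vs-metastasis pair, falling
    back to metastasis-metastasis pairs when the patient has no primary
    sample (metastasis-only patients).
    """
    records = [r for r in records if not r.is_normal]
    patient_id = patient_id or (records[0].patient_id if records else "?") or "?"
    primaries = [r for r in records if r.tissue_class == "primary_tumour"]
    mets = [r for r in records if r.tissue_class != "primary_tumour"]

    if scope == "intra_primary":
        if len(primaries) < 2:
            raise ValueError(f"insufficient samples: patient {patient_id} "
                             f"has {len(primaries)} primary tumours")
        pairs = list(combinations(sorted(primaries, key=lambda r: r.sample_id), 2))
    elif scope == "primary_vs_met":
        if primaries and mets:
            pairs = [
                (p, m)
                for p in sorted(primaries, key=lambda r: r.sample_id)
                for m in sorted(mets, key=lambda r: r.sample_id)
            ]
        elif not primaries and len(mets) >= 2:
            pairs = list(combinations(sorted(mets, key=lambda r: r.sample_id), 2))
        else:
            raise ValueError(
                f"insufficient samples: patient {patient_id} has no eligible pairs"
            )
    else:
        raise ValueError(f"unknown scope {scope!r}")

    return JaccardResult(
        scope=scope,
        unit_id=patient_id,
        pairs=_pairwise(pairs, predicate, key_mode),
    )


def intertumoural_gene_jaccard(
    records_by_patient: dict[str, list[SampleRecord]],
    gene: str,
    predicate: Optional[Callable[[Variant], bool]] = None,
    key_mode: str = "genomic",
) -> JaccardResult:
    """Median Jaccard over all cross-patient pairs of pooled per-patient
    variant sets restricted to one gene (interpretive convention mirroring
    the intra-patient median-of-pairs rule)."""
    if predicate is None:
        predicate = select_jaccard_geneset(genes=[gene])
    else:
        base = predicate
        predicate = lambda v: v.gene == gene and base(v)  # noqa: E731

    pooled: dict[str, set] = {}
    for patient_id, records in records_by_patient.items():
        tumours = [r for r in records if not r.is_normal]
        if not tumours:
            continue
        keys: set = set()
        for r in tumours:
            keys |= _sample_keys(r, predicate, key_mode)
        pooled[patient_id] = keys

    pairs = []
    for pa, pb in combinations(sorted(pooled), 2):
        ka, kb = pooled[pa], pooled[pb]
        pairs.append((pa, pb, len(ka & kb), len(ka | kb), jaccard(ka, kb)))
    return JaccardResult(scope="inter_patient", unit_id=gene, pairs=pairs)


def cohort_heterogeneity(
    records_by_patient: dict[str, list[SampleRecord]],
    predicate: Optional[Callable[[Variant], bool]] = None,
    key_mode: str = "genomic",
    genes: Iterable[str] = ("KRAS", "CDKN2A", "TP53", "SMAD4"),
) -> dict[str, list[JaccardResult]]:
    """All computable heterogeneity results for a cohort.

    Patients without enough eligible samples for a scope are skipped.
    """
    results: dict[str, list[JaccardResult]] = {
        "intra_primary": [],
        "primary_vs_met": [],
        "inter_patient": [],
    }
    for patient_id, records in sorted(records_by_patient.items()):
        for scope in ("intra_primary", "primary_vs_met"):
            try:
                results[scope].append(
                    patient_median_jaccard(
                        records, scope, patient_id, predicate, key_mode
                    )
                )
            except ValueError:
                continue
    for gene in genes:
        results["inter_patient"].append(
            intertumoural_gene_jaccard(records_by_patient, gene, predicate, key_mode)
        )
    return results


def write_heterogeneity_tables(
    results: dict[str, list[JaccardResult]],
    pairs_path: str | Path,
    summary_path: str | Path,
) -> None:
    """One row per pair (shared/union/jaccard) and one row per unit median."""
    with open(pairs_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["scope", "unit_id", "sample_a", "sample_b",
                         "shared", "union", "jaccard"])
        for scope, items in results.items():
            for res in items:
                for a, b, shared, union, j in res.pairs:
                    writer.writerow(
                        [scope, res.unit_id, a, b, shared, union,
                         "NA" if j is None else f"{j:.6g}"]
                    )
    with open(summary_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["scope", "unit_id", "n_pairs", "median_jaccard"])
        for scope, items in results.items():
            for res in items:
                med = res.median_jaccard
                writer.writerow(
                    [scope, res.unit_id, len(res.pairs),
                     "NA" if med is None else f"{med:.6g}"]
                )
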