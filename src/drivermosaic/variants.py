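"""Somatic variant ingestion, filtering and consequence classification.

Reads per-sample variant calls (VCF 4.x via pysam, or a flat TSV dialect),
normalizes alleles, applies the allele-frequency filter, subtracts matched
normals, assigns variants to the targeted genes and classifies coding
consequences against the minimal transcript models.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .transcripts import TranscriptModel, complement_base

log = logging.getLogger(__name__)

CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "synonymous",
        "intronic",
        "splice",
        "noncoding",
    }
)

#: consequence classes that count as somatic driver mutations downstream
COUNTED_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice"}
)

TISSUE_CLASSES = frozenset(
    {
        "normal",
        "primary_tumour",
        "lymph_node_met",
        "liver_met",
        "peritoneal_met",
        "omental_met",
        "abdominal_wall_met",
    }
)

#: figure-legend style abbreviations for tissue classes
TISSUE_ABBREV = {
    "normal": "N",
    "primary_tumour": "PT",
    "lymph_node_met": "LNM",
    "liver_met": "LM",
    "peritoneal_met": "PM",
    "omental_met": "OM",
    "abdominal_wall_met": "AWM",
}
ABBREV_TO_CLASS = {v: k for k, v in TISSUE_ABBREV.items()}

#: the ddPCR multiplex panel vocabulary (codons 12/13)
DDPCR_PANEL = ("G12A", "G12C", "G12D", "G12R", "G12S", "G12V", "G13D")

#: constitutional polymorphisms subtracted when no matched normal exists
DEFAULT_GERMLINE_DENYLIST = frozenset({("TP53", "P72R")})


def _translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class Variant:
    """One normalized somatic call."""

    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    gene: Optional[str] = None
    consequence: Optional[str] = None
    protein_change: Optional[str] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref != self.ref.upper() or self.alt != self.alt.upper():
            raise ValueError("alleles must be uppercase")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"af {self.af} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} < 1")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class SampleRecord:
    """A tissue sample, its patient/tissue metadata and filtered variants."""

    sample_id: str
    patient_id: Optional[str]
    tissue_class: Optional[str]
    variants: set[Variant]

    def __post_init__(self) -> None:
        if self.tissue_class is not None and self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")

    @property
    def is_normal(self) -> bool:
        return self.tissue_class == "normal"


@dataclass(frozen=True)
class HotspotCall:
    """A KRAS hotspot call from sequencing or the ddPCR panel."""

    patient_id: Optional[str]
    sample_id: Optional[str]
    assay: str  # "sequencing" | "ddpcr"
    mutation_label: str


# ---------------------------------------------------------------------------
# allele normalization and identity
# ---------------------------------------------------------------------------


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping at least one base of each.

    Without a reference genome full left-alignment is impossible; trimming
    alone still yields stable identity keys across callers that pad anchors
    differently.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def identity_key(variant: Variant, mode: str = "genomic") -> tuple:
    """Comparable identity key for a variant.

    ``genomic`` keys by (chrom, pos, ref, alt); ``protein`` keys by
    (gene, protein_change) so distinct nucleotide events with the same
    protein effect collapse.
    """
    if mode == "genomic":
        return (variant.chrom, variant.pos, variant.ref, variant.alt)
    if mode == "protein":
        if variant.gene is None or variant.protein_change is None:
            return (variant.chrom, variant.pos, variant.ref, variant.alt)
        return (variant.gene, variant.protein_change)
    raise ValueError(f"unknown identity mode {mode!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("sample_id", "chrom", "pos", "ref", "alt", "af")


def _read_tsv(path: Path) -> dict[str, set[Variant]]:
    by_sample: dict[str, set[Variant]] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not set(TSV_COLUMNS) <= set(reader.fieldnames):
            missing = set(TSV_COLUMNS) - set(reader.fieldnames or [])
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row in reader:
            lineno = reader.line_num
            try:
                pos, ref, alt = normalize_alleles(
                    int(row["pos"]), row["ref"], row["alt"]
                )
                qual = row.get("qual")
                variant = Variant(
                    chrom=row["chrom"],
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    af=float(row["af"]),
                    quality=float(qual) if qual not in (None, "", ".") else None,
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc
            by_sample.setdefault(row["sample_id"], set()).add(variant)
    return by_sample


def _vcf_sample_af(rec, sample: str, alt_index: int = 0) -> float:
    fmt = rec.samples[sample]
    af = fmt.get("AF")
    if af is not None:
        return float(af[alt_index] if isinstance(af, tuple) else af)
    ad = fmt.get("AD")
    if ad is not None and len(ad) >= alt_index + 2 and ad[0] is not None:
        depth = ad[0] + ad[alt_index + 1]
        if depth > 0:
            return ad[alt_index + 1] / depth
    raise ValueError(
        f"sample {sample} at {rec.chrom}:{rec.pos} has neither an AF format "
        "field nor usable allelic depths (AD); supply AF or AD in the VCF"
    )


def _read_vcf(path: Path) -> dict[str, set[Variant]]:
    import pysam

    by_sample: dict[str, set[Variant]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(
                f"{path}: VCF has no sample columns; per-sample genotypes are required"
            )
        for rec in vcf:
            for alt_index, alt in enumerate(rec.alts or ()):
                for sample in samples:
                    fmt = rec.samples[sample]
                    gt = fmt.get("GT")
                    has_gt = gt is not None and any(a is not None for a in gt)
                    if has_gt and not any(a == alt_index + 1 for a in gt if a is not None):
                        continue  # this sample does not carry this alt
                    if not has_gt and len(samples) > 1:
                        continue  # multi-sample VCF without genotype: ambiguous
                    try:
                        af = _vcf_sample_af(rec, sample, alt_index)
                    except ValueError:
                        if len(samples) == 1 and "AF" in rec.info:
                            info_af = rec.info["AF"]
                            af = float(
                                info_af[alt_index]
                                if isinstance(info_af, tuple)
                                else info_af
                            )
                        else:
                            raise
                    pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                    variant = Variant(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_n,
                        af=af,
                        quality=rec.qual,
                    )
                    by_sample.setdefault(sample, set()).add(variant)
    return by_sample


def read_variants(
    path: str | Path,
    format: str = "tsv",
    sample_sheet: Optional[dict[str, dict]] = None,
) -> list[SampleRecord]:
    """Read per-sample variant calls from a VCF or the TSV dialect.

    Multi-allelic records are split into one Variant per alt; alleles are
    trimmed/normalized; AF is taken from the AF field or computed from AD.
    ``sample_sheet`` (sample_id -> {patient_id, tissue_class}) fills in
    patient metadata when provided.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        by_sample = _read_tsv(path)
    elif format == "vcf":
        by_sample = _read_vcf(path)
    else:
        raise ValueError(f"format must be 'vcf' or 'tsv', got {format!r}")

    records = []
    for sample_id in sorted(by_sample):
        meta = (sample_sheet or {}).get(sample_id, {})
        records.append(
            SampleRecord(
                sample_id=sample_id,
                patient_id=meta.get("patient_id"),
                tissue_class=meta.get("tissue_class"),
                variants=by_sample[sample_id],
            )
        )
    return records


def load_sample_sheet(path: str | Path) -> dict[str, dict]:
    """Read the sample sheet TSV (sample_id, patient_id, tissue_class[, age])."""
    sheet: dict[str, dict] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample_id", "patient_id", "tissue_class"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
        for row in reader:
            tissue = row["tissue_class"]
            tissue = ABBREV_TO_CLASS.get(tissue, tissue)
            if tissue not in TISSUE_CLASSES:
                raise ValueError(
                    f"{path}: unknown tissue class {row['tissue_class']!r} "
                    f"at line {reader.line_num}"
                )
            if row["sample_id"] in sheet:
                raise ValueError(f"{path}: duplicate sample_id {row['sample_id']!r}")
            sheet[row["sample_id"]] = {
                "patient_id": row["patient_id"],
                "tissue_class": tissue,
                "age": float(row["age"]) if row.get("age") not in (None, "") else None,
            }
    return sheet


def write_variants_tsv(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write SampleRecords back to the TSV dialect (round-trip safe)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS + ("qual",))
        for record in sorted(records, key=lambda r: r.sample_id):
            for v in sorted(record.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
                writer.writerow(
                    [
                        record.sample_id,
                        v.chrom,
                        v.pos,
                        v.ref,
                        v.alt,
                        repr(v.af),
                        "" if v.quality is None else repr(v.quality),
                    ]
                )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_by_af(variants: Iterable[Variant], threshold: float = 0.2) -> set[Variant]:
    """Keep variants with allele frequency >= threshold (inclusive)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    return {v for v in variants if v.af >= threshold}


def subtract_matched_normal(
    tumour: SampleRecord,
    normal: SampleRecord,
    key_mode: str = "genomic",
) -> SampleRecord:
    """Remove from a tumour sample any variant seen in the matched normal.

    Variants shared with the normal are constitutional, not somatic; removed
    calls are logged with a germline/constitutional tag.
    """
    if tumour.patient_id != normal.patient_id:
        raise ValueError(
            f"patient mismatch: {tumour.patient_id!r} vs {normal.patient_id!r}"
        )
    if normal.tissue_class is not None and not normal.is_normal:
        raise ValueError(f"{normal.sample_id} is not a normal sample")
    normal_keys = {identity_key(v, key_mode) for v in normal.variants}
    kept, removed = set(), []
    for v in tumour.variants:
        if identity_key(v, key_mode) in normal_keys:
            removed.append(v)
        else:
            kept.add(v)
    for v in removed:
        log.info(
            "germline/constitutional: removed %s:%s %s>%s from %s",
            v.chrom, v.pos, v.ref, v.alt, tumour.sample_id,
        )
    return replace_variants(tumour, kept)


def subtract_denylist(
    record: SampleRecord,
    denylist: frozenset[tuple[str, str]] = DEFAULT_GERMLINE_DENYLIST,
) -> SampleRecord:
    """Remove known constitutional polymorphisms (gene, protein_change) when
    no matched normal is available."""
    kept = {
        v
        for v in record.variants
        if (v.gene, v.protein_change) not in denylist
    }
    return replace_variants(record, kept)


def replace_variants(record: SampleRecord, variants: set[Variant]) -> SampleRecord:
    return SampleRecord(
        sample_id=record.sample_id,
        patient_id=record.patient_id,
        tissue_class=record.tissue_class,
        variants=variants,
    )


# ---------------------------------------------------------------------------
# gene assignment and consequence annotation
# ---------------------------------------------------------------------------


def assign_gene(
    variant: Variant, models: dict[str, TranscriptModel] | Sequence[TranscriptModel]
) -> Optional[str]:
    """Gene whose target interval contains the variant position (inclusive)."""
    if isinstance(models, dict):
        models = list(models.values())
    for model in models:
        if model.chrom == variant.chrom and model.in_target(variant.pos):
            return model.gene
    return None


def annotate_consequence(
    variant: Variant, model: TranscriptModel
) -> tuple[str, Optional[str]]:
    """Classify a variant against a transcript model.

    SNVs inside the CDS are translated with the standard genetic code
    (reverse-complemented on '-' strand models, codon numbering honouring
    ``codon_offset``); CDS indels are frameshift/inframe by length mod 3;
    near-boundary positions are splice; in-target non-coding positions are
    intronic.
    """
    if variant.chrom != model.chrom:
        raise ValueError(
            f"variant chrom {variant.chrom} does not match model {model.chrom}"
        )

    if variant.is_snv:
        idx = model.genomic_to_cds(variant.pos)
        if idx is None:
            return _noncoding_class(variant.pos, model), None
        codon_idx, within = divmod(idx, 3)
        codon_number = codon_idx + model.codon_offset
        start = codon_idx * 3
        if start + 3 > len(model.cds_sequence):
            raise ValueError(f"model too short: codon {codon_number} of {model.gene}")
        ref_codon = model.cds_sequence[start : start + 3]
        cds_ref = variant.ref if model.strand == "+" else complement_base(variant.ref)
        cds_alt = variant.alt if model.strand == "+" else complement_base(variant.alt)
        if ref_codon[within] != cds_ref:
            log.warning(
                "%s:%s ref %s disagrees with %s model base %s; using model",
                variant.chrom, variant.pos, variant.ref, model.gene, ref_codon[within],
            )
        alt_codon = ref_codon[:within] + cds_alt + ref_codon[within + 1 :]
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon(alt_codon)
        change = f"{ref_aa}{codon_number}{alt_aa}"
        if alt_aa == ref_aa:
            return "synonymous", change
        if alt_aa == "*":
            return "nonsense", change
        return "missense", change

    # indel: does any affected base (anchor or span) touch the CDS?
    span = range(variant.pos, variant.pos + max(len(variant.ref), 2) - 1 + 1)
    if any(model.genomic_to_cds(p) is not None for p in span):
        diff = abs(len(variant.alt) - len(variant.ref))
        return ("frameshift" if diff % 3 else "inframe_indel"), None
    return _noncoding_class(variant.pos, model), None


def _noncoding_class(pos: int, model: TranscriptModel) -> str:
    if model.near_splice(pos):
        return "splice"
    if model.in_target(pos):
        return "intronic"
    return "noncoding"


def annotate_sample(
    record: SampleRecord, models: dict[str, TranscriptModel]
) -> SampleRecord:
    """Assign genes and consequences to every variant of a sample."""
    annotated = set()
    for v in record.variants:
        gene = assign_gene(v, models)
        if gene is None:
            annotated.add(replace(v, gene=None, consequence="noncoding"))
            continue
        consequence, change = annotate_consequence(v, models[gene])
        annotated.add(
            replace(v, gene=gene, consequence=consequence, protein_change=change)
        )
    return replace_variants(record, annotated)


# ---------------------------------------------------------------------------
# KRAS hotspots
# ---------------------------------------------------------------------------

_HOTSPOT_CODONS = {12, 13, 61}
_NONSYNONYMOUS = frozenset({"missense", "nonsense"})


def parse_protein_change(change: str) -> Optional[tuple[str, int, str]]:
    if not change or len(change) < 3:
        return None
    ref_aa, alt_aa = change[0], change[-1]
    digits = change[1:-1]
    if not digits.isdigit():
        return None
    return ref_aa, int(digits), alt_aa


def detect_kras_hotspot(
    variants: Iterable[Variant],
    patient_id: Optional[str] = None,
    sample_id: Optional[str] = None,
) -> list[HotspotCall]:
    """Sequencing-derived KRAS hotspot calls at codons 12, 13 and 61.

    Only nonsynonymous substitutions qualify; labels outside the ddPCR panel
    vocabulary collapse to ``other_codon12_13`` or ``Q61x``.
    """
    calls = []
    for v in sorted(
        (v for v in variants if v.gene == "KRAS"),
        key=lambda v: (v.chrom, v.pos, v.ref, v.alt),
    ):
        if v.consequence not in _NONSYNONYMOUS or v.protein_change is None:
            continue
        parsed = parse_protein_change(v.protein_change)
        if parsed is None:
            continue
        _, codon, _ = parsed
        if codon not in _HOTSPOT_CODONS:
            continue
        if v.protein_change in DDPCR_PANEL:
            label = v.protein_change
        elif codon in (12, 13):
            label = "other_codon12_13"
        else:
            label = "Q61x"
        calls.append(
            HotspotCall(
                patient_id=patient_id,
                sample_id=sample_id,
                assay="sequencing",
                mutation_label=label,
            )
        )
    return calls


def read_ddpcr_table(path: str | Path) -> list[dict]:
    """Read the ddPCR assay table (patient_id, sample_id, mutation_label, result)."""
    rows = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"patient_id", "sample_id", "mutation_label", "result"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: ddPCR table needs columns {sorted(required)}")
        for row in reader:
            if row["result"] not in {"positive", "negative"}:
                raise ValueError(
                    f"{path}: result must be positive/negative at line {reader.line_num}"
                )
            rows.append(dict(row))
    return rows
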