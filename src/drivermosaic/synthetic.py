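"""Synthetic multi-region cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: ~33
patients with 1-5 tumour samples each, truncal KRAS hotspots drawn from a
codon-12/13/61 spectrum, patient-level tumour-suppressor mutations placed
truncally with probability ``truncal_sharing`` (else in a single random
sample), Poisson sample-private extra variants, allele frequencies straddling
the counting threshold, an optional constitutional polymorphism present in
the matched normal, and IHC measurements emitted conditional on the
underlying gene status. Output files use the exact dialects consumed by the
ingest and IHC modules, alongside TSV truth records.

Reproducibility: one seed; each patient draws from a substream derived
deterministically from (seed, patient index), so cohorts are stable under
changes of ``n_patients``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np

from .heterogeneity import jaccard
from .transcripts import TranscriptModel, complement_base, load_transcript_models
from .variants import DDPCR_PANEL, parse_protein_change

DRIVER_GENES = ("KRAS", "CDKN2A", "TP53", "SMAD4")
SUPPRESSOR_GENES = ("CDKN2A", "TP53", "SMAD4")
MARKER_FOR_GENE = {"CDKN2A": "p16", "TP53": "p53", "SMAD4": "SMAD4"}

#: TP53 P72R: the seeded constitutional polymorphism (c.215C>G)
GERMLINE_GENE = "TP53"
GERMLINE_CDS_INDEX = 214

_MET_CLASSES = (
    "lymph_node_met",
    "liver_met",
    "peritoneal_met",
    "omental_met",
    "abdominal_wall_met",
)
_MET_WEIGHTS = (0.40, 0.24, 0.16, 0.12, 0.08)
_ABBR = {
    "primary_tumour": "PT",
    "lymph_node_met": "LNM",
    "liver_met": "LM",
    "peritoneal_met": "PM",
    "omental_met": "OM",
    "abdominal_wall_met": "AWM",
}


@dataclass
class CohortConfig:
    """Generative parameters; defaults follow the reference cohort's
    per-gene patient alteration rates."""

    n_patients: int = 33
    samples_per_patient: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.25, 3: 0.18, 4: 0.12, 5: 0.10}
    )
    p_gene: dict[str, float] = field(
        default_factory=lambda: {
            "KRAS": 0.88,
            "CDKN2A": 0.52,
            "TP53": 0.82,
            "SMAD4": 0.33,
        }
    )
    truncal_sharing: float = 0.7
    private_rate: float = 0.6
    hotspot_spectrum: dict[str, float] = field(
        default_factory=lambda: {
            "G12V": 0.26,
            "G12D": 0.22,
            "G12R": 0.12,
            "G12C": 0.10,
            "G12A": 0.08,
            "G12S": 0.08,
            "G13D": 0.09,
            "Q61H": 0.05,
        }
    )
    ihc_noise: float = 0.05
    germline_rate: float = 0.33
    p_normal_sample: float = 0.6
    af_range: tuple[float, float] = (0.05, 0.6)
    status_af_range: tuple[float, float] = (0.2, 0.6)
    af_threshold: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name, p in [
            ("truncal_sharing", self.truncal_sharing),
            ("ihc_noise", self.ihc_noise),
            ("germline_rate", self.germline_rate),
            ("p_normal_sample", self.p_normal_sample),
            *((f"p_gene[{g}]", v) for g, v in self.p_gene.items()),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.private_rate < 0:
            raise ValueError("private_rate must be >= 0")
        for label, dist in [
            ("samples_per_patient", self.samples_per_patient),
            ("hotspot_spectrum", self.hotspot_spectrum),
        ]:
            total = sum(dist.values())
            if not math.isclose(total, 1.0, rel_tol=1e-6):
                raise ValueError(f"{label} probabilities sum to {total}, not 1")
            if any(w < 0 for w in dist.values()):
                raise ValueError(f"{label} has negative weights")
        if set(self.p_gene) != set(DRIVER_GENES):
            raise ValueError(f"p_gene must cover exactly {DRIVER_GENES}")
        lo, hi = self.af_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid af_range {self.af_range}")


@dataclass
class SyntheticVariant:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    samples: tuple[str, ...]
    truncal: bool
    origin: str  # status | private | germline | hotspot
    protein_change: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PatientTruth:
    patient_id: str
    samples: list[tuple[str, str]]  # (sample_id, tissue_class)
    gene_status: dict[str, bool]
    protein_status: dict[str, bool]
    hotspot_label: Optional[str]
    variants: list[SyntheticVariant]
    true_median_jaccard: Optional[float]


# ---------------------------------------------------------------------------
# variant realization against the transcript models
# ---------------------------------------------------------------------------


def _genomic_snv(
    model: TranscriptModel, cds_index: int, cds_alt: str
) -> tuple[int, str, str]:
    pos = model.cds_to_genomic(cds_index)
    cds_ref = model.cds_sequence[cds_index]
    if model.strand == "+":
        return pos, cds_ref, cds_alt
    return pos, complement_base(cds_ref), complement_base(cds_alt)


def hotspot_variant(model: TranscriptModel, label: str) -> tuple[int, str, str]:
    """Realize a protein-level hotspot label (e.g. G12V) as a genomic SNV,
    choosing the first base change (in codon order) producing the target
    residue."""
    from .variants import _translate_codon

    parsed = parse_protein_change(label)
    if parsed is None:
        raise ValueError(f"cannot parse hotspot label {label!r}")
    ref_aa, codon_number, alt_aa = parsed
    codon = model.codon(codon_number)
    if _translate_codon(codon) != ref_aa:
        raise ValueError(
            f"{model.gene} codon {codon_number} is {_translate_codon(codon)}, "
            f"not {ref_aa}"
        )
    local = codon_number - model.codon_offset
    for within in range(3):
        for base in "ACGT":
            if base == codon[within]:
                continue
            mutant = codon[:within] + base + codon[within + 1 :]
            if _translate_codon(mutant) == alt_aa:
                return _genomic_snv(model, local * 3 + within, base)
    raise ValueError(f"no single-base change realizes {label} on {model.gene}")


def random_nonsynonymous_snv(
    model: TranscriptModel, rng: np.random.Generator, forbidden: set[int]
) -> tuple[int, str, str]:
    """Rejection-sample a missense/nonsense SNV in the model's CDS avoiding
    the given genomic positions."""
    from .variants import _translate_codon

    n_codons = len(model.cds_sequence) // 3
    for _ in range(1000):
        codon_local = int(rng.integers(1, n_codons))  # skip the start codon
        within = int(rng.integers(3))
        idx = codon_local * 3 + within
        codon = model.cds_sequence[codon_local * 3 : codon_local * 3 + 3]
        base = "ACGT"[int(rng.integers(4))]
        if base == codon[within]:
            continue
        mutant = codon[:within] + base + codon[within + 1 :]
        if _translate_codon(mutant) == _translate_codon(codon):
            continue  # synonymous; not a status-conferring event
        pos, ref, alt = _genomic_snv(model, idx, base)
        if pos in forbidden:
            continue
        return pos, ref, alt
    raise RuntimeError(f"could not sample a nonsynonymous SNV in {model.gene}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo + (hi - lo) * rng.random())


def simulate_patient(
    config: CohortConfig,
    index: int,
    models: dict[str, TranscriptModel],
) -> PatientTruth:
    rng = np.random.default_rng([config.seed, index])
    patient_id = f"P{index + 1:03d}"

    sizes = sorted(config.samples_per_patient)
    weights = [config.samples_per_patient[k] for k in sizes]
    n_tumour = int(rng.choice(sizes, p=weights))

    classes = ["primary_tumour"]
    for _ in range(n_tumour - 1):
        if rng.random() < 0.5:
            classes.append("primary_tumour")
        else:
            classes.append(str(rng.choice(_MET_CLASSES, p=_MET_WEIGHTS)))
    counters: dict[str, int] = {}
    samples: list[tuple[str, str]] = []
    for tissue in classes:
        counters[tissue] = counters.get(tissue, 0) + 1
        samples.append((f"{patient_id}-{_ABBR[tissue]}{counters[tissue]}", tissue))
    has_normal = rng.random() < config.p_normal_sample
    if has_normal:
        samples.append((f"{patient_id}-N", "normal"))
    tumour_ids = tuple(s for s, t in samples if t != "normal")
    all_ids = tuple(s for s, _ in samples)

    variants: list[SyntheticVariant] = []
    used_positions: set[int] = set()

    def place(truncal: bool) -> tuple[tuple[str, ...], bool]:
        if truncal or len(tumour_ids) == 1:
            return tumour_ids, True
        chosen = tumour_ids[int(rng.integers(len(tumour_ids)))]
        return (chosen,), False

    # constitutional polymorphism: present in every sample including normal
    if rng.random() < config.germline_rate:
        model = models[GERMLINE_GENE]
        pos, ref, alt = _genomic_snv(model, GERMLINE_CDS_INDEX, "G")
        variants.append(
            SyntheticVariant(
                gene=GERMLINE_GENE, chrom=model.chrom, pos=pos, ref=ref, alt=alt,
                af=round(_uniform(rng, 0.4, 0.6), 4),
                samples=all_ids, truncal=True, origin="germline",
                protein_change="P72R",
            )
        )
        used_positions.add(pos)

    gene_status: dict[str, bool] = {}
    hotspot_label: Optional[str] = None

    # KRAS hotspot
    gene_status["KRAS"] = rng.random() < config.p_gene["KRAS"]
    if gene_status["KRAS"]:
        labels = sorted(config.hotspot_spectrum)
        label_weights = [config.hotspot_spectrum[k] for k in labels]
        hotspot_label = str(rng.choice(labels, p=label_weights))
        model = models["KRAS"]
        pos, ref, alt = hotspot_variant(model, hotspot_label)
        carried, truncal = place(rng.random() < config.truncal_sharing)
        variants.append(
            SyntheticVariant(
                gene="KRAS", chrom=model.chrom, pos=pos, ref=ref, alt=alt,
                af=round(_uniform(rng, *config.status_af_range), 4),
                samples=carried, truncal=truncal, origin="hotspot",
                protein_change=hotspot_label,
            )
        )
        used_positions.add(pos)

    # tumour suppressors: one status-conferring variant, then sample-private
    # extras (subclonal hits in the already-mutated gene)
    for gene in SUPPRESSOR_GENES:
        model = models[gene]
        gene_status[gene] = rng.random() < config.p_gene[gene]
        if not gene_status[gene]:
            continue
        pos, ref, alt = random_nonsynonymous_snv(model, rng, used_positions)
        carried, truncal = place(rng.random() < config.truncal_sharing)
        variants.append(
            SyntheticVariant(
                gene=gene, chrom=model.chrom, pos=pos, ref=ref, alt=alt,
                af=round(_uniform(rng, *config.status_af_range), 4),
                samples=carried, truncal=truncal, origin="status",
            )
        )
        used_positions.add(pos)
        for sample_id in tumour_ids:
            for _ in range(int(rng.poisson(config.private_rate))):
                pos, ref, alt = random_nonsynonymous_snv(model, rng, used_positions)
                variants.append(
                    SyntheticVariant(
                        gene=gene, chrom=model.chrom, pos=pos, ref=ref, alt=alt,
                        af=round(_uniform(rng, *config.af_range), 4),
                        samples=(sample_id,), truncal=False, origin="private",
                    )
                )
                used_positions.add(pos)

    # protein truth: gene status flipped with the misclassification rate
    protein_status = {}
    for gene, marker in MARKER_FOR_GENE.items():
        flip = rng.random() < config.ihc_noise
        protein_status[marker] = gene_status[gene] != flip

    return PatientTruth(
        patient_id=patient_id,
        samples=samples,
        gene_status=gene_status,
        protein_status=protein_status,
        hotspot_label=hotspot_label,
        variants=variants,
        true_median_jaccard=_true_median_jaccard(
            variants, tumour_ids, config.af_threshold
        ),
    )


def _true_median_jaccard(
    variants: list[SyntheticVariant],
    tumour_ids: tuple[str, ...],
    threshold: float,
) -> Optional[float]:
    """Median pairwise Jaccard over tumour samples using counted somatic
    variants (af >= threshold, germline excluded)."""
    if len(tumour_ids) < 2:
        return None
    keys_by_sample = {s: set() for s in tumour_ids}
    for v in variants:
        if v.origin == "germline" or v.af < threshold:
            continue
        for s in v.samples:
            if s in keys_by_sample:
                keys_by_sample[s].add(v.key)
    values = [
        j
        for a, b in combinations(tumour_ids, 2)
        if (j := jaccard(keys_by_sample[a], keys_by_sample[b])) is not None
    ]
    if not values:
        return None
    values.sort()
    mid = len(values) // 2
    return values[mid] if len(values) % 2 else (values[mid - 1] + values[mid]) / 2


def simulate_cohort(
    config: CohortConfig, models: Optional[dict[str, TranscriptModel]] = None
) -> list[PatientTruth]:
    config.validate()
    if models is None:
        models = load_transcript_models()
    return [simulate_patient(config, i, models) for i in range(config.n_patients)]


# ---------------------------------------------------------------------------
# file emission (dialects of the ingest/IHC modules)
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write all input + truth files; returns paths.

    Byte-identical across runs for the same (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients = simulate_cohort(config)

    paths = {
        name: outdir / fname
        for name, fname in [
            ("samples", "samples.tsv"),
            ("variants", "variants.tsv"),
            ("ddpcr", "ddpcr.tsv"),
            ("ihc", "ihc.tsv"),
            ("truth_patients", "truth_patients.tsv"),
            ("truth_variants", "truth_variants.tsv"),
        ]
    }

    def writer(handle):
        return csv.writer(handle, delimiter="\t", lineterminator="\n")

    with open(paths["samples"], "w", newline="") as handle:
        w = writer(handle)
        w.writerow(["sample_id", "patient_id", "tissue_class", "age"])
        for i, p in enumerate(patients):
            rng = np.random.default_rng([config.seed, i, 1])
            age = int(rng.integers(31, 50))
            for sample_id, tissue in p.samples:
                w.writerow([sample_id, p.patient_id, tissue, age])

    with open(paths["variants"], "w", newline="") as handle:
        w = writer(handle)
        w.writerow(["sample_id", "chrom", "pos", "ref", "alt", "af"])
        for p in patients:
            for v in p.variants:
                for sample_id in v.samples:
                    w.writerow(
                        [sample_id, v.chrom, v.pos, v.ref, v.alt, f"{v.af:.4f}"]
                    )

    with open(paths["ddpcr"], "w", newline="") as handle:
        w = writer(handle)
        w.writerow(["patient_id", "sample_id", "mutation_label", "result"])
        for p in patients:
            label = (
                p.hotspot_label
                if p.hotspot_label in DDPCR_PANEL
                else "G12D"  # panel assay run regardless; Q61 is not covered
            )
            carriers: set[str] = set()
            if p.hotspot_label in DDPCR_PANEL:
                for v in p.variants:
                    if v.origin == "hotspot":
                        carriers = set(v.samples)
            for sample_id, tissue in p.samples:
                if tissue == "normal":
                    continue
                result = "positive" if sample_id in carriers else "negative"
                w.writerow([p.patient_id, sample_id, label, result])

    with open(paths["ihc"], "w", newline="") as handle:
        w = writer(handle)
        w.writerow(
            ["sample_id", "marker", "percent_positive", "nuclear_stain_present",
             "cytoplasmic_stain_present", "positive_cells", "cells_counted"]
        )
        for i, p in enumerate(patients):
            rng = np.random.default_rng([config.seed, i, 2])
            for sample_id, tissue in p.samples:
                if tissue == "normal":
                    continue
                _emit_ihc_rows(w, sample_id, p.protein_status, rng)

    with open(paths["truth_patients"], "w", newline="") as handle:
        w = writer(handle)
        w.writerow(
            ["patient_id", "n_samples", "KRAS_mut", "CDKN2A_mut", "TP53_mut",
             "SMAD4_mut", "hotspot_label", "p16_altered", "p53_altered",
             "SMAD4_altered", "true_median_jaccard"]
        )
        for p in patients:
            med = p.true_median_jaccard
            w.writerow(
                [
                    p.patient_id,
                    len(p.samples),
                    *(int(p.gene_status[g]) for g in DRIVER_GENES),
                    p.hotspot_label or ".",
                    *(int(p.protein_status[m]) for m in ("p16", "p53", "SMAD4")),
                    "NA" if med is None else f"{med:.6g}",
                ]
            )

    with open(paths["truth_variants"], "w", newline="") as handle:
        w = writer(handle)
        w.writerow(
            ["patient_id", "gene", "chrom", "pos", "ref", "alt", "af",
             "truncal", "origin", "counted", "samples"]
        )
        for p in patients:
            for v in p.variants:
                w.writerow(
                    [
                        p.patient_id, v.gene, v.chrom, v.pos, v.ref, v.alt,
                        f"{v.af:.4f}", int(v.truncal), v.origin,
                        int(v.af >= config.af_threshold and v.origin != "germline"),
                        ",".join(v.samples),
                    ]
                )
    return paths


def _emit_ihc_rows(writer, sample_id: str, protein_status: dict, rng) -> None:
    # p16: loss == absent nuclear staining
    if protein_status["p16"]:
        nuclear, cyto = False, rng.random() < 0.5
    else:
        nuclear, cyto = True, rng.random() < 0.5
    writer.writerow([sample_id, "p16", ".", int(nuclear), int(cyto), ".", "."])
    # p53: loss (<5%) or overexpression (>=30%) vs normal band
    if protein_status["p53"]:
        if rng.random() < 0.2:
            percent = _uniform(rng, 0.0, 4.5)
        else:
            percent = _uniform(rng, 30.0, 95.0)
    else:
        percent = _uniform(rng, 5.0, 25.0)
    writer.writerow([sample_id, "p53", f"{percent:.2f}", ".", ".", ".", "."])
    # SMAD4: loss == neither compartment stains
    if protein_status["SMAD4"]:
        nuclear, cyto = False, False
    else:
        nuclear, cyto = True, rng.random() < 0.5
    writer.writerow([sample_id, "SMAD4", ".", int(nuclear), int(cyto), ".", "."])
    # Ki67: hot-spot counts out of 500 cells
    positive = int(rng.integers(25, 301))
    writer.writerow([sample_id, "Ki67", ".", ".", ".", positive, 500])


# ---------------------------------------------------------------------------
# analytic expectation for a two-sample patient
# ---------------------------------------------------------------------------


def expected_jaccard(
    config: CohortConfig,
    counted_only: bool = True,
    max_private: int = 200,
) -> Optional[float]:
    """Exact expected pairwise Jaccard for a two-sample patient.

    Generative model for two tumour samples: each gene g is mutated with
    probability p_g and contributes one patient-level variant, truncal (in
    both samples) with probability s, else private to one sample. Each
    mutated tumour-suppressor gene additionally contributes Poisson(lam)
    sample-private variants per sample. With T truncal, S singleton
    patient-level and K total sample-private variants,

        J = T / (T + S + K),   K ~ Poisson(2 * lam * m_ts),

    where m_ts is the number of mutated suppressor genes. The expectation is
    taken over gene subsets, binomial truncal counts and the (truncated)
    Poisson, conditioned on a non-empty union (the empty/empty case is NA).
    With ``counted_only`` the private rate is thinned by the probability that
    a private variant's allele frequency clears the counting threshold
    (status variants always clear it by construction).
    """
    config.validate()
    s = config.truncal_sharing
    lam = config.private_rate
    if counted_only:
        lo, hi = config.af_range
        thr = config.af_threshold
        q = max(0.0, min(1.0, (hi - max(lo, thr)) / (hi - lo)))
        lam *= q

    genes = DRIVER_GENES
    numer = 0.0
    defined_mass = 0.0
    for mask in range(1, 1 << len(genes)):
        subset = [g for i, g in enumerate(genes) if mask >> i & 1]
        p_subset = 1.0
        for i, g in enumerate(genes):
            p = config.p_gene[g]
            p_subset *= p if mask >> i & 1 else 1.0 - p
        if p_subset == 0.0:
            continue
        m = len(subset)
        m_ts = sum(1 for g in subset if g in SUPPRESSOR_GENES)
        mu = 2.0 * lam * m_ts
        expectation = 0.0
        for t in range(m + 1):
            p_t = math.comb(m, t) * s**t * (1.0 - s) ** (m - t)
            if p_t == 0.0:
                continue
            if mu == 0.0:
                expectation += p_t * (t / m)
                continue
            pois = math.exp(-mu)
            for k in range(max_private + 1):
                expectation += p_t * pois * (t / (m + k))
                pois *= mu / (k + 1)
        numer += p_subset * expectation
        defined_mass += p_subset
    if defined_mass == 0.0:
        return None
    return numer / defined_mass
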