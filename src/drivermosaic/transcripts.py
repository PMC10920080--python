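"""Minimal transcript models for the targeted driver genes.

A :class:`TranscriptModel` describes just enough of a gene to classify a
variant's coding consequence: the genomic coordinates of the modelled coding
segments, the coding-strand CDS sequence covering those segments, the codon
number of the first modelled codon (partial models are allowed), and the
flanking amplicon/target intervals used for gene assignment.

Models ship as a small text file (see ``data/transcript_models.txt`` for the
format) and are loaded with :func:`load_transcript_models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class TranscriptModel:
    """A (possibly partial) coding model of one gene.

    ``cds_segments`` are 1-based inclusive genomic intervals in transcription
    order (for '-' strand genes that means decreasing genomic coordinates).
    ``cds_sequence`` is the coding-strand sequence of the concatenated
    segments. ``codon_offset`` anchors codon numbering for partial models.
    ``targets`` are the assay territories used for gene assignment.
    """

    gene: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_sequence: str
    codon_offset: int = 1
    targets: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        total = sum(e - s + 1 for s, e in self.cds_segments)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"{self.gene}: segment lengths ({total}) do not match "
                f"cds_sequence length ({len(self.cds_sequence)})"
            )
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length not divisible by 3")
        for s, e in self.cds_segments:
            if s > e:
                raise ValueError(f"{self.gene}: inverted segment ({s}, {e})")
        by_start = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene}: overlapping cds segments")
        expected = sorted(self.cds_segments, reverse=self.strand == "-")
        if list(self.cds_segments) != expected:
            raise ValueError(
                f"{self.gene}: segments must be in transcription order"
            )

    # ---- coordinate mapping ------------------------------------------------

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """0-based CDS index for a genomic position, or None outside the CDS."""
        offset = 0
        for start, end in self.cds_segments:
            if start <= pos <= end:
                if self.strand == "+":
                    return offset + (pos - start)
                return offset + (end - pos)
            offset += end - start + 1
        return None

    def cds_to_genomic(self, idx: int) -> int:
        """Genomic position of a 0-based CDS index."""
        if idx < 0:
            raise IndexError(idx)
        offset = 0
        for start, end in self.cds_segments:
            length = end - start + 1
            if idx < offset + length:
                local = idx - offset
                return start + local if self.strand == "+" else end - local
            offset += length
        raise IndexError(f"CDS index {idx} beyond model {self.gene}")

    def in_target(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.targets)

    def near_splice(self, pos: int, within: int = 2) -> bool:
        """True when pos lies outside the CDS but within ``within`` bases of
        a coding-segment boundary."""
        if self.genomic_to_cds(pos) is not None:
            return False
        for start, end in self.cds_segments:
            if start - within <= pos < start or end < pos <= end + within:
                return True
        return False

    def codon(self, codon_number: int) -> str:
        """Reference codon (coding strand) for an absolute codon number."""
        local = codon_number - self.codon_offset
        start = local * 3
        if local < 0 or start + 3 > len(self.cds_sequence):
            raise ValueError(
                f"model too short: codon {codon_number} outside {self.gene} model"
            )
        return self.cds_sequence[start : start + 3]


def _parse_block(lines: list[list[str]]) -> TranscriptModel:
    fields: dict[str, str] = {}
    segments: list[tuple[int, int]] = []
    targets: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    for parts in lines:
        key = parts[0]
        if key == "segment":
            segments.append((int(parts[1]), int(parts[2])))
        elif key == "target":
            targets.append((int(parts[1]), int(parts[2])))
        elif key == "sequence":
            seq_parts.append(parts[1])
        else:
            fields[key] = parts[1]
    strand = fields["strand"]
    segments.sort(reverse=strand == "-")
    return TranscriptModel(
        gene=fields["gene"],
        chrom=fields["chrom"],
        strand=strand,
        cds_segments=tuple(segments),
        cds_sequence="".join(seq_parts).upper(),
        codon_offset=int(fields.get("codon_offset", "1")),
        targets=tuple(sorted(targets)),
    )


def load_transcript_models(path: str | Path | None = None) -> dict[str, TranscriptModel]:
    """Load transcript models from ``path`` or the packaged default file."""
    if path is None:
        ref = resources.files("drivermosaic") / "data" / "transcript_models.txt"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    models: dict[str, TranscriptModel] = {}
    block: list[list[str]] = []
    for raw in text.splitlines() + [""]:
        line = raw.strip()
        if not line or line.startswith("#"):
            if block:
                model = _parse_block(block)
                models[model.gene] = model
                block = []
            continue
        block.append(line.split("\t"))
    return models
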