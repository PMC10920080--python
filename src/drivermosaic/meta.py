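"""Fisher-exact meta-synthesis of alteration rates against reference cohorts.

The two-sided p-value uses the conventional point-probability summation rule:
sum the hypergeometric probabilities of all tables with the observed margins
whose point probability does not exceed the observed table's (with a small
relative tolerance for floating-point ties). Reference cohort counts ship as
a versioned TSV; user-supplied literature counts use the same schema.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from scipy.stats import hypergeom

_TIE_TOLERANCE = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 comparison: (a, b) group-1 altered/unaltered, (c, d) group-2."""

    label: str
    a: int
    b: int
    c: int
    d: int
    p_two_sided: float
    odds_ratio: float

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05

    def formatted_p(self) -> str:
        """Table-style rendering: 4 decimals, 'ns' when p >= 0.05."""
        return "ns" if self.p_two_sided >= 0.05 else f"{self.p_two_sided:.4f}"


def fisher_exact_two_sided(
    a: int, b: int, c: int, d: int, label: str = ""
) -> ContingencyResult:
    """Two-sided Fisher's exact test by point-probability summation."""
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"negative count in table {counts}")
    if any(x != int(x) for x in counts):
        raise ValueError(f"non-integer count in table {counts}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")

    row1, col1 = a + b, a + c
    lo, hi = max(0, col1 - (c + d)), min(row1, col1)
    support = range(lo, hi + 1)
    pmf = hypergeom.pmf(list(support), n, col1, row1)
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * _TIE_TOLERANCE].sum())
    p = min(p, 1.0)

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(label, a, b, c, d, p, odds)


@dataclass
class ReferenceCohort:
    """Alteration counts for one reference (or pooled) cohort."""

    name: str
    age_class: str  # EOPC | LOPC
    n_donors: int
    altered: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, count in self.altered.items():
            if count < 0 or count > self.n_donors:
                raise ValueError(
                    f"{self.name}: {gene} altered count {count} outside "
                    f"[0, {self.n_donors}]"
                )

    def rate(self, gene: str) -> float:
        return self.altered[gene] / self.n_donors


def load_reference_counts(
    path: str | Path | None = None,
) -> dict[str, ReferenceCohort]:
    """Load reference cohorts from ``path`` or the packaged ICGC counts.

    Schema: TSV with columns cohort, age_class, gene, altered, n.
    """
    if path is None:
        handle = (
            resources.files("drivermosaic") / "data" / "icgc_reference.tsv"
        ).open()
    else:
        handle = open(path, newline="")
    cohorts: dict[str, ReferenceCohort] = {}
    with handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"cohort", "age_class", "gene", "altered", "n"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        for row in reader:
            name = row["cohort"]
            n = int(row["n"])
            cohort = cohorts.get(name)
            if cohort is None:
                cohort = cohorts[name] = ReferenceCohort(
                    name=name, age_class=row["age_class"], n_donors=n
                )
            elif cohort.n_donors != n:
                raise ValueError(f"{name}: inconsistent n ({cohort.n_donors} vs {n})")
            cohort.altered[row["gene"]] = int(row["altered"])
    return cohorts


def pool_eopc(*cohorts: ReferenceCohort, name: str = "pooled-EOPC") -> ReferenceCohort:
    """Element-wise pooling of disjoint cohorts (sum counts and denominators)."""
    if len(cohorts) < 2:
        raise ValueError("pooling needs at least two cohorts")
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ValueError(f"cohorts overlap: {names}")
    genes = set().union(*(c.altered for c in cohorts))
    pooled = ReferenceCohort(
        name=name,
        age_class=cohorts[0].age_class,
        n_donors=sum(c.n_donors for c in cohorts),
    )
    for gene in genes:
        pooled.altered[gene] = sum(c.altered.get(gene, 0) for c in cohorts)
    return pooled


def compare_rates(
    our: ReferenceCohort,
    references: dict[str, ReferenceCohort],
    genes: Iterable[str] = ("KRAS", "CDKN2A", "TP53", "SMAD4"),
    lopc: str = "LOPC-ICGC",
    eopc_ref: Optional[str] = "EOPC-ICGC",
) -> list[ContingencyResult]:
    """Per gene: LOPC vs reference-EOPC, LOPC vs ours, LOPC vs pooled EOPC.

    Raw (unadjusted) two-sided p-values; use :func:`benjamini_hochberg` for
    an optional correction.
    """
    if lopc not in references:
        raise ValueError(f"missing reference cohort {lopc!r}")
    lopc_cohort = references[lopc]
    eopc_cohort = references.get(eopc_ref) if eopc_ref else None
    results = []
    for gene in genes:
        if gene not in lopc_cohort.altered:
            raise ValueError(f"reference {lopc} lacks counts for {gene}")
        if gene not in our.altered:
            raise ValueError(f"cohort {our.name} lacks counts for {gene}")
        la, ln = lopc_cohort.altered[gene], lopc_cohort.n_donors
        comparisons = []
        if eopc_cohort is not None:
            comparisons.append((f"{gene}:{lopc}-vs-{eopc_cohort.name}", eopc_cohort))
        comparisons.append((f"{gene}:{lopc}-vs-{our.name}", our))
        if eopc_cohort is not None:
            pooled = pool_eopc(eopc_cohort, our)
            comparisons.append((f"{gene}:{lopc}-vs-{pooled.name}", pooled))
        for lbl, other in comparisons:
            oa, on = other.altered[gene], other.n_donors
            results.append(
                fisher_exact_two_sided(la, ln - la, oa, on - oa, label=lbl)
            )
    return results


def benjamini_hochberg(results: list[ContingencyResult]) -> dict[str, float]:
    """BH-adjusted p-values keyed by comparison label."""
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p_two_sided)
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_last, i in enumerate(reversed(order)):
        rank = m - rank_from_last
        running = min(running, results[i].p_two_sided * m / rank)
        adjusted[i] = running
    return {results[i].label: adjusted[i] for i in range(m)}


def write_meta_table(
    results: list[ContingencyResult], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["comparison", "a", "b", "c", "d", "p_two_sided", "p_rendered",
             "odds_ratio"]
        )
        for r in results:
            writer.writerow(
                [r.label, r.a, r.b, r.c, r.d, f"{r.p_two_sided:.6g}",
                 r.formatted_p(),
                 "inf" if math.isinf(r.odds_ratio) else f"{r.odds_ratio:.6g}"]
            )
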