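"""Potentially-amplifiable-locus (PAL) screening.

A PAL is a repeat locus with a designed primer pair. Primer occurrence
counts in the raw read pool act as a copy-number proxy: too few occurrences
suggest the primer sequence carries sequencing error, while more occurrences
than the genome coverage suggest the primer region is repeated in the genome
and would amplify multiple loci. Coverage itself is estimated as the grand
median of per-gene median read depths over a panel of single-copy gene
fragments.

Counting is exact-match, both orientations, overlapping matches included,
over all reads pooled (mates are not deduplicated).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import revcomp, round_half_up
from .io_core import ReadRecord


@dataclass(frozen=True)
class PrimerPair:
    """A candidate locus's primers with their read-pool occurrence counts."""

    locus_id: str
    forward: str
    reverse: str
    fwd_count: int = 0
    rev_count: int = 0

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or set(p) - set("ACGT"):
                raise ValueError(
                    f"{self.locus_id}: {name} primer must be non-empty ACGT"
                )


@dataclass(frozen=True)
class CoverageEstimate:
    """Per-gene median depths and their grand median (the filter's upper bound)."""

    per_gene_median: dict[str, float]
    grand_median: float
    n_genes: int
    min_median: float
    max_median: float


@dataclass(frozen=True)
class PalDecision:
    locus_id: str
    kept: bool
    reason: str  # ok | fwd_low | fwd_high | rev_low | rev_high

    def __post_init__(self) -> None:
        if self.kept != (self.reason == "ok"):
            raise ValueError("kept must correspond to reason == 'ok'")


def _count_overlapping(text: str, pattern: str) -> int:
    n = 0
    i = text.find(pattern)
    while i != -1:
        n += 1
        i = text.find(pattern, i + 1)
    return n


def count_primer_occurrences(
    primer: str, reads: Iterable[ReadRecord | str]
) -> int:
    """Exact, possibly overlapping matches of the primer or its reverse
    complement summed over all read sequences.

    A reverse-complement-palindromic primer is counted once per position.
    """
    if not primer or len(primer) < 10:
        raise ValueError("primer must be ACGT and at least 10 bp")
    if set(primer) - set("ACGT"):
        raise ValueError(f"primer {primer!r} contains non-ACGT symbols (N?)")
    rc = revcomp(primer)
    total = 0
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else read
        total += _count_overlapping(seq, primer)
        if rc != primer:
            total += _count_overlapping(seq, rc)
    return total


def count_pair_occurrences(
    pairs: Sequence[PrimerPair], reads: Iterable[ReadRecord | str]
) -> list[PrimerPair]:
    """Fill fwd_count/rev_count for each pair over a single pass-able pool."""
    pool = [r.sequence if isinstance(r, ReadRecord) else r for r in reads]
    return [
        replace(
            p,
            fwd_count=count_primer_occurrences(p.forward, pool),
            rev_count=count_primer_occurrences(p.reverse, pool),
        )
        for p in pairs
    ]


def estimate_coverage(depth_table: Mapping[str, Sequence[float]]) -> CoverageEstimate:
    """Median depth per gene, then the grand median of those medians.

    Even-length medians are the mean of the two central values. Genes whose
    every position has zero depth are uncovered and excluded; the result
    mirrors a "grand median (min, max)" coverage report.
    """
    if not depth_table:
        raise ValueError("depth table is empty")
    per_gene: dict[str, float] = {}
    for gene, depths in depth_table.items():
        if len(depths) == 0:
            raise ValueError(f"gene {gene!r} has no positions")
        if max(depths) <= 0:
            continue
        per_gene[gene] = float(np.median(np.asarray(depths, dtype=float)))
    if not per_gene:
        raise ValueError("no gene has any covered position")
    medians = np.array(list(per_gene.values()))
    return CoverageEstimate(
        per_gene_median=per_gene,
        grand_median=float(np.median(medians)),
        n_genes=len(per_gene),
        min_median=float(medians.min()),
        max_median=float(medians.max()),
    )


def max_count_from_coverage(coverage: CoverageEstimate | float) -> int:
    """Upper occurrence bound from a coverage estimate: round half up."""
    gm = coverage.grand_median if isinstance(coverage, CoverageEstimate) else coverage
    return round_half_up(float(gm))


def filter_pals(
    pairs: Sequence[PrimerPair],
    min_count: int = 2,
    max_count: int | None = None,
    coverage: CoverageEstimate | float | None = None,
) -> list[PalDecision]:
    """Apply the PAL keep-rule to counted primer pairs.

    A locus is kept iff both primers occur between ``min_count`` and
    ``max_count`` times inclusive ("less than two ... more than the estimated
    genome coverage" removals). ``max_count`` defaults to the rounded grand
    median coverage. Decisions are per-pair independent and report the first
    failing bound in the order fwd_low, fwd_high, rev_low, rev_high.
    """
    if max_count is None:
        if coverage is None:
            raise ValueError("either max_count or coverage is required")
        max_count = max_count_from_coverage(coverage)
    if max_count < min_count:
        raise ValueError("max_count must be >= min_count")
    out = []
    for p in pairs:
        if p.fwd_count < min_count:
            reason = "fwd_low"
        elif p.fwd_count > max_count:
            reason = "fwd_high"
        elif p.rev_count < min_count:
            reason = "rev_low"
        elif p.rev_count > max_count:
            reason = "rev_high"
        else:
            reason = "ok"
        out.append(PalDecision(p.locus_id, reason == "ok", reason))
    return out
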