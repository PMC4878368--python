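"""Perfect short-sequence-repeat (SSR) discovery in shotgun reads.

A microsatellite motif is a primitive DNA word of length 2-6 (its length is
the "kmer": dimer, trimer, ... hexamer). Motifs are reported under a
canonical name so that the same repeat seen on either strand or at any phase
(AG, GA, CT, TC) counts as one motif class. Only perfect, uninterrupted runs
are detected: an N breaks a run, and imperfect or compound repeats are out of
scope by design.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._util import revcomp
from .io_core import ReadRecord

KMER_RANGE = range(2, 7)

#: Minimum perfect repeat units per motif length for a run to be reported.
#: Overridable through RunConfig.min_units.
DEFAULT_MIN_UNITS: dict[int, int] = {2: 8, 3: 6, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class MotifSpec:
    """A validated repeat motif; ``canonical`` is True if the motif equals
    its canonical (strand- and rotation-invariant) representative."""

    motif: str
    canonical: bool

    def __post_init__(self) -> None:
        _validate_motif(self.motif)


@dataclass(frozen=True)
class SSRHit:
    """One maximal perfect repeat run in one read (0-based half-open)."""

    read_id: str
    canonical_motif: str
    kmer: int
    units: int
    start: int
    end: int
    strand_motif: str

    def __post_init__(self) -> None:
        if self.end - self.start != self.kmer * self.units:
            raise ValueError("SSRHit span must equal kmer * units")


@dataclass
class RepeatSummary:
    """Counts of detected repeats keyed by (kmer, canonical motif)."""

    by_motif: Counter = field(default_factory=Counter)

    @property
    def by_kmer(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (kmer, _), n in self.by_motif.items():
            out[kmer] = out.get(kmer, 0) + n
        return out

    @property
    def total(self) -> int:
        return sum(self.by_motif.values())


def _is_primitive(motif: str) -> bool:
    """True unless the motif is a whole-number repetition of a shorter word."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _validate_motif(motif: str) -> None:
    if not (2 <= len(motif) <= 6):
        raise ValueError(f"motif {motif!r}: length must be 2-6")
    bad = set(motif) - set("ACGT")
    if bad:
        raise ValueError(f"motif {motif!r}: non-ACGT symbols {sorted(bad)}")
    if not _is_primitive(motif):
        raise ValueError(f"motif {motif!r} is reducible to a shorter period")


def canonical_motif(motif: str) -> str:
    """Canonical name of a motif class.

    The lexicographically smallest string among all cyclic rotations of the
    motif and of its reverse complement, so e.g. TG, GT, CA and AC all map to
    "AC". Idempotent and strand-invariant by construction.
    """
    _validate_motif(motif)
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def scan_read(
    record: ReadRecord, min_units: Mapping[int, int] | None = None
) -> list[SSRHit]:
    """All maximal perfect repeat runs in a read, sorted by start.

    For each motif length k the read is scanned for maximal stretches where
    position j matches position j-k; a stretch of L consecutive matches spans
    L+k bases, i.e. floor((L+k)/k) whole units, and is reported when the unit
    count reaches ``min_units[k]`` and the leading k-mer is primitive. The
    primitivity requirement is what stops an (AC)x8 run from also surfacing
    as a reducible 4-mer or 6-mer call. Runs containing N are split at the N.
    When two calls at different motif lengths cover the identical interval
    only the smallest motif length is kept.
    """
    mu = dict(DEFAULT_MIN_UNITS)
    if min_units:
        mu.update(min_units)
    missing = [k for k in KMER_RANGE if k not in mu]
    if missing:
        raise ValueError(f"min_units missing kmer(s) {missing}")

    seq = record.sequence
    n = len(seq)
    hits: dict[tuple[int, int], SSRHit] = {}
    for k in KMER_RANGE:
        j = k
        while j < n:
            # advance to the next position matching k bases back, N excluded
            if seq[j] != seq[j - k] or seq[j] == "N":
                j += 1
                continue
            s = j - k
            while j < n and seq[j] == seq[j - k] and seq[j] != "N":
                j += 1
            # matches cover s..j-1 against s+k..j-1; repeat region is seq[s:j]
            units = (j - s) // k
            motif = seq[s : s + k]
            if units >= mu[k] and "N" not in motif and _is_primitive(motif):
                end = s + units * k
                key = (s, end)
                if key not in hits or k < hits[key].kmer:
                    hits[key] = SSRHit(
                        read_id=record.read_id,
                        canonical_motif=canonical_motif(motif),
                        kmer=k,
                        units=units,
                        start=s,
                        end=end,
                        strand_motif=motif,
                    )
    return sorted(hits.values(), key=lambda h: (h.start, h.kmer))


def scan_reads(
    records: Iterable[ReadRecord], min_units: Mapping[int, int] | None = None
) -> list[SSRHit]:
    """scan_read over a read pool, concatenated in input order."""
    out: list[SSRHit] = []
    for rec in records:
        out.extend(scan_read(rec, min_units))
    return out


def summarize_repeats(hits: Iterable[SSRHit]) -> RepeatSummary:
    """Tally hits per (kmer, canonical motif); the grand total equals the
    number of hits."""
    summary = RepeatSummary()
    for h in hits:
        summary.by_motif[(h.kmer, h.canonical_motif)] += 1
    return summary
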