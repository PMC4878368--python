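"""Ground-truthed simulators for every pipeline stage.

Three generators emulate the data each stage consumes, at toy scale and with
a complete truth record, so the whole pipeline is testable without any
external download:

* reads with planted perfect repeats and planted primer sites at known copy
  numbers, over a rejection-sampled background guaranteed free of accidental
  repeats or primer matches (count assertions are exact, not probabilistic);
* diploid genotype matrices drawn from HWE allele frequencies distorted by a
  null allele — null/null draws drop out as missing, null/visible draws
  surface as apparent homozygotes — plus replicate genotypes with independent
  miscalls;
* fragment-size peak calls as allele label plus uniform jitter.

One integer seed drives a named random stream per component, so adding a
stream never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp, stream_rng
from .io_core import PEAK_COLUMNS, GenotypeMatrix, ReadRecord
from .pal_screen import _count_overlapping
from .ssr_discovery import DEFAULT_MIN_UNITS, canonical_motif, scan_read

#: Sentinel allele label for the non-amplifying (null) allele in truth records.
NULL_ALLELE = -1

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Everything the simulators planted, keyed so each stage can be audited."""

    seed: int
    planted_ssrs: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (read_id, motif, units, start)
    primer_copies: dict[str, int] = field(default_factory=dict)
    primer_positions: list[tuple[str, str, int, str]] = field(default_factory=list)
    # (read_id, locus, start, strand)
    allele_freqs: dict[int, float] = field(default_factory=dict)
    true_genotypes: dict[str, tuple[int, int]] = field(default_factory=dict)
    null_freq: float | None = None
    miscall_rate: float | None = None
    missing_rate: float | None = None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _is_clean(seq: str, primers: Sequence[str], min_units) -> bool:
    """No accidental repeat passing thresholds, no accidental primer site."""
    if scan_read(ReadRecord("bg", seq), min_units):
        return False
    for p in primers:
        if p in seq or revcomp(p) in seq:
            return False
    return True


def _clean_background(rng, read_len, primers, min_units, max_tries=1000) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, read_len)
        if _is_clean(seq, primers, min_units):
            return seq
    raise RuntimeError("could not draw a clean background read")


def simulate_reads(
    n_reads: int,
    read_len: int,
    planted: Sequence[tuple[str, int, int]] = (),
    primer_sites: Sequence[tuple[str, str, int]] = (),
    seed: int = 0,
    min_units: Mapping[int, int] | None = None,
) -> tuple[list[ReadRecord], SimTruth]:
    """Simulate a read pool with planted repeats and primer sites.

    ``planted`` lists (motif, units, copies): the perfect run motif x units is
    spliced into ``copies`` distinct reads at random recorded positions.
    ``primer_sites`` lists (locus, primer, copies): each copy is spliced in a
    random orientation. Background bases are i.i.d. uniform ACGT, re-drawn on
    collision, so every discovery or count made downstream is exactly the
    planted truth.
    """
    mu = dict(DEFAULT_MIN_UNITS)
    if min_units:
        mu.update(min_units)
    rng = stream_rng(seed, "reads")
    all_primers = [p for _, p, _ in primer_sites]

    jobs: list[tuple[str, tuple]] = []
    for motif, units, copies in planted:
        if len(motif) * units > read_len:
            raise ValueError(f"planted repeat {motif}x{units} exceeds read_len")
        canonical_motif(motif)  # validates
        jobs += [("ssr", (motif, units))] * copies
    for locus, primer, copies in primer_sites:
        if len(primer) > read_len:
            raise ValueError(f"primer for {locus} exceeds read_len")
        jobs += [("primer", (locus, primer))] * copies
    if len(jobs) > n_reads:
        raise ValueError("more planted copies than reads")

    slots = rng.permutation(n_reads)[: len(jobs)]
    by_slot = dict(zip(slots.tolist(), jobs))

    truth = SimTruth(seed=seed, primer_copies={loc: c for loc, _, c in primer_sites})
    reads: list[ReadRecord] = []
    for i in range(n_reads):
        read_id = f"sim_{i:05d}"
        job = by_slot.get(i)
        if job is None:
            seq = _clean_background(rng, read_len, all_primers, mu)
        else:
            seq = _plant(rng, read_len, job, all_primers, mu, truth, read_id)
        reads.append(ReadRecord(read_id, seq, "I" * read_len))
    return reads, truth


def _plant(rng, read_len, job, all_primers, min_units, truth, read_id, max_tries=1000):
    kind, payload = job
    if kind == "ssr":
        motif, units = payload
        insert = motif * units
    else:
        locus, primer = payload
        strand = "+" if rng.random() < 0.5 else "-"
        insert = primer if strand == "+" else revcomp(primer)
    for _ in range(max_tries):
        pos = int(rng.integers(0, read_len - len(insert) + 1))
        seq = _clean_background(rng, read_len, all_primers, min_units)
        seq = seq[:pos] + insert + seq[pos + len(insert):]
        if kind == "ssr":
            hits = scan_read(ReadRecord(read_id, seq), min_units)
            ok = (
                len(hits) == 1
                and hits[0].start == pos
                and hits[0].end == pos + len(insert)
                and hits[0].units == units
                and not any(p in seq or revcomp(p) in seq for p in all_primers)
            )
            if ok:
                truth.planted_ssrs.append((read_id, motif, units, pos))
                return seq
        else:
            n_this = _count_overlapping(seq, primer) + (
                _count_overlapping(seq, revcomp(primer)) if revcomp(primer) != primer else 0
            )
            others = [p for p in all_primers if p != primer]
            ok = (
                n_this == 1
                and not any(p in seq or revcomp(p) in seq for p in others)
                and not scan_read(ReadRecord(read_id, seq), min_units)
            )
            if ok:
                truth.primer_positions.append((read_id, locus, pos, strand))
                return seq
    raise RuntimeError("could not plant feature without collision")


def simulate_genotypes(
    n_ind: int,
    allele_freqs: Mapping[int, float],
    null_freq: float = 0.0,
    miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    locus_id: str = "simlocus",
    replicate: bool = True,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a diploid genotype column under HWE with a null allele.

    ``allele_freqs`` maps visible allele labels (integer bp) to frequencies
    summing to 1; internally they are scaled by (1 - null_freq) and a null
    allele carries the remaining null_freq. Each individual draws two
    independent copies: null/null comes out missing, null/visible comes out
    as an apparent homozygote for the visible allele. An extra independent
    ``missing_rate`` models amplification failure unrelated to nulls. When
    ``replicate`` is set, a second genotyping round re-reports each observed
    genotype, miscalled with probability ``miscall_rate`` (one allele replaced
    by a different visible label, so a miscall always changes the unordered
    pair). Truth — including the pre-dropout genotypes — is returned alongside.
    """
    labels = sorted(allele_freqs)
    total = float(sum(allele_freqs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"visible allele frequencies sum to {total}, not 1")
    if not 0.0 <= null_freq <= 1.0:
        raise ValueError("null_freq must lie in [0, 1]")
    rng = stream_rng(seed, "genotypes", locus_id)

    full = labels + [NULL_ALLELE]
    probs = np.array([allele_freqs[a] * (1 - null_freq) for a in labels] + [null_freq])
    probs /= probs.sum()

    truth = SimTruth(
        seed=seed,
        allele_freqs={a: float(p) for a, p in zip(full, probs)},
        null_freq=null_freq,
        miscall_rate=miscall_rate if replicate else None,
        missing_rate=missing_rate,
    )
    individuals = [f"ind_{i:04d}" for i in range(n_ind)]
    calls: dict[tuple[str, str, int], tuple[int, int] | None] = {}
    # draw everything up front so the per-individual loop is cheap
    copies = rng.choice(len(full), size=(n_ind, 2), p=probs)
    u_missing = rng.random(n_ind)
    u_miscall = rng.random(n_ind)
    which_allele = rng.integers(0, 2, size=n_ind)
    wrong_draw = rng.integers(0, max(len(labels) - 1, 1), size=n_ind)
    for i, ind in enumerate(individuals):
        a, b = full[copies[i, 0]], full[copies[i, 1]]
        truth.true_genotypes[ind] = (min(a, b), max(a, b))
        if a == NULL_ALLELE and b == NULL_ALLELE:
            obs = None
        elif a == NULL_ALLELE or b == NULL_ALLELE:
            vis = b if a == NULL_ALLELE else a
            obs = (vis, vis)
        else:
            obs = (min(a, b), max(a, b))
        if obs is not None and missing_rate > 0 and u_missing[i] < missing_rate:
            obs = None
        calls[(ind, locus_id, 1)] = obs
        if replicate:
            rep = obs
            if rep is not None and len(labels) > 1 and u_miscall[i] < miscall_rate:
                which = int(which_allele[i])
                keep = rep[1 - which]
                wrong_pool = [x for x in labels if x != rep[which]]
                wrong = wrong_pool[int(wrong_draw[i]) % len(wrong_pool)]
                rep = (min(keep, wrong), max(keep, wrong))
            calls[(ind, locus_id, 2)] = rep
    return GenotypeMatrix(individuals, [locus_id], calls), truth


def combine_matrices(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge single-locus matrices (same individuals) into one multi-locus one."""
    individuals = matrices[0].individuals
    loci: list[str] = []
    calls: dict = {}
    for m in matrices:
        if m.individuals != individuals:
            raise ValueError("matrices must share the same individuals")
        loci.extend(m.loci)
        calls.update(m.calls)
    return GenotypeMatrix(individuals, loci, calls)


def simulate_peaks(
    matrix: GenotypeMatrix,
    motif_len: int | Mapping[str, int],
    jitter: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit raw fragment-size peak calls for every non-missing genotype.

    Each allele label becomes label + Uniform(-jitter, +jitter); homozygotes
    emit a single peak (the fragment-analysis convention the binning stage
    reverses). ``jitter`` must stay below half the repeat unit or bins would
    merge by construction.
    """
    rng = stream_rng(seed, "peaks")
    rows = []
    for (ind, locus, rep), call in matrix.calls.items():
        ml = motif_len if isinstance(motif_len, int) else motif_len[locus]
        if jitter >= ml / 2:
            raise ValueError("jitter must be < motif_len / 2")
        if call is None:
            continue
        a, b = call
        if a == b:
            rows.append((ind, locus, rep, a + rng.uniform(-jitter, jitter), np.nan))
        else:
            x = a + rng.uniform(-jitter, jitter)
            y = b + rng.uniform(-jitter, jitter)
            rows.append((ind, locus, rep, min(x, y), max(x, y)))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)
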