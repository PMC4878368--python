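"""Fragment-size allele binning.

Capillary electrophoresis reports fragment sizes as fractional base pairs;
true alleles of a microsatellite differ by whole repeat units. Binning turns
the raw sizes of a locus into discrete integer allele labels. Visual
histogram binning is replaced here by an explicit single-linkage gap rule,
with two quantitative surrogates for "bins could not be clearly assigned":
adjacent bins whose label spacing is not a whole number of repeat units, and
bins whose internal spread exceeds motif_len - 1. Loci scoring too high on
these are flagged ambiguous and excluded from characterization, the way a
smeared, continuous size ladder would be dropped after visual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .io_core import GenotypeMatrix

logger = logging.getLogger("msatkit")


@dataclass(frozen=True)
class AlleleBin:
    label: int  # integer bp
    lower: float  # assignment interval, inclusive
    upper: float


@dataclass
class AlleleBinMap:
    """Ordered, non-overlapping allele bins of one locus.

    Each bin's [lower, upper] is its assignment interval: the member sizes
    padded by half the gap threshold (clipped at the midpoint to the next bin
    so intervals never overlap) and always containing the bin's own label.
    """

    locus_id: str
    bins: list[AlleleBin]
    ambiguous: bool
    ambiguity_score: float

    @property
    def labels(self) -> list[int]:
        return [b.label for b in self.bins]

    def assign(self, size: float) -> int | None:
        """Bin label containing the size, or None if it falls outside all bins."""
        for b in self.bins:
            if b.lower <= size <= b.upper:
                return b.label
        return None


def bin_alleles(
    sizes: Sequence[float],
    motif_len: int,
    gap_factor: float = 0.5,
    ambiguity_threshold: float = 0.25,
    locus_id: str = "",
) -> AlleleBinMap:
    """Cluster raw fragment sizes of one locus into allele bins.

    Single-linkage on the sorted sizes: a new bin starts whenever the gap to
    the previous size exceeds ``gap_factor * motif_len``. The bin label is
    the round-half-up of the bin's median size. The ambiguity score is

        (#adjacent bin pairs whose label spacing is not a positive whole
         multiple of motif_len  +  #bins whose spread exceeds motif_len - 1)
        / #bins

    and the locus is flagged ambiguous when it exceeds the threshold.
    Deterministic and invariant to input order.
    """
    if len(sizes) == 0:
        raise ValueError(f"locus {locus_id!r}: no sizes to bin")
    if not (2 <= motif_len <= 6):
        raise ValueError(f"motif_len {motif_len} outside 2-6")
    xs = np.sort(np.asarray(sizes, dtype=float))
    gap_thr = gap_factor * motif_len

    clusters: list[list[float]] = [[xs[0]]]
    for a, b in zip(xs, xs[1:]):
        if b - a > gap_thr:
            clusters.append([])
        clusters[-1].append(b)

    pad = gap_thr / 2.0
    raw = []
    for c in clusters:
        label = round_half_up(float(np.median(c)))
        raw.append((label, min(c[0], label), max(c[-1], label), c[-1] - c[0]))

    bins: list[AlleleBin] = []
    for i, (label, lo, hi, _) in enumerate(raw):
        lower = lo - pad
        upper = hi + pad
        if i > 0:
            lower = max(lower, (raw[i - 1][2] + lo) / 2.0)
        if i + 1 < len(raw):
            upper = min(upper, (hi + raw[i + 1][1]) / 2.0)
        bins.append(AlleleBin(label, lower, upper))

    n_bad_spacing = 0
    for (la, *_), (lb, *_) in zip(raw, raw[1:]):
        d = lb - la
        if d <= 0 or d % motif_len != 0:
            n_bad_spacing += 1
    n_wide = sum(1 for (*_, spread) in raw if spread > motif_len - 1)
    score = (n_bad_spacing + n_wide) / len(raw)
    return AlleleBinMap(
        locus_id=locus_id,
        bins=bins,
        ambiguous=score > ambiguity_threshold,
        ambiguity_score=score,
    )


def assign_genotypes(
    peaks: pd.DataFrame, bin_maps: Mapping[str, AlleleBinMap]
) -> tuple[GenotypeMatrix, dict]:
    """Map raw peak calls to binned diploid genotypes.

    One peak present means a homozygote (label duplicated); a size falling
    outside every bin of its locus makes the whole call missing, is logged,
    and is tallied in the returned report. Loci flagged ambiguous must be
    excluded before calling; passing one is an error.
    """
    for locus in peaks["locus"].unique():
        if str(locus) not in bin_maps:
            raise ValueError(f"no bin map for locus {locus!r}")
        if bin_maps[str(locus)].ambiguous:
            raise ValueError(f"locus {locus!r} is flagged ambiguous; exclude it first")

    calls: dict[tuple[str, str, int], tuple[int, int] | None] = {}
    individuals: list[str] = []
    loci: list[str] = []
    n_out = 0
    n_calls = 0
    for row in peaks.itertuples(index=False):
        ind, locus, rep = str(row.individual), str(row.locus), int(row.replicate)
        bm = bin_maps[locus]
        n_calls += 1
        a = bm.assign(float(row.size_a))
        b_raw = row.size_b
        b = a if pd.isna(b_raw) else bm.assign(float(b_raw))
        if a is None or b is None:
            n_out += 1
            logger.warning(
                "assign_genotypes: %s/%s rep %d: peak outside all bins -> missing",
                ind, locus, rep,
            )
            calls[(ind, locus, rep)] = None
        else:
            calls[(ind, locus, rep)] = (min(a, b), max(a, b))
        if ind not in individuals:
            individuals.append(ind)
        if locus not in loci:
            loci.append(locus)
    report = {
        "n_calls": n_calls,
        "n_out_of_bin": n_out,
        "out_of_bin_rate": (n_out / n_calls) if n_calls else 0.0,
    }
    return GenotypeMatrix(individuals, loci, calls), report
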