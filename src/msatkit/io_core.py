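"""Readers, writers and configuration for every external format.

No science lives here: FASTQ streams, long/wide genotype CSV, peak-call CSV,
primer and read-depth TSV, the locus-summary table, and the YAML run
configuration. Every file written by the toolkit starts with a comment
header recording the tool version, a hash of the configuration and the seed,
so a result can always be traced back to the run that produced it.

Fragment sizes are fractional before binning and integer allele labels
afterwards; all coordinates are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import pandas as pd
import yaml

from ._util import DNA_ALPHABET

__version__ = "0.1.0"

logger = logging.getLogger("msatkit")

# Long-format genotype CSV columns (the native dialect).
GENOTYPE_COLUMNS = ["individual", "locus", "replicate", "size_a", "size_b"]

PEAK_COLUMNS = ["individual", "locus", "replicate", "size_a", "size_b"]

SUMMARY_COLUMNS = [
    "locus", "n", "range_min", "range_max", "n_alleles", "obs_het", "exp_het",
    "hwe_p_raw", "hwe_p_adj", "allelic_richness", "null_freq", "error_rate",
]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, upper-case bases, optional phred string."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: non-DNA symbols {sorted(bad)}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline, recorded in every output header.

    min_units
        Minimum number of perfect repeat units per motif length (kmer) for a
        run to be reported by the discovery stage.
    min_primer_count / max_primer_count
        Inclusive occurrence bounds of the PAL keep-rule. ``max_primer_count``
        of None means "derive from the genome-coverage estimate".
    gap_factor
        A new allele bin starts when the gap between sorted fragment sizes
        exceeds ``gap_factor * motif_len``.
    ambiguity_threshold
        Loci whose bin-map ambiguity score exceeds this are excluded.
    mc_permutations
        Monte-Carlo permutations (B) of the Hardy-Weinberg test.
    adjust_method
        Multiple-testing adjustment: "holm" (step-down) or "bh" (step-up FDR).
    rarefaction_g
        Standardized number of allele copies for allelic richness; None means
        twice the smallest per-locus complete sample size in the data set.
    """

    min_units: dict[int, int] = field(
        default_factory=lambda: {2: 8, 3: 6, 4: 4, 5: 4, 6: 4}
    )
    min_primer_count: int = 2
    max_primer_count: int | None = None
    gap_factor: float = 0.5
    ambiguity_threshold: float = 0.25
    mc_permutations: int = 1999
    adjust_method: str = "holm"
    rarefaction_g: int | None = None
    homozygote_from_single: bool = True
    adjust_monomorphic: bool = False
    precision: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mc_permutations < 1:
            raise ValueError("mc_permutations must be >= 1")
        if self.min_primer_count < 0:
            raise ValueError("min_primer_count must be non-negative")
        if self.gap_factor <= 0 or self.ambiguity_threshold < 0:
            raise ValueError("thresholds must be positive")
        if self.adjust_method not in ("holm", "bh"):
            raise ValueError(f"unknown adjust_method {self.adjust_method!r}")
        if any(v < 1 for v in self.min_units.values()):
            raise ValueError("min_units values must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "min_units" in data:
            data["min_units"] = {int(k): int(v) for k, v in data["min_units"].items()}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]


def header_lines(config: RunConfig | None = None) -> list[str]:
    """Comment header written at the top of every output file."""
    cfg = config or RunConfig()
    return [
        f"# msatkit {__version__}",
        f"# config_hash={cfg.config_hash()}",
        f"# seed={cfg.seed}",
    ]


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a plain or gzipped FASTQ file.

    Lower-case bases are upper-cased. Malformed four-line blocks raise a
    ValueError naming the offending line number, which Bio.SeqIO's FASTQ
    iterator does not report; the format handled here is always the plain
    four-line layout this toolkit itself writes.
    """
    count = 0
    with _open_text(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            if not head:
                break
            lineno += 1
            if not head.startswith("@"):
                raise ValueError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(
                    f"{path}: line {lineno}: truncated FASTQ record"
                )
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"{path}: line {lineno - 1}: expected '+' line")
            seq = seq.strip().upper()
            qual = qual.rstrip("\n")
            if len(qual) != len(seq):
                raise ValueError(
                    f"{path}: line {lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            count += 1
            yield ReadRecord(head[1:].strip().split()[0], seq, qual)
    logger.info("read_fastq: %d records from %s", count, path)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as four-line FASTQ (gzipped if path ends in .gz)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid calls per (individual, locus, replicate).

    A call is an unordered pair of integer allele labels (binned fragment
    sizes in bp) stored sorted, or None for missing. Missingness is explicit:
    every (individual, locus, replicate) combination present in the source
    keeps its key, so round-trips preserve the missing-data pattern exactly.
    """

    individuals: list[str]
    loci: list[str]
    calls: dict[tuple[str, str, int], tuple[int, int] | None]

    @property
    def replicates(self) -> list[int]:
        return sorted({k[2] for k in self.calls})

    def get(self, individual: str, locus: str, replicate: int = 1):
        return self.calls.get((individual, locus, replicate))

    def complete_genotypes(self, locus: str, replicate: int = 1) -> dict[str, tuple[int, int]]:
        """Individuals with a non-missing call at the locus, in input order."""
        out = {}
        for ind in self.individuals:
            g = self.calls.get((ind, locus, replicate))
            if g is not None:
                out[ind] = g
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (ind, locus, rep), call in self.calls.items():
            a, b = (call if call is not None else (None, None))
            rows.append((ind, locus, rep, a, b))
        return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def _normalize_pair(a, b, homozygote_from_single: bool):
    """Turn raw (size_a, size_b) cells into a sorted pair, None, or 'half'."""
    a_missing = a is None or (isinstance(a, float) and pd.isna(a))
    b_missing = b is None or (isinstance(b, float) and pd.isna(b))
    if a_missing and b_missing:
        return None
    if a_missing or b_missing:
        present = b if a_missing else a
        if homozygote_from_single:
            v = int(round(float(present)))
            return (v, v)
        return "half"
    x, y = int(round(float(a))), int(round(float(b)))
    return (min(x, y), max(x, y))


def read_genotype_table(
    path: str | Path,
    layout: str = "long",
    column_map: Mapping[str, str] | None = None,
    homozygote_from_single: bool = True,
) -> GenotypeMatrix:
    """Read a genotype CSV into a GenotypeMatrix.

    The native dialect is long format with columns
    ``individual,locus,replicate,size_a,size_b``; missing is an empty cell or
    "NA". ``column_map`` renames source columns to the native names, so a
    deposited table with its own header can be ingested without editing.
    A wide layout (one row per individual, two columns ``<locus>_a`` /
    ``<locus>_b`` per locus) is accepted and normalized to long on read.

    Rows with exactly one allele present become homozygous pairs when
    ``homozygote_from_single`` is true (the fragment-analysis convention);
    otherwise they are flagged invalid and stored as missing.
    """
    df = pd.read_csv(path, comment="#", na_values=["NA", ""], dtype={0: str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    if layout == "wide":
        df = _wide_to_long(df)
    elif layout != "long":
        raise ValueError(f"unknown layout {layout!r}")
    missing_cols = [c for c in GENOTYPE_COLUMNS[:2] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    for col in ("size_a", "size_b"):
        if col not in df.columns:
            df[col] = pd.NA

    calls: dict[tuple[str, str, int], tuple[int, int] | None] = {}
    individuals: list[str] = []
    loci: list[str] = []
    n_half = 0
    for row in df.itertuples(index=False):
        ind, locus, rep = str(row.individual), str(row.locus), int(row.replicate)
        key = (ind, locus, rep)
        if key in calls:
            raise ValueError(f"{path}: duplicate call for {key}")
        pair = _normalize_pair(row.size_a, row.size_b, homozygote_from_single)
        if pair == "half":
            n_half += 1
            pair = None
        calls[key] = pair
        if ind not in individuals:
            individuals.append(ind)
        if locus not in loci:
            loci.append(locus)
    if n_half:
        logger.warning(
            "read_genotype_table: %d half-calls (one allele) treated as invalid",
            n_half,
        )
    return GenotypeMatrix(individuals, loci, calls)


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    if "individual" not in df.columns:
        raise ValueError("wide genotype table needs an 'individual' column")
    locus_cols = [c for c in df.columns if c not in ("individual", "replicate")]
    loci = []
    for c in locus_cols:
        if c.endswith("_a"):
            if c[:-2] + "_b" not in locus_cols:
                raise ValueError(f"unknown locus column {c!r}: no matching _b")
            loci.append(c[:-2])
        elif not c.endswith("_b"):
            raise ValueError(f"unknown locus column {c!r}")
    rows = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        rep = int(d.get("replicate", 1) or 1)
        for locus in loci:
            rows.append(
                (d["individual"], locus, rep, d[f"{locus}_a"], d[f"{locus}_b"])
            )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def write_genotype_table(
    matrix: GenotypeMatrix, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write the long-format CSV; missing alleles become empty cells."""
    df = matrix.to_frame()
    with open(path, "w") as fh:
        fh.write("\n".join(header_lines(config)) + "\n")
        df.to_csv(fh, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Peak calls, primers, depths
# ---------------------------------------------------------------------------

def read_peak_calls(path: str | Path) -> pd.DataFrame:
    """Raw fragment-size peak calls: individual, locus, replicate, size_a[, size_b].

    Sizes may be fractional (capillary estimates); size_a <= size_b when both
    are present and all sizes are positive.
    """
    df = pd.read_csv(path, comment="#", na_values=["NA", ""])
    missing = [c for c in ("individual", "locus", "size_a") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if "size_b" not in df.columns:
        df["size_b"] = pd.NA
    both = df["size_b"].notna() & df["size_a"].notna()
    if (df.loc[df["size_a"].notna(), "size_a"] <= 0).any():
        raise ValueError(f"{path}: non-positive fragment size")
    if (df.loc[both, "size_a"] > df.loc[both, "size_b"]).any():
        raise ValueError(f"{path}: size_a > size_b")
    return df[PEAK_COLUMNS]


def read_primer_table(path: str | Path) -> pd.DataFrame:
    """TSV of candidate loci: locus, forward, reverse primer sequences."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("locus", "forward", "reverse") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_depth_table(path: str | Path) -> dict[str, list[float]]:
    """Per-gene per-position depth TSV (gene, position, depth) -> depth lists."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("gene", "position", "depth") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, list[float]] = {}
    for gene, sub in df.groupby("gene", sort=False):
        out[str(gene)] = sub["depth"].astype(float).tolist()
    return out


# ---------------------------------------------------------------------------
# Locus summaries
# ---------------------------------------------------------------------------

def write_locus_summaries(
    summaries: Sequence,
    path: str | Path,
    config: RunConfig | None = None,
    precision: int | None = None,
) -> None:
    """One TSV row per locus, mirroring a characterization table.

    Columns are fixed (see SUMMARY_COLUMNS); floats are printed at the
    configured precision (default 2 decimals) and an absent error rate is an
    empty cell.
    """
    prec = precision if precision is not None else (config or RunConfig()).precision

    def fmt(x) -> str:
        if x is None:
            return ""
        if isinstance(x, float):
            return f"{x:.{prec}f}"
        return str(x)

    with open(path, "w") as fh:
        fh.write("\n".join(header_lines(config)) + "\n")
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            row = [
                s.locus_id, s.n, s.range_min, s.range_max, s.n_alleles,
                float(s.obs_het), float(s.exp_het), float(s.hwe_p_raw),
                float(s.hwe_p_adj), float(s.allelic_richness),
                float(s.null_freq),
                None if s.error_rate is None else float(s.error_rate),
            ]
            fh.write("\t".join(fmt(x) for x in row) + "\n")


def read_locus_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
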