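"""Per-locus population-genetic characterization of microsatellite markers.

For each scorable locus this module computes the sample size, fragment-size
range, allele count, observed and expected heterozygosity, a Monte-Carlo
Hardy-Weinberg test with multiple-testing adjustment across loci, rarefaction
allelic richness, the Brookfield (1996) null-allele frequency estimate, and a
replicate genotyping error rate.

Expected heterozygosity uses Nei's unbiased small-sample estimator

    He = 2n/(2n - 1) * (1 - sum_i p_i^2)

which equals the probability that two allele copies drawn without replacement
from the sample differ. The Brookfield estimator

    r = max(0, (He - Ho) / (1 + He))

infers the frequency of a non-amplifying (null) allele from the heterozygote
deficit; it is zero whenever observed meets or exceeds expected
heterozygosity. Allelic richness is the expected number of distinct alleles
in a hypergeometric subsample of g copies,

    A(g) = sum_i [1 - C(N - N_i, g) / C(N, g)],

computed with log-gamma for numerical stability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from ._util import stream_rng
from .io_core import GenotypeMatrix, RunConfig

Genotype = tuple[int, int]


@dataclass(frozen=True)
class AlleleCounts:
    """Allele copy counts at one locus (N = 2 x number of individuals)."""

    locus_id: str
    counts: dict[int, int]
    N: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.N:
            raise ValueError("allele counts must sum to N")
        if self.N % 2:
            raise ValueError("N (allele copies) must be even")

    @classmethod
    def from_genotypes(cls, genotypes: Sequence[Genotype], locus_id: str = "") -> "AlleleCounts":
        c: Counter = Counter()
        for a, b in genotypes:
            c[a] += 1
            c[b] += 1
        return cls(locus_id, dict(c), 2 * len(genotypes))

    def frequencies(self) -> dict[int, float]:
        return {a: n / self.N for a, n in self.counts.items()}


@dataclass
class LocusSummary:
    """One characterization-table row for one locus."""

    locus_id: str
    n: int
    range_min: int
    range_max: int
    n_alleles: int
    obs_het: float
    exp_het: float
    hwe_p_raw: float
    hwe_p_adj: float
    allelic_richness: float
    null_freq: float
    error_rate: float | None = None


def observed_het(genotypes: Sequence[Genotype]) -> float:
    """Fraction of complete genotypes that are heterozygous."""
    if len(genotypes) == 0:
        raise ValueError("no complete genotypes")
    return sum(1 for a, b in genotypes if a != b) / len(genotypes)


def expected_het(counts: AlleleCounts, unbiased: bool = True) -> float:
    """Nei's expected heterozygosity; unbiased applies the 2n/(2n-1) factor."""
    if counts.N < 2:
        raise ValueError("need at least two allele copies")
    ss = sum((n / counts.N) ** 2 for n in counts.counts.values())
    h = 1.0 - ss
    if unbiased:
        h *= counts.N / (counts.N - 1)
    return h


def _expected_class_counts(freqs: np.ndarray, n: int) -> np.ndarray:
    """HWE-expected genotype-class counts as a flat (k*k) vector.

    Class (i, j) with i <= j sits at index i*k + j; expected counts are
    n p_i^2 for homozygotes and 2 n p_i p_j for heterozygotes. Entries for
    i > j stay zero and are masked out of the statistic.
    """
    k = len(freqs)
    exp = np.zeros(k * k)
    for i in range(k):
        exp[i * k + i] = n * freqs[i] ** 2
        for j in range(i + 1, k):
            exp[i * k + j] = 2 * n * freqs[i] * freqs[j]
    return exp


def _class_counts(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """Genotype-class counts (rows x k*k) from paired allele-code arrays."""
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    idx = lo * k + hi
    if idx.ndim == 1:
        return np.bincount(idx, minlength=k * k)
    rows = idx.shape[0]
    offsets = (np.arange(rows) * (k * k))[:, None]
    return np.bincount((idx + offsets).ravel(), minlength=rows * k * k).reshape(
        rows, k * k
    )


def hwe_test_mc(
    genotypes: Sequence[Genotype],
    B: int = 1999,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo Hardy-Weinberg test p-value for one locus.

    The statistic is the Pearson chi-square of observed genotype-class counts
    against HWE expectations at the sample allele frequencies. The null
    distribution comes from B random re-pairings of the pooled allele copies
    (shuffle the 2n copies, pair consecutive); the p-value is
    (1 + #{permuted stat >= observed}) / (B + 1), so a fixed seed makes it
    bit-reproducible. Monomorphic loci return 1 by convention.
    """
    counts = AlleleCounts.from_genotypes(genotypes)
    k = len(counts.counts)
    if k < 2:
        return 1.0
    rng = rng if rng is not None else stream_rng(seed, "hwe")
    n = len(genotypes)
    alleles = sorted(counts.counts)
    code = {a: i for i, a in enumerate(alleles)}
    freqs = np.array([counts.counts[a] / counts.N for a in alleles])
    exp = _expected_class_counts(freqs, n)
    mask = exp > 0

    obs_a = np.array([code[g[0]] for g in genotypes])
    obs_b = np.array([code[g[1]] for g in genotypes])
    obs_counts = _class_counts(obs_a, obs_b, k)
    obs = float(((obs_counts[mask] - exp[mask]) ** 2 / exp[mask]).sum())

    pool = np.concatenate([obs_a, obs_b])
    perms = rng.permuted(np.tile(pool, (B, 1)), axis=1)
    perm_counts = _class_counts(perms[:, 0::2], perms[:, 1::2], k)
    stats = ((perm_counts[:, mask] - exp[mask]) ** 2 / exp[mask]).sum(axis=1)
    return float((1 + (stats >= obs - 1e-12).sum()) / (B + 1))


def adjust_pvalues(pvals: Sequence[float], method: str = "holm") -> list[float]:
    """Holm step-down or Benjamini-Hochberg step-up adjusted p-values,
    order-preserving with the input and clipped at 1."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return list(multipletests(arr, method=key)[1])


def null_allele_freq(obs_het: float, exp_het: float) -> float:
    """Brookfield estimator 1 of the null-allele frequency.

    r = (He - Ho) / (1 + He), truncated at zero when observed heterozygosity
    meets or exceeds the expectation. Rounding happens only at report time.
    """
    for name, v in (("obs_het", obs_het), ("exp_het", exp_het)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return max(0.0, (exp_het - obs_het) / (1.0 + exp_het))


def _log_comb(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def allelic_richness(counts: AlleleCounts, g: int) -> float:
    """Rarefaction allelic richness: expected distinct alleles among g copies
    drawn without replacement from the N sampled copies."""
    if not 1 <= g <= counts.N:
        raise ValueError(f"g={g} outside [1, N={counts.N}]")
    total = 0.0
    for ni in counts.counts.values():
        if counts.N - ni < g:
            total += 1.0  # the allele is certainly in every subsample
        else:
            total += 1.0 - np.exp(_log_comb(counts.N - ni, g) - _log_comb(counts.N, g))
    return float(total)


def genotyping_error_rate(
    rep1: Mapping[str, Genotype], rep2: Mapping[str, Genotype]
) -> float:
    """Per-genotype discordance between two replicate genotyping rounds.

    Individuals with a complete genotype in both replicates are compared as
    unordered allele pairs; the rate is the fraction that differ.
    """
    common = [k for k in rep1 if k in rep2]
    if not common:
        raise ValueError("no individual is complete in both replicates")
    diff = sum(
        1 for k in common
        if tuple(sorted(rep1[k])) != tuple(sorted(rep2[k]))
    )
    return diff / len(common)


def summarize_locus(
    locus_id: str,
    genotypes: Mapping[str, Genotype],
    replicate: Mapping[str, Genotype] | None = None,
    config: RunConfig | None = None,
    g: int | None = None,
) -> LocusSummary:
    """Assemble every characterization statistic for one locus.

    ``genotypes`` maps individual -> complete genotype (missing individuals
    simply absent). ``g`` is the rarefaction size; by default the full sample
    (g = N), which makes richness equal the allele count — pipeline-level
    callers pass the standardized g instead. The adjusted p-value is filled
    with the raw one here and overwritten by the across-locus adjustment.
    """
    cfg = config or RunConfig()
    gts = list(genotypes.values())
    if not gts:
        raise ValueError(f"locus {locus_id!r}: no complete genotypes")
    counts = AlleleCounts.from_genotypes(gts, locus_id)
    ho = observed_het(gts)
    he = expected_het(counts) if counts.N >= 2 else 0.0
    g_eff = min(g if g is not None else counts.N, counts.N)
    p = hwe_test_mc(
        gts, B=cfg.mc_permutations,
        rng=stream_rng(cfg.seed, "hwe", locus_id),
    )
    err = None
    if replicate is not None:
        err = genotyping_error_rate(genotypes, replicate)
    labels = sorted(counts.counts)
    return LocusSummary(
        locus_id=locus_id,
        n=len(gts),
        range_min=labels[0],
        range_max=labels[-1],
        n_alleles=len(labels),
        obs_het=ho,
        exp_het=he,
        hwe_p_raw=p,
        hwe_p_adj=p,
        allelic_richness=allelic_richness(counts, g_eff),
        null_freq=null_allele_freq(ho, he),
        error_rate=err,
    )


def characterize(
    matrix: GenotypeMatrix,
    config: RunConfig | None = None,
    replicate_pair: tuple[int, int] = (1, 2),
) -> list[LocusSummary]:
    """Characterize every locus of a genotype matrix.

    The rarefaction size defaults to twice the smallest per-locus complete
    sample size across loci (config.rarefaction_g overrides). Error rates are
    computed when the matrix carries both replicates of ``replicate_pair``.
    HWE p-values are adjusted across loci with the configured method;
    monomorphic loci (p = 1 by convention) join the adjustment only when
    ``config.adjust_monomorphic`` is set, and keep p_adj = 1 otherwise.
    """
    cfg = config or RunConfig()
    rep_main, rep_other = replicate_pair
    has_replicate = rep_other in matrix.replicates

    per_locus: dict[str, dict[str, Genotype]] = {}
    for locus in matrix.loci:
        gts = matrix.complete_genotypes(locus, rep_main)
        if gts:
            per_locus[locus] = gts
    if not per_locus:
        raise ValueError("no locus has any complete genotype")

    if cfg.rarefaction_g is not None:
        g = cfg.rarefaction_g
    else:
        g = 2 * min(len(v) for v in per_locus.values())

    summaries = []
    for locus, gts in per_locus.items():
        rep = matrix.complete_genotypes(locus, rep_other) if has_replicate else None
        summaries.append(summarize_locus(locus, gts, rep, cfg, g=g))

    if cfg.adjust_monomorphic:
        idx = list(range(len(summaries)))
    else:
        idx = [i for i, s in enumerate(summaries) if s.n_alleles > 1]
    if idx:
        adj = adjust_pvalues([summaries[i].hwe_p_raw for i in idx], cfg.adjust_method)
        for i, p in zip(idx, adj):
            summaries[i].hwe_p_adj = p
    return summaries
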