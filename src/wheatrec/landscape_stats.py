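"""Recombination-landscape summaries and the DSB expectation calculator.

Includes the shared-CO census across lines, the genic-bias comparison
(gene counts in windows centred on COs versus windows centred on all array
SNPs), chromosome-length-normalized genome profiles with a trailing moving
average, average-linkage clustering of CO profiles with plain bootstrap
support, and the arithmetic chain from cytologically counted double-strand
breaks (DSBs) to the number of potentially detectable allelic gene
conversions after single-seed descent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.spatial.distance import pdist, squareform

from .io_formats import GeneIndex, GenomeLayout, RecombinationEvent


def shared_event_distribution(
    events_by_line: Mapping[str, Sequence[RecombinationEvent]],
) -> dict:
    """Histogram of how many lines share each distinct CO site.

    Array COs are keyed by (chrom, window-start position); the histogram
    maps sharing count -> number of sites, and the fraction of sites seen
    in exactly one line is reported alongside.
    """
    site_lines: dict[tuple[str, int], set[str]] = {}
    for line, events in events_by_line.items():
        for e in events:
            site_lines.setdefault((e.chrom, e.start), set()).add(line)
    hist: dict[int, int] = {}
    for lines in site_lines.values():
        hist[len(lines)] = hist.get(len(lines), 0) + 1
    n_sites = len(site_lines)
    return {
        "histogram": dict(sorted(hist.items())),
        "n_sites": n_sites,
        "unique_fraction": hist.get(1, 0) / n_sites if n_sites else float("nan"),
    }


def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample two-tailed Welch t test; identical degenerate samples give
    t = 0, p = 1 rather than NaN."""
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def gene_association_stats(
    co_sites: Sequence[tuple[str, int]],
    snp_sites: Sequence[tuple[str, int]],
    genes: GeneIndex,
    layout: GenomeLayout,
    window: int = 40_000_000,
    sharing: Sequence[int] | None = None,
) -> dict:
    """Do COs sit in gene-rich neighbourhoods?

    Counts genes overlapping the ``window``-bp interval centred on each CO
    site, compares against equally sized windows centred on every array SNP
    (Welch two-tailed t test), and, when per-CO sharing counts are given,
    reports the Pearson correlation between gene count and the number of
    lines carrying the CO. Windows are clipped at chromosome ends.
    """
    half = window // 2

    def counts(sites):
        out = []
        for chrom, pos in sites:
            lo = max(1, pos - half)
            hi = min(layout.lengths[chrom], pos + half)
            out.append(genes.count(chrom, lo, hi))
        return np.asarray(out, dtype=float)

    co_counts = counts(co_sites)
    snp_counts = counts(snp_sites)
    t, p = _welch_t(co_counts, snp_counts)
    result = {
        "co_gene_counts": co_counts,
        "snp_gene_counts": snp_counts,
        "t_statistic": t,
        "p_value": p,
        "mean_co_genes": float(co_counts.mean()),
        "mean_snp_genes": float(snp_counts.mean()),
    }
    if sharing is not None:
        share = np.asarray(sharing, dtype=float)
        if len(share) != len(co_counts):
            raise ValueError("sharing vector length must match CO sites")
        if len(share) < 2:
            raise ValueError("need at least 2 COs for a correlation")
        if np.var(share) == 0 or np.var(co_counts) == 0:
            r, pr = float("nan"), float("nan")
        else:
            r, pr = sps.pearsonr(co_counts, share)
        result["pearson_r"] = float(r)
        result["pearson_p"] = float(pr)
    return result


def normalized_genome_profile(
    events: Sequence[RecombinationEvent],
    layout: GenomeLayout,
    target_length: int = 500_000_000,
    bin_size: int = 20_000_000,
    ma_period: int = 15,
) -> dict:
    """Event density along a common normalized chromosome axis.

    Every event position is scaled by target_length / chromosome length,
    counts are accumulated in ``bin_size`` bins of the normalized axis
    across all chromosomes, and a trailing simple moving average of window
    ``ma_period`` is reported (NaN for the first period-1 bins).
    """
    n_bins = int(np.ceil(target_length / bin_size))
    if ma_period > n_bins:
        raise ValueError("moving-average period exceeds the number of bins")
    counts = np.zeros(n_bins, dtype=np.int64)
    for e in events:
        L = layout.lengths[e.chrom]
        scaled = e.start * target_length / L
        k = min(int((scaled - 1) // bin_size), n_bins - 1)
        counts[max(k, 0)] += 1
    ma = np.full(n_bins, np.nan)
    if len(counts) >= ma_period:
        kernel = np.ones(ma_period) / ma_period
        ma[ma_period - 1 :] = np.convolve(counts, kernel, mode="valid")
    return {"bin_size": bin_size, "counts": counts, "moving_average": ma}


def correlation_dissimilarity(matrix: np.ndarray) -> np.ndarray:
    """Condensed pairwise dissimilarity d = 1 - Pearson r between rows."""
    d = pdist(matrix, metric="correlation")
    return np.nan_to_num(d, nan=1.0)  # zero-variance resamples -> uncorrelated


def _clades(linkage: np.ndarray, n: int) -> set[frozenset[int]]:
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    clades = set()
    for k, (a, b, _h, _c) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        clades.add(merged)
    return clades


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    support: dict[frozenset[str], float]

    def clade_support(self, *labels: str) -> float:
        return self.support.get(frozenset(labels), 0.0)


def cluster_profiles(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    bootstrap: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Average-linkage clustering of profile rows with bootstrap support.

    Dissimilarity is 1 - Pearson r between row vectors. Clade support is
    the plain bootstrap proportion: the fraction of ``bootstrap``
    column-resampled trees containing the clade. Zero-variance rows cannot
    be placed by a correlation metric and are dropped with a warning.
    Deterministic given ``seed``.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index) if labels is None else list(labels)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(len(X))] if labels is None else list(labels)
    keep = X.std(axis=1) > 0
    if not keep.all():
        dropped = [l for l, k in zip(labels, keep) if not k]
        warnings.warn(f"dropping zero-variance rows: {dropped}")
        X = X[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    n = len(X)
    if n < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    Z = _average_linkage(correlation_dissimilarity(X))
    ref_clades = _clades(Z, n)
    counts = {c: 0 for c in ref_clades}
    rng = np.random.default_rng(seed)
    m = X.shape[1]
    for _ in range(bootstrap):
        cols = rng.integers(0, m, size=m)
        Zb = _average_linkage(correlation_dissimilarity(X[:, cols]))
        for clade in _clades(Zb, n):
            if clade in counts:
                counts[clade] += 1
    support = {
        frozenset(labels[i] for i in clade): c / bootstrap
        for clade, c in counts.items()
    }
    return ClusterResult(labels=labels, linkage=Z, support=support)


@dataclass
class DsbParams:
    """Parameters of the DSB -> detectable-allelic-GC expectation chain.

    ``mean_foci``/``sd_foci``: immunostained DSB focus count per male
    meiosis; ``sex_factor`` doubles the count to include female meioses;
    ``generations`` is the number of meioses an F_n single-seed-descent line
    has passed through; ``halving_ratio`` is the per-generation decay of
    detectability as homozygosity rises (~50%).
    """

    mean_foci: float = 2133.0
    sd_foci: float = 157.0
    sex_factor: float = 2.0
    generations: int = 8
    halving_ratio: float = 0.5

    def __post_init__(self):
        if not (self.mean_foci > self.sd_foci >= 0):
            raise ValueError("require mean > sd >= 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0 < self.halving_ratio <= 1):
            raise ValueError("halving ratio must lie in (0, 1]")


def dsb_expectations(params: DsbParams | None = None) -> dict:
    """Expected DSB counts per meiosis, cumulatively over the generations,
    and the number with the potential to be detectable allelic GCs.

    Per-meiosis bounds are sex_factor x (mean -+ sd); the cumulative range
    multiplies by the generation count; the detectable range discounts each
    successive generation by the halving ratio (exact geometric sum, then
    rounded up to a whole event).
    """
    p = params or DsbParams()
    lo = p.sex_factor * (p.mean_foci - p.sd_foci)
    hi = p.sex_factor * (p.mean_foci + p.sd_foci)
    geom = sum(p.halving_ratio ** (g - 1) for g in range(1, p.generations + 1))
    return {
        "per_meiosis": (lo, hi),
        "cumulative": (p.generations * lo, p.generations * hi),
        "detectable": (math.ceil(lo * geom), math.ceil(hi * geom)),
    }
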