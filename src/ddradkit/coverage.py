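"""Coverage diagnostics for multiplexed libraries.

Per-sample and merged breadth/depth, fixed-width bin count matrices,
sample-sample correlation with clustering order, PCA on binned counts,
per-pool common sites, and the experimental-vs-artificial pool comparison.

Aligned read mates are treated as independent segments throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

__all__ = [
    "AlignmentSet",
    "CoverageSummary",
    "BinCountMatrix",
    "CorrelationResult",
    "PCAResult",
    "PoolComparison",
    "coverage_summary",
    "bin_counts",
    "correlation_matrix",
    "pca_bins",
    "common_sites",
    "artificial_pool_test",
]

# segments for one sample: chrom -> (n, 2) int array of 0-based half-open intervals
Segments = Dict[str, np.ndarray]


@dataclass
class AlignmentSet:
    """Aligned segments per sample plus chromosome sizes and pool assignment."""

    chrom_lengths: Dict[str, int]
    segments: Dict[str, Segments] = field(default_factory=dict)
    pools: Dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> List[str]:
        return list(self.segments)

    def add_sample(self, sample: str, segs: Segments, pool: Optional[str] = None) -> None:
        for chrom, arr in segs.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"unknown chromosome {chrom!r} for sample {sample!r}")
            if arr.size and (arr[:, 0].min() < 0 or arr[:, 1].max() > self.chrom_lengths[chrom]):
                raise ValueError(f"segment outside chromosome bounds on {chrom!r}")
        self.segments[sample] = segs
        if pool is not None:
            self.pools[sample] = pool

    def n_segments(self, sample: str) -> int:
        return sum(len(a) for a in self.segments[sample].values())

    def merged_segments(self, samples: Optional[Sequence[str]] = None) -> Segments:
        samples = list(samples) if samples is not None else self.samples
        merged: Segments = {}
        for chrom in self.chrom_lengths:
            arrs = [
                self.segments[s][chrom]
                for s in samples
                if chrom in self.segments[s] and len(self.segments[s][chrom])
            ]
            if arrs:
                merged[chrom] = np.concatenate(arrs, axis=0)
        return merged


def _depth_array(segs: np.ndarray, length: int) -> np.ndarray:
    """Per-position depth via a difference array (vectorized pileup)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    if len(segs):
        np.add.at(diff, segs[:, 0], 1)
        np.add.at(diff, segs[:, 1], -1)
    return np.cumsum(diff[:-1])


def covered_mask(
    segs: Segments, chrom_lengths: Mapping[str, int], depth_min: int = 1
) -> Dict[str, np.ndarray]:
    """Boolean per-position mask of sites with depth >= depth_min."""
    return {
        chrom: _depth_array(segs.get(chrom, np.empty((0, 2), dtype=np.int64)), ln) >= depth_min
        for chrom, ln in chrom_lengths.items()
    }


@dataclass
class CoverageSummary:
    covered_positions: int
    genome_length: int
    breadth_fraction: float
    mean_depth: float
    depth_min: int

    def to_dict(self) -> dict:
        return {
            "covered_positions": self.covered_positions,
            "genome_length": self.genome_length,
            "breadth_fraction": self.breadth_fraction,
            "mean_depth": self.mean_depth,
            "depth_min": self.depth_min,
        }


def coverage_summary(
    segs: Segments, chrom_lengths: Mapping[str, int], depth_min: int = 1
) -> CoverageSummary:
    """Breadth (fraction of positions with depth >= depth_min) and mean depth
    over the covered positions only."""
    genome_length = sum(chrom_lengths.values())
    if genome_length == 0:
        raise ValueError("genome length is zero")
    covered = 0
    depth_sum = 0
    for chrom, ln in chrom_lengths.items():
        depth = _depth_array(segs.get(chrom, np.empty((0, 2), dtype=np.int64)), ln)
        mask = depth >= depth_min
        covered += int(mask.sum())
        depth_sum += int(depth[mask].sum())
    mean_depth = depth_sum / covered if covered else 0.0
    return CoverageSummary(covered, genome_length, covered / genome_length, mean_depth, depth_min)


@dataclass
class BinCountMatrix:
    """Samples x fixed-width genome bins read-count matrix.

    A segment contributes to exactly one bin: the one containing its leftmost
    aligned base. The last bin of each chromosome may be short.
    """

    bin_size: int
    samples: List[str]
    bins: List[Tuple[str, int, int]]
    counts: np.ndarray  # (n_samples, n_bins) int64

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{c}:{s}-{e}" for c, s, e in self.bins]
        return pd.DataFrame(self.counts.T, index=idx, columns=self.samples)


def bin_counts(aset: AlignmentSet, bin_size: int = 1000) -> BinCountMatrix:
    bins: List[Tuple[str, int, int]] = []
    offsets: Dict[str, int] = {}
    for chrom, ln in aset.chrom_lengths.items():
        offsets[chrom] = len(bins)
        for start in range(0, ln, bin_size):
            bins.append((chrom, start, min(start + bin_size, ln)))
    counts = np.zeros((len(aset.samples), len(bins)), dtype=np.int64)
    for i, sample in enumerate(aset.samples):
        for chrom, segs in aset.segments[sample].items():
            if not len(segs):
                continue
            idx = offsets[chrom] + segs[:, 0] // bin_size
            np.add.at(counts[i], idx, 1)
    return BinCountMatrix(bin_size, list(aset.samples), bins, counts)


@dataclass
class CorrelationResult:
    corr: pd.DataFrame
    order: List[str]          # dendrogram leaf order (average linkage on 1 - r)
    excluded: List[str]       # constant-count samples, undefined correlation

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "excluded": self.excluded,
            "corr": self.corr.to_dict(),
        }


def correlation_matrix(bcm: BinCountMatrix, method: str = "spearman") -> CorrelationResult:
    """Pairwise sample correlations of bin counts plus a clustering order."""
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if len(bcm.samples) < 2:
        raise ValueError("need at least two samples")
    df = pd.DataFrame(bcm.counts.T, columns=bcm.samples)
    constant = [s for s in bcm.samples if df[s].nunique() <= 1]
    kept = [s for s in bcm.samples if s not in constant]
    corr = df[kept].corr(method=method)
    if len(kept) > 2:
        dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
        order = [kept[i] for i in leaves_list(average(dist))]
    else:
        order = kept
    return CorrelationResult(corr, order, constant)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    explained_pct: np.ndarray     # percentage of variance per component

    def to_dict(self) -> dict:
        return {
            "explained_pct": [float(x) for x in self.explained_pct],
            "scores": self.scores.to_dict(),
        }


def pca_bins(bcm: BinCountMatrix, n_components: Optional[int] = None) -> PCAResult:
    """PCA of log1p bin counts, bin-wise centered, no scaling."""
    n = len(bcm.samples)
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    from sklearn.decomposition import PCA

    x = np.log1p(bcm.counts.astype(float))
    n_components = n_components or min(n - 1, 10)
    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore", divide="ignore"):  # all-constant input
        scores = pca.fit_transform(x)  # sklearn centers features (bins) itself
        explained = np.nan_to_num(pca.explained_variance_ratio_) * 100.0
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(pd.DataFrame(scores, index=bcm.samples, columns=cols), explained)


def common_sites(
    aset: AlignmentSet, samples: Sequence[str], depth_min: int = 1
) -> int:
    """Genome positions covered at depth >= depth_min in ALL given samples."""
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    total = 0
    for chrom, ln in aset.chrom_lengths.items():
        inter: Optional[np.ndarray] = None
        for s in samples:
            segs = aset.segments[s].get(chrom, np.empty((0, 2), dtype=np.int64))
            mask = _depth_array(segs, ln) >= depth_min
            inter = mask if inter is None else (inter & mask)
            if not inter.any():
                break
        total += int(inter.sum())
    return total


@dataclass
class PoolComparison:
    pools: List[str]
    experimental: List[int]
    artificial: List[int]
    mean_experimental: float
    mean_artificial: float
    t_statistic: float
    p_value: float
    n_pools: int

    def to_dict(self) -> dict:
        return {
            "pools": self.pools,
            "experimental_common_sites": self.experimental,
            "artificial_common_sites": self.artificial,
            "mean_experimental": self.mean_experimental,
            "mean_artificial": self.mean_artificial,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_pools": self.n_pools,
        }


def artificial_pool_test(
    aset: AlignmentSet,
    k_per_pool: int = 3,
    seed: int = 0,
    depth_min: int = 1,
) -> PoolComparison:
    """Compare common sites of experimental pools against in silico re-pools.

    Each artificial pool draws ``k_per_pool`` samples from every experimental
    pool, without replacement, so every sample is used exactly once. Requires
    equal-sized pools with ``k_per_pool * n_pools == pool size``. Significance
    is a paired two-sided t-test across pools.
    """
    pools: Dict[str, List[str]] = {}
    for sample in aset.samples:
        if sample not in aset.pools:
            raise ValueError(f"sample {sample!r} has no pool assignment")
        pools.setdefault(aset.pools[sample], []).append(sample)
    pool_names = sorted(pools)
    n_pools = len(pool_names)
    sizes = {len(v) for v in pools.values()}
    if len(sizes) != 1:
        raise ValueError(f"pools are not equal-sized: { {p: len(v) for p, v in pools.items()} }")
    (pool_size,) = sizes
    if k_per_pool * n_pools != pool_size:
        raise ValueError(
            f"k_per_pool ({k_per_pool}) x n_pools ({n_pools}) != pool size ({pool_size})"
        )

    rng = np.random.default_rng(seed)
    artificial: List[List[str]] = [[] for _ in range(n_pools)]
    for name in pool_names:
        members = list(pools[name])
        rng.shuffle(members)
        for j in range(n_pools):
            artificial[j].extend(members[j * k_per_pool : (j + 1) * k_per_pool])

    exp_counts = [common_sites(aset, pools[p], depth_min) for p in pool_names]
    art_counts = [common_sites(aset, grp, depth_min) for grp in artificial]
    t_stat, p_val = stats.ttest_rel(exp_counts, art_counts)
    return PoolComparison(
        pools=pool_names,
        experimental=exp_counts,
        artificial=art_counts,
        mean_experimental=float(np.mean(exp_counts)),
        mean_artificial=float(np.mean(art_counts)),
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_pools=n_pools,
    )
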