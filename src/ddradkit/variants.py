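"""Variant-set summaries: SSR detection, Ts/Tv, InDel statistics, sharing
distribution, MAF/missingness filtering, rate summaries, and variant density.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SSRRecord",
    "VariantRecord",
    "GenotypeMatrix",
    "DEFAULT_MIN_REPEATS",
    "ssr_scan",
    "classify_indel_ssr",
    "tstv",
    "indel_stats",
    "sharing_distribution",
    "filter_dataset",
    "rate_summary",
    "density_windows",
    "variants_per_common_site",
    "ssr_motif_summary",
]

#: Minimum repeat-unit counts per motif length (mono through hexa).
DEFAULT_MIN_REPEATS: Dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

MISSING = -1


@dataclass(frozen=True)
class SSRRecord:
    """A microsatellite: tandem repeat of an irreducible 1-6 nt motif.

    ``start``/``end`` are 0-based half-open over the scanned sequence;
    ``repeats`` counts full motif units (summed over runs for imperfect SSRs).
    """

    motif: str
    repeats: int
    start: int
    end: int
    perfect: bool = True


def _is_irreducible(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def _min_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _perfect_runs(seq: str, m: int) -> List[Tuple[int, int, str, int]]:
    """Maximal perfect tandem runs of period ``m`` with >= 2 full units.

    Returns (start, end, motif-as-found, repeat count); ``end`` covers full
    units only. Motifs that are themselves periodic (e.g. ``ATAT``) are
    skipped — the shorter-period scan reports them.
    """
    runs = []
    n = len(seq)
    i = 0
    while i + 2 * m <= n:
        j = i + m
        while j < n and seq[j] == seq[j - m]:
            j += 1
        reps = (j - i) // m
        if reps >= 2:
            motif = seq[i : i + m]
            if "N" not in motif and _is_irreducible(motif):
                runs.append((i, i + reps * m, motif, reps))
            i = j - m + 1
        else:
            i += 1
    return runs


def ssr_scan(
    sequence: str,
    min_repeats: Optional[Mapping[int, int]] = None,
    max_interruption: int = 4,
) -> List[SSRRecord]:
    """Detect SSRs with 1-6 nt motifs in a DNA string.

    A perfect SSR is a maximal uninterrupted tandem run meeting the minimum
    repeat count for its motif length. Runs of the same motif (up to rotation)
    separated by at most ``max_interruption`` bases merge into one imperfect
    SSR whose summed unit count must meet the threshold. Records wholly
    contained in an SSR of a shorter motif are suppressed.
    """
    thresholds = dict(DEFAULT_MIN_REPEATS)
    if min_repeats:
        thresholds.update(min_repeats)
    min_repeats = thresholds
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")

    candidates: List[SSRRecord] = []
    for m in sorted(min_repeats):
        if not 1 <= m <= 6:
            raise ValueError("motif lengths must be between 1 and 6")
        threshold = min_repeats[m]
        runs = _perfect_runs(seq, m)
        # group by rotation class for interruption merging
        groups: Dict[str, List[Tuple[int, int, str, int]]] = {}
        for run in runs:
            groups.setdefault(_min_rotation(run[2]), []).append(run)
        for grp in groups.values():
            grp.sort()
            chain = [grp[0]]
            for run in grp[1:]:
                if run[0] - chain[-1][1] <= max_interruption:
                    chain.append(run)
                else:
                    candidates.extend(_emit(chain, threshold))
                    chain = [run]
            candidates.extend(_emit(chain, threshold))

    # suppress records wholly explained by another SSR: either a shorter-motif
    # record covering the same span, or any strictly larger covering run (e.g.
    # an interrupted mononucleotide chain inside a perfect pentanucleotide run)
    kept: List[SSRRecord] = []
    for rec in sorted(candidates, key=lambda r: (r.start, len(r.motif))):
        if any(
            o is not rec
            and o.start <= rec.start
            and rec.end <= o.end
            and (
                len(o.motif) < len(rec.motif)
                or (o.end - o.start) > (rec.end - rec.start)
            )
            for o in candidates
        ):
            continue
        kept.append(rec)
    return kept


def _emit(chain: List[Tuple[int, int, str, int]], threshold: int) -> List[SSRRecord]:
    total = sum(r[3] for r in chain)
    if total < threshold:
        return []
    return [
        SSRRecord(
            motif=chain[0][2],
            repeats=total,
            start=chain[0][0],
            end=chain[-1][1],
            perfect=len(chain) == 1,
        )
    ]


@dataclass(frozen=True)
class VariantRecord:
    """One multi-allelic variant site. ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    var_type: str = "SNP"  # SNP | InDel | SSR

    def __post_init__(self) -> None:
        if not 1 <= len(self.alts) <= 3:
            raise ValueError("1 to 3 alternative alleles supported")

    @property
    def alleles(self) -> Tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def is_snp(self) -> bool:
        return all(len(a) == 1 for a in self.alleles)


class GenotypeMatrix:
    """Variants x samples diploid genotype calls.

    Calls are stored as allele-index pairs (``-1/-1`` = missing; half-calls
    are treated as missing at load time). Index 0 is the reference allele.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        alleles: np.ndarray,
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (len(variants), len(samples), 2):
            raise ValueError(
                f"allele array shape {alleles.shape} != ({len(variants)}, {len(samples)}, 2)"
            )
        # half-calls -> missing
        half = (alleles == MISSING).any(axis=2)
        alleles[half] = MISSING
        self.variants = list(variants)
        self.samples = list(samples)
        self.alleles = alleles

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def data_points(self) -> int:
        return self.n_variants * self.n_samples

    def called_mask(self) -> np.ndarray:
        return self.alleles[:, :, 0] != MISSING

    def missing_fraction(self) -> np.ndarray:
        # exact count ratio: boundary comparisons (strict "<") must not be
        # perturbed by floating-point noise from 1 - mean()
        missing = self.n_samples - self.called_mask().sum(axis=1)
        return missing / self.n_samples

    def het_mask(self) -> np.ndarray:
        return self.called_mask() & (self.alleles[:, :, 0] != self.alleles[:, :, 1])

    def maf(self, mode: str = "second_most_frequent") -> np.ndarray:
        """Per-variant minor allele frequency among called alleles.

        ``second_most_frequent`` (default): frequency of the second most
        frequent allele; ``one_minus_major``: 1 - major allele frequency.
        """
        if mode not in ("second_most_frequent", "one_minus_major"):
            raise ValueError(f"unknown MAF mode {mode!r}")
        out = np.zeros(self.n_variants)
        for i in range(self.n_variants):
            flat = self.alleles[i].reshape(-1)
            flat = flat[flat != MISSING]
            if flat.size == 0:
                continue
            counts = np.bincount(flat)
            if (counts > 0).sum() < 2:
                continue
            freqs = np.sort(counts[counts > 0])[::-1] / flat.size
            out[i] = (1.0 - freqs[0]) if mode == "one_minus_major" else freqs[1]
        return out

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            [self.variants[i] for i in idx], self.samples, self.alleles[idx].copy()
        )


def classify_indel_ssr(
    variant: VariantRecord,
    genome: Mapping[str, str],
    flank: int = 50,
    min_repeats: Optional[Mapping[int, int]] = None,
    max_interruption: int = 4,
) -> bool:
    """True if an InDel lies in/creates an SSR when embedded in its flanks.

    Each allele (reference and alternatives) is substituted into the genomic
    context with ``flank`` bases on both sides; the variant is SSR-classified
    iff any allele's context contains an SSR overlapping the allele span.
    """
    if variant.chrom not in genome:
        raise ValueError(f"chromosome {variant.chrom!r} absent from genome")
    seq = genome[variant.chrom].upper()
    start = variant.pos - 1
    if start < 0 or start + len(variant.ref) > len(seq):
        raise ValueError(f"variant at {variant.chrom}:{variant.pos} outside sequence")
    left = seq[max(0, start - flank) : start]
    right = seq[start + len(variant.ref) : start + len(variant.ref) + flank]
    for allele in variant.alleles:
        context = left + allele + right
        span = (len(left), len(left) + len(allele))
        for rec in ssr_scan(context, min_repeats, max_interruption):
            if rec.start < span[1] and rec.end > span[0]:
                return True
    return False


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def tstv(snps: Iterable[Tuple[str, str]]) -> Tuple[int, int, Optional[float]]:
    """Transition/transversion counts and ratio for biallelic SNP (ref, alt) pairs.

    Transitions are A<->G and C<->T. The ratio is rounded to two decimals and
    is ``None`` (flagged undefined) when there are no transversions.
    """
    ts = tv = 0
    for ref, alt in snps:
        ref, alt = ref.upper(), alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            raise ValueError(f"not a biallelic SNP allele pair: {ref!r}->{alt!r}")
        if frozenset((ref, alt)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    ratio = round(ts / tv, 2) if tv else None
    return ts, tv, ratio


@dataclass
class InDelStats:
    deletions: int
    insertions: int
    del_ins_ratio: Optional[float]
    length_diff_histogram: Counter
    class_fractions: Dict[str, float]   # '1-2', '3-10', '11+'
    flagged_same_length: int = 0

    def to_dict(self) -> dict:
        return {
            "deletions": self.deletions,
            "insertions": self.insertions,
            "del_ins_ratio": self.del_ins_ratio,
            "length_diff_histogram": dict(sorted(self.length_diff_histogram.items())),
            "class_fractions": self.class_fractions,
            "flagged_same_length": self.flagged_same_length,
        }


def indel_stats(indels: Iterable[VariantRecord]) -> InDelStats:
    """Deletion/insertion accounting per alternative allele.

    An alternative allele shorter than the reference is a deletion, longer is
    an insertion; equal length is flagged (not an InDel). A multiallelic
    record can contribute both classes.
    """
    deletions = insertions = flagged = 0
    hist: Counter = Counter()
    for rec in indels:
        for alt in rec.alts:
            diff = len(alt) - len(rec.ref)
            if diff == 0:
                flagged += 1
                continue
            if diff < 0:
                deletions += 1
            else:
                insertions += 1
            hist[abs(diff)] += 1
    total = deletions + insertions
    classes = {"1-2": 0, "3-10": 0, "11+": 0}
    for diff, n in hist.items():
        key = "1-2" if diff <= 2 else ("3-10" if diff <= 10 else "11+")
        classes[key] += n
    fractions = {k: (v / total if total else 0.0) for k, v in classes.items()}
    ratio = round(deletions / insertions, 2) if insertions else None
    return InDelStats(deletions, insertions, ratio, hist, fractions, flagged)


def sharing_distribution(gm: GenotypeMatrix) -> Dict[str, np.ndarray]:
    """Number of variants genotyped (non-missing) in exactly k samples.

    Returns ``per_k`` (index k-1 -> variants called in exactly k samples,
    k = 1..N) and ``at_least_k`` (cumulative from above).
    """
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    called_per_variant = gm.called_mask().sum(axis=1)
    per_k = np.bincount(called_per_variant, minlength=gm.n_samples + 1)[1:]
    at_least = np.cumsum(per_k[::-1])[::-1]
    return {"per_k": per_k, "at_least_k": at_least}


@dataclass
class FilterSummary:
    kept_total: int
    kept_by_type: Dict[str, int]
    removed_total: int
    all_missing: int
    max_missing_fraction: float
    min_maf: float

    def to_dict(self) -> dict:
        return {
            "kept_total": self.kept_total,
            "kept_by_type": self.kept_by_type,
            "removed_total": self.removed_total,
            "all_missing": self.all_missing,
            "max_missing_fraction": self.max_missing_fraction,
            "min_maf": self.min_maf,
        }


def filter_dataset(
    gm: GenotypeMatrix,
    max_missing_fraction: float = 0.05,
    min_maf: float = 0.01,
    maf_mode: str = "second_most_frequent",
) -> Tuple[GenotypeMatrix, FilterSummary]:
    """Keep variants with missing fraction strictly below ``max_missing_fraction``
    and MAF at or above ``min_maf`` (strict/inclusive bounds intentional)."""
    if not (0 <= max_missing_fraction <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    missing = gm.missing_fraction()
    maf = gm.maf(maf_mode)
    keep = (missing < max_missing_fraction) & (maf >= min_maf)
    filtered = gm.subset_variants(keep)
    by_type: Dict[str, int] = {}
    for v in filtered.variants:
        by_type[v.var_type] = by_type.get(v.var_type, 0) + 1
    all_missing = int((gm.called_mask().sum(axis=1) == 0).sum())
    summary = FilterSummary(
        kept_total=filtered.n_variants,
        kept_by_type=by_type,
        removed_total=gm.n_variants - filtered.n_variants,
        all_missing=all_missing,
        max_missing_fraction=max_missing_fraction,
        min_maf=min_maf,
    )
    return filtered, summary


def rate_summary(gm: GenotypeMatrix) -> Dict[str, float]:
    """Data points, % missing and % heterozygous over all matrix cells."""
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    dp = gm.data_points
    missing = dp - int(gm.called_mask().sum())
    het = int(gm.het_mask().sum())
    return {
        "data_points": dp,
        "pct_missing": 100.0 * missing / dp,
        "pct_heterozygous": 100.0 * het / dp,
    }


def density_windows(
    variants: Iterable[VariantRecord],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 1000,
) -> Dict[str, np.ndarray]:
    """Per-chromosome variant counts in fixed windows tiling the genome."""
    out = {
        chrom: np.zeros(-(-ln // window_bp), dtype=np.int64)
        for chrom, ln in chrom_lengths.items()
    }
    for v in variants:
        if v.chrom not in out:
            raise ValueError(f"unknown chromosome {v.chrom!r}")
        idx = (v.pos - 1) // window_bp
        if not 0 <= idx < len(out[v.chrom]):
            raise ValueError(f"variant {v.chrom}:{v.pos} outside chromosome")
        out[v.chrom][idx] += 1
    return out


def variants_per_common_site(total_common_sites: int, n_universal_variants: int) -> int:
    """Floored number of commonly covered sites per universally genotyped variant."""
    if n_universal_variants <= 0:
        raise ValueError("n_universal_variants must be positive")
    if total_common_sites <= 0:
        raise ValueError("total_common_sites must be positive")
    return total_common_sites // n_universal_variants


def ssr_motif_summary(records: Sequence[SSRRecord]) -> Dict[str, object]:
    """Motif composition of an SSR set: counts and percentage shares.

    Motifs are reported as found (no reverse-complement merging). Percentage
    shares by motif length are over the full set, rounded to two decimals.
    """
    by_length: Counter = Counter(len(r.motif) for r in records)
    by_motif: Counter = Counter(r.motif for r in records)
    total = len(records)
    pct_by_length = {
        k: round(100.0 * v / total, 2) for k, v in sorted(by_length.items())
    }
    return {
        "total": total,
        "by_motif_length": dict(sorted(by_length.items())),
        "pct_by_motif_length": pct_by_length,
        "by_motif": dict(sorted(by_motif.items())),
        "perfect": sum(r.perfect for r in records),
        "imperfect": sum(not r.perfect for r in records),
    }
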