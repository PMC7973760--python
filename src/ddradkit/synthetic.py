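"""Seeded synthetic genomes, alignments and genotype matrices.

The generators plant known structure — restriction sites at controlled
densities, site-free "centromere-like" spans, an oversampled "organellar"
hotspot, per-sample yield dispersion, pool-level size-window shifts, and
genotypes at chosen minor-allele frequencies — and emit truth tables so every
analysis stage can be tested against construction.

All randomness flows from ``SyntheticDesign.seed`` through named substreams,
so equal designs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .coverage import AlignmentSet
from .digestion import BUILTIN_ENZYMES, Fragment, RestrictionEnzyme, SizeWindow, digest, find_cut_sites, profile
from .variants import GenotypeMatrix, VariantRecord, MISSING

__all__ = ["SyntheticDesign", "gen_genome", "gen_reads", "gen_genotypes"]

_SUBSTREAM = {"genome": 0, "reads": 1, "genotypes": 2}


@dataclass
class SyntheticDesign:
    """Full parameterization of the simulator."""

    genome_length: int = 200_000
    chrom_name: str = "chrSim1"
    rare_enzyme: str = "PstI"
    frequent_enzyme: str = "MboI"
    rare_sites_per_kb: float = 0.5
    frequent_sites_per_kb: float = 3.0
    centromere_spans: Tuple[Tuple[int, int], ...] = ()
    hotspot_span: Optional[Tuple[int, int]] = None
    hotspot_copy_number: int = 10
    ssr_tracts: Tuple[Tuple[str, int], ...] = ()  # (motif, repeats) planted in order
    n_pools: int = 2
    samples_per_pool: int = 6
    window_center: int = 350
    window_width: int = 100
    pool_window_shift: int = 0
    yield_mean: float = 500.0  # read pairs per sample
    yield_cv: float = 0.28
    read_length: int = 225
    n_snp: int = 200
    n_indel: int = 40
    n_ssr_variants: int = 0
    maf_beta_a: float = 0.8
    maf_beta_b: float = 3.0
    min_maf: float = 0.02
    missing_rate: float = 0.05
    coverage_linked_missingness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if min(self.rare_sites_per_kb, self.frequent_sites_per_kb) < 0:
            raise ValueError("site densities must be >= 0")
        spans = sorted(self.centromere_spans) + (
            [tuple(self.hotspot_span)] if self.hotspot_span else []
        )
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"planted spans overlap: {(s1, e1)} and {(s2, e2)}")
        for s, e in spans:
            if not 0 <= s < e <= self.genome_length:
                raise ValueError(f"span {(s, e)} outside genome")

    @property
    def window(self) -> SizeWindow:
        half = self.window_width // 2
        return SizeWindow(self.window_center - half, self.window_center + half)

    def pool_window(self, pool_index: int) -> SizeWindow:
        """Effective size-selection window of a pool.

        The batch effect is modeled as a window shift applied to the second
        half of the pools, producing two blocks of similarly covered samples.
        """
        shift = self.pool_window_shift if pool_index >= self.n_pools // 2 else 0
        w = self.window
        return SizeWindow(w.min_bp + shift, w.max_bp + shift)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SUBSTREAM[stage]])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticDesign":
        raw = json.loads(text)
        for key in ("centromere_spans", "ssr_tracts"):
            if key in raw:
                raw[key] = tuple(tuple(x) for x in raw[key])
        if raw.get("hotspot_span"):
            raw["hotspot_span"] = tuple(raw["hotspot_span"])
        return cls(**raw)


def _scrub_motifs(
    seq: np.ndarray, enzymes: Sequence[RestrictionEnzyme], rng: np.random.Generator,
    protected: Optional[np.ndarray] = None,
) -> None:
    """Mutate bases until no enzyme site remains outside ``protected`` positions."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for _ in range(50):
        dirty = False
        text = seq.tobytes().decode()
        for enz in enzymes:
            for cut in find_cut_sites(text, enz):
                start = cut - enz.cut_offset
                idx = np.arange(start, start + len(enz.recognition))
                idx = idx[(idx >= 0) & (idx < len(seq))]
                if protected is not None:
                    idx = idx[~protected[idx]]
                if len(idx) == 0:
                    continue
                j = int(rng.choice(idx))
                current = seq[j]
                choices = bases[bases != current]
                seq[j] = rng.choice(choices)
                dirty = True
        if not dirty:
            return
    raise RuntimeError("failed to scrub incidental restriction sites")


def gen_genome(design: SyntheticDesign) -> Tuple[Dict[str, str], Dict[str, object]]:
    """Generate a genome with planted restriction sites and feature spans.

    Returns the genome (one chromosome) and a truth table with the planted
    cut positions per enzyme, centromere spans, hotspot span and SSR tracts.
    """
    rng = design.rng("genome")
    enz_a = BUILTIN_ENZYMES[design.rare_enzyme]
    enz_b = BUILTIN_ENZYMES[design.frequent_enzyme]
    n = design.genome_length
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)

    # forbidden spans: no planted sites inside centromeres; SSR tracts and
    # motifs must not collide with each other
    blocked = np.zeros(n, dtype=bool)
    for s, e in design.centromere_spans:
        blocked[s:e] = True

    protected = np.zeros(n, dtype=bool)

    # plant SSR tracts at evenly spread positions clear of blocked spans
    ssr_truth: List[Tuple[str, int, int, int]] = []  # motif, repeats, start, end
    if design.ssr_tracts:
        anchors = np.linspace(0, n, num=len(design.ssr_tracts) + 2, dtype=int)[1:-1]
        for (motif, repeats), pos in zip(design.ssr_tracts, anchors):
            tract = (motif * repeats).encode()
            pos = int(pos)
            if blocked[pos : pos + len(tract)].any() or pos + len(tract) > n:
                raise ValueError("SSR tract collides with a planted span")
            seq[pos : pos + len(tract)] = np.frombuffer(tract, dtype="S1")
            protected[pos : pos + len(tract)] = True
            ssr_truth.append((motif, repeats, pos, pos + len(tract)))

    _scrub_motifs(seq, (enz_a, enz_b), rng, protected)

    def plant(enzyme: RestrictionEnzyme, density_per_kb: float) -> List[int]:
        count = int(round(density_per_kb * n / 1000))
        motif_len = len(enzyme.recognition)
        sites: List[int] = []
        taken = blocked | protected
        tries = 0
        while len(sites) < count and tries < count * 200:
            tries += 1
            pos = int(rng.integers(10, n - motif_len - 10))
            if taken[pos - 8 : pos + motif_len + 8].any():
                continue
            seq[pos : pos + motif_len] = np.frombuffer(
                enzyme.recognition.encode(), dtype="S1"
            )
            taken[pos - 8 : pos + motif_len + 8] = True
            protected[pos : pos + motif_len] = True
            sites.append(pos + enzyme.cut_offset)
        if len(sites) < count:
            raise RuntimeError(f"could not place {count} {enzyme.name} sites")
        return sorted(sites)

    cuts_a = plant(enz_a, design.rare_sites_per_kb)
    cuts_b = plant(enz_b, design.frequent_sites_per_kb)
    # planting motifs may have spawned incidental sites at junctions
    _scrub_motifs(seq, (enz_a, enz_b), rng, protected)

    genome = {design.chrom_name: seq.tobytes().decode()}
    truth = {
        "cut_sites": {enz_a.name: cuts_a, enz_b.name: cuts_b},
        "centromere_spans": list(design.centromere_spans),
        "hotspot_span": design.hotspot_span,
        "ssr_tracts": ssr_truth,
    }
    for enz, expected in ((enz_a, cuts_a), (enz_b, cuts_b)):
        found = find_cut_sites(genome[design.chrom_name], enz)
        if found != expected:
            raise RuntimeError(f"planted {enz.name} sites not recovered exactly")
    return genome, truth


def _sample_names(design: SyntheticDesign) -> List[Tuple[str, str, int]]:
    names = []
    for p in range(design.n_pools):
        for s in range(design.samples_per_pool):
            names.append((f"P{p + 1}S{s + 1:02d}", f"pool{p + 1}", p))
    return names


def gen_reads(
    design: SyntheticDesign,
    genome: Mapping[str, str],
    fragments: Optional[Sequence[Fragment]] = None,
) -> Tuple[AlignmentSet, Dict[str, object]]:
    """Simulate per-sample read-pair alignments from size-selected fragments.

    Per sample, the yield (read pairs) is gamma-distributed with the design
    mean and CV; fragments are AB+BA products whose length falls inside the
    sample's pool-shifted window, drawn with replacement (hotspot fragments
    weighted by copy number); each draw emits the two fragment-end segments.
    """
    enz_a = BUILTIN_ENZYMES[design.rare_enzyme]
    enz_b = BUILTIN_ENZYMES[design.frequent_enzyme]
    if fragments is None:
        fragments = digest(genome, (enz_a, enz_b))
    ab = [
        f for f in fragments
        if {f.left_end, f.right_end} == {enz_a.name, enz_b.name}
    ]
    rng = design.rng("reads")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    aset = AlignmentSet(chrom_lengths=chrom_lengths)
    yields: Dict[str, int] = {}
    for sample, pool, pidx in _sample_names(design):
        window = design.pool_window(pidx)
        eligible = [f for f in ab if window.contains(f.length)]
        if not eligible:
            raise ValueError(f"no AB+BA fragments inside window {window} for {pool}")
        weights = np.array(
            [
                design.hotspot_copy_number
                if design.hotspot_span
                and f.start >= design.hotspot_span[0]
                and f.end <= design.hotspot_span[1]
                else 1.0
                for f in eligible
            ]
        )
        weights /= weights.sum()
        if design.yield_cv > 0:
            shape = 1.0 / design.yield_cv**2
            n_pairs = int(round(rng.gamma(shape, design.yield_mean / shape)))
        else:
            n_pairs = int(round(design.yield_mean))
        n_pairs = max(n_pairs, 1)
        yields[sample] = n_pairs
        draws = rng.choice(len(eligible), size=n_pairs, replace=True, p=weights)
        segs: List[Tuple[int, int]] = []
        for k in draws:
            f = eligible[k]
            rl = min(design.read_length, f.length)
            segs.append((f.start, f.start + rl))
            segs.append((f.end - rl, f.end))
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for (s, e), k in zip(segs, np.repeat(draws, 2)):
            by_chrom.setdefault(eligible[k].chrom, []).append((s, e))
        aset.add_sample(
            sample,
            {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()},
            pool=pool,
        )
    truth = {"yields": yields, "n_ab_fragments": len(ab)}
    return aset, truth


def gen_genotypes(
    design: SyntheticDesign,
    genome: Mapping[str, str],
    fragments: Optional[Sequence[Fragment]] = None,
    yields: Optional[Mapping[str, int]] = None,
) -> Tuple[GenotypeMatrix, Dict[str, object]]:
    """Simulate a multi-sample genotype matrix with known MAF and missingness.

    Variant positions fall inside windowed AB+BA fragments (the sequenced
    portion of the genome). Genotypes are Hardy-Weinberg draws at a per-variant
    MAF from Beta(a, b) truncated below at ``min_maf``; missingness is
    Bernoulli, optionally scaled inversely with each sample's read yield.
    """
    enz_a = BUILTIN_ENZYMES[design.rare_enzyme]
    enz_b = BUILTIN_ENZYMES[design.frequent_enzyme]
    if fragments is None:
        fragments = digest(genome, (enz_a, enz_b))
    window = design.window
    loci = [
        f for f in fragments
        if {f.left_end, f.right_end} == {enz_a.name, enz_b.name}
        and window.contains(f.length)
    ]
    if not loci:
        raise ValueError("no windowed AB+BA fragments to place variants on")
    rng = design.rng("genotypes")
    names = [s for s, _, _ in _sample_names(design)]
    n_samples = len(names)
    chrom = design.chrom_name
    seq = genome[chrom]

    records: List[VariantRecord] = []
    true_maf: List[float] = []
    used: set = set()

    def pick_position(span_needed: int = 1) -> int:
        for _ in range(10_000):
            f = loci[int(rng.integers(len(loci)))]
            if f.length <= span_needed + 12:
                continue
            pos = int(rng.integers(f.start + 6, f.end - span_needed - 6))
            if all((pos + d) not in used for d in range(-span_needed, span_needed + 1)):
                for d in range(span_needed):
                    used.add(pos + d)
                return pos
        raise RuntimeError("could not place variant")

    bases = "ACGT"
    for _ in range(design.n_snp):
        pos = pick_position()
        ref = seq[pos]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        records.append(VariantRecord(chrom, pos + 1, ref, (alt,), "SNP"))
    for _ in range(design.n_indel):
        pos = pick_position(span_needed=12)
        d = int(rng.integers(1, 11))
        if rng.random() < 0.5:  # deletion of d bases after the anchor
            ref = seq[pos : pos + 1 + d]
            alt = seq[pos]
        else:  # insertion of d random bases after the anchor
            ref = seq[pos]
            alt = ref + "".join(bases[int(rng.integers(4))] for _ in range(d))
        records.append(VariantRecord(chrom, pos + 1, ref, (alt,), "InDel"))
    for motif, repeats in (design.ssr_tracts or ())[: design.n_ssr_variants]:
        # one-unit expansion inside a planted tract -> guaranteed SSR InDel
        start = next(t[2] for t in _ssr_tract_lookup(design, genome) if t[0] == motif)
        ref = seq[start - 1]
        alt = ref + motif
        records.append(VariantRecord(chrom, start, ref, (alt,), "SSR"))

    alleles = np.full((len(records), n_samples, 2), MISSING, dtype=np.int8)
    yields_arr = None
    if design.coverage_linked_missingness and yields:
        yields_arr = np.array([yields[s] for s in names], dtype=float)
    for i in range(len(records)):
        maf = float(
            np.clip(rng.beta(design.maf_beta_a, design.maf_beta_b), design.min_maf, 0.5)
        )
        true_maf.append(maf)
        gt = (rng.random((n_samples, 2)) < maf).astype(np.int8)
        if design.missing_rate > 0:
            if yields_arr is not None:
                rate = design.missing_rate * (yields_arr.mean() / yields_arr)
                rate = np.clip(rate, 0.0, 0.95)
            else:
                rate = np.full(n_samples, design.missing_rate)
            miss = rng.random(n_samples) < rate
            gt[miss] = MISSING
        alleles[i] = gt

    order = np.argsort([r.pos for r in records], kind="stable")
    records = [records[i] for i in order]
    true_maf = [true_maf[i] for i in order]
    alleles = alleles[order]
    gm = GenotypeMatrix(records, names, alleles)
    truth = {
        "maf": true_maf,
        "var_types": [r.var_type for r in records],
        "missing_rate": design.missing_rate,
    }
    return gm, truth


def _ssr_tract_lookup(design: SyntheticDesign, genome: Mapping[str, str]):
    # recompute the deterministic tract anchor positions used by gen_genome
    n = design.genome_length
    anchors = np.linspace(0, n, num=len(design.ssr_tracts) + 2, dtype=int)[1:-1]
    return [
        (motif, repeats, int(pos), int(pos) + len(motif) * repeats)
        for (motif, repeats), pos in zip(design.ssr_tracts, anchors)
    ]
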