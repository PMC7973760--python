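"""Orchestrate the full workflow: digestion -> design -> coverage -> variants.

Each stage runs only when its inputs are configured; stage outputs land under
``config.out_dir`` and every headline statistic is collected into one
``summary.json``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .. import coverage as cov
from .. import design as dsg
from .. import variants as var
from ..digestion import BUILTIN_ENZYMES, RestrictionEnzyme, SizeWindow, digest, profile
from .config import PipelineConfig
from . import formats

log = logging.getLogger("ddrad")


class PipelineError(RuntimeError):
    pass


def _load_enzymes(config: PipelineConfig) -> List[RestrictionEnzyme]:
    table = dict(BUILTIN_ENZYMES)
    if config.enzyme_table:
        for line in Path(config.enzyme_table).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, motif, offset, *rest = line.split("\t")
            meth = bool(rest) and rest[0].lower() in ("1", "true", "yes")
            table[name] = RestrictionEnzyme(name, motif, int(offset), meth)
    names = [n.strip() for n in config.enzymes.split(",") if n.strip()]
    missing = [n for n in names if n not in table]
    if missing:
        raise PipelineError(f"unknown enzyme(s) {missing}; provide --enzyme-table")
    return [table[n] for n in names]


def _load_alignments(config: PipelineConfig) -> cov.AlignmentSet:
    path = Path(config.alignments)
    if not path.exists():
        raise PipelineError(f"coverage stage: alignments path not found: {path}")
    if path.is_dir():
        aset: Optional[cov.AlignmentSet] = None
        for sam in sorted(path.glob("*.sam")) + sorted(path.glob("*.bam")):
            segs, lengths = formats.read_sam(sam, config.min_mapq_exclusive)
            if aset is None:
                aset = cov.AlignmentSet(chrom_lengths=lengths)
            aset.add_sample(sam.stem, segs)
        if aset is None:
            raise PipelineError(f"coverage stage: no SAM/BAM files in {path}")
    else:
        aset = formats.read_interval_tsv(path)
    if config.pool_map:
        pm = Path(config.pool_map)
        if not pm.exists():
            raise PipelineError(f"coverage stage: pool map not found: {pm}")
        aset.pools.update(formats.read_pool_map(pm))
    return aset


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run all configured stages and return (and write) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = SizeWindow(config.window_min, config.window_max)
    summary: Dict[str, object] = {"config": config.to_json()}

    if config.genome_fasta:
        gpath = Path(config.genome_fasta)
        if not gpath.exists():
            raise PipelineError(f"digestion stage: genome not found: {gpath}")
        log.info("digestion: loading %s", gpath)
        genome = formats.read_fasta(gpath)
        enzymes = _load_enzymes(config)
        diagnostics: Dict[str, int] = {}
        fragments = digest(genome, enzymes, diagnostics)
        prof = profile(fragments, window, enzymes, genome_id=gpath.name)
        formats.write_fragments_bed(fragments, out / "fragments.bed")
        formats.write_length_histogram(prof.length_histogram, out / "length_histogram.tsv")
        formats.write_json(prof.to_dict() | diagnostics, out / "digest_profile.json")
        summary["digestion"] = prof.to_dict() | diagnostics

        plan = dsg.make_plan(prof.windowed_ab_ba, window, config.yield_bp_per_sample)
        formats.write_json(plan.to_dict(), out / "design_plan.json")
        summary["design"] = plan.to_dict()

    if config.alignments:
        aset = _load_alignments(config)
        log.info("coverage: %d samples", len(aset.samples))
        per_sample = {
            s: cov.coverage_summary(
                aset.segments[s], aset.chrom_lengths, config.depth_min
            ).to_dict()
            for s in aset.samples
        }
        merged = cov.coverage_summary(
            aset.merged_segments(), aset.chrom_lengths, config.depth_min
        )
        bcm = cov.bin_counts(aset, config.bin_size)
        formats.write_bin_matrix(bcm, out / "bin_counts.tsv")
        corr = cov.correlation_matrix(bcm, config.correlation_method)
        corr.corr.to_csv(out / "correlation.tsv", sep="\t")
        summary["coverage"] = {
            "per_sample": per_sample,
            "merged": merged.to_dict(),
            "correlation_order": corr.order,
            "correlation_excluded": corr.excluded,
        }
        if len(aset.samples) >= 3:
            pca = cov.pca_bins(bcm)
            pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            summary["coverage"]["pca_explained_pct"] = [
                float(x) for x in pca.explained_pct
            ]
        if aset.pools:
            pools = sorted(set(aset.pools.values()))
            per_pool = {
                p: cov.common_sites(
                    aset,
                    [s for s in aset.samples if aset.pools.get(s) == p],
                    config.depth_min,
                )
                for p in pools
            }
            summary["coverage"]["common_sites_per_pool"] = per_pool
            summary["coverage"]["common_sites_all"] = cov.common_sites(
                aset, aset.samples, config.depth_min
            )
            try:
                comp = cov.artificial_pool_test(
                    aset, config.k_per_pool, config.seed, config.depth_min
                )
                formats.write_json(comp.to_dict(), out / "pool_comparison.json")
                summary["coverage"]["pool_comparison"] = comp.to_dict()
            except ValueError as exc:
                log.warning("coverage: artificial pool test skipped: %s", exc)

    if config.vcf:
        vpath = Path(config.vcf)
        if not vpath.exists():
            raise PipelineError(f"variants stage: VCF not found: {vpath}")
        gm = formats.read_vcf(vpath)
        log.info("variants: %d x %d", gm.n_variants, gm.n_samples)
        snp_pairs = [
            (v.ref, v.alts[0])
            for v in gm.variants
            if v.var_type == "SNP" and len(v.alts) == 1
        ]
        ts, tv, ratio = var.tstv(snp_pairs) if snp_pairs else (0, 0, None)
        indels = [v for v in gm.variants if v.var_type in ("InDel", "SSR")]
        istats = var.indel_stats(indels) if indels else None
        sharing = var.sharing_distribution(gm)
        filtered, fsummary = var.filter_dataset(
            gm, config.max_missing, config.min_maf
        )
        formats.write_vcf(filtered, out / "filtered.vcf")
        chrom_lengths = {}
        for v in gm.variants:
            chrom_lengths[v.chrom] = max(
                chrom_lengths.get(v.chrom, 0), v.pos + len(v.ref)
            )
        density = var.density_windows(gm.variants, chrom_lengths, config.density_window)
        with open(out / "sharing.tsv", "w") as fh:
            fh.write("k\tvariants_exactly_k\tvariants_at_least_k\n")
            for k in range(1, gm.n_samples + 1):
                fh.write(
                    f"{k}\t{sharing['per_k'][k - 1]}\t{sharing['at_least_k'][k - 1]}\n"
                )
        with open(out / "density.tsv", "w") as fh:
            fh.write("chrom\twindow_start\tcount\n")
            for chrom, counts in density.items():
                for i, c in enumerate(counts):
                    fh.write(f"{chrom}\t{i * config.density_window}\t{c}\n")
        summary["variants"] = {
            "n_variants": gm.n_variants,
            "n_samples": gm.n_samples,
            "rates": var.rate_summary(gm),
            "tstv": {"transitions": ts, "transversions": tv, "ratio": ratio},
            "indel_stats": istats.to_dict() if istats else None,
            "filter": fsummary.to_dict(),
            "filtered_rates": (
                var.rate_summary(filtered) if filtered.n_variants else None
            ),
        }

    formats.write_json(summary, out / "summary.json")
    return summary
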