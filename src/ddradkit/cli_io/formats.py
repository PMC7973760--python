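"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython (gzip-transparent), SAM/BAM via pysam, VCF via pysam,
plus a human-readable 4-column interval TSV dialect (sample, chrom, 0-based
start, half-open end) accepted everywhere BAM is.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO

from ..coverage import AlignmentSet, BinCountMatrix, Segments
from ..digestion import Fragment
from ..variants import GenotypeMatrix, VariantRecord, MISSING

#: Keep alignments with MAPQ strictly greater than this (matches "MAPQ > 3").
DEFAULT_MIN_MAPQ_EXCLUSIVE = 3


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> Dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- alignments

def read_sam(
    path: str | Path,
    min_mapq_exclusive: int = DEFAULT_MIN_MAPQ_EXCLUSIVE,
) -> Tuple[Segments, Dict[str, int]]:
    """Read one sample's aligned segments from SAM/BAM, filtering on MAPQ."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        chrom_lengths = dict(zip(af.references, af.lengths))
        for rec in af:
            if rec.is_unmapped or rec.mapping_quality <= min_mapq_exclusive:
                continue
            by_chrom.setdefault(rec.reference_name, []).append(
                (rec.reference_start, rec.reference_end)
            )
    segs = {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}
    return segs, chrom_lengths


def write_sam(aset: AlignmentSet, out_dir: str | Path, read_length_hint: int = 225) -> List[Path]:
    """Write one plain-text SAM per sample (unpaired records, MAPQ 60)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = list(aset.chrom_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": aset.chrom_lengths[c]} for c in refs],
        }
    )
    paths = []
    for sample in aset.samples:
        path = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            i = 0
            for chrom in refs:
                segs = aset.segments[sample].get(chrom)
                if segs is None or not len(segs):
                    continue
                for start, end in segs[np.argsort(segs[:, 0], kind="stable")]:
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{sample}.{i}"
                    a.reference_id = refs.index(chrom)
                    a.reference_start = int(start)
                    a.mapping_quality = 60
                    length = int(end - start)
                    a.query_sequence = "N" * length
                    a.cigartuples = [(0, length)]
                    out.write(a)
                    i += 1
        paths.append(path)
    return paths


def read_interval_tsv(
    path: str | Path,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> AlignmentSet:
    """Read the 4-column dialect: sample, chrom, start, end (0-based half-open).

    When ``chrom_lengths`` is not given, lengths default to the maximum end
    seen per chromosome.
    """
    rows: List[Tuple[str, str, int, int]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, chrom, start, end = line.split("\t")[:4]
            rows.append((sample, chrom, int(start), int(end)))
    if chrom_lengths is None:
        chrom_lengths = {}
        for _, chrom, _, end in rows:
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end)
    aset = AlignmentSet(chrom_lengths=dict(chrom_lengths))
    per_sample: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    for sample, chrom, start, end in rows:
        per_sample.setdefault(sample, {}).setdefault(chrom, []).append((start, end))
    for sample, by_chrom in per_sample.items():
        aset.add_sample(
            sample, {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}
        )
    return aset


def write_interval_tsv(aset: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tchrom\tstart\tend\n")
        for sample in aset.samples:
            for chrom, segs in aset.segments[sample].items():
                for start, end in segs:
                    fh.write(f"{sample}\t{chrom}\t{start}\t{end}\n")


def read_pool_map(path: str | Path) -> Dict[str, str]:
    pools = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pool = line.split("\t")[:2]
            pools[sample] = pool
    return pools


def write_pool_map(pools: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tpool\n")
        for sample, pool in pools.items():
            fh.write(f"{sample}\t{pool}\n")


# -------------------------------------------------------------------- variants

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load variants + GT calls. Variant type comes from INFO/VT when present,
    otherwise inferred (all alleles length 1 -> SNP, else InDel)."""
    records: List[VariantRecord] = []
    rows: List[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = tuple(rec.alts or ())
            if not alts:
                continue
            vt = rec.info.get("VT")
            if isinstance(vt, tuple):
                vt = vt[0]
            if vt is None:
                vt = "SNP" if all(len(a) == 1 for a in (rec.ref,) + alts) else "InDel"
            records.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alts, str(vt)))
            row = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for j, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt and len(gt) == 2 and None not in gt:
                    row[j] = gt
            rows.append(row)
    alleles = (
        np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    return GenotypeMatrix(records, samples, alleles)


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a minimal plain-text VCF with GT calls and INFO/VT variant type."""
    chroms: Dict[str, int] = dict(chrom_lengths or {})
    for v in gm.variants:
        end = v.pos + len(v.ref)
        chroms[v.chrom] = max(chroms.get(v.chrom, 0), end)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in chroms.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, v in enumerate(gm.variants):
            calls = []
            for j in range(gm.n_samples):
                a, b = gm.alleles[i, j]
                calls.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t"
                f"VT={v.var_type}\tGT\t" + "\t".join(calls) + "\n"
            )


# --------------------------------------------------------------------- tables

def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Fragments as BED: name = leftEnzyme_rightEnzyme, score = length."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.left_end}_{f.right_end}\t{f.length}\n"
            )


def write_length_histogram(histogram: Mapping[int, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("length_bp\tcount\n")
        for length in sorted(histogram):
            fh.write(f"{length}\t{histogram[length]}\n")


def write_bin_matrix(bcm: BinCountMatrix, path: str | Path) -> None:
    bcm.to_frame().to_csv(path, sep="\t", index_label="bin")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
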