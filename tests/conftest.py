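from __future__ import annotations

import itertools

import numpy as np
import pytest

from ddradkit.digestion import BUILTIN_ENZYMES, SizeWindow
from ddradkit.synthetic import SyntheticDesign, gen_genome

# ------------------------------------------------------------------ oracles
# Independent brute-force implementations used to cross-check the package.

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


def naive_cut_sites(sequence: str, motif: str, cut_offset: int) -> list[int]:
    """Position-by-position scan; expands the motif to every concrete string."""
    seq = sequence.upper()
    concrete = {
        "".join(p) for p in itertools.product(*(_IUPAC_SETS[c] for c in motif))
    }
    out = set()
    for i in range(len(seq) - len(motif) + 1):
        if seq[i : i + len(motif)] in concrete:
            out.add(i + cut_offset)
    return sorted(out)


def naive_pileup(segments: np.ndarray, length: int) -> np.ndarray:
    """Per-position depth by looping over every base of every segment."""
    depth = np.zeros(length, dtype=int)
    for start, end in segments:
        for pos in range(start, end):
            depth[pos] += 1
    return depth


# ----------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def enzymes():
    return BUILTIN_ENZYMES


@pytest.fixture(scope="session")
def window_300_400():
    return SizeWindow(300, 400)


@pytest.fixture(scope="session")
def random_genome_100kb():
    """100-kb random sequence with naturally occurring restriction sites."""
    rng = np.random.default_rng(20210318)
    return {"chrR": "".join(rng.choice(list("ACGT"), size=100_000))}


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(
        genome_length=120_000,
        rare_sites_per_kb=0.6,
        frequent_sites_per_kb=3.0,
        n_pools=2,
        samples_per_pool=6,
        yield_mean=300,
        seed=11,
        ssr_tracts=(("AT", 8), ("A", 12), ("ATG", 6)),
        n_ssr_variants=2,
        centromere_spans=((50_000, 58_000),),
        hotspot_span=(90_000, 94_000),
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    genome, truth = gen_genome(small_design)
    return small_design, genome, truth
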