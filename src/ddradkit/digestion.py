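"""In silico restriction digestion, fragment end classification and enzyme-pair ranking.

Coordinates are 0-based half-open throughout; a cut position is a between-base
index so that fragment length equals ``end - start`` and the fragments of one
chromosome tile it exactly.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "CHROM_END",
    "RestrictionEnzyme",
    "Fragment",
    "SizeWindow",
    "DigestProfile",
    "BUILTIN_ENZYMES",
    "find_cut_sites",
    "digest",
    "profile",
    "rank_pairs",
    "single_enzyme_profile",
]

#: Sentinel end label for fragment boundaries created by chromosome termini.
CHROM_END = "CHROM_END"

# IUPAC nucleotide codes -> the set of bases each matches.  ``N`` in a target
# sequence only ever matches the code N itself (an unknown base must not be
# claimed as a restriction site).
_IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


class EnzymeConfigError(ValueError):
    """Raised for invalid enzyme definitions (bad IUPAC code, bad offset)."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition motif plus top-strand cut offset.

    ``cut_offset`` is the distance in bases from the motif start to the
    top-strand cut. ``methylation_sensitive`` is metadata only; methylation is
    not modeled in the digestion simulation.
    """

    name: str
    recognition: str
    cut_offset: int
    methylation_sensitive: bool = False

    def __post_init__(self) -> None:
        motif = self.recognition.upper()
        object.__setattr__(self, "recognition", motif)
        if len(motif) < 1:
            raise EnzymeConfigError(f"{self.name}: empty recognition motif")
        bad = [c for c in motif if c not in _IUPAC]
        if bad:
            raise EnzymeConfigError(
                f"{self.name}: invalid IUPAC code(s) {bad!r} in {motif!r}"
            )
        if not 0 <= self.cut_offset <= len(motif):
            raise EnzymeConfigError(
                f"{self.name}: cut_offset {self.cut_offset} outside [0, {len(motif)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return _revcomp(self.recognition) == self.recognition

    def _regex(self, motif: Optional[str] = None) -> "re.Pattern[str]":
        motif = motif or self.recognition
        # Lookahead so overlapping occurrences are all reported.
        expanded = "".join(
            f"[{_IUPAC[c]}]" if len(_IUPAC[c]) > 1 else _IUPAC[c] for c in motif
        )
        return re.compile(f"(?={expanded})")


#: REBASE definitions for the enzymes used by the platform. Overridable via
#: config/CLI (``--enzyme-table``).
BUILTIN_ENZYMES: Dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in (
        RestrictionEnzyme("PstI", "CTGCAG", 5, methylation_sensitive=True),
        RestrictionEnzyme("MboI", "GATC", 0, methylation_sensitive=False),
        RestrictionEnzyme("MspI", "CCGG", 1, methylation_sensitive=False),
        RestrictionEnzyme("EcoRI", "GAATTC", 1, methylation_sensitive=True),
        RestrictionEnzyme("SphI", "GCATGC", 5, methylation_sensitive=True),
        RestrictionEnzyme("ApeKI", "GCWGC", 1, methylation_sensitive=True),
    )
}


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length window in bp."""

    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not 0 <= self.min_bp <= self.max_bp:
            raise ValueError(f"invalid window [{self.min_bp}, {self.max_bp}]")

    def contains(self, length: int) -> bool:
        return self.min_bp <= length <= self.max_bp

    @classmethod
    def parse(cls, text: str) -> "SizeWindow":
        lo, hi = text.replace("-", ":").split(":")
        return cls(int(lo), int(hi))

    def __str__(self) -> str:
        return f"{self.min_bp}:{self.max_bp}"


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    left_end: str
    right_end: str

    @property
    def length(self) -> int:
        return self.end - self.start


def find_cut_sites(sequence: str, enzyme: RestrictionEnzyme) -> List[int]:
    """Return sorted, deduplicated top-strand cut positions for ``enzyme``.

    A motif match starting at index ``i`` yields cut position
    ``i + cut_offset``. Matching is case-insensitive. For non-palindromic
    enzymes the reverse strand is scanned as well (via the reverse complement
    of the motif) and the corresponding top-strand cut positions are merged in.
    """
    seq = sequence.upper()
    positions = {
        m.start() + enzyme.cut_offset for m in enzyme._regex().finditer(seq)
    }
    if not enzyme.is_palindromic:
        rc = _revcomp(enzyme.recognition)
        off = len(enzyme.recognition) - enzyme.cut_offset
        positions.update(
            m.start() + off for m in enzyme._regex(rc).finditer(seq)
        )
    return sorted(positions)


def digest(
    genome: Mapping[str, str],
    enzymes: Sequence[RestrictionEnzyme],
    diagnostics: Optional[Dict[str, int]] = None,
) -> List[Fragment]:
    """Digest ``genome`` with one or two enzymes and return labeled fragments.

    Per chromosome, all enzymes' cut positions are merged and sorted; each
    internal boundary carries the name of the cutting enzyme, terminal
    boundaries carry :data:`CHROM_END`. When both enzymes cut at the same
    position, one boundary is kept, labeled with the lexicographically smaller
    enzyme name, and the event is counted in ``diagnostics['coincident_cuts']``.
    """
    if not genome:
        raise ValueError("empty genome")
    if len(enzymes) == 2 and enzymes[0].name == enzymes[1].name:
        # Degenerate pair (E, E) collapses to a single digest.
        enzymes = enzymes[:1]
    if len(enzymes) not in (1, 2):
        raise ValueError("digest takes one or two enzymes")

    coincident = 0
    fragments: List[Fragment] = []
    for chrom, seq in genome.items():
        cuts: Dict[int, str] = {}
        for enz in enzymes:
            for pos in find_cut_sites(seq, enz):
                if pos <= 0 or pos >= len(seq):
                    continue
                if pos in cuts and cuts[pos] != enz.name:
                    coincident += 1
                    cuts[pos] = min(cuts[pos], enz.name)
                else:
                    cuts[pos] = enz.name
        bounds = sorted(cuts)
        prev_pos, prev_label = 0, CHROM_END
        for pos in bounds:
            fragments.append(Fragment(chrom, prev_pos, pos, prev_label, cuts[pos]))
            prev_pos, prev_label = pos, cuts[pos]
        fragments.append(Fragment(chrom, prev_pos, len(seq), prev_label, CHROM_END))
    if diagnostics is not None:
        diagnostics["coincident_cuts"] = coincident
    return fragments


_CLASSES = ("ab_ba", "aa", "bb", "chrom_end")


@dataclass
class DigestProfile:
    """Per-class fragment counts (overall and inside a size window).

    Classes partition the fragment set: ``chrom_end`` takes precedence (any
    fragment touching a chromosome terminus), then ``ab_ba`` (the two ends cut
    by the two distinct enzymes of the pair), then ``aa``/``bb`` (both ends the
    same enzyme).
    """

    genome_id: str
    enzymes: Tuple[str, ...]
    window: SizeWindow
    overall: Dict[str, int] = field(default_factory=lambda: dict.fromkeys(_CLASSES, 0))
    windowed: Dict[str, int] = field(default_factory=lambda: dict.fromkeys(_CLASSES, 0))
    total_fragments: int = 0
    length_histogram: Counter = field(default_factory=Counter)

    @property
    def windowed_ab_ba(self) -> int:
        return self.windowed["ab_ba"]

    def to_dict(self) -> dict:
        return {
            "genome": self.genome_id,
            "enzymes": list(self.enzymes),
            "window": [self.window.min_bp, self.window.max_bp],
            "total_fragments": self.total_fragments,
            "overall": dict(self.overall),
            "windowed": dict(self.windowed),
        }


def _classify(frag: Fragment, enz_a: str, enz_b: str) -> str:
    if frag.left_end == CHROM_END or frag.right_end == CHROM_END:
        return "chrom_end"
    ends = {frag.left_end, frag.right_end}
    if enz_a != enz_b and ends == {enz_a, enz_b}:
        return "ab_ba"
    if ends == {enz_a}:
        return "aa"
    if ends == {enz_b}:
        return "bb"
    raise ValueError(f"fragment ends {ends} not produced by ({enz_a}, {enz_b})")


def profile(
    fragments: Iterable[Fragment],
    window: SizeWindow,
    enzymes: Sequence[RestrictionEnzyme],
    genome_id: str = "",
) -> DigestProfile:
    """Classify fragments by end labels and count them overall and in ``window``."""
    enz_a = enzymes[0].name
    enz_b = enzymes[1].name if len(enzymes) > 1 else enz_a
    prof = DigestProfile(genome_id, tuple(e.name for e in enzymes), window)
    for frag in fragments:
        cls = _classify(frag, enz_a, enz_b)
        prof.overall[cls] += 1
        prof.total_fragments += 1
        prof.length_histogram[frag.length] += 1
        if window.contains(frag.length):
            prof.windowed[cls] += 1
    return prof


def rank_pairs(
    genome: Mapping[str, str],
    pairs: Sequence[Tuple[RestrictionEnzyme, RestrictionEnzyme]],
    window: SizeWindow,
    genome_id: str = "",
) -> List[Tuple[Tuple[str, str], DigestProfile]]:
    """Rank enzyme pairs by windowed AB+BA fragment count, descending.

    Ties are broken lexicographically by pair name so that the ordering is
    deterministic.
    """
    if not pairs:
        raise ValueError("need at least one enzyme pair")
    results = []
    for enz_a, enz_b in pairs:
        frags = digest(genome, (enz_a, enz_b))
        prof = profile(frags, window, (enz_a, enz_b), genome_id)
        results.append(((enz_a.name, enz_b.name), prof))
    results.sort(key=lambda item: (-item[1].windowed_ab_ba, item[0]))
    return results


def single_enzyme_profile(
    genome: Mapping[str, str],
    enzyme: RestrictionEnzyme,
    window: SizeWindow,
    genome_id: str = "",
) -> DigestProfile:
    """Single-enzyme digest profile; all internal fragments are class AA."""
    frags = digest(genome, (enzyme,))
    return profile(frags, window, (enzyme,), genome_id)
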