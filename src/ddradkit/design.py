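"""Sequencing-design arithmetic: target bp, expected depth, yield conversion."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

from .digestion import SizeWindow

__all__ = [
    "DesignPlan",
    "target_bp_range",
    "expected_depth",
    "yield_to_reads",
    "make_plan",
]


def target_bp_range(n_loci: int, window: SizeWindow) -> Tuple[int, int]:
    """Exact (min, max) target base pairs for ``n_loci`` fragments in ``window``."""
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    return n_loci * window.min_bp, n_loci * window.max_bp


def expected_depth(yield_bp: float, target_range: Tuple[int, int]) -> Tuple[float, float]:
    """Fold-coverage (depth at max target, depth at min target) for a per-sample yield.

    The low end divides by the larger target (conservative); values are real
    and conventionally reported to one decimal.
    """
    t_min, t_max = target_range
    if t_min <= 0 or t_max <= 0:
        raise ValueError("target bp must be positive")
    if yield_bp <= 0:
        raise ValueError("yield_bp must be positive")
    return yield_bp / t_max, yield_bp / t_min


def yield_to_reads(
    yield_bp: float,
    read_length: int,
    paired: bool = True,
    bases_counted: str = "one_mate",
) -> float:
    """Convert a base-pair yield into a read (pair) count.

    Two conventions are implemented because published yield statements mix
    them: ``both_mates`` counts both mates of a pair toward the yield
    (pairs = yield / (2 * read_length)); ``one_mate`` counts one
    (pairs = yield / read_length). The default is ``one_mate``, which equates
    a 250 Mb per-sample yield with one million 2x250 bp read pairs.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if bases_counted not in ("both_mates", "one_mate"):
        raise ValueError("bases_counted must be 'both_mates' or 'one_mate'")
    denom = read_length * (2 if (paired and bases_counted == "both_mates") else 1)
    return yield_bp / denom


@dataclass
class DesignPlan:
    n_loci: int
    window_min_bp: int
    window_max_bp: int
    target_bp_min: int
    target_bp_max: int
    yield_bp_per_sample: float
    expected_depth_min: float
    expected_depth_max: float
    n_samples: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["expected_depth_min"] = round(self.expected_depth_min, 1)
        d["expected_depth_max"] = round(self.expected_depth_max, 1)
        return d


def make_plan(
    n_loci: int,
    window: SizeWindow,
    yield_bp_per_sample: float,
    n_samples: int = 1,
) -> DesignPlan:
    t_min, t_max = target_bp_range(n_loci, window)
    d_min, d_max = expected_depth(yield_bp_per_sample, (t_min, t_max))
    return DesignPlan(
        n_loci=n_loci,
        window_min_bp=window.min_bp,
        window_max_bp=window.max_bp,
        target_bp_min=t_min,
        target_bp_max=t_max,
        yield_bp_per_sample=yield_bp_per_sample,
        expected_depth_min=d_min,
        expected_depth_max=d_max,
        n_samples=n_samples,
    )
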