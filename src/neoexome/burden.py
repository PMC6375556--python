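"""Callable genome size and mutation burden per megabase.

The burden denominator is the number of callable bases — positions with
sequencing depth at or above a minimum (20 reads by default). Burden is
reported in two modes: *all* counts every kept SNV (synonymous, intronic and
intergenic included) plus INDELs; *nonsyn* counts only missense, stop-gained
and splice-site SNVs plus INDELs. One Mb is 10^6 bases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import DepthTrack
from .records import NONSYNONYMOUS, SNV, VariantRecord

MB = 1_000_000
DEFAULT_MIN_DEPTH = 20


@dataclass
class BurdenResult:
    sample_id: str
    callable_mb: float
    n_variants_all: int
    n_variants_nonsyn: int
    burden_all: float  # variants per Mb
    burden_nonsyn: float

    def rounded(self, sigfigs: int = 2) -> tuple[float, float]:
        """Burdens rounded to two significant figures, the reporting style used
        alongside the raw values."""
        def _round(x: float) -> float:
            if x == 0:
                return 0.0
            from math import floor, log10

            return round(x, -int(floor(log10(abs(x)))) + (sigfigs - 1))

        return _round(self.burden_all), _round(self.burden_nonsyn)


def callable_bases(track: DepthTrack, min_depth: int = DEFAULT_MIN_DEPTH) -> int:
    """Number of positions with depth >= min_depth (boundary inclusive)."""
    if track.length == 0:
        raise ValueError("empty depth track")
    return track.bases_at_least(min_depth)


def _counts(records: list[VariantRecord]) -> tuple[int, int]:
    n_all = len(records)
    n_nonsyn = sum(1 for r in records if r.kind != SNV or r.consequence in NONSYNONYMOUS)
    return n_all, n_nonsyn


def mutation_burden(
    records: list[VariantRecord], callable_base_count: int, sample_id: str | None = None
) -> BurdenResult:
    """Per-Mb burden of a sample's kept variants over its callable bases."""
    if callable_base_count <= 0:
        raise ValueError("callable bases must be positive")
    n_all, n_nonsyn = _counts(records)
    mb = callable_base_count / MB
    sid = sample_id if sample_id is not None else (records[0].sample_id if records else "")
    return BurdenResult(
        sample_id=sid,
        callable_mb=mb,
        n_variants_all=n_all,
        n_variants_nonsyn=n_nonsyn,
        burden_all=n_all / mb,
        burden_nonsyn=n_nonsyn / mb,
    )
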