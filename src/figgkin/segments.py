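"""IBD segments, Cotterman coefficients, and kinship-coefficient conversion.

An IBD1 segment is a haploid match (the pair shares exactly one haplotype over
the interval); an IBD2 segment is a diploid match (both haplotypes shared).
Summed genetic lengths convert to Cotterman coefficients as

    kappa1 = L(IBD1) / L(genome)
    kappa2 = L(IBD2) / L(genome)
    kappa0 = 1 - kappa1 - kappa2

and to the kinship coefficient as theta = kappa2/2 + kappa1/4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "IBDSegment",
    "SegmentSet",
    "CottermanCoeffs",
    "cotterman_from_segments",
    "theta_from_kappa",
]


@dataclass(frozen=True)
class IBDSegment:
    chrom: int
    start_bp: float
    end_bp: float
    start_cm: float
    end_cm: float
    ibd_class: str  # "IBD1" | "IBD2"
    n_markers: int

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp or self.end_cm < self.start_cm:
            raise ValueError("segment end must exceed start")
        if self.ibd_class not in ("IBD1", "IBD2"):
            raise ValueError(f"unknown IBD class {self.ibd_class!r}")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def length_bp(self) -> float:
        return self.end_bp - self.start_bp


@dataclass
class SegmentSet:
    """Detected (or ground-truth) IBD segments for one pair of individuals."""

    segments: list[IBDSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def by_class(self, ibd_class: str) -> list[IBDSegment]:
        return [s for s in self.segments if s.ibd_class == ibd_class]

    def total_cm(self, ibd_class: str) -> float:
        return float(sum(s.length_cm for s in self.by_class(ibd_class)))

    @property
    def l_ibd1(self) -> float:
        return self.total_cm("IBD1")

    @property
    def l_ibd2(self) -> float:
        return self.total_cm("IBD2")


@dataclass(frozen=True)
class CottermanCoeffs:
    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for v in (self.k0, self.k1, self.k2):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError("Cotterman coefficients must lie in [0, 1]")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("Cotterman coefficients must sum to 1")


def cotterman_from_segments(segset: SegmentSet, l_genome: float) -> CottermanCoeffs:
    """Convert summed segment lengths (cM) to (kappa0, kappa1, kappa2)."""
    if l_genome <= 0:
        raise ValueError("genome length must be positive")
    l1, l2 = segset.l_ibd1, segset.l_ibd2
    if l1 < 0 or l2 < 0:
        raise ValueError("segment lengths must be non-negative")
    if l1 + l2 > l_genome * (1 + 1e-12):
        warnings.warn("IBD length exceeds genome length; clipping", stacklevel=2)
        l2 = min(l2, l_genome)
        l1 = min(l1, l_genome - l2)
    k1 = l1 / l_genome
    k2 = l2 / l_genome
    return CottermanCoeffs(k0=1.0 - k1 - k2, k1=k1, k2=k2)


def theta_from_kappa(kappa: CottermanCoeffs) -> float:
    """Kinship coefficient theta = kappa2/2 + kappa1/4."""
    return kappa.k2 / 2.0 + kappa.k1 / 4.0
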