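"""Genetic maps: monotone physical (bp) <-> genetic (cM) coordinates per autosome.

A :class:`GeneticMap` stores, per chromosome, a piecewise-linear interpolation
table from base-pair position to centimorgan position.  Synthetic maps built by
:func:`generate_map` use a constant recombination rate per chromosome (two
knots); maps read from a recombination-map file may have arbitrarily many knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "generate_map", "HUMAN_AUTOSOME_CM", "GENOME_LENGTH_CM"]

#: Sex-averaged genetic lengths (cM) of the 22 human autosomes (chr1..chr22),
#: approximate values from pedigree-based linkage maps.  Used only as relative
#: weights: generate_map rescales them so the genome totals the requested length.
HUMAN_AUTOSOME_CM = np.array(
    [
        286.3, 268.6, 223.3, 214.6, 204.1, 192.0, 187.2, 168.0, 166.4, 181.1,
        158.2, 174.7, 125.8, 120.8, 141.9, 134.0, 128.5, 117.9, 107.9, 108.3,
        62.8, 74.1,
    ]
)

#: Default autosomal genome length in cM (the total of the sex-averaged map
#: used for kinship-coefficient normalisation).
GENOME_LENGTH_CM = 3346.30


@dataclass
class GeneticMap:
    """Per-chromosome bp<->cM interpolation tables.

    Parameters
    ----------
    chrom_ids
        Chromosome identifiers (ints, 1-based by convention).
    bp_knots, cm_knots
        One array per chromosome; ``cm_knots[i]`` is non-decreasing and aligned
        with ``bp_knots[i]``.  The last knot defines the chromosome lengths.
    """

    chrom_ids: list[int]
    bp_knots: list[np.ndarray]
    cm_knots: list[np.ndarray]
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.chrom_ids) == len(self.bp_knots) == len(self.cm_knots)):
            raise ValueError("chrom_ids, bp_knots and cm_knots must align")
        for bp, cm in zip(self.bp_knots, self.cm_knots):
            if len(bp) != len(cm) or len(bp) < 2:
                raise ValueError("each chromosome needs >= 2 aligned knots")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ValueError("map knots must be monotone (cM non-decreasing in bp)")
        if self.total_cm <= 0:
            raise ValueError("total genetic length must be positive")
        self._index = {c: i for i, c in enumerate(self.chrom_ids)}

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant_rate(
        cls, lengths_cm: np.ndarray, bp_per_cm: float, chrom_ids: list[int] | None = None
    ) -> "GeneticMap":
        """Uniform-recombination-rate map: ``cM = bp / bp_per_cm`` per chromosome."""
        lengths_cm = np.asarray(lengths_cm, dtype=float)
        if np.any(lengths_cm <= 0) or bp_per_cm <= 0:
            raise ValueError("chromosome lengths and bp_per_cm must be positive")
        ids = list(chrom_ids) if chrom_ids is not None else list(range(1, len(lengths_cm) + 1))
        bp = [np.array([0.0, round(l * bp_per_cm)]) for l in lengths_cm]
        cm = [np.array([0.0, l]) for l in lengths_cm]
        return cls(ids, bp, cm)

    # -- queries -----------------------------------------------------------

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_ids)

    @property
    def lengths_cm(self) -> np.ndarray:
        return np.array([cm[-1] for cm in self.cm_knots])

    @property
    def lengths_bp(self) -> np.ndarray:
        return np.array([bp[-1] for bp in self.bp_knots])

    @property
    def total_cm(self) -> float:
        return float(sum(cm[-1] for cm in self.cm_knots))

    @property
    def chromosomes(self) -> list[tuple[int, int, float]]:
        """(id, physical_length_bp, genetic_length_cM) triples."""
        return [
            (c, int(bp[-1]), float(cm[-1]))
            for c, bp, cm in zip(self.chrom_ids, self.bp_knots, self.cm_knots)
        ]

    def chrom_length_cm(self, chrom: int) -> float:
        return float(self.cm_knots[self._index[chrom]][-1])

    def chrom_length_bp(self, chrom: int) -> int:
        return int(self.bp_knots[self._index[chrom]][-1])

    def bp_to_cm(self, chrom: int, bp: np.ndarray | float) -> np.ndarray | float:
        i = self._index[chrom]
        return np.interp(bp, self.bp_knots[i], self.cm_knots[i])

    def cm_to_bp(self, chrom: int, cm: np.ndarray | float) -> np.ndarray | float:
        # inverse interpolation; flat cM stretches map to their left edge
        i = self._index[chrom]
        return np.interp(cm, self.cm_knots[i], self.bp_knots[i])


def generate_map(
    n_chrom: int = 22,
    total_cm: float = GENOME_LENGTH_CM,
    bp_per_cm: float = 1e6,
    seed: int | None = None,
) -> GeneticMap:
    """Build a human-like constant-rate genetic map.

    Chromosome genetic lengths are taken proportionally to the sex-averaged
    human autosome lengths (:data:`HUMAN_AUTOSOME_CM`, cycled if ``n_chrom``
    exceeds 22) and rescaled so they sum to ``total_cm`` exactly.  The
    construction is deterministic; ``seed`` is accepted for interface symmetry
    with the other generators.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if total_cm <= 0 or bp_per_cm <= 0:
        raise ValueError("total_cm and bp_per_cm must be positive")
    weights = np.resize(HUMAN_AUTOSOME_CM, n_chrom).astype(float)
    lengths = weights * (total_cm / weights.sum())
    return GeneticMap.constant_rate(lengths, bp_per_cm)
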