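"""Genotyping-error injection and discordance classification.

Three error types on biallelic genotypes (alt-allele dosage 0/1/2):

* drop-in  — an extra allele appears: homozygote -> heterozygote;
* drop-out — an allele is lost: heterozygote -> a random homozygote;
* switch   — opposite homozygotes are called: 0 <-> 2.

Each genotype is perturbed independently with probability ``rate``; given a
perturbation, the type is drawn from the composition weights restricted to the
types applicable to that genotype class (drop-in/switch for homozygotes,
drop-out for heterozygotes) and renormalised — the vectorised equivalent of
re-sampling inapplicable draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ErrorSpec", "ErrorProfile", "inject_errors", "inject_errors_phased",
           "classify_discordance"]

MISSING = -1


@dataclass(frozen=True)
class ErrorSpec:
    """Per-genotype error rate and type composition.

    ``composition`` is (drop_in, drop_out, switch) weights summing to 1; the
    default ``None`` means "uniform over the types applicable to each genotype
    class".
    """

    rate: float
    composition: tuple[float, float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("error rate must lie in [0, 1]")
        if self.composition is not None:
            w = np.asarray(self.composition, dtype=float)
            if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("composition must be 3 non-negative weights summing to 1")


@dataclass(frozen=True)
class ErrorProfile:
    """Counts of per-site genotype comparisons between a reference and a test call set."""

    drop_in: int
    drop_out: int
    switch: int
    concordant: int
    missing_involved: int

    @property
    def compared(self) -> int:
        return self.drop_in + self.drop_out + self.switch + self.concordant

    @property
    def overall_rate(self) -> float:
        n = self.compared
        return (self.drop_in + self.drop_out + self.switch) / n if n else 0.0

    def rates(self) -> dict[str, float]:
        n = self.compared or 1
        return {
            "drop_in": self.drop_in / n,
            "drop_out": self.drop_out / n,
            "switch": self.switch / n,
            "overall": self.overall_rate,
        }

    def to_frame(self, sample: str = "") -> pd.DataFrame:
        r = self.rates()
        return pd.DataFrame(
            {"sample": sample, "type": ["drop_in", "drop_out", "switch", "overall"],
             "rate": [r["drop_in"], r["drop_out"], r["switch"], r["overall"]]}
        )


def _perturb(geno: np.ndarray, spec: ErrorSpec, rng: np.random.Generator,
             uniforms: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Return (perturbed copy, boolean mask of altered entries)."""
    g = np.array(geno, dtype=np.int8, copy=True)
    u = rng.random(g.shape) if uniforms is None else uniforms
    hit = (u < spec.rate) & (g != MISSING)

    if spec.composition is None:
        w_in, w_out, w_sw = 1.0, 1.0, 1.0
    else:
        w_in, w_out, w_sw = spec.composition

    het = hit & (g == 1)
    hom = hit & ((g == 0) | (g == 2))
    # heterozygotes: only drop-out applies (skip if it carries no weight)
    if w_out > 0:
        idx = np.where(het)
        g[idx] = rng.choice(np.array([0, 2], dtype=np.int8), size=len(idx[0]))
    else:
        het &= False
    # homozygotes: drop-in vs switch, renormalised
    tot = w_in + w_sw
    if tot > 0:
        to_het = np.zeros(g.shape, dtype=bool)
        to_het[hom] = rng.random(int(hom.sum())) < (w_in / tot)
        to_sw = hom & ~to_het
        g[to_het] = 1
        g[to_sw] = 2 - g[to_sw]
    else:
        hom &= False
    return g, het | hom


def inject_errors(genotypes: np.ndarray, spec: ErrorSpec,
                  uniforms: np.ndarray | None = None) -> np.ndarray:
    """Perturb a dosage matrix according to ``spec``; missing entries untouched.

    ``uniforms`` optionally supplies the per-genotype uniform draws deciding
    which entries are hit, enabling common-random-number coupling across error
    rates (the hit sets are then nested in ``rate``).
    """
    rng = np.random.default_rng(spec.seed)
    perturbed, _ = _perturb(genotypes, spec, rng, uniforms)
    return perturbed


def inject_errors_phased(haplotypes: np.ndarray, spec: ErrorSpec,
                         uniforms: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Inject genotype errors and keep a phased representation consistent.

    Errors are drawn at the genotype level exactly as :func:`inject_errors`;
    altered sites are re-phased arbitrarily (a perfect-phasing idealisation:
    the erroneous genotype is what a phaser would see).  Returns
    ``(haplotypes, genotypes)`` after injection.
    """
    rng = np.random.default_rng(spec.seed)
    geno = (haplotypes[0::2].astype(np.int8) + haplotypes[1::2]).astype(np.int8)
    new_geno, altered = _perturb(geno, spec, rng, uniforms)
    haps = np.array(haplotypes, copy=True)
    rows, cols = np.where(altered)
    flip = rng.integers(0, 2, size=len(rows))
    h0 = np.where(new_geno[rows, cols] == 2, 1, np.where(new_geno[rows, cols] == 0, 0, flip))
    h1 = new_geno[rows, cols] - h0
    haps[2 * rows, cols] = h0.astype(np.uint8)
    haps[2 * rows + 1, cols] = h1.astype(np.uint8)
    return haps, new_geno


def classify_discordance(ref_genotypes: np.ndarray, test_genotypes: np.ndarray) -> ErrorProfile:
    """Classify per-site discordances between aligned reference and test calls.

    hom -> het retaining the original allele is a drop-in, het -> hom a
    drop-out, hom -> opposite hom a switch.  Sites with missing data on either
    side are counted separately and excluded from the rate denominator.
    """
    ref = np.asarray(ref_genotypes)
    test = np.asarray(test_genotypes)
    if ref.shape != test.shape:
        raise ValueError("reference and test genotype matrices must be aligned")
    miss = (ref == MISSING) | (test == MISSING)
    ok = ~miss
    same = ok & (ref == test)
    drop_in = ok & ((ref == 0) | (ref == 2)) & (test == 1)
    drop_out = ok & (ref == 1) & ((test == 0) | (test == 2))
    switch = ok & (np.abs(ref.astype(np.int16) - test) == 2)
    return ErrorProfile(
        drop_in=int(drop_in.sum()),
        drop_out=int(drop_out.sum()),
        switch=int(switch.sum()),
        concordant=int(same.sum()),
        missing_involved=int(miss.sum()),
    )
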