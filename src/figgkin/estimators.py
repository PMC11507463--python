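"""Four kinship estimators: one method-of-moments and three IBD-segment-based.

* :func:`king_theta` — method-of-moments kinship from genome-wide IBS counts
  (homogeneous-population form; may be negative).
* :func:`ibis_segments` — phase-free IBD from opposite-homozygote-free marker
  runs, thresholded on genetic length (2 cM) and marker count (186).
* :func:`truffle_segments` — phase-free IBD1/IBD2 from IBS runs, thresholded
  on the chance-match probability (10^-8) and physical length (5 Mb IBD1,
  2 Mb IBD2), with an error-bridging tolerance.
* :func:`germline_segments` — phased IBD from exact haplotype matches found by
  aligned word seeding and maximal extension, thresholded at 3 cM.

Segment-based estimators convert segments to theta via the Cotterman
coefficients; all thresholds live in :class:`EstimatorConfig` with the study's
settings as defaults.  The marker-count and probability thresholds are the
detectors' false-positive control and are deliberately density-invariant: a
sparse panel raises the effective minimum segment length, which is the
mechanism behind segment-method degradation on small panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .panel import MarkerPanel
from .segments import (
    IBDSegment,
    SegmentSet,
    cotterman_from_segments,
    theta_from_kappa,
)

__all__ = [
    "EstimatorConfig",
    "KinshipEstimate",
    "InsufficientDataError",
    "king_theta",
    "ibis_segments",
    "ibis_theta",
    "truffle_segments",
    "truffle_theta",
    "germline_segments",
    "germline_theta",
    "estimate_all",
]

MISSING = -1


class InsufficientDataError(ValueError):
    """No usable overlapping genotypes for a pair."""


@dataclass(frozen=True)
class EstimatorConfig:
    """Detection thresholds for the three segment-based estimators."""

    ibis_min_cm: float = 2.0
    ibis_min_markers: int = 186
    ibis_kinship_constant: float = 0.00138
    ibis_mismatch_tolerance: float = 0.0  # max opposite-hom density bridged into a run
    ibis_emit_ibd2: bool = True
    truffle_log10_pmatch: float = -8.0
    truffle_min_mb_ibd1: float = 5.0
    truffle_min_mb_ibd2: float = 2.0
    truffle_error_tolerance: float = 0.01  # max incompatible-site density bridged
    germline_min_cm: float = 3.0
    germline_word_size: int = 64

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "truffle_log10_pmatch":
                if v >= 0:
                    raise ValueError("truffle_log10_pmatch must be negative")
            elif f.name in ("ibis_mismatch_tolerance", "truffle_error_tolerance"):
                if not 0 <= v < 1:
                    raise ValueError(f"{f.name} must lie in [0, 1)")
            elif f.name != "ibis_emit_ibd2" and v <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass(frozen=True)
class KinshipEstimate:
    """Per-method kinship coefficients for one pair (NaN = undefined)."""

    theta_king: float
    theta_ibis: float
    theta_truffle: float
    theta_germline: float
    id_a: str = ""
    id_b: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "theta_king": self.theta_king,
            "theta_ibis": self.theta_ibis,
            "theta_truffle": self.theta_truffle,
            "theta_germline": self.theta_germline,
        }


# ----------------------------------------------------------------- KING -----


def king_theta(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Method-of-moments kinship from IBS counts.

    With N_het,het the count of sites where both individuals are heterozygous,
    N_opp the count of opposite-homozygote sites and N_het^i each individual's
    heterozygous-site count (over sites non-missing in both):

        theta = (N_het,het - 2 * N_opp) / (N_het^a + N_het^b)

    The estimate can be negative; it is undefined (NaN) when neither
    individual carries a heterozygous site.
    """
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    ok = (ga != MISSING) & (gb != MISSING)
    if not ok.any():
        raise InsufficientDataError("no overlapping non-missing sites")
    ga, gb = ga[ok], gb[ok]
    het_a = int(np.count_nonzero(ga == 1))
    het_b = int(np.count_nonzero(gb == 1))
    if het_a + het_b == 0:
        return float("nan")
    n_hh = int(np.count_nonzero((ga == 1) & (gb == 1)))
    n_opp = int(np.count_nonzero(np.abs(ga.astype(np.int16) - gb) == 2))
    return (n_hh - 2.0 * n_opp) / (het_a + het_b)


# ------------------------------------------------------------ run helpers ---


def _maximal_runs(bad: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of consecutive False entries."""
    good = ~bad
    if not good.any():
        return []
    d = np.diff(good.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if good[0]:
        starts.insert(0, 0)
    if good[-1]:
        ends.append(len(good) - 1)
    return list(zip(starts, ends))


def _bridge_runs(runs: list[tuple[int, int]], bad_idx: np.ndarray,
                 tolerance: float) -> list[tuple[int, int]]:
    """Greedily merge adjacent runs across isolated incompatible sites.

    Two runs separated by exactly one incompatible marker are merged while the
    incompatible-site density of the merged run stays within ``tolerance``.
    """
    if tolerance <= 0 or len(runs) < 2:
        return runs
    bad = set(int(i) for i in bad_idx)
    merged = [[s, e, 0] for s, e in runs]  # [start, end, n_bad_inside]
    changed = True
    while changed:
        changed = False
        out = [merged[0]]
        for nxt in merged[1:]:
            cur = out[-1]
            gap = nxt[0] - cur[1] - 1
            n_bad = cur[2] + nxt[2] + gap
            span = nxt[1] - cur[0] + 1
            if gap == 1 and (cur[1] + 1) in bad and n_bad / span <= tolerance:
                cur[1], cur[2] = nxt[1], n_bad
                changed = True
            else:
                out.append(nxt)
        merged = out
    return [(s, e) for s, e, _ in merged]


def _mask_to_segments(mask: np.ndarray, chrom: int, pos_bp: np.ndarray,
                      pos_cm: np.ndarray, ibd_class: str) -> list[IBDSegment]:
    segs = []
    for s, e in _maximal_runs(~mask):
        if e <= s or pos_bp[e] <= pos_bp[s]:
            continue  # a single marker carries no length
        segs.append(
            IBDSegment(
                chrom=chrom,
                start_bp=float(pos_bp[s]),
                end_bp=float(pos_bp[e]),
                start_cm=float(pos_cm[s]),
                end_cm=float(pos_cm[e]),
                ibd_class=ibd_class,
                n_markers=int(e - s + 1),
            )
        )
    return segs


def _check_aligned(geno_a: np.ndarray, geno_b: np.ndarray, panel: MarkerPanel) -> None:
    if len(geno_a) != len(panel) or len(geno_b) != len(panel):
        raise ValueError("genotype vectors must align with the marker panel")


# ----------------------------------------------------------------- IBIS -----


def ibis_segments(geno_a: np.ndarray, geno_b: np.ndarray, panel: MarkerPanel,
                  cfg: EstimatorConfig | None = None) -> SegmentSet:
    """Phase-free IBD detection from opposite-homozygote-free runs.

    A maximal run of consecutive markers free of opposite homozygotes (up to
    the configured mismatch density) is emitted as IBD1 iff its genetic length
    is >= ``ibis_min_cm`` and it spans >= ``ibis_min_markers`` markers.  With
    ``ibis_emit_ibd2``, identical-genotype sub-runs meeting the same two
    criteria are emitted as IBD2 and excluded from IBD1.
    """
    cfg = cfg or EstimatorConfig()
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    _check_aligned(ga, gb, panel)
    segs: list[IBDSegment] = []
    for chrom, sl in panel.chrom_slices():
        a, b = ga[sl], gb[sl]
        pos_bp, pos_cm = panel.pos_bp[sl], panel.pos_cm[sl]
        ok = (a != MISSING) & (b != MISSING)
        opp = ok & (np.abs(a.astype(np.int16) - b) == 2)
        runs = _bridge_runs(_maximal_runs(opp), np.flatnonzero(opp),
                            cfg.ibis_mismatch_tolerance)
        ibd1 = np.zeros(len(a), dtype=bool)
        for s, e in runs:
            if e - s + 1 >= cfg.ibis_min_markers and pos_cm[e] - pos_cm[s] >= cfg.ibis_min_cm:
                ibd1[s : e + 1] = True
        ibd2 = np.zeros(len(a), dtype=bool)
        if cfg.ibis_emit_ibd2:
            diff = ok & (a != b)
            for s, e in _maximal_runs(diff | ~ibd1):
                if e - s + 1 >= cfg.ibis_min_markers and pos_cm[e] - pos_cm[s] >= cfg.ibis_min_cm:
                    ibd2[s : e + 1] = True
        segs.extend(_mask_to_segments(ibd2, chrom, pos_bp, pos_cm, "IBD2"))
        segs.extend(_mask_to_segments(ibd1 & ~ibd2, chrom, pos_bp, pos_cm, "IBD1"))
    return SegmentSet(segs)


def ibis_theta(segset: SegmentSet, l_genome: float,
               cfg: EstimatorConfig | None = None) -> float:
    """theta = kappa2/2 + kappa1/4 + supplemental constant (default 0.00138)."""
    cfg = cfg or EstimatorConfig()
    kappa = cotterman_from_segments(segset, l_genome)
    return theta_from_kappa(kappa) + cfg.ibis_kinship_constant


# -------------------------------------------------------------- TRUFFLE -----


def truffle_segments(geno_a: np.ndarray, geno_b: np.ndarray, panel: MarkerPanel,
                     cfg: EstimatorConfig | None = None) -> SegmentSet:
    """Phase-free IBD1/IBD2 detection with a chance-probability criterion.

    IBD1 candidates are opposite-homozygote-free runs, IBD2 candidates are
    identical-genotype runs (both bridged at the configured error tolerance).
    A candidate is emitted iff the probability that the run is compatible by
    chance under Hardy-Weinberg — per-site 1 - 2 p^2 q^2 for IBD1 and
    p^4 + (2pq)^2 + q^4 for IBD2, multiplied across the run — is below
    10^``truffle_log10_pmatch`` and its physical span reaches the class
    minimum (5 Mb IBD1, 2 Mb IBD2).  IBD2 intervals are excluded from IBD1.
    """
    cfg = cfg or EstimatorConfig()
    ga = np.asarray(geno_a)
    gb = np.asarray(geno_b)
    _check_aligned(ga, gb, panel)
    freqs = panel.alt_freq
    if np.any(~np.isfinite(freqs)):
        raise ValueError("panel allele frequencies are required")
    segs: list[IBDSegment] = []
    for chrom, sl in panel.chrom_slices():
        a, b = ga[sl], gb[sl]
        pos_bp, pos_cm = panel.pos_bp[sl], panel.pos_cm[sl]
        p = freqs[sl]
        q = 1.0 - p
        log_p1 = np.log10(1.0 - 2.0 * p**2 * q**2)
        log_p2 = np.log10((p**2) ** 2 + (2 * p * q) ** 2 + (q**2) ** 2)
        ok = (a != MISSING) & (b != MISSING)
        # missing sites are neutral: no evidence contribution
        cum1 = np.concatenate([[0.0], np.cumsum(np.where(ok, log_p1, 0.0))])
        cum2 = np.concatenate([[0.0], np.cumsum(np.where(ok, log_p2, 0.0))])

        def accepted(mask_bad, cum, min_mb, n=len(a), bp=pos_bp):
            out = np.zeros(n, dtype=bool)
            runs = _bridge_runs(_maximal_runs(mask_bad), np.flatnonzero(mask_bad),
                                cfg.truffle_error_tolerance)
            for s, e in runs:
                if bp[e] - bp[s] < min_mb * 1e6:
                    continue
                if cum[e + 1] - cum[s] < cfg.truffle_log10_pmatch:
                    out[s : e + 1] = True
            return out

        opp = ok & (np.abs(a.astype(np.int16) - b) == 2)
        diff = ok & (a != b)
        ibd1 = accepted(opp, cum1, cfg.truffle_min_mb_ibd1)
        ibd2 = accepted(diff, cum2, cfg.truffle_min_mb_ibd2)
        segs.extend(_mask_to_segments(ibd2, chrom, pos_bp, pos_cm, "IBD2"))
        segs.extend(_mask_to_segments(ibd1 & ~ibd2, chrom, pos_bp, pos_cm, "IBD1"))
    return SegmentSet(segs)


def truffle_theta(segset: SegmentSet, l_genome: float) -> float:
    """theta = kappa2/2 + kappa1/4 from summed segment lengths."""
    kappa = cotterman_from_segments(segset, l_genome)
    return theta_from_kappa(kappa)


# ------------------------------------------------------------- GERMLINE -----


def _hap_match_runs(x: np.ndarray, y: np.ndarray, pos_cm: np.ndarray,
                    word: int, min_cm: float) -> list[tuple[int, int]]:
    """Maximal exact-match runs seeded by fully matching aligned words.

    A maximal agreement run is reported iff it contains at least one complete
    word of the aligned word grid (the hash-seed condition) and spans
    >= ``min_cm``.
    """
    mismatch = x != y
    out = []
    for s, e in _maximal_runs(mismatch):
        k = -(-s // word)  # first word fully right of s
        if k * word + word - 1 > e:
            continue
        if pos_cm[e] - pos_cm[s] < min_cm:
            continue
        out.append((s, e))
    return out


def germline_segments(hap_a0: np.ndarray, hap_a1: np.ndarray,
                      hap_b0: np.ndarray, hap_b1: np.ndarray,
                      panel: MarkerPanel,
                      cfg: EstimatorConfig | None = None) -> SegmentSet:
    """Phased IBD detection by exact haplotype matching.

    All four cross-individual haplotype pairings are scanned for maximal
    exact-match runs (word-seeded); runs of genetic length >= 3 cM are kept.
    Intervals where both of one individual's haplotypes pair off with the
    other's two haplotypes are IBD2; intervals covered by at least one pairing
    otherwise are IBD1.
    """
    cfg = cfg or EstimatorConfig()
    haps = [np.asarray(h) for h in (hap_a0, hap_a1, hap_b0, hap_b1)]
    for h in haps:
        if len(h) != len(panel):
            raise ValueError("haplotype vectors must align with the marker panel")
        if h.min(initial=0) < 0 or h.max(initial=0) > 1:
            raise ValueError("germline_segments requires phased 0/1 haplotypes")
    segs: list[IBDSegment] = []
    pairings = [(0, 2), (0, 3), (1, 2), (1, 3)]  # (a-hap, b-hap)
    for chrom, sl in panel.chrom_slices():
        pos_bp, pos_cm = panel.pos_bp[sl], panel.pos_cm[sl]
        n = sl.stop - sl.start
        cov = {}
        for i, j in pairings:
            mask = np.zeros(n, dtype=bool)
            for s, e in _hap_match_runs(haps[i][sl], haps[j][sl], pos_cm,
                                        cfg.germline_word_size, cfg.germline_min_cm):
                mask[s : e + 1] = True
            cov[(i, j)] = mask
        ibd2 = (cov[(0, 2)] & cov[(1, 3)]) | (cov[(0, 3)] & cov[(1, 2)])
        any_cov = cov[(0, 2)] | cov[(0, 3)] | cov[(1, 2)] | cov[(1, 3)]
        segs.extend(_mask_to_segments(ibd2, chrom, pos_bp, pos_cm, "IBD2"))
        segs.extend(_mask_to_segments(any_cov & ~ibd2, chrom, pos_bp, pos_cm, "IBD1"))
    return SegmentSet(segs)


def germline_theta(segset: SegmentSet, l_genome: float) -> float:
    return truffle_theta(segset, l_genome)


# ----------------------------------------------------------- orchestration --


def estimate_all(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    panel: MarkerPanel,
    l_genome: float,
    haps_a: tuple[np.ndarray, np.ndarray] | None = None,
    haps_b: tuple[np.ndarray, np.ndarray] | None = None,
    cfg: EstimatorConfig | None = None,
    id_a: str = "",
    id_b: str = "",
) -> KinshipEstimate:
    """Run all four estimators on one pair; failures yield NaN, never raise."""
    cfg = cfg or EstimatorConfig()
    nan = float("nan")

    def guard(fn):
        try:
            return float(fn())
        except (ValueError, ZeroDivisionError):
            return nan

    t_king = guard(lambda: king_theta(geno_a, geno_b))
    t_ibis = guard(lambda: ibis_theta(ibis_segments(geno_a, geno_b, panel, cfg), l_genome, cfg))
    t_truffle = guard(
        lambda: truffle_theta(truffle_segments(geno_a, geno_b, panel, cfg), l_genome)
    )
    if haps_a is not None and haps_b is not None:
        t_germ = guard(
            lambda: germline_theta(
                germline_segments(haps_a[0], haps_a[1], haps_b[0], haps_b[1], panel, cfg),
                l_genome,
            )
        )
    else:
        t_germ = nan
    return KinshipEstimate(t_king, t_ibis, t_truffle, t_germ, id_a, id_b)
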