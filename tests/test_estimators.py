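"""Kinship estimators: hand-computed examples, thresholds, and brute-force
oracle equivalence of all three segment detectors on randomized instances."""

import math

import numpy as np
import pandas as pd
import pytest

import figgkin as fk
from figgkin.estimators import (
    EstimatorConfig,
    InsufficientDataError,
    estimate_all,
    germline_segments,
    ibis_segments,
    ibis_theta,
    king_theta,
    truffle_segments,
    truffle_theta,
)
from figgkin.panel import MarkerPanel
from figgkin.segments import IBDSegment, SegmentSet, cotterman_from_segments, theta_from_kappa

# ---------------------------------------------------------------- helpers ---


def _make_panel(pos_cm, freqs, chrom=1, bp_per_cm=1e6):
    pos_cm = np.asarray(pos_cm, dtype=float)
    t = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": np.round(pos_cm * bp_per_cm).astype(np.int64) + 1,
            "pos_cm": pos_cm,
            "ref": "A",
            "alt": "G",
            "alt_freq": np.asarray(freqs, dtype=float),
        }
    )
    return MarkerPanel(t)


def _scan_runs(bad):
    """Independent scalar scan for maximal bad-free index runs."""
    runs, i, n = [], 0, len(bad)
    while i < n:
        if bad[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not bad[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def _set_to_segments(idx_set, panel, ibd_class):
    """Independent marker-index-set -> segment-tuple conversion."""
    out = set()
    for chrom, sl in panel.chrom_slices():
        local = sorted(i for i in idx_set if sl.start <= i < sl.stop)
        while local:
            s = e = local.pop(0)
            while local and local[0] == e + 1:
                e = local.pop(0)
            if panel.pos_bp[e] > panel.pos_bp[s]:
                out.add(
                    (chrom, round(float(panel.pos_cm[s]), 9),
                     round(float(panel.pos_cm[e]), 9), ibd_class, e - s + 1)
                )
    return out


def _segset_tuples(segset):
    return {
        (s.chrom, round(s.start_cm, 9), round(s.end_cm, 9), s.ibd_class, s.n_markers)
        for s in segset.segments
    }


def naive_ibis(ga, gb, panel, cfg):
    n = len(panel)
    ok = [(ga[i] != -1 and gb[i] != -1) for i in range(n)]
    opp = [ok[i] and abs(int(ga[i]) - int(gb[i])) == 2 for i in range(n)]
    s1 = set()
    for chrom, sl in panel.chrom_slices():
        for s, e in _scan_runs(opp[sl]):
            s, e = s + sl.start, e + sl.start
            if e - s + 1 >= cfg.ibis_min_markers and panel.pos_cm[e] - panel.pos_cm[s] >= cfg.ibis_min_cm:
                s1.update(range(s, e + 1))
    s2 = set()
    if cfg.ibis_emit_ibd2:
        bad2 = [(ok[i] and ga[i] != gb[i]) or i not in s1 for i in range(n)]
        for chrom, sl in panel.chrom_slices():
            for s, e in _scan_runs(bad2[sl]):
                s, e = s + sl.start, e + sl.start
                if e - s + 1 >= cfg.ibis_min_markers and panel.pos_cm[e] - panel.pos_cm[s] >= cfg.ibis_min_cm:
                    s2.update(range(s, e + 1))
    return _set_to_segments(s2, panel, "IBD2") | _set_to_segments(s1 - s2, panel, "IBD1")


def naive_truffle(ga, gb, panel, cfg):
    n = len(panel)
    p = panel.alt_freq
    ok = [(ga[i] != -1 and gb[i] != -1) for i in range(n)]
    opp = [ok[i] and abs(int(ga[i]) - int(gb[i])) == 2 for i in range(n)]
    diff = [ok[i] and ga[i] != gb[i] for i in range(n)]

    def collect(bad, site_prob, min_mb):
        keep = set()
        for chrom, sl in panel.chrom_slices():
            for s, e in _scan_runs(bad[sl]):
                s, e = s + sl.start, e + sl.start
                if panel.pos_bp[e] - panel.pos_bp[s] < min_mb * 1e6:
                    continue
                prob = math.prod(site_prob(i) for i in range(s, e + 1) if ok[i])
                if prob < 10**cfg.truffle_log10_pmatch:
                    keep.update(range(s, e + 1))
        return keep

    s1 = collect(opp, lambda i: 1 - 2 * p[i] ** 2 * (1 - p[i]) ** 2,
                 cfg.truffle_min_mb_ibd1)
    s2 = collect(
        diff,
        lambda i: p[i] ** 4 + (2 * p[i] * (1 - p[i])) ** 2 + (1 - p[i]) ** 4,
        cfg.truffle_min_mb_ibd2,
    )
    return _set_to_segments(s2, panel, "IBD2") | _set_to_segments(s1 - s2, panel, "IBD1")


def naive_germline(ha0, ha1, hb0, hb1, panel, cfg):
    haps = [ha0, ha1, hb0, hb1]
    w = cfg.germline_word_size
    cov = {}
    for a, b in [(0, 2), (0, 3), (1, 2), (1, 3)]:
        keep = set()
        for chrom, sl in panel.chrom_slices():
            mism = [haps[a][i] != haps[b][i] for i in range(sl.start, sl.stop)]
            for s, e in _scan_runs(mism):
                s, e = s + sl.start, e + sl.start
                has_word = any(
                    s <= k * w and (k + 1) * w - 1 <= e
                    for k in range(len(panel) // w + 1)
                )
                if has_word and panel.pos_cm[e] - panel.pos_cm[s] >= cfg.germline_min_cm:
                    keep.update(range(s, e + 1))
        cov[(a, b)] = keep
    ibd2 = (cov[(0, 2)] & cov[(1, 3)]) | (cov[(0, 3)] & cov[(1, 2)])
    allcov = cov[(0, 2)] | cov[(0, 3)] | cov[(1, 2)] | cov[(1, 3)]
    return _set_to_segments(ibd2, panel, "IBD2") | _set_to_segments(allcov - ibd2, panel, "IBD1")


def _random_instance(rng, n_markers, missing_rate=0.0):
    """Two individuals with planted shared haplotype stretches."""
    density = rng.uniform(20, 70)
    gmap = fk.generate_map(1, n_markers / density, 1e6)
    panel, haps = fk.generate_founders(
        2, n_markers, gmap, seed=int(rng.integers(2**31))
    )
    A = haps.alleles.copy()
    for _ in range(int(rng.integers(0, 4))):
        i0 = int(rng.integers(0, n_markers))
        ln = int(rng.integers(5, max(6, n_markers // 2)))
        src, dst = int(rng.integers(0, 2)), int(rng.integers(2, 4))
        A[dst, i0 : i0 + ln] = A[src, i0 : i0 + ln]
    ga = (A[0].astype(np.int8) + A[1]).astype(np.int8)
    gb = (A[2].astype(np.int8) + A[3]).astype(np.int8)
    if missing_rate:
        for g in (ga, gb):
            g[rng.random(n_markers) < missing_rate] = -1
    return panel, A, ga, gb


# ------------------------------------------------------------------- KING ---


class TestKing:
    def test_six_site_hand_count(self):
        # a = (Aa, Aa, AA, aa, Aa, AA), b = (Aa, AA, AA, AA, aa, AA)
        a = np.array([1, 1, 0, 2, 1, 0], dtype=np.int8)
        b = np.array([1, 0, 0, 0, 2, 0], dtype=np.int8)
        assert king_theta(a, b) == pytest.approx(-0.25)

    def test_identical_genotypes_give_half(self):
        g = np.array([0, 1, 1, 2, 1, 0, 2], dtype=np.int8)
        assert king_theta(g, g) == pytest.approx(0.5)

    def test_unrelated_monte_carlo_zero(self):
        gmap = fk.generate_map(1, 2000.0, 1e6)
        panel, haps = fk.generate_founders(2, 100_000, gmap, seed=21)
        g = haps.genotypes()
        theta = king_theta(g[0], g[1])
        # null sd of the estimator is ~1/sqrt(n_informative)
        assert abs(theta) < 3 * 1.0 / np.sqrt(len(panel))

    def test_missing_sites_excluded(self):
        a = np.array([1, -1, 0, 2], dtype=np.int8)
        b = np.array([1, 0, -1, 0], dtype=np.int8)
        # only sites 0 and 3 compared: N_hh=1, N_opp=1, hets=1+1
        assert king_theta(a, b) == pytest.approx((1 - 2) / 2)

    def test_no_overlap_raises(self):
        with pytest.raises(InsufficientDataError):
            king_theta(np.array([-1, -1]), np.array([0, 1]))

    def test_no_heterozygotes_undefined(self):
        assert np.isnan(king_theta(np.array([0, 0, 2]), np.array([0, 2, 2])))


# ------------------------------------------------------- threshold checks ---


class TestIbisThresholds:
    @pytest.mark.parametrize("n_markers, expect_segments", [(185, 0), (186, 1)])
    def test_marker_count_criterion(self, n_markers, expect_segments):
        """A perfectly shared 3 cM run needs 186 markers to qualify."""
        pos = np.linspace(0.0, 3.0, n_markers)
        panel = _make_panel(pos, np.full(n_markers, 0.3))
        g = np.ones(n_markers, dtype=np.int8)  # all heterozygous, identical
        cfg = EstimatorConfig(ibis_emit_ibd2=False)
        segs = ibis_segments(g, g, panel, cfg)
        assert len(segs.by_class("IBD1")) == expect_segments

    def test_parent_offspring_near_full_coverage(self, small_family):
        fam, gmap, panel = (small_family[k] for k in ("family", "gmap", "panel"))
        cfg = EstimatorConfig(ibis_emit_ibd2=False)
        segs = ibis_segments(fam.genotypes_of("F1"), fam.genotypes_of("A1"), panel, cfg)
        assert segs.l_ibd1 >= 0.99 * gmap.total_cm

    def test_unsorted_panel_rejected(self):
        t = _make_panel([0.0, 1.0, 2.0], [0.3, 0.3, 0.3]).table.iloc[[1, 0, 2]]
        with pytest.raises(ValueError):
            MarkerPanel(t.reset_index(drop=True))


class TestTruffleThresholds:
    @pytest.mark.parametrize("n_sites, expect", [(137, 0), (138, 1)])
    def test_probability_criterion_at_maf_half(self, n_sites, expect):
        """Per-site chance compatibility 7/8 at MAF 0.5: the 1e-8 criterion
        needs exactly 138 compatible sites ((7/8)^138 < 1e-8 <= (7/8)^137)."""
        pos = np.linspace(0.0, 6.85, n_sites)  # physical span > 5 Mb
        panel = _make_panel(pos, np.full(n_sites, 0.5))
        a = np.ones(n_sites, dtype=np.int8)
        b = np.zeros(n_sites, dtype=np.int8)  # het vs hom: compatible, not identical
        segs = truffle_segments(a, b, panel)
        assert len(segs.by_class("IBD1")) == expect

    def test_physical_length_criterion(self):
        """A 4 Mb run fails the 5 Mb IBD1 minimum however improbable."""
        n = 400
        pos = np.linspace(0.0, 4.0, n)
        panel = _make_panel(pos, np.full(n, 0.5))
        a = np.ones(n, dtype=np.int8)
        b = np.zeros(n, dtype=np.int8)
        assert len(truffle_segments(a, b, panel)) == 0

    def test_identical_individual_full_ibd2(self, small_family):
        fam, gmap, panel = (small_family[k] for k in ("family", "gmap", "panel"))
        g = fam.genotypes_of("A2")
        segs = truffle_segments(g, g, panel)
        kappa = cotterman_from_segments(segs, gmap.total_cm)
        assert kappa.k2 > 0.98
        assert len(segs.by_class("IBD2")) == 4  # one run per chromosome

    def test_error_bridging_tolerance(self):
        """An isolated opposite homozygote inside a long shared run is bridged
        when the density tolerance allows it, splitting the run otherwise."""
        n = 801
        pos = np.linspace(0.0, 16.0, n)
        panel = _make_panel(pos, np.full(n, 0.5))
        a = np.ones(n, dtype=np.int8)
        b = np.zeros(n, dtype=np.int8)  # compatible but never identical
        a[400] = 2  # one opposite-homozygote (switch error) mid-run
        tol = EstimatorConfig(truffle_error_tolerance=1 / 100)
        no_tol = EstimatorConfig(truffle_error_tolerance=0.0)
        bridged = truffle_segments(a, b, panel, tol)
        split = truffle_segments(a, b, panel, no_tol)
        assert len(bridged.by_class("IBD1")) == 1
        assert bridged.by_class("IBD1")[0].n_markers == n
        assert len(split.by_class("IBD1")) == 2


class TestGermline:
    def test_parent_offspring_full_coverage(self, small_family):
        fam, gmap, panel = (small_family[k] for k in ("family", "gmap", "panel"))
        segs = germline_segments(
            *fam.haplotypes_of("F1"), *fam.haplotypes_of("A1"), panel
        )
        assert segs.l_ibd1 + segs.l_ibd2 >= 0.99 * gmap.total_cm

    def test_unrelated_rarely_yield_segments(self):
        """Independent founders at 10K markers: chance matches almost never
        survive the word seed plus the 3 cM minimum."""
        gmap = fk.generate_map(22, 200.0, 1e6)
        hits = 0
        for seed in range(20):
            panel, haps = fk.generate_founders(2, 10_000, gmap, seed=seed)
            segs = germline_segments(*haps.alleles[:4], panel=panel)
            hits += bool(len(segs))
        assert hits <= 1  # no segments in >= 95% of runs

    def test_unphased_input_rejected(self):
        panel = _make_panel([0.0, 1.0], [0.3, 0.3])
        bad = np.array([0, 2])
        with pytest.raises(ValueError):
            germline_segments(bad, bad, bad, bad, panel)


# -------------------------------------------------------- theta conversion --


class TestThetaConversion:
    def _seg(self, cls, start, end, chrom=1):
        return IBDSegment(chrom, start * 1e6, end * 1e6, start, end, cls, 10)

    def test_cotterman_printed_formulas(self):
        half = SegmentSet([self._seg("IBD1", 0.0, 1673.15)])
        k = cotterman_from_segments(half, 3346.30)
        assert k.k1 == pytest.approx(0.5)
        empty = cotterman_from_segments(SegmentSet(), 3346.30)
        assert (empty.k0, empty.k1, empty.k2) == (1.0, 0.0, 0.0)
        full2 = cotterman_from_segments(
            SegmentSet([self._seg("IBD2", 0.0, 3346.30)]), 3346.30
        )
        assert (full2.k0, full2.k1, full2.k2) == pytest.approx((0.0, 0.0, 1.0))

    def test_theta_formula_values(self):
        assert theta_from_kappa(fk.CottermanCoeffs(0, 0, 1)) == 0.5
        assert theta_from_kappa(fk.CottermanCoeffs(0, 1, 0)) == 0.25
        assert theta_from_kappa(fk.CottermanCoeffs(1, 0, 0)) == 0.0

    def test_ibis_constant(self):
        assert ibis_theta(SegmentSet(), 3346.30) == pytest.approx(0.00138)
        full1 = SegmentSet([self._seg("IBD1", 0.0, 3346.30)])
        assert ibis_theta(full1, 3346.30) == pytest.approx(0.25 + 0.00138)

    def test_theta_monotone_in_added_segments(self):
        base = SegmentSet([self._seg("IBD1", 0.0, 100.0)])
        more = SegmentSet(base.segments + [self._seg("IBD1", 200.0, 250.0, chrom=2)])
        for fn in (truffle_theta, lambda s, l: ibis_theta(s, l)):
            assert fn(more, 3346.30) > fn(base, 3346.30)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            cotterman_from_segments(SegmentSet(), 0.0)


# ------------------------------------------------------ oracle equivalence --


class TestOracleEquivalence:
    """Each detector matches an independent quadratic reference scanner on
    randomized instances of <= 1000 markers (with planted sharing)."""

    N_INSTANCES = 70

    def test_ibis_matches_naive(self):
        rng = np.random.default_rng(101)
        for i in range(self.N_INSTANCES):
            n = int(rng.integers(50, 1000))
            panel, _, ga, gb = _random_instance(rng, n, missing_rate=0.02)
            cfg = EstimatorConfig(
                ibis_min_markers=int(rng.integers(3, 30)),
                ibis_min_cm=float(rng.uniform(0.2, 1.5)),
                ibis_emit_ibd2=bool(rng.integers(0, 2)),
            )
            got = _segset_tuples(ibis_segments(ga, gb, panel, cfg))
            assert got == naive_ibis(ga, gb, panel, cfg), f"instance {i}"

    def test_truffle_matches_naive(self):
        rng = np.random.default_rng(202)
        for i in range(self.N_INSTANCES):
            n = int(rng.integers(50, 1000))
            panel, _, ga, gb = _random_instance(rng, n, missing_rate=0.02)
            cfg = EstimatorConfig(
                truffle_log10_pmatch=float(rng.uniform(-10, -2)),
                truffle_min_mb_ibd1=float(rng.uniform(0.2, 1.5)),
                truffle_min_mb_ibd2=float(rng.uniform(0.1, 1.0)),
                truffle_error_tolerance=0.0,
            )
            got = _segset_tuples(truffle_segments(ga, gb, panel, cfg))
            assert got == naive_truffle(ga, gb, panel, cfg), f"instance {i}"

    def test_germline_matches_naive(self):
        rng = np.random.default_rng(303)
        for i in range(self.N_INSTANCES):
            n = int(rng.integers(50, 1000))
            panel, A, _, _ = _random_instance(rng, n)
            cfg = EstimatorConfig(
                germline_word_size=int(rng.integers(4, 17)),
                germline_min_cm=float(rng.uniform(0.3, 1.5)),
            )
            got = _segset_tuples(germline_segments(*A[:4], panel=panel, cfg=cfg))
            assert got == naive_germline(*A[:4], panel=panel, cfg=cfg), f"instance {i}"


# ----------------------------------------------------------- estimate_all ---


class TestEstimateAll:
    def test_self_pair_all_half(self, small_family):
        fam, gmap, panel = (small_family[k] for k in ("family", "gmap", "panel"))
        g = fam.genotypes_of("B2")
        h = fam.haplotypes_of("B2")
        est = estimate_all(g, g, panel, gmap.total_cm, h, h)
        assert est.theta_king == pytest.approx(0.5)
        assert est.theta_ibis == pytest.approx(0.5 + 0.00138, abs=0.01)
        assert est.theta_truffle == pytest.approx(0.5, abs=0.01)
        assert est.theta_germline == pytest.approx(0.5, abs=0.01)

    def test_founder_pair_near_zero(self, small_family):
        fam, gmap, panel = (small_family[k] for k in ("family", "gmap", "panel"))
        est = estimate_all(
            fam.genotypes_of("F2"), fam.genotypes_of("F4"), panel, gmap.total_cm,
            fam.haplotypes_of("F2"), fam.haplotypes_of("F4"),
        )
        assert est.theta_truffle == 0.0
        assert est.theta_germline == 0.0
        assert abs(est.theta_king) < 0.02

    def test_deterministic(self, small_family):
        fam, gmap, panel = (small_family[k] for k in ("family", "gmap", "panel"))
        args = (fam.genotypes_of("A1"), fam.genotypes_of("B1"), panel, gmap.total_cm,
                fam.haplotypes_of("A1"), fam.haplotypes_of("B1"))
        assert estimate_all(*args) == estimate_all(*args)
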