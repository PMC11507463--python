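"""Experiment orchestration: cohort building, panel-size and error-rate grids.

The grids mirror the study design: estimate kinship for every designated pair
with all four methods across (a) a ladder of down-sampled panels at a fixed
error rate of zero, and (b) a ladder of injected genotyping-error rates on a
fixed panel, scoring each condition against reference ranges learned on the
error-free/full-panel reference condition.

Desk-scale defaults preserve the study's marker density rather than its
genome size: the minimum adequate panel of the full design is ~49 SNPs/cM
(164K SNPs over 3346.30 cM), so the default cohort places 20K markers on a
400 cM scaled 22-autosome genome (50 SNPs/cM).  ``GridConfig.full_scale``
restores the full genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, MetricsReport, compute_metrics, reference_ranges
from .combine import BUNDLED_MODELS, CombinationModel, build_feature_frame
from .errors import ErrorSpec, classify_discordance, inject_errors_phased
from .estimators import EstimatorConfig, estimate_all
from .genmap import GENOME_LENGTH_CM, generate_map
from .panel import generate_founders
from .simulate import Cohort, run_cohort
from .vcfio import hwe_exact_test, read_map_file, read_vcf

__all__ = ["GridConfig", "build_cohort", "estimate_pairs", "run_panel_grid",
           "run_error_grid", "real_data_entry", "METHODS"]

log = logging.getLogger("figgkin")

METHODS = ["king", "ibis", "truffle", "germline"]


@dataclass(frozen=True)
class GridConfig:
    """Study-design knobs for the simulation grids."""

    n_chrom: int = 22
    total_cm: float = 400.0
    bp_per_cm: float = 1e6
    panel_size: int = 20_000
    n_founders: int = 208
    n_families: int | None = 18
    n_replicates: int = 1
    panel_ladder: tuple[int, ...] | None = None  # default: 11 successive halvings
    error_ladder: tuple[float, ...] = (0.0, 0.001, 0.005, 0.01, 0.05, 0.10)
    error_composition: tuple[float, float, float] | None = None
    seed: int = 0
    estimator_config: EstimatorConfig = field(default_factory=EstimatorConfig)

    def __post_init__(self) -> None:
        if self.panel_ladder is not None:
            if not self.panel_ladder or any(s <= 0 for s in self.panel_ladder):
                raise ValueError("panel ladder must be non-empty and positive")
            if max(self.panel_ladder) > self.panel_size:
                raise ValueError("panel ladder exceeds the generated panel size")
        if not self.error_ladder or any(not 0 <= e <= 1 for e in self.error_ladder):
            raise ValueError("error rates must lie in [0, 1]")

    @property
    def ladder(self) -> tuple[int, ...]:
        if self.panel_ladder is not None:
            return self.panel_ladder
        return tuple(max(1, self.panel_size // 2**i) for i in range(11))

    @classmethod
    def full_scale(cls, **overrides) -> "GridConfig":
        """The full study design: whole-genome map, 164K panel, 10 replicates."""
        base = dict(total_cm=GENOME_LENGTH_CM, panel_size=164_000, n_replicates=10)
        base.update(overrides)
        return cls(**base)


def build_cohort(cfg: GridConfig) -> Cohort:
    """Map + founders + simulated families for one configuration."""
    ss = np.random.SeedSequence(cfg.seed)
    s_founders, s_cohort = ss.spawn(2)
    gmap = generate_map(cfg.n_chrom, cfg.total_cm, cfg.bp_per_cm)
    panel, founders = generate_founders(
        cfg.n_founders, cfg.panel_size, gmap, seed=s_founders
    )
    log.info("cohort: %d founders, %d markers, %.1f cM", cfg.n_founders,
             cfg.panel_size, gmap.total_cm)
    return run_cohort(
        panel, founders, gmap,
        n_replicates=cfg.n_replicates, n_families=cfg.n_families,
        seed=s_cohort.generate_state(1)[0] % (2**31),
    )


def estimate_pairs(
    cohort: Cohort,
    cfg: EstimatorConfig | None = None,
    marker_idx: np.ndarray | None = None,
    error: ErrorSpec | None = None,
    error_uniform_seed: int | None = None,
) -> pd.DataFrame:
    """All four kinship estimates for every designated pair of the cohort.

    ``marker_idx`` restricts estimation to a panel subset; ``error`` injects
    genotyping errors per family first (phase kept consistent).  When
    ``error_uniform_seed`` is set, the per-genotype uniform draws deciding
    which sites are hit are derived from it alone, so hit sets are nested
    across error rates (common random numbers).
    """
    cfg = cfg or EstimatorConfig()
    panel = cohort.panel if marker_idx is None else cohort.panel.take(marker_idx)
    l_genome = cohort.gmap.total_cm
    rows = []
    for fi, (fam_key, fam) in enumerate(cohort.families.items()):
        haps = fam.haplotypes if marker_idx is None else fam.haplotypes[:, marker_idx]
        if error is not None and error.rate > 0:
            spec = ErrorSpec(error.rate, error.composition,
                             seed=(error.seed or 0) * 100_003 + fi)
            uniforms = None
            if error_uniform_seed is not None:
                u_rng = np.random.default_rng(error_uniform_seed * 100_003 + fi)
                uniforms = u_rng.random((len(fam.ids), haps.shape[1]))
            haps, geno = inject_errors_phased(haps, spec, uniforms)
        else:
            geno = (haps[0::2].astype(np.int8) + haps[1::2]).astype(np.int8)
        fam_pairs = cohort.pairs[cohort.pairs["family"] == fam_key]
        for _, pr in fam_pairs.iterrows():
            ia, ib = fam.index_of(pr.id_a), fam.index_of(pr.id_b)
            est = estimate_all(
                geno[ia], geno[ib], panel, l_genome,
                haps_a=(haps[2 * ia], haps[2 * ia + 1]),
                haps_b=(haps[2 * ib], haps[2 * ib + 1]),
                cfg=cfg, id_a=pr.id_a, id_b=pr.id_b,
            )
            rows.append({
                "family": fam_key, "id_a": pr.id_a, "id_b": pr.id_b,
                "degree": pr.degree, "kinship": pr.kinship, **est.as_dict(),
            })
    return pd.DataFrame(rows)


def _long(estimates: pd.DataFrame, methods=METHODS) -> pd.DataFrame:
    long = estimates.melt(
        id_vars=["degree"],
        value_vars=[f"theta_{m}" for m in methods],
        var_name="method", value_name="theta",
    )
    long["method"] = long["method"].str.removeprefix("theta_")
    return long


def _score(estimates: pd.DataFrame, method: str, ranges, clf_cfg) -> MetricsReport:
    return compute_metrics(
        estimates[f"theta_{method}"].to_numpy(),
        estimates["degree"].to_numpy(),
        ranges=ranges, cfg=clf_cfg, method=method,
    )


def run_panel_grid(
    cfg: GridConfig,
    cohort: Cohort | None = None,
    clf_cfg: ClassifierConfig | None = None,
) -> dict:
    """Estimate/classify/score at every panel-ladder rung, error-free.

    Reference ranges come from the largest rung.  Returns ``{"reports":
    {(method, rung): MetricsReport}, "estimates": {rung: DataFrame},
    "ranges": ...}``.
    """
    cohort = cohort or build_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    ladder = sorted(set(cfg.ladder), reverse=True)
    estimates: dict[int, pd.DataFrame] = {}
    for rung in ladder:
        if rung > len(cohort.panel):
            raise ValueError(f"ladder rung {rung} exceeds panel size {len(cohort.panel)}")
        idx = None
        if rung < len(cohort.panel):
            idx = np.sort(rng.choice(len(cohort.panel), size=rung, replace=False))
        log.info("panel grid: rung %d", rung)
        estimates[rung] = estimate_pairs(cohort, cfg.estimator_config, marker_idx=idx)
    ranges = reference_ranges(_long(estimates[ladder[0]]))
    reports = {
        (m, rung): _score(est, m, ranges, clf_cfg)
        for rung, est in estimates.items()
        for m in METHODS
    }
    return {"reports": reports, "estimates": estimates, "ranges": ranges}


def run_error_grid(
    cfg: GridConfig,
    cohort: Cohort | None = None,
    combo_model: CombinationModel | str | None = "M7",
    clf_cfg: ClassifierConfig | None = None,
) -> dict:
    """Estimate/classify/score at every injected genotyping-error rate.

    The panel is held fixed (the configured minimum panel); reference ranges
    come from the zero-error condition.  ``combo_model`` adds a fifth method
    column evaluated from the 13-feature fusion (a bundled tag like "M7" or a
    fitted :class:`CombinationModel`).
    """
    cohort = cohort or build_cohort(cfg)
    if isinstance(combo_model, str):
        combo_model = BUNDLED_MODELS[combo_model]
    estimates: dict[float, pd.DataFrame] = {}
    for rate in cfg.error_ladder:
        log.info("error grid: rate %.3f", rate)
        est = estimate_pairs(
            cohort, cfg.estimator_config,
            error=ErrorSpec(rate, cfg.error_composition, seed=cfg.seed + 1),
            error_uniform_seed=cfg.seed + 2,
        )
        if combo_model is not None:
            feats = build_feature_frame(est)
            est["theta_combination"] = np.asarray(combo_model.predict(feats))
        estimates[rate] = est
    methods = METHODS + (["combination"] if combo_model is not None else [])
    base = min(estimates)
    ranges = reference_ranges(_long(estimates[base], methods))
    reports = {
        (m, rate): _score(est, m, ranges, clf_cfg)
        for rate, est in estimates.items()
        for m in methods
    }
    return {"reports": reports, "estimates": estimates, "ranges": ranges,
            "combo_model": combo_model}


def real_data_entry(
    vcf_ref,
    vcf_query,
    map_file,
    cfg: EstimatorConfig | None = None,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    clf_cfg: ClassifierConfig | None = None,
) -> dict:
    """Kinship inference between reference and query call sets.

    Markers are intersected on (chrom, pos, ref, alt), then filtered to
    biallelic SNPs with MAF > ``maf_min`` and Hardy-Weinberg exact p >
    ``hwe_p_min`` (both computed on the reference samples).  The i-th
    reference sample is paired with the i-th query sample; each pair gets a
    genotype-discordance profile, all four kinship estimates, and a degree
    call per method.
    """
    ref = read_vcf(vcf_ref)
    query = read_vcf(vcf_query)
    if len(ref.samples) != len(query.samples):
        raise ValueError("reference and query VCFs must carry paired samples")
    gmap = read_map_file(map_file)

    key_cols = ["chrom", "pos_bp", "ref", "alt"]
    ref_keys = ref.table.reset_index().rename(columns={"index": "i_ref"})
    q_keys = query.table.reset_index().rename(columns={"index": "i_query"})
    merged = ref_keys.merge(q_keys, on=key_cols, how="inner")
    if merged.empty:
        raise ValueError("no overlapping markers between the two VCFs")
    i_ref = merged["i_ref"].to_numpy()
    i_query = merged["i_query"].to_numpy()

    g_ref = ref.genotypes[:, i_ref]
    g_query = query.genotypes[:, i_query]
    n_samp = g_ref.shape[0]
    n_het = (g_ref == 1).sum(axis=0)
    n_hom0 = (g_ref == 0).sum(axis=0)
    n_hom2 = (g_ref == 2).sum(axis=0)
    called = n_het + n_hom0 + n_hom2
    with np.errstate(invalid="ignore", divide="ignore"):
        af = (n_het + 2 * n_hom2) / (2 * np.maximum(called, 1))
    maf = np.minimum(af, 1 - af)
    hwe_p = np.array([
        hwe_exact_test(int(h), int(a), int(b)) for h, a, b in zip(n_het, n_hom0, n_hom2)
    ])
    keep = (called > 0) & (maf > maf_min) & (hwe_p > hwe_p_min)
    log.info("real-data entry: %d shared markers, %d pass filters", len(merged),
             int(keep.sum()))

    sub = merged.loc[keep, key_cols].reset_index(drop=True)
    panel_vcf_like = ref.__class__(sub, ref.samples, g_ref[:, keep], None)
    panel = panel_vcf_like.to_panel(gmap)
    g_ref, g_query = g_ref[:, keep], g_query[:, keep]
    h_ref = ref.haplotypes[:, i_ref][:, keep] if ref.haplotypes is not None else None
    h_query = query.haplotypes[:, i_query][:, keep] if query.haplotypes is not None else None

    from .classify import UNDEFINED, classify_degree

    results = []
    profiles = {}
    for i in range(n_samp):
        prof = classify_discordance(g_ref[i], g_query[i])
        profiles[(ref.samples[i], query.samples[i])] = prof
        est = estimate_all(
            g_ref[i], g_query[i], panel, gmap.total_cm,
            haps_a=(h_ref[2 * i], h_ref[2 * i + 1]) if h_ref is not None else None,
            haps_b=(h_query[2 * i], h_query[2 * i + 1]) if h_query is not None else None,
            cfg=cfg, id_a=ref.samples[i], id_b=query.samples[i],
        )
        row = {"id_a": ref.samples[i], "id_b": query.samples[i],
               "error_rate": prof.overall_rate, **est.as_dict()}
        for m, theta in est.as_dict().items():
            label = UNDEFINED if not np.isfinite(theta) else classify_degree(theta, clf_cfg)
            row[m.replace("theta_", "degree_")] = label
        results.append(row)
    return {"panel": panel, "profiles": profiles,
            "estimates": pd.DataFrame(results)}
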