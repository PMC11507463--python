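"""Gamete-dropping pedigree simulation with full founder-ancestry tracking.

Each non-founder haplotype is a recombinant mosaic of its parent's two
haplotypes: the crossover count per chromosome is Poisson(length_cM / 100)
(no interference, sex-averaged map) with breakpoints uniform in genetic
position.  Ancestry is tracked as piecewise-constant founder-haplotype label
tracks, so true IBD between any two simulated individuals is available exactly
— the ground truth the segment detectors are validated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .panel import HaplotypeSet, MarkerPanel
from .pedigree import Pedigree, template_pedigree
from .segments import IBDSegment, SegmentSet

__all__ = [
    "Track",
    "InheritanceRecord",
    "FamilyData",
    "Cohort",
    "simulate_family",
    "run_cohort",
    "true_ibd_segments",
]

# A label track is (breaks, labels): breaks[i] is the cM start of the i-th
# segment, breaks[0] == 0, labels[i] is a global founder-haplotype row index.
Track = tuple[np.ndarray, np.ndarray]


@dataclass
class InheritanceRecord:
    """Per individual, per haplotype, per chromosome: founder-ancestry tracks."""

    tracks: dict[str, tuple[list[Track], list[Track]]]

    def of(self, individual: str) -> tuple[list[Track], list[Track]]:
        return self.tracks[individual]


@dataclass
class FamilyData:
    """One simulated family: members, genotypes, phased haplotypes, ancestry."""

    ids: list[str]
    haplotypes: np.ndarray  # (2*n, m) uint8, member order as in ids
    genotypes: np.ndarray  # (n, m) int8 alt-dosage
    record: InheritanceRecord
    founder_assignment: dict[str, int]  # pedigree founder slot -> founder pool index

    def index_of(self, individual: str) -> int:
        return self.ids.index(individual)

    def genotypes_of(self, individual: str) -> np.ndarray:
        return self.genotypes[self.index_of(individual)]

    def haplotypes_of(self, individual: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.index_of(individual)
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]


@dataclass
class Cohort:
    """A collection of simulated families with their labeled evaluation pairs."""

    pairs: pd.DataFrame  # columns: family, id_a, id_b, degree, kinship
    families: dict[str, FamilyData]
    panel: MarkerPanel
    gmap: GeneticMap
    pedigree: Pedigree

    @property
    def n_families(self) -> int:
        return len(self.families)


def _slice_track(breaks: np.ndarray, labels: np.ndarray, lo: float, hi: float):
    i = int(np.searchsorted(breaks, lo, side="right")) - 1
    j = int(np.searchsorted(breaks, hi, side="left"))
    return [lo, *breaks[i + 1 : j]], list(labels[i:j])


def _merge_adjacent(breaks: list[float], labels: list[int]) -> Track:
    out_b, out_l = [breaks[0]], [labels[0]]
    for b, l in zip(breaks[1:], labels[1:]):
        if l == out_l[-1]:
            continue
        out_b.append(b)
        out_l.append(l)
    return np.asarray(out_b), np.asarray(out_l)


def _gamete(parent: tuple[list[Track], list[Track]], gmap: GeneticMap,
            rng: np.random.Generator) -> list[Track]:
    """One meiosis: recombine the parent's two label tracks on every chromosome."""
    child_tracks: list[Track] = []
    for ci, chrom in enumerate(gmap.chrom_ids):
        length = gmap.chrom_length_cm(chrom)
        n_xo = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(0.0, length, n_xo))
        cur = int(rng.integers(2))
        bounds = [0.0, *cuts, length]
        breaks: list[float] = []
        labels: list[int] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:  # coincident cuts
                cur ^= 1
                continue
            b, l = _slice_track(*parent[cur][ci], lo, hi)
            breaks.extend(b)
            labels.extend(l)
            cur ^= 1
        child_tracks.append(_merge_adjacent(breaks, labels))
    return child_tracks


def _founder_tracks(hap_row: int, gmap: GeneticMap) -> list[Track]:
    return [
        (np.array([0.0]), np.array([hap_row], dtype=np.int64)) for _ in gmap.chrom_ids
    ]


def _realize_alleles(tracks: list[Track], panel: MarkerPanel,
                     founder_alleles: np.ndarray) -> np.ndarray:
    out = np.empty(len(panel), dtype=np.uint8)
    for ci, (chrom, sl) in enumerate(panel.chrom_slices()):
        breaks, labels = tracks[ci]
        idx = np.searchsorted(breaks, panel.pos_cm[sl], side="right") - 1
        cols = np.arange(sl.start, sl.stop)
        out[sl] = founder_alleles[labels[idx], cols]
    return out


def simulate_family(
    ped: Pedigree,
    panel: MarkerPanel,
    founder_haps: HaplotypeSet,
    gmap: GeneticMap,
    seed: int | np.random.SeedSequence | None = None,
    founder_assignment: dict[str, int] | None = None,
) -> FamilyData:
    """Drop gametes through one pedigree and realize genotypes on the panel.

    ``founder_assignment`` maps each pedigree founder slot to an individual
    index in the founder pool; by default the first founders in the pool fill
    the slots in template order.
    """
    rng = np.random.default_rng(seed)
    slots = ped.founders
    if founder_assignment is None:
        if founder_haps.n_individuals < len(slots):
            raise ValueError(
                f"founder pool exhausted: need {len(slots)}, have {founder_haps.n_individuals}"
            )
        founder_assignment = {s: i for i, s in enumerate(slots)}

    tracks: dict[str, tuple[list[Track], list[Track]]] = {}
    for slot, row in founder_assignment.items():
        tracks[slot] = (
            _founder_tracks(2 * row, gmap),
            _founder_tracks(2 * row + 1, gmap),
        )

    order = sorted(ped.nodes, key=lambda n: ped._depth[n])
    for nid in order:
        node = ped.nodes[nid]
        if node.is_founder:
            continue
        tracks[nid] = (
            _gamete(tracks[node.father], gmap, rng),
            _gamete(tracks[node.mother], gmap, rng),
        )

    record = InheritanceRecord(tracks)
    ids = list(order)
    haps = np.empty((2 * len(ids), len(panel)), dtype=np.uint8)
    for i, nid in enumerate(ids):
        for h in (0, 1):
            haps[2 * i + h] = _realize_alleles(tracks[nid][h], panel, founder_haps.alleles)
    genotypes = (haps[0::2].astype(np.int8) + haps[1::2]).astype(np.int8)
    return FamilyData(ids, haps, genotypes, record, founder_assignment)


def run_cohort(
    panel: MarkerPanel,
    founder_haps: HaplotypeSet,
    gmap: GeneticMap,
    ped: Pedigree | None = None,
    n_replicates: int = 1,
    n_families: int | None = None,
    seed: int | None = None,
) -> Cohort:
    """Simulate the full family design: founders are recycled across replicates.

    Per replicate, ``floor(pool_size / n_founder_slots)`` families are built
    from disjoint founder subsets (capped at ``n_families`` if given), so a
    208-individual pool yields 18 families per replicate and 180 families over
    ten replicates.
    """
    ped = ped or template_pedigree()
    slots = ped.founders
    if founder_haps.n_individuals < len(slots):
        raise ValueError("founder pool smaller than the pedigree's founder slots")
    per_rep = founder_haps.n_individuals // len(slots)
    if n_families is not None:
        per_rep = min(per_rep, n_families)

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_replicates)
    families: dict[str, FamilyData] = {}
    pair_rows = []
    labels = ped.pair_labels()
    for r, rep_seed in enumerate(rep_seeds):
        rep_rng = np.random.default_rng(rep_seed)
        perm = rep_rng.permutation(founder_haps.n_individuals)
        fam_seeds = rep_seed.spawn(per_rep)
        for f in range(per_rep):
            key = f"r{r}f{f}"
            assignment = {
                s: int(perm[f * len(slots) + k]) for k, s in enumerate(slots)
            }
            families[key] = simulate_family(
                ped, panel, founder_haps, gmap, fam_seeds[f], assignment
            )
            for pl in labels:
                pair_rows.append(
                    (key, pl.id_a, pl.id_b, pl.degree, float(pl.kinship))
                )
    pairs = pd.DataFrame(
        pair_rows, columns=["family", "id_a", "id_b", "degree", "kinship"]
    )
    return Cohort(pairs, families, panel, gmap, ped)


def true_ibd_segments(
    record: InheritanceRecord,
    a: str,
    b: str,
    gmap: GeneticMap,
    panel: MarkerPanel | None = None,
) -> SegmentSet:
    """Exact IBD1/IBD2 intervals between two simulated individuals.

    IBD2 covers intervals where the two founder-haplotype labels of ``a`` pair
    off exactly with the two labels of ``b``; IBD1 covers intervals with
    exactly one shared label.  IBD2 regions are not double-counted as IBD1.
    """
    ta, tb = record.of(a), record.of(b)
    segs: list[IBDSegment] = []
    for ci, chrom in enumerate(gmap.chrom_ids):
        length = gmap.chrom_length_cm(chrom)
        all_tracks = [ta[0][ci], ta[1][ci], tb[0][ci], tb[1][ci]]
        bounds = np.unique(np.concatenate([t[0] for t in all_tracks] + [np.array([length])]))
        # label of each track on each elementary interval
        labs = np.stack(
            [
                t[1][np.searchsorted(t[0], bounds[:-1], side="right") - 1]
                for t in all_tracks
            ]
        )
        la0, la1, lb0, lb1 = labs
        ibd2 = ((la0 == lb0) & (la1 == lb1)) | ((la0 == lb1) & (la1 == lb0))
        any_share = (
            (la0 == lb0) | (la0 == lb1) | (la1 == lb0) | (la1 == lb1)
        )
        cls = np.where(ibd2, 2, np.where(any_share, 1, 0))
        # merge adjacent intervals of equal class
        change = np.flatnonzero(np.diff(cls) != 0) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(cls)]])
        for s, e in zip(starts, ends):
            if cls[s] == 0:
                continue
            lo, hi = float(bounds[s]), float(bounds[e])
            if hi <= lo:
                continue
            n_mark = 0
            if panel is not None:
                pc = panel.pos_cm[panel.chrom == chrom]
                n_mark = int(np.searchsorted(pc, hi) - np.searchsorted(pc, lo))
            segs.append(
                IBDSegment(
                    chrom=chrom,
                    start_bp=float(gmap.cm_to_bp(chrom, lo)),
                    end_bp=float(gmap.cm_to_bp(chrom, hi)),
                    start_cm=lo,
                    end_cm=hi,
                    ibd_class="IBD2" if cls[s] == 2 else "IBD1",
                    n_markers=n_mark,
                )
            )
    return SegmentSet(segs)
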