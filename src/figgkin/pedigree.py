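"""Pedigree template, exact kinship, and relationship-degree labels.

The family template is a fixed 11-founder, multi-generation pedigree combining
lineal relatives with full and half collateral branches.  Its 30 designated
pairs cover first- through seventh-degree relationships plus unrelated pairs
with per-degree counts (3, 5, 6, 4, 4, 3, 2) and 3 unrelated — i.e. one
family's share of the 180-family study design totals
(540, 900, 1080, 720, 720, 540, 360, 540).

Kinship is computed exactly (rational arithmetic) by the standard recursion
phi(x, x) = 1/2 for outbred x and phi(x, y) = [phi(father(x), y) +
phi(mother(x), y)] / 2, recursing on the generationally deeper node; founders
are pairwise unrelated.  For outbred degree-d relatives phi = 1/2^(d+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

__all__ = [
    "Pedigree",
    "PairLabel",
    "template_pedigree",
    "pedigree_kinship",
    "degree_from_kinship",
    "DEGREE_LABELS",
]

#: Classification bins in decreasing-kinship order.
DEGREE_LABELS = ["twin", "1st", "2nd", "3rd", "4th", "5th", "6th", "7th", "unrelated"]

_ORDINAL = {1: "1st", 2: "2nd", 3: "3rd", 4: "4th", 5: "5th", 6: "6th", 7: "7th"}


@dataclass(frozen=True)
class Node:
    id: str
    sex: str  # "M" | "F"
    father: str | None = None
    mother: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class PairLabel:
    """A designated pair with its pedigree-exact kinship and degree label."""

    id_a: str
    id_b: str
    degree: str
    kinship: Fraction


@dataclass
class Pedigree:
    nodes: dict[str, Node]
    designated_pairs: list[tuple[str, str]]
    _depth: dict[str, int] = field(init=False, repr=False)
    _phi_cache: dict[tuple[str, str], Fraction] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for n in self.nodes.values():
            if (n.father is None) != (n.mother is None):
                raise ValueError(f"{n.id}: non-founders need exactly two parents")
            for p in (n.father, n.mother):
                if p is not None and p not in self.nodes:
                    raise KeyError(f"{n.id}: unknown parent {p}")
        self._depth = {}
        self._phi_cache = {}
        for nid in self.nodes:
            self._compute_depth(nid, ())

    def _compute_depth(self, nid: str, stack: tuple) -> int:
        if nid in stack:
            raise ValueError("pedigree contains a cycle")
        if nid not in self._depth:
            n = self.nodes[nid]
            if n.is_founder:
                self._depth[nid] = 0
            else:
                self._depth[nid] = 1 + max(
                    self._compute_depth(n.father, stack + (nid,)),
                    self._compute_depth(n.mother, stack + (nid,)),
                )
        return self._depth[nid]

    @property
    def founders(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if n.is_founder]

    def kinship(self, a: str, b: str) -> Fraction:
        """Exact kinship coefficient phi(a, b)."""
        if a not in self.nodes or b not in self.nodes:
            raise KeyError(f"unknown individual: {a if a not in self.nodes else b}")
        return self._phi(a, b)

    def _phi(self, a: str, b: str) -> Fraction:
        key = (a, b) if a <= b else (b, a)
        if key in self._phi_cache:
            return self._phi_cache[key]
        if a == b:
            # outbred pedigree (enforced by template choice): phi(x,x) = 1/2
            phi = Fraction(1, 2)
        else:
            # recurse on the deeper node; it cannot be an ancestor of the other
            x, y = (a, b) if self._depth[a] >= self._depth[b] else (b, a)
            nx = self.nodes[x]
            if nx.is_founder:
                phi = Fraction(0)
            else:
                phi = (self._phi(nx.father, y) + self._phi(nx.mother, y)) / 2
        self._phi_cache[key] = phi
        return phi

    def pair_labels(self) -> list[PairLabel]:
        out = []
        for a, b in self.designated_pairs:
            phi = self.kinship(a, b)
            out.append(PairLabel(a, b, degree_from_kinship(phi), phi))
        return out


def pedigree_kinship(ped: Pedigree, a: str, b: str) -> Fraction:
    return ped.kinship(a, b)


def degree_from_kinship(phi: Fraction | float) -> str:
    """Map a pedigree-exact kinship value to its relationship-degree label.

    Admissible values are 1/2 (twin/same individual), 1/2^(d+1) for degrees
    d = 1..7, and 0 (unrelated); anything else (e.g. inbred values) is
    rejected.
    """
    phi = Fraction(phi).limit_denominator(1 << 20) if not isinstance(phi, Fraction) else phi
    if phi == 0:
        return "unrelated"
    if phi == Fraction(1, 2):
        return "twin"
    for d in range(1, 8):
        if phi == Fraction(1, 2 ** (d + 1)):
            return _ORDINAL[d]
    raise ValueError(f"kinship {phi} is not an admissible outbred pedigree value")


def template_pedigree() -> Pedigree:
    """The fixed 11-founder family template with its 30 designated pairs.

    Structure: founding couple F1 x F2 with full-sib children A1 and B1; F1's
    second spouse F3 gives the half-sib H1.  Each of A, B descends four
    generations and H three, with a married-in founder spouse per generation
    (F4..F11).  Pairs across the A/B lines are full collateral (sibs, first,
    second, third cousins and removed variants); pairs into the H line are
    half collateral; pairs within a line and from F1 are lineal.
    """
    nodes: dict[str, Node] = {}

    def founder(nid: str, sex: str) -> None:
        nodes[nid] = Node(nid, sex)

    def child(nid: str, sex: str, father: str, mother: str) -> None:
        nodes[nid] = Node(nid, sex, father, mother)

    for nid in ("F1", "F6"):
        founder(nid, "M")
    for nid in ("F2", "F3", "F4", "F5", "F7", "F8", "F9", "F10", "F11"):
        founder(nid, "F")

    # full-sib line A: A1 (gen 1) .. A4 (gen 4)
    child("A1", "M", "F1", "F2")
    child("A2", "M", "A1", "F4")
    child("A3", "F", "A2", "F5")
    child("A4", "M", "F6", "A3")
    # full-sib line B
    child("B1", "M", "F1", "F2")
    child("B2", "M", "B1", "F7")
    child("B3", "M", "B2", "F8")
    child("B4", "M", "B3", "F9")
    # half-sib line H (through F1's second spouse)
    child("H1", "M", "F1", "F3")
    child("H2", "M", "H1", "F10")
    child("H3", "M", "H2", "F11")

    pairs = [
        # 1st degree (3): full sibs, parent-offspring x2
        ("A1", "B1"), ("F1", "A1"), ("A3", "A4"),
        # 2nd degree (5): half sibs x2, avuncular, grandparental x2
        ("A1", "H1"), ("B1", "H1"), ("A1", "B2"), ("F1", "A2"), ("F1", "B2"),
        # 3rd degree (6): first cousins, grand-avuncular x2, great-grandparental x3
        ("A2", "B2"), ("A1", "B3"), ("B1", "A3"), ("F1", "A3"), ("F1", "B3"), ("A1", "A4"),
        # 4th degree (4)
        ("A2", "B3"), ("A3", "B2"), ("F1", "A4"), ("A1", "H3"),
        # 5th degree (4): second cousins and removed variants
        ("A3", "B3"), ("A2", "B4"), ("A4", "B2"), ("A4", "H1"),
        # 6th degree (3)
        ("A3", "B4"), ("A4", "B3"), ("A4", "H2"),
        # 7th degree (2): third cousins (full and half)
        ("A4", "B4"), ("A4", "H3"),
        # unrelated (3): married-in founders vs the other lines
        ("F2", "H1"), ("F4", "F7"), ("F5", "B4"),
    ]
    return Pedigree(nodes=nodes, designated_pairs=pairs)
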