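"""Gene order, rearrangement detection, spacer/overlap accounting and
control-region repeat structure.

Rearrangement is quantified with a circular, strand-aware breakpoint metric:
the number of gene adjacencies present in the query order but absent from
the reference order.  This identifies rearranged blocks (the quantity of
interest for mitogenome architecture comparisons) without committing to any
particular rearrangement scenario or distance model.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .mito_io import (CANONICAL_GENES, GeneFeature, Mitogenome,
                      ancestral_insect_order)

SignedGene = tuple[str, str, int]  # (name, strand, copy_index)


@dataclass
class GeneOrder:
    """Circular, signed gene order of one genome, rotated to an anchor gene."""

    taxon: str
    order: list[SignedGene]
    anchor: str

    def names(self) -> list[str]:
        return [g[0] for g in self.order]


@dataclass
class RearrangementReport:
    breakpoints: int
    moved_genes: set[str]
    duplicated: list[tuple[str, int]]
    missing_genes: set[str]
    extra_genes: set[str]


@dataclass
class Boundary:
    left: str
    right: str
    gap: int  # >=1 spacer, 0 abutting, <0 overlap of |gap| bp


@dataclass
class SpacerOverlapReport:
    boundaries: list[Boundary]
    spacer_count: int
    spacer_bp: int
    overlap_count: int
    overlap_bp: int
    contained: list[tuple[str, str]] = field(default_factory=list)  # (inner, outer)
    cr_length: int | None = None

    @property
    def longest_spacer(self) -> int:
        return max((b.gap for b in self.boundaries if b.gap > 0), default=0)


@dataclass
class RepeatReport:
    """A tandem repeat array: ``copies`` repeats of ``unit`` over ``span``.

    ``unit`` is the per-position consensus over the copies, with an IUPAC
    degeneracy code at positions where the copies vary (at most
    ``variable_positions`` such positions were allowed during detection).
    """

    unit: str
    copies: int
    span: tuple[int, int]
    variable_positions: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Gene order and rearrangement
# ---------------------------------------------------------------------------

def gene_order(genome: Mitogenome, anchor: str = "trnI",
               include_cr: bool = False) -> GeneOrder:
    """Signed circular gene order, rotated so the anchor gene comes first.

    Default anchor trnI matches the conventional insect mitogenome
    linearization; if absent, the first feature is used with a warning.
    """
    feats = [f for f in genome.features
             if include_cr or f.ftype != "control_region"]
    if not feats:
        raise ValueError(f"{genome.id}: no features to order")
    order = [(f.name, f.strand, f.copy_index) for f in feats]
    names = [g[0] for g in order]
    if anchor in names:
        i = names.index(anchor)
    else:
        warnings.warn(f"{genome.id}: anchor {anchor!r} absent; rotating to first feature")
        i = 0
    return GeneOrder(genome.id, order[i:] + order[:i], order[i][0])


def reference_order(name: str = "ancestral") -> GeneOrder:
    """A shipped reference order; currently the putative ancestral arthropod
    arrangement (control region excluded)."""
    if name != "ancestral":
        raise ValueError(f"unknown reference order {name!r}")
    rows = [(n, s, 1) for n, ftype, s in ancestral_insect_order()
            if ftype != "control_region"]
    return GeneOrder("ancestral", rows, rows[0][0])


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _canonical_adjacency(a: SignedGene, b: SignedGene) -> tuple:
    """Strand-aware canonical form of the circular adjacency a->b.

    Reading the circle on the opposite strand turns a->b into
    rev(b)->rev(a); both readings denote the same physical junction, so the
    lexicographically smaller is used.  Copy indices are ignored (copies
    of a gene are interchangeable context-wise)."""
    fwd = ((a[0], a[1]), (b[0], b[1]))
    rev = ((b[0], _flip(b[1])), (a[0], _flip(a[1])))
    return min(fwd, rev)


def _adjacency_multiset(order: GeneOrder) -> Counter:
    n = len(order.order)
    return Counter(_canonical_adjacency(order.order[i], order.order[(i + 1) % n])
                   for i in range(n))


def compare_orders(query: GeneOrder, reference: GeneOrder) -> RearrangementReport:
    """Breakpoint comparison of two circular signed gene orders.

    Breakpoints = adjacencies (as a multiset, so duplicated genes are matched
    greedily by their surrounding context) present in the query but absent
    from the reference.  Moved genes are those flanking disrupted
    adjacencies; gene content differences vs the 37-gene canon are reported
    separately.
    """
    if not query.order or not reference.order:
        raise ValueError("orders must be non-empty")
    q_adj = _adjacency_multiset(query)
    r_adj = _adjacency_multiset(reference)
    disrupted = q_adj - r_adj
    breakpoints = sum(disrupted.values())
    moved = set()
    for (left, right), _ in disrupted.items():
        moved.add(left[0])
        moved.add(right[0])
    copies = Counter(g[0] for g in query.order)
    duplicated = sorted((name, k) for name, k in copies.items() if k > 1)
    canon = set(CANONICAL_GENES)
    present = set(copies)
    return RearrangementReport(
        breakpoints=breakpoints,
        moved_genes=moved,
        duplicated=duplicated,
        missing_genes=canon - present,
        extra_genes=present - canon,
    )


# ---------------------------------------------------------------------------
# Spacers and overlaps
# ---------------------------------------------------------------------------

def _contains(outer: GeneFeature, inner: GeneFeature, length: int) -> bool:
    """Containment on the circle, honoring the end>length wrap encoding."""
    for shift in (0, length):
        if (outer.start <= inner.start + shift
                and inner.end + shift <= outer.end):
            return True
    return False


def spacers_overlaps(genome: Mitogenome, include_cr: bool = False) -> SpacerOverlapReport:
    """Gap/overlap at every boundary between consecutive features on the circle.

    gap = next.start - prev.end on the linearized J-strand (the wrap
    boundary closes the circle).  Positive gaps are intergenic spacers,
    negative gaps are overlaps, 0 means abutting.  Features nested inside
    another feature are excluded from the boundary walk and listed
    separately; the control region is excluded by default and reported as
    its length only.
    """
    L = genome.length
    feats = list(genome.features)
    cr_length = None
    if not include_cr:
        crs = [f for f in feats if f.ftype == "control_region"]
        if crs:
            cr_length = sum(f.length for f in crs)
        feats = [f for f in feats if f.ftype != "control_region"]
    contained = []
    kept = []
    for f in feats:
        outer = next((g for g in feats if g is not f and _contains(g, f, L)), None)
        if outer is not None:
            contained.append((f.label(), outer.label()))
        else:
            kept.append(f)
    if len(kept) < 2:
        raise ValueError("need at least two non-nested features")
    kept.sort(key=lambda f: (f.start, f.end))
    boundaries = []
    for prev, nxt in zip(kept, kept[1:]):
        boundaries.append(Boundary(prev.label(), nxt.label(), nxt.start - prev.end))
    # wrap boundary: last feature around the origin back to the first
    last, first = kept[-1], kept[0]
    boundaries.append(Boundary(last.label(), first.label(),
                               first.start + L - last.end))
    spacers = [b.gap for b in boundaries if b.gap >= 1]
    overlaps = [-b.gap for b in boundaries if b.gap < 0]
    return SpacerOverlapReport(
        boundaries=boundaries,
        spacer_count=len(spacers), spacer_bp=sum(spacers),
        overlap_count=len(overlaps), overlap_bp=sum(overlaps),
        contained=contained, cr_length=cr_length)


# ---------------------------------------------------------------------------
# Tandem repeats and poly-T
# ---------------------------------------------------------------------------

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

IUPAC_SETS = {code: bases for bases, code in _IUPAC.items()}


def matches_iupac(base: str, code: str) -> bool:
    return base in IUPAC_SETS.get(code, frozenset())


def find_tandem_repeats(region: str, unit_len_range: tuple[int, int] = (5, 50),
                        min_copies: int = 3,
                        max_variable_positions: int = 1) -> list[RepeatReport]:
    """Maximal non-overlapping tandem arrays by exhaustive unit scan.

    For every unit length k in the range and every start, consecutive
    k-blocks are accreted while they differ from the first block at no more
    than ``max_variable_positions`` (cumulative) positions.  Candidate
    arrays with >= min_copies copies are then selected greedily, ties broken
    by (more copies, longer span, leftmost).  Positions where the copies
    vary are reported as an IUPAC consensus in the unit (e.g. R for a G/A
    first base).  O(len(region) x max unit length); exhaustive and
    deterministic, entirely adequate at control-region scale.
    """
    region = region.upper()
    lo, hi = unit_len_range
    candidates = []
    for k in range(max(1, lo), hi + 1):
        i = 0
        while i + k * min_copies <= len(region):
            unit0 = region[i:i + k]
            variable: set[int] = set()
            copies = 1
            while True:
                j = i + copies * k
                block = region[j:j + k]
                if len(block) < k:
                    break
                diff = {p for p in range(k) if block[p] != unit0[p]}
                if len(variable | diff) > max_variable_positions:
                    break
                variable |= diff
                copies += 1
            if copies >= min_copies:
                candidates.append((copies, copies * k, i, k))
                i += copies * k  # further starts inside this array are sub-arrays
            else:
                i += 1
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    chosen: list[RepeatReport] = []
    taken: list[tuple[int, int]] = []
    for copies, span_len, start, k in candidates:
        end = start + span_len
        if any(not (end <= s or start >= e) for s, e in taken):
            continue
        blocks = [region[start + c * k: start + (c + 1) * k] for c in range(copies)]
        unit = "".join(
            _IUPAC[frozenset(b[p] for b in blocks)] for p in range(k))
        var = tuple(p for p in range(k) if len({b[p] for b in blocks}) > 1)
        chosen.append(RepeatReport(unit, copies, (start, end), var))
        taken.append((start, end))
    chosen.sort(key=lambda r: r.span[0])
    return chosen


def longest_polyT(region: str) -> tuple[int, int | None]:
    """Length and 0-based start of the longest run of T (leftmost on ties);
    (0, None) when the region contains no T."""
    if not region:
        raise ValueError("empty region")
    region = region.upper()
    best_len, best_start = 0, None
    run_start = None
    for i, b in enumerate(region + "$"):
        if b == "T":
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    return best_len, best_start
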