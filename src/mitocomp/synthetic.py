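"""Synthetic annotated mitogenomes and divergent taxon sets with known truth.

The generator emulates the structures of an insect (delphacid-like)
mitogenome so that every analysis stage can be exercised against planted
ground truth: a ~16 kb circular genome with the 37-gene metazoan canon,
heavy A+T bias, a rearranged gene order (trnC-trnW swap, nad6-trnP-trnT
block, an extra trnC copy), characteristic start/stop codons including
incomplete stops, intergenic spacers and small tRNA overlaps, and a
control region carrying a tandem-repeat array with a degenerate (G/A)
first base plus a long poly-T run.

Divergent taxon sets are produced by codon-level simulation along a guide
tree: single-base changes are proposed uniformly, changes creating stop
codons are rejected, synonymous changes are always accepted and
non-synonymous ones accepted with probability omega — so the realized
dN/dS of a simulated gene is omega by construction, which is the truth the
Ka/Ks estimators are tested against.  No indels are simulated; alignments
come back gap-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

from .codon_usage import BASES, GeneticCode, _dna
from .mito_io import (CANONICAL_GENES, GeneAlignment, GeneFeature, Mitogenome,
                      ancestral_insect_order, revcomp)

_COMP = str.maketrans("ACGT", "TGCA")

#: Default per-gene lengths (bp).  PCG lengths are congruent mod 3 with the
#: default stop policy below: multiples of 3 for complete TAA stops, 3k+1
#: for a trailing incomplete T, 3k+2 for TT.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "atp6": 672, "atp8": 94,
    "nad1": 928, "nad2": 960, "nad3": 352, "nad4": 1338, "nad4l": 288,
    "nad5": 1718, "nad6": 523, "cytb": 1141,
    "rrnS": 750, "rrnL": 1020,
    "trnS1": 57, "trnK": 71, "trnL1": 66, "trnL2": 66,
}
for _aa in ("A", "C", "D", "E", "F", "G", "H", "I", "M", "N", "P", "Q",
            "R", "S2", "T", "V", "W", "Y"):
    DEFAULT_GENE_LENGTHS["trn" + _aa] = 64

#: Start codons observed in the study organism (ATN initiation).
DEFAULT_START_CODONS: dict[str, str] = {
    "nad2": "ATA", "nad3": "ATA", "atp6": "ATA",
    "cox1": "ATG", "cox3": "ATG", "nad5": "ATG", "nad4l": "ATG",
    "cytb": "ATG", "nad1": "ATG",
    "cox2": "ATT", "atp8": "ATT", "nad4": "ATT", "nad6": "ATT",
}

#: Stop policy: complete 'TAA', or incomplete 'T' / 'TT' (polyadenylation-
#: completed); TT in nad5 and T in atp8, nad3, nad6, cytb, nad1.
DEFAULT_STOP_POLICY: dict[str, str] = {
    "cox1": "TAA", "atp6": "TAA", "nad4": "TAA", "nad4l": "TAA",
    "nad2": "TAA", "cox2": "TAA", "cox3": "TAA",
    "nad5": "TT", "atp8": "T", "nad3": "T", "nad6": "T", "cytb": "T",
    "nad1": "T",
}

#: Named spacers mirroring the large intergenic spacers of the study genome.
DEFAULT_NAMED_SPACERS: dict[tuple[str, str], int] = {
    ("nad2", "trnC"): 345,
    ("trnM", "nad2"): 111,
    ("trnH", "nad4"): 128,
    ("trnL1", "rrnL"): 183,
}

#: Small overlaps at tRNA-tRNA boundaries (bp).
DEFAULT_OVERLAPS: dict[tuple[str, str], int] = {
    ("trnA", "trnR"): 3,
    ("trnR", "trnN"): 1,
}

#: 19 bp core following the degenerate (G/A) first base of the control-region
#: repeat unit; the full planted unit is 20 bp.
DEFAULT_REPEAT_CORE = "ATATATATATATAAATATA"


@dataclass
class CRSpec:
    """Control-region blueprint: total length, tandem-repeat array and poly-T."""

    length: int = 1304
    repeat_core: str = DEFAULT_REPEAT_CORE  # unit = (G/A) + core
    repeat_copies: int = 15
    include_repeats: bool = True
    polyt_len: int = 24
    include_polyt: bool = True


@dataclass
class GenomeBlueprint:
    """Everything the genome generator needs; lengths + spacers - overlaps
    determine the genome length."""

    genome_id: str = "synthetic"
    order: str | list[tuple[str, str, str]] = "nlugens-like"  # or 'ancestral'/custom
    gene_lengths: dict[str, int] = field(default_factory=dict)
    base_composition: tuple[float, float, float, float] = (0.426, 0.349, 0.088, 0.137)
    exact_composition: bool = True
    cr: CRSpec = field(default_factory=CRSpec)
    include_cr: bool = True
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_policy: dict[str, str] = field(default_factory=dict)
    spacers: dict[tuple[str, str], int] = field(default_factory=dict)
    overlaps: dict[tuple[str, str], int] = field(default_factory=dict)
    default_spacer_range: tuple[int, int] = (0, 5)
    seed: int = 0


@dataclass
class GenomeTruth:
    """Every planted quantity, for oracle tests against the analyses."""

    base_counts: dict[str, int]
    length: int
    order: list[tuple[str, str, int]]          # (name, strand, copy_index)
    boundary_gaps: list[tuple[str, str, int]]  # (left, right, gap) incl. wrap
    feature_coords: list[tuple[str, int, int, int, str]]  # (name, copy, start, end, strand)
    repeat_span: tuple[int, int] | None
    repeat_unit_len: int | None
    repeat_copies: int | None
    polyt_start: int | None
    polyt_len: int | None
    cr_span: tuple[int, int] | None
    start_codons: dict[str, str]
    stop_codons: dict[str, str]
    seed: int


def nlugens_like_order() -> list[tuple[str, str, str]]:
    """Ancestral order with the study organism's rearrangements applied:
    trnW-trnC swapped to trnC-trnW (with an extra trnC copy) and the
    trnT-trnP-nad6 block reversed to nad6-trnP-trnT."""
    rows = ancestral_insect_order()
    names = [r[0] for r in rows]
    by = {r[0]: r for r in rows}
    iW, iC = names.index("trnW"), names.index("trnC")
    rows[iW], rows[iC] = by["trnC"], by["trnW"]
    rows.insert(names.index("trnW") + 1, by["trnC"])  # extra copy after first
    names = [r[0] for r in rows]
    iT = names.index("trnT")
    assert names[iT:iT + 3] == ["trnT", "trnP", "nad6"]
    rows[iT:iT + 3] = [by["nad6"], by["trnP"], by["trnT"]]
    return rows


def _resolve_order(bp: GenomeBlueprint) -> list[tuple[str, str, str]]:
    if isinstance(bp.order, str):
        if bp.order == "ancestral":
            rows = ancestral_insect_order()
        elif bp.order == "nlugens-like":
            rows = nlugens_like_order()
        else:
            raise ValueError(f"unknown order {bp.order!r}")
    else:
        rows = list(bp.order)
    if not bp.include_cr:
        rows = [r for r in rows if r[1] != "control_region"]
    return rows


def _round_counts(fracs: tuple[float, ...], L: int) -> list[int]:
    raw = [f * L for f in fracs]
    base = [math.floor(x) for x in raw]
    short = L - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def generate_genome(bp: GenomeBlueprint | None = None) -> tuple[Mitogenome, GenomeTruth]:
    """Build an annotated mitogenome with exactly planted structures.

    With ``exact_composition`` the unconstrained positions are filled by
    drawing without replacement from the exact residual base multiset, so
    whole-genome tallies hit the target composition to the base; in-frame
    stop codons arising in PCG bodies are then repaired by tally-preserving
    swaps with non-coding positions.  Deterministic per seed.
    """
    bp = bp or GenomeBlueprint()
    rng = np.random.default_rng(bp.seed)
    code = GeneticCode()
    lengths = {**DEFAULT_GENE_LENGTHS, **bp.gene_lengths}
    starts = {**DEFAULT_START_CODONS, **bp.start_codons}
    stops = {**DEFAULT_STOP_POLICY, **bp.stop_policy}
    order = _resolve_order(bp)

    # --- layout: walk the circle from the linearization origin (trnI) ---
    counts_by_name: dict[str, int] = {}
    feats: list[GeneFeature] = []
    gaps: list[tuple[str, str, int]] = []
    cursor = 0
    named_spacers = {**DEFAULT_NAMED_SPACERS, **bp.spacers}
    overlaps = {**DEFAULT_OVERLAPS, **bp.overlaps}
    prev_name = None
    for name, ftype, strand in order:
        L_f = bp.cr.length if ftype == "control_region" else lengths[name]
        if prev_name is not None:
            key = (prev_name, name)
            if key in overlaps:
                gap = -overlaps[key]
            elif key in named_spacers:
                gap = named_spacers[key]
            else:
                lo, hi = bp.default_spacer_range
                gap = int(rng.integers(lo, hi + 1))
            gaps.append((prev_name, name, gap))
            cursor += gap
        counts_by_name[name] = counts_by_name.get(name, 0) + 1
        feats.append(GeneFeature(name, ftype, cursor, cursor + L_f, strand,
                                 counts_by_name[name]))
        cursor += L_f
        prev_name = name
    wrap_key = (prev_name, order[0][0])
    wrap_gap = named_spacers.get(wrap_key, 0)
    gaps.append((prev_name, order[0][0], wrap_gap))
    L = cursor + wrap_gap

    # --- constrained positions ---
    seq = np.full(L, b"?", dtype="S1")
    fixed = np.zeros(L, dtype=bool)
    pcg_internal = np.zeros(L, dtype=bool)

    def set_bases(pos: int, bases: str) -> None:
        for k, b in enumerate(bases):
            seq[pos + k] = b.encode()
            fixed[pos + k] = True

    truth_starts: dict[str, str] = {}
    truth_stops: dict[str, str] = {}
    for f in feats:
        if f.ftype != "PCG":
            continue
        start_codon = starts[f.name]
        stop = stops[f.name]
        n_stop = len(stop)
        if (f.length - n_stop) % 3 or (n_stop < 3 and (f.length % 3) != n_stop):
            raise ValueError(f"{f.name}: length {f.length} inconsistent with stop {stop!r}")
        truth_starts[f.name] = start_codon
        truth_stops[f.name] = stop
        if f.strand == "+":
            set_bases(f.start, start_codon)
            set_bases(f.end - n_stop, stop)
            pcg_internal[f.start:f.end] = True
        else:
            set_bases(f.end - 3, revcomp(start_codon))
            set_bases(f.start, revcomp(stop))
            pcg_internal[f.start:f.end] = True

    repeat_span = polyt_start = cr_span = None
    cr_feat = next((f for f in feats if f.ftype == "control_region"), None)
    if cr_feat is not None:
        cr_span = (cr_feat.start, cr_feat.end)
        pos = cr_feat.start + 60  # leading filler
        if bp.cr.include_repeats:
            unit_len = 1 + len(bp.cr.repeat_core)
            set_bases(pos, "CGG")  # breaks any accidental extension leftward
            pos += 3
            repeat_span = (pos, pos + bp.cr.repeat_copies * unit_len)
            for c in range(bp.cr.repeat_copies):
                first = "G" if c % 2 == 0 else "A"
                set_bases(pos, first + bp.cr.repeat_core)
                pos += unit_len
            set_bases(pos, "GGC")
            pos += 3
        if bp.cr.include_polyt:
            pos += 40
            set_bases(pos, "A" + "T" * bp.cr.polyt_len + "A")
            polyt_start = pos + 1
            pos += bp.cr.polyt_len + 2
        if pos > cr_feat.end:
            raise ValueError("control region too short for its planted structures")

    # --- fill unconstrained positions ---
    free_idx = np.flatnonzero(~fixed)
    if bp.exact_composition:
        target = _round_counts(bp.base_composition, L)
        have = {b: int(np.count_nonzero(seq == b.encode())) for b in BASES}
        residual = {b: target[i] - have[b] for i, b in enumerate("ATGC")}
        if any(v < 0 for v in residual.values()):
            raise ValueError(f"composition target infeasible: residual {residual}")
        pool = np.array([b.encode() for b in "ATGC" for _ in range(residual[b])])
        assert len(pool) == len(free_idx)
        rng.shuffle(pool)
        seq[free_idx] = pool
    else:
        probs = np.array(bp.base_composition) / sum(bp.base_composition)
        draw = rng.choice(np.array([b"A", b"T", b"G", b"C"]), size=len(free_idx), p=probs)
        seq[free_idx] = draw

    # --- repair in-frame stop codons in PCG bodies (tally-preserving swaps) ---
    pool_arr = np.flatnonzero(~fixed & ~pcg_internal)
    rng.shuffle(pool_arr)
    pool_positions = [int(i) for i in pool_arr]
    pool_cursor = 0

    def swap_in(j_index: int, wanted: set[bytes]) -> None:
        nonlocal pool_cursor
        for k in range(pool_cursor, len(pool_positions)):
            p = pool_positions[k]
            if seq[p] in wanted:
                seq[j_index], seq[p] = seq[p], seq[j_index]
                pool_positions[pool_cursor], pool_positions[k] = \
                    pool_positions[k], pool_positions[pool_cursor]
                pool_cursor += 1
                return
        raise ValueError("cannot repair stop codon under composition constraint")

    for f in feats:
        if f.ftype != "PCG":
            continue
        n_codons = f.length // 3
        for i in range(n_codons):
            if f.strand == "+":
                j0 = f.start + 3 * i
                codon = seq[j0:j0 + 3].tobytes().decode()
            else:
                j_hi = f.end - 1 - 3 * i
                codon = seq[j_hi - 2:j_hi + 1].tobytes().decode()
                codon = codon.translate(_COMP)[::-1]
            if codon not in ("TAA", "TAG"):
                continue
            if fixed[f.start + 3 * i] if f.strand == "+" else fixed[f.end - 1 - 3 * i]:
                continue  # planted stop codon itself
            # change coding position 0 (the T) to a non-T base
            if f.strand == "+":
                j = f.start + 3 * i
                swap_in(j, {b"A", b"C", b"G"})
            else:
                j = f.end - 1 - 3 * i
                swap_in(j, {b"T", b"G", b"C"})  # J-strand complements of A/C/G

    sequence = seq.tobytes().decode()
    genome = Mitogenome(bp.genome_id, sequence, True, feats)
    comp_counts = {b: sequence.count(b) for b in "ATGC"}
    truth = GenomeTruth(
        base_counts=comp_counts, length=L,
        order=[(f.name, f.strand, f.copy_index) for f in feats],
        boundary_gaps=gaps,
        feature_coords=[(f.name, f.copy_index, f.start, f.end, f.strand) for f in feats],
        repeat_span=repeat_span,
        repeat_unit_len=(1 + len(bp.cr.repeat_core)) if repeat_span else None,
        repeat_copies=bp.cr.repeat_copies if repeat_span else None,
        polyt_start=polyt_start,
        polyt_len=bp.cr.polyt_len if polyt_start is not None else None,
        cr_span=cr_span,
        start_codons=truth_starts, stop_codons=truth_stops,
        seed=bp.seed)
    return genome, truth


# ---------------------------------------------------------------------------
# Codon-level divergence simulation
# ---------------------------------------------------------------------------

@dataclass
class DivergenceSpec:
    """Guide tree plus per-gene selection intensity for taxon simulation.

    ``tree`` is Newick with branch lengths in expected substitution
    proposals per nucleotide site; ``omega`` is the acceptance probability
    of non-synonymous proposals (scalar or per-gene), so the realized
    dN/dS truth equals omega.
    """

    tree: str = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);"
    omega: float | Mapping[str, float] = 0.2
    rate: float = 1.0
    seed: int = 0


@dataclass
class EvolveTruth:
    omega: dict[str, float]
    realized_syn: dict[str, int]
    realized_nonsyn: dict[str, int]


def random_cds(n_codons: int, rng: np.random.Generator,
               code: GeneticCode | None = None, start: str = "ATG") -> str:
    """A stop-free in-frame CDS of ``n_codons`` codons (no terminal stop)."""
    code = code or GeneticCode()
    sense = code.sense_codons
    idx = rng.integers(0, len(sense), size=n_codons - 1)
    return start + "".join(sense[i] for i in idx)


def _evolve_branch(cds: list[str], t: float, omega: float, rate: float,
                   rng: np.random.Generator, code: GeneticCode,
                   tally: dict[str, int]) -> list[str]:
    L = len(cds)
    n_prop = rng.poisson(t * rate * L)
    for _ in range(n_prop):
        site = int(rng.integers(0, L))
        old = cds[site]
        alts = [b for b in BASES if b != old]
        new = alts[int(rng.integers(0, 3))]
        ci = site // 3
        within = site % 3
        codon = cds[3 * ci] + cds[3 * ci + 1] + cds[3 * ci + 2]
        new_codon = codon[:within] + new + codon[within + 1:]
        if code.is_stop(new_codon):
            continue
        if code.aa(new_codon) == code.aa(codon):
            tally["syn"] += 1
        else:
            if rng.random() >= omega:
                continue
            tally["nonsyn"] += 1
        cds[site] = new
    return cds


def evolve_taxa(root_genes: Mapping[str, str], spec: DivergenceSpec | None = None
                ) -> tuple[dict[str, GeneAlignment], EvolveTruth]:
    """Simulate gap-free per-gene codon alignments along the guide tree.

    Root sequences must be in-frame, stop-free CDS (any trailing incomplete
    stop should be stripped first).  Deterministic per spec.seed.
    """
    spec = spec or DivergenceSpec()
    code = GeneticCode()
    rng = np.random.default_rng(spec.seed)
    tree = dendropy.Tree.get(data=spec.tree, schema="newick")
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    alignments: dict[str, GeneAlignment] = {}
    omega_map: dict[str, float] = {}
    syn_tally: dict[str, int] = {}
    nonsyn_tally: dict[str, int] = {}
    for gene in sorted(root_genes):
        cds = _dna(root_genes[gene])
        if len(cds) % 3:
            raise ValueError(f"{gene}: root CDS not in frame")
        omega = (spec.omega if isinstance(spec.omega, (int, float))
                 else spec.omega[gene])
        if omega <= 0:
            raise ValueError("omega must be positive")
        omega_map[gene] = float(omega)
        tally = {"syn": 0, "nonsyn": 0}
        seqs: dict[int, list[str]] = {id(tree.seed_node): list(cds)}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            child = _evolve_branch(list(parent), t, float(omega), spec.rate,
                                   rng, code, tally)
            seqs[id(node)] = child
        rows = {lf.taxon.label: "".join(seqs[id(lf)])
                for lf in tree.leaf_node_iter()}
        alignments[gene] = GeneAlignment(gene, leaves, [rows[t] for t in leaves],
                                         codon_aligned=True)
        syn_tally[gene] = tally["syn"]
        nonsyn_tally[gene] = tally["nonsyn"]
    return alignments, EvolveTruth(omega_map, syn_tally, nonsyn_tally)
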