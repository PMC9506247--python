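"""Concatenated PCG supermatrix construction, partition files and a
desk-scale neighbor-joining tree.

The supermatrix follows the conventional PCG123 design: all thirteen
protein-coding genes, all three codon positions, concatenated in the fixed
order nad2, cox1, cox2, atp8, atp6, cox3, nad3, nad5, nad4, nad4l, nad6,
cytb, nad1, with per-gene and per-codon-position partitions recorded in
1-based inclusive coordinates for interchange with ML tools.  Tree
inference here is neighbor joining on a distance matrix — exact on additive
matrices and deterministic — intended for desk-scale checks; the written
supermatrix/partition files are the inputs for external ML programs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .divergence import jc_distance, pairwise_p_distance, _jc_or_nan
from .mito_io import GeneAlignment, MitoValidationError, read_alignment

#: Concatenation order of the 13 protein-coding genes in the PCG123 matrix.
PCG123_ORDER = ("nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
                "nad5", "nad4", "nad4l", "nad6", "cytb", "nad1")


@dataclass
class Partition:
    label: str
    start: int  # 1-based inclusive
    end: int
    kind: str   # 'gene' or 'codon-position'
    stride: int = 1


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: list[Partition] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def gene_partitions(self) -> list[Partition]:
        return [p for p in self.partitions if p.kind == "gene"]

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def concatenate(alignments: list[GeneAlignment], gap_fill: bool = False) -> Supermatrix:
    """Concatenate per-gene codon alignments into a PCG123 supermatrix.

    Genes are placed in the canonical PCG123 order (any extra genes follow
    alphabetically); taxa are ordered lexicographically over the union.  A
    taxon missing a gene is an error unless ``gap_fill`` pads it with gaps.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    by_gene = {a.gene: a for a in alignments}
    if len(by_gene) != len(alignments):
        raise ValueError("duplicate gene among alignments")
    for a in alignments:
        if not a.codon_aligned:
            raise MitoValidationError(f"{a.gene}: alignment is not codon-aligned")
    order = [g for g in PCG123_ORDER if g in by_gene]
    order += sorted(set(by_gene) - set(PCG123_ORDER))
    taxa = sorted({t for a in alignments for t in a.taxa})
    missing = [(t, g) for g in order for t in taxa if t not in by_gene[g].taxa]
    if missing and not gap_fill:
        raise ValueError(f"taxa missing genes (use gap_fill to pad): {missing}")
    rows = {t: [] for t in taxa}
    partitions: list[Partition] = []
    pos = 0
    for g in order:
        a = by_gene[g]
        L = a.length
        for t in taxa:
            rows[t].append(a.row(t) if t in a.taxa else "-" * L)
        partitions.append(Partition(g, pos + 1, pos + L, "gene"))
        for k in range(3):
            partitions.append(Partition(f"{g}_pos{k + 1}", pos + 1 + k, pos + L,
                                        "codon-position", stride=3))
        pos += L
    return Supermatrix(taxa, ["".join(rows[t]) for t in taxa], partitions)


# ---------------------------------------------------------------------------
# Distance matrices and neighbor joining
# ---------------------------------------------------------------------------

def jc_distance_matrix(taxa: list[str], rows: list[str]) -> pd.DataFrame:
    """Pairwise Jukes-Cantor distance matrix (NaN where saturated)."""
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _jc_or_nan(pairwise_p_distance(rows[i], rows[j]))
    return pd.DataFrame(d, index=taxa, columns=taxa)


def nj_tree(dist: pd.DataFrame | np.ndarray,
            labels: list[str] | None = None) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking.

    The Q-criterion minimum is resolved by the smallest (i, j) index pair;
    negative branch lengths are clamped to 0 with a warning.  The returned
    tree is unrooted (trifurcating root node).  Exact on additive matrices.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.to_numpy(dtype=float, copy=True)
    else:
        d = np.array(dist, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(len(d))]
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains missing entries")

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.4g} on {a}-{b}; clamped to 0")
            return 0.0
        return x

    nodes = [f"{lab}" for lab in labels]  # newick fragments
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li = clamp(li, nodes[i], nodes[j])
        lj = clamp(lj, nodes[j], nodes[i])
        new = len(nodes)
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        active = [k for k in active if k not in (i, j)] + [new]
    # three-point formulas close the unrooted tree with a trifurcation
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    li, lj, lk = (clamp(li, nodes[i], "root"), clamp(lj, nodes[j], "root"),
                  clamp(lk, nodes[k], "root"))
    newick = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _sanitize(name: str) -> str:
    out = "".join(c if c.isalnum() or c in "._-" else "_" for c in name)
    return out or "_"


def write_supermatrix(sm: Supermatrix, path: str | Path,
                      format: str = "fasta") -> dict[str, str]:
    """Write the matrix as FASTA or relaxed PHYLIP.

    Taxon ids carrying characters unsafe in these formats are relaxed to
    alphanumeric/._- names; the (original -> written) mapping is returned
    and, when any name changed, also written next to the matrix as
    ``<path>.names.tsv``.
    """
    path = Path(path)
    mapping = {t: _sanitize(t) for t in sm.taxa}
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("sanitized taxon names collide; rename taxa")
    with open(path, "w") as fh:
        if format == "fasta":
            for t, row in zip(sm.taxa, sm.rows):
                fh.write(f">{mapping[t]}\n{row}\n")
        elif format == "phylip-relaxed":
            fh.write(f" {len(sm.taxa)} {sm.length}\n")
            width = max(len(m) for m in mapping.values()) + 2
            for t, row in zip(sm.taxa, sm.rows):
                fh.write(f"{mapping[t]:<{width}}{row}\n")
        else:
            raise ValueError(f"unknown supermatrix format {format!r}")
    if any(t != m for t, m in mapping.items()):
        with open(str(path) + ".names.tsv", "w") as fh:
            fh.write("original\twritten\n")
            for t, m in mapping.items():
                fh.write(f"{t}\t{m}\n")
    return mapping


def read_supermatrix(path: str | Path) -> Supermatrix:
    aln = read_alignment(path, gene="supermatrix")
    return Supermatrix(aln.taxa, aln.rows)


def write_partitions(sm: Supermatrix, path: str | Path,
                     codon_positions: bool = True) -> None:
    """RAxML-style partition file: gene blocks and, optionally,
    ``gene_pos1 = start-end\\3`` codon-position blocks."""
    with open(path, "w") as fh:
        for p in sm.partitions:
            if p.kind == "gene":
                fh.write(f"DNA, {p.label} = {p.start}-{p.end}\n")
            elif codon_positions:
                fh.write(f"DNA, {p.label} = {p.start}-{p.end}\\{p.stride}\n")


def write_newick(tree: dendropy.Tree, path: str | Path,
                 outgroup: str | None = None) -> None:
    """Serialize a tree; an outgroup id roots the written Newick only."""
    if outgroup is not None:
        tree = tree.clone(depth=1)
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
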