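"""Nucleotide composition, A+T content and AT/GC strand skews.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on
exact integer base counts.  Ambiguous bases (N) are excluded from every
denominator, so percentages refer to counted A/C/G/T and skews stay
well-defined.  Whole-genome values are computed on the J-strand; per-class
values for stranded gene classes use coding-sense sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .mito_io import Mitogenome, extract_gene


@dataclass
class BaseComposition:
    """Exact base counts plus derived percentages and skews for one region."""

    region_label: str
    countA: int
    countT: int
    countG: int
    countC: int
    countN: int = 0

    @property
    def total(self) -> int:
        """Counted unambiguous bases."""
        return self.countA + self.countT + self.countG + self.countC

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total

    @property
    def pctA(self) -> float: return self._pct(self.countA)

    @property
    def pctT(self) -> float: return self._pct(self.countT)

    @property
    def pctG(self) -> float: return self._pct(self.countG)

    @property
    def pctC(self) -> float: return self._pct(self.countC)

    @property
    def pctAT(self) -> float: return self._pct(self.countA + self.countT)

    @property
    def pctGC(self) -> float: return self._pct(self.countG + self.countC)

    @property
    def at_skew(self) -> float:
        """(A-T)/(A+T); NaN when A+T = 0 (undefined, not zero)."""
        at = self.countA + self.countT
        return (self.countA - self.countT) / at if at else math.nan

    @property
    def gc_skew(self) -> float:
        """(G-C)/(G+C); NaN when G+C = 0."""
        gc = self.countG + self.countC
        return (self.countG - self.countC) / gc if gc else math.nan


def compose(seq: str, label: str = "region") -> BaseComposition:
    """Exact composition of one DNA string."""
    if not seq:
        raise ValueError("cannot compose an empty sequence")
    seq = seq.upper()
    return BaseComposition(
        region_label=label,
        countA=seq.count("A"), countT=seq.count("T"),
        countG=seq.count("G"), countC=seq.count("C"),
        countN=len(seq) - sum(seq.count(b) for b in "ACGT"))


def compose_counts(countA: int, countT: int, countG: int, countC: int,
                   label: str = "region") -> BaseComposition:
    """Composition object from pre-tallied base counts (e.g. published tables)."""
    return BaseComposition(label, countA, countT, countG, countC)


def compose_by_class(genome: Mitogenome) -> list[BaseComposition]:
    """Composition per feature class plus strand-partitioned PCG sets.

    Emits rows for: whole genome (J-strand), all PCGs, tRNAs, rRNAs, CR
    (coding-sense concatenations), and J-strand / N-strand PCG subsets.
    Classes absent from the annotation are simply omitted.
    """
    rows = [compose(genome.sequence, "whole genome")]
    classes = {
        "PCGs": [f for f in genome.features if f.ftype == "PCG"],
        "tRNAs": [f for f in genome.features if f.ftype == "tRNA"],
        "rRNAs": [f for f in genome.features if f.ftype == "rRNA"],
        "CR": [f for f in genome.features if f.ftype == "control_region"],
        "J-strand PCGs": [f for f in genome.features
                          if f.ftype == "PCG" and f.strand == "+"],
        "N-strand PCGs": [f for f in genome.features
                          if f.ftype == "PCG" and f.strand == "-"],
    }
    for label, feats in classes.items():
        if not feats:
            continue
        concat = "".join(extract_gene(genome, f) for f in feats)
        rows.append(compose(concat, label))
    return rows


def compose_per_gene(genome: Mitogenome) -> list[BaseComposition]:
    """One composition row per annotated feature, on coding sense."""
    return [compose(extract_gene(genome, f), f.label()) for f in genome.features]


def skew_scatter_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """Per-taxon whole-genome (J-strand) AT%/GC% and skews, ordered by taxon id.

    This is the table behind the classic AT%-vs-AT-skew / GC%-vs-GC-skew
    comparison across related mitogenomes.
    """
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate genome ids: {sorted({i for i in ids if ids.count(i) > 1})}")
    rows = []
    for g in sorted(genomes, key=lambda g: g.id):
        c = compose(g.sequence, g.id)
        rows.append({"taxon": g.id, "pctAT": c.pctAT, "at_skew": c.at_skew,
                     "pctGC": c.pctGC, "gc_skew": c.gc_skew})
    return pd.DataFrame(rows, columns=["taxon", "pctAT", "at_skew", "pctGC", "gc_skew"])


def composition_table(rows: list[BaseComposition]) -> pd.DataFrame:
    """Tabular view of composition rows (percentages at full precision;
    round at print time: 1 dp for percentages, 4 dp for skews)."""
    return pd.DataFrame([
        {"region": r.region_label, "A": r.countA, "T": r.countT, "G": r.countG,
         "C": r.countC, "N": r.countN, "pctA": r.pctA, "pctT": r.pctT,
         "pctG": r.pctG, "pctC": r.pctC, "pctAT": r.pctAT,
         "at_skew": r.at_skew, "gc_skew": r.gc_skew}
        for r in rows])
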