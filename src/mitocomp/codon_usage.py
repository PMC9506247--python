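"""Codon counting, RSCU, amino-acid usage, start/stop classification and
fold-degeneracy profiling under the invertebrate mitochondrial genetic code.

The genetic code defaults to NCBI translation table 5, under which AGA/AGG
encode Ser, AUA encodes Met and UGA encodes Trp — so the Ser synonymous
family has eight codons and Met/Trp have two each.  RSCU(c) is the observed
count of codon c divided by the mean count of its synonymous family
(equivalently count x family size / family total); 1 means no bias.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

BASES = "ACGT"


def _dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


class GeneticCode:
    """A 64-codon genetic code with synonymous-family and degeneracy queries.

    Wraps an NCBI translation table (default 5, invertebrate mitochondrial).
    Codons are handled in DNA alphabet internally; RNA spellings (with U)
    are accepted everywhere.
    """

    def __init__(self, table_id: int = 5):
        self.table_id = table_id
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self._aa = dict(table.forward_table)
        for stop in table.stop_codons:
            self._aa[stop] = "*"
        if len(self._aa) != 64:
            raise ValueError(f"translation table {table_id} does not map 64 codons")
        self._families: dict[str, tuple[str, ...]] = {}
        for codon, aa in sorted(self._aa.items()):
            self._families.setdefault(aa, ())
            self._families[aa] += (codon,)
        self.start_codons = tuple(table.start_codons)

    def aa(self, codon: str) -> str:
        """One-letter amino acid, '*' for stop."""
        return self._aa[_dna(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.aa(codon) == "*"

    def family(self, aa: str) -> tuple[str, ...]:
        """All codons encoding ``aa`` (the synonymous family)."""
        return self._families[aa]

    def family_size(self, codon: str) -> int:
        return len(self.family(self.aa(codon)))

    @property
    def sense_codons(self) -> list[str]:
        return [c for c in sorted(self._aa) if self._aa[c] != "*"]

    @property
    def stop_codons(self) -> list[str]:
        return [c for c in sorted(self._aa) if self._aa[c] == "*"]

    def synonymous_changes(self, codon: str, pos: int) -> int:
        """Of the 3 single-base changes at ``pos``, how many preserve the
        amino acid.  Changes that create a stop codon count as
        non-preserving; querying a stop codon raises."""
        codon = _dna(codon)
        aa = self.aa(codon)
        if aa == "*":
            raise ValueError(f"{codon} is a stop codon")
        s = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if self.aa(alt) == aa:
                s += 1
        return s

    def degeneracy_class(self, codon: str, pos: int) -> str:
        """'P0FD', 'P2FD' or 'P4FD' for the site (codon, position).

        0-fold: no synonymous single-base change; 4-fold: all three changes
        synonymous; everything in between (classical 2- and 3-fold) is
        pooled into the 2-fold class.
        """
        s = self.synonymous_changes(codon, pos)
        return "P0FD" if s == 0 else ("P4FD" if s == 3 else "P2FD")


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------

@dataclass
class StartStopEntry:
    """Start/stop classification of one coding sequence."""

    gene: str
    start_codon: str
    stop_codon: str  # complete triplet, or incomplete 'T' / 'TT', or ''
    complete: bool

    @property
    def incomplete(self) -> bool:
        return len(self.stop_codon) in (1, 2)


@dataclass
class CodonCountResult:
    gene: str
    counts: Counter
    start_stop: StartStopEntry
    ambiguous_codons: int = 0
    internal_stop_positions: list[int] = field(default_factory=list)


def count_codons(cds: str, code: GeneticCode | None = None,
                 gene: str = "cds") -> CodonCountResult:
    """Count sense codons of an in-frame CDS.

    The sequence is read in frame 0.  A trailing 1-2 bp remainder is recorded
    as an incomplete stop codon (completed to UAA by polyadenylation in vivo)
    and excluded from the counts, as is a complete terminal stop.  Internal
    stop codons trigger a warning (with codon index) but are not fatal;
    codons containing non-ACGT symbols are skipped and tallied.
    """
    if code is None:
        code = GeneticCode()
    cds = _dna(cds)
    if len(cds) < 6:
        raise ValueError(f"{gene}: CDS shorter than two codons")
    n_full = len(cds) // 3
    remainder = cds[3 * n_full:]
    codons = [cds[3 * i: 3 * i + 3] for i in range(n_full)]

    stop_codon, complete = "", False
    if remainder:
        stop_codon = remainder  # incomplete stop: 'T' or 'TT' typically
    elif codons and set(codons[-1]) <= set(BASES) and code.is_stop(codons[-1]):
        stop_codon, complete = codons[-1], True
        codons = codons[:-1]

    counts: Counter = Counter()
    ambiguous = 0
    internal_stops = []
    for i, codon in enumerate(codons):
        if set(codon) - set(BASES):
            ambiguous += 1
            continue
        if code.is_stop(codon):
            internal_stops.append(i)
            warnings.warn(f"{gene}: internal stop codon {codon} at codon {i}")
            continue
        counts[codon] += 1
    start = codons[0] if codons else ""
    return CodonCountResult(gene, counts, StartStopEntry(gene, start, stop_codon, complete),
                            ambiguous, internal_stops)


def count_codons_by_gene(cds_by_gene: Mapping[str, str],
                         code: GeneticCode | None = None) -> list[CodonCountResult]:
    code = code or GeneticCode()
    return [count_codons(cds, code, gene) for gene, cds in cds_by_gene.items()]


def pooled_counts(results: Iterable[CodonCountResult],
                  per_gene_mean: bool = False) -> dict[str, float]:
    """Sum (or average over genes) the per-gene codon counts."""
    results = list(results)
    total: Counter = Counter()
    for r in results:
        total.update(r.counts)
    if per_gene_mean and results:
        return {c: n / len(results) for c, n in total.items()}
    return dict(total)


# ---------------------------------------------------------------------------
# RSCU and amino-acid usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Per-codon counts and RSCU plus per-amino-acid usage percentages.

    Counts may be raw totals or per-gene means; RSCU is invariant under
    uniform scaling so both conventions give identical RSCU values.
    """

    counts: dict[str, float]       # DNA-alphabet codon -> count
    rscu_values: dict[str, float]  # NaN where the whole family is unobserved
    aa_percent: dict[str, float]
    total_nonstop: float
    code: GeneticCode

    def to_frame(self, rna: bool = True) -> pd.DataFrame:
        rows = []
        for codon in sorted(self.code.sense_codons) + self.code.stop_codons:
            rows.append({
                "codon": _rna(codon) if rna else codon,
                "aa": self.code.aa(codon),
                "count": self.counts.get(codon, 0.0),
                "rscu": self.rscu_values.get(codon, 0.0),
            })
        return pd.DataFrame(rows)


def rscu(counts: Mapping[str, float], code: GeneticCode | None = None) -> CodonUsageTable:
    """RSCU(c) = count(c) x family size / family total, per synonymous family.

    Stop codons are excluded.  A family with zero total leaves its codons'
    RSCU undefined (NaN).  Accepts codons in DNA or RNA spelling.
    """
    code = code or GeneticCode()
    clean = {}
    for codon, n in counts.items():
        codon = _dna(codon)
        if n < 0:
            raise ValueError(f"negative count for {codon}")
        if not code.is_stop(codon):
            clean[codon] = clean.get(codon, 0.0) + float(n)
    values: dict[str, float] = {}
    for aa, family in code._families.items():
        if aa == "*":
            continue
        family_total = sum(clean.get(c, 0.0) for c in family)
        for c in family:
            if family_total > 0:
                values[c] = clean.get(c, 0.0) * len(family) / family_total
            else:
                values[c] = math.nan
    total = sum(clean.values())
    return CodonUsageTable(clean, values, aa_usage(clean, code) if total > 0 else {},
                           total, code)


def aa_usage(counts: Mapping[str, float], code: GeneticCode | None = None) -> dict[str, float]:
    """Percent of non-stop codons per amino acid; sums to 100 at full precision."""
    code = code or GeneticCode()
    totals: dict[str, float] = {}
    grand = 0.0
    for codon, n in counts.items():
        codon = _dna(codon)
        if code.is_stop(codon):
            continue
        aa = code.aa(codon)
        totals[aa] = totals.get(aa, 0.0) + float(n)
        grand += float(n)
    if grand <= 0:
        raise ValueError("no non-stop codons counted")
    return {aa: 100.0 * n / grand for aa, n in sorted(totals.items())}


# ---------------------------------------------------------------------------
# Fold-degeneracy (0/2/4-fold) A+T profiling
# ---------------------------------------------------------------------------

FOLD_CLASSES = ("P0FD", "P2FD", "P4FD")


@dataclass
class FoldClassProfile:
    """Per-gene, per-class A+T%% for each taxon, with across-taxon mean/SD."""

    per_taxon: pd.DataFrame  # columns: gene, taxon, fold_class, at_pct, n_sites
    summary: pd.DataFrame    # columns: gene, fold_class, mean_at_pct, sd_at_pct


def classify_fold_sites(cds: str, code: GeneticCode | None = None) -> list[str]:
    """Class ('P0FD'/'P2FD'/'P4FD') of every site of an in-frame CDS.

    Sites in codons containing N (or in stop codons, which have no amino
    acid) are marked '' and excluded from profiling.
    """
    code = code or GeneticCode()
    cds = _dna(cds)
    out = []
    for i in range(len(cds) // 3):
        codon = cds[3 * i: 3 * i + 3]
        if set(codon) - set(BASES) or code.is_stop(codon):
            out.extend([""] * 3)
            continue
        out.extend(code.degeneracy_class(codon, p) for p in range(3))
    return out


def fold_class_profile(cds_sets: Mapping[str, Mapping[str, str]],
                       code: GeneticCode | None = None) -> FoldClassProfile:
    """A+T%% at 0/2/4-fold degenerate sites per gene per taxon.

    ``cds_sets`` maps gene -> taxon -> in-frame coding sequence (terminal
    stops may be present and are ignored via classification).  The summary
    gives the across-taxon mean and sample SD per gene and class.
    """
    code = code or GeneticCode()
    rows = []
    for gene in sorted(cds_sets):
        for taxon in sorted(cds_sets[gene]):
            cds = _dna(cds_sets[gene][taxon])
            classes = classify_fold_sites(cds, code)
            for fc in FOLD_CLASSES:
                sites = [cds[i] for i, c in enumerate(classes) if c == fc]
                at = sum(1 for b in sites if b in "AT")
                rows.append({
                    "gene": gene, "taxon": taxon, "fold_class": fc,
                    "at_pct": 100.0 * at / len(sites) if sites else math.nan,
                    "n_sites": len(sites)})
    per_taxon = pd.DataFrame(rows)
    summary = (per_taxon.groupby(["gene", "fold_class"], as_index=False)
               .agg(mean_at_pct=("at_pct", "mean"),
                    sd_at_pct=("at_pct", lambda s: s.std(ddof=1))))
    return FoldClassProfile(per_taxon, summary)


def start_stop_report(cds_by_gene: Mapping[str, str],
                      code: GeneticCode | None = None) -> list[StartStopEntry]:
    """Start/stop codon classification for a set of coding sequences."""
    code = code or GeneticCode()
    return [count_codons(cds, code, gene).start_stop
            for gene, cds in sorted(cds_by_gene.items())]
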