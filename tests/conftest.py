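"""Shared fixtures: published codon-usage counts, toy genomes, and
independent oracles used to cross-check the package's own algorithms."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp import GeneFeature, GenomeBlueprint, Mitogenome, generate_genome

# Published per-codon counts (per-gene means over the 13 PCGs) for the
# brown-planthopper mitogenome; RNA spelling as printed.
TABLE1_COUNTS = {
    "UUU": 25.5, "UUC": 4.5, "UUA": 25.7, "UUG": 3.5,
    "CUU": 4.8, "CUC": 0.8, "CUA": 4.5, "CUG": 0.5,
    "AUU": 26.1, "AUC": 3.5, "AUA": 16.5, "AUG": 2.7,
    "GUU": 4.8, "GUC": 0.6, "GUA": 4.5, "GUG": 0.6,
    "UCU": 8.5, "UCC": 2.5, "UCA": 7.3, "UCG": 0.5,
    "CCU": 3.4, "CCC": 2.9, "CCA": 3.4, "CCG": 0.2,
    "ACU": 4.5, "ACC": 2.2, "ACA": 4.1, "ACG": 0.2,
    "GCU": 2.8, "GCC": 1.0, "GCA": 2.0, "GCG": 0.1,
    "UAU": 9.6, "UAC": 2.0, "UAA": 0.0, "UAG": 0.0,
    "CAU": 3.5, "CAC": 1.5, "CAA": 3.1, "CAG": 0.6,
    "AAU": 11.2, "AAC": 2.3, "AAA": 8.9, "AAG": 1.5,
    "GAU": 3.3, "GAC": 1.2, "GAA": 5.5, "GAG": 0.6,
    "UGU": 3.0, "UGC": 0.2, "UGA": 5.2, "UGG": 0.8,
    "CGU": 1.1, "CGC": 0.1, "CGA": 1.8, "CGG": 0.4,
    "AGU": 3.9, "AGC": 0.5, "AGA": 5.9, "AGG": 0.8,
    "GGU": 4.8, "GGC": 0.5, "GGA": 5.1, "GGG": 2.1,
}

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


def translate5(codon: str) -> str:
    """Independent amino-acid lookup (Biopython, invertebrate mito code);
    '*' for stops."""
    return str(Seq(codon).translate(table=5))


def oracle_fold_class(codon: str, pos: int) -> str:
    """9-neighbor brute force: count amino-acid-preserving single-base
    substitutions at pos (stop-creating = non-preserving)."""
    aa = translate5(codon)
    assert aa != "*"
    s = sum(
        1 for b in BASES
        if b != codon[pos] and translate5(codon[:pos] + b + codon[pos + 1:]) == aa)
    return {0: "P0FD", 3: "P4FD"}.get(s, "P2FD")


def oracle_ng_differences(a: str, b: str) -> tuple[float, float] | None:
    """Pathway-enumeration oracle for (syn, nonsyn) differences between two
    codons: explicit recursion over substitution orderings, Biopython
    translation, stop-passing pathways discarded.  None when every pathway
    hits a stop."""
    diff = [p for p in range(3) if a[p] != b[p]]
    outcomes: list[tuple[int, int]] = []
    for perm in itertools.permutations(diff):
        cur, syn, nonsyn, ok = a, 0, 0, True
        for p in perm:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if translate5(nxt) == "*":
                ok = False
                break
            if translate5(nxt) == translate5(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            outcomes.append((syn, nonsyn))
    if not outcomes:
        return None
    return (sum(o[0] for o in outcomes) / len(outcomes),
            sum(o[1] for o in outcomes) / len(outcomes))


def oracle_ng_sites(codon: str) -> float:
    """Synonymous site count of one codon by 9-neighbor enumeration."""
    aa = translate5(codon)
    s = 0
    for p in range(3):
        for b2 in BASES:
            if b2 == codon[p]:
                continue
            if translate5(codon[:p] + b2 + codon[p + 1:]) == aa:
                s += 1
    return s / 3.0


def toy_genome(seq: str, feats: list[tuple], genome_id: str = "toy",
               circular: bool = True) -> Mitogenome:
    """Mitogenome from (name, ftype, start, end, strand[, copy]) tuples."""
    features = [GeneFeature(*f) for f in feats]
    return Mitogenome(genome_id, seq, circular, features)


@pytest.fixture(scope="session")
def planted():
    """Default synthetic genome (study-like order) with its truth record."""
    return generate_genome(GenomeBlueprint(seed=42))


@pytest.fixture(scope="session")
def planted_ancestral():
    return generate_genome(GenomeBlueprint(seed=7, order="ancestral"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
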