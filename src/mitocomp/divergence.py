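"""Pairwise distances, sliding-window nucleotide diversity (Pi) and
Nei-Gojobori Ka/Ks with Jukes-Cantor multiple-hit adjustment.

Nucleotide diversity Pi is the mean pairwise proportion of differing sites;
Ka and Ks are non-synonymous and synonymous substitutions per respective
site under Nei-Gojobori (1986) counting: per-codon site totals from the
fraction of single-base changes that are synonymous, and observed
differences apportioned by equal weighting over all substitution pathways
(pathways through stop codons excluded and the weights renormalized).
The Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) maps an observed
proportion p of differences to substitutions per site.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_usage import BASES, GeneticCode, _dna
from .mito_io import GeneAlignment


class SaturationError(ValueError):
    """Jukes-Cantor correction undefined: observed p >= 0.75."""


def pairwise_p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, with pairwise deletion of columns
    containing gaps or ambiguous bases; NaN when nothing is comparable."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a, b = a.upper(), b.upper()
    diffs = compared = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            compared += 1
            if x != y:
                diffs += 1
    return diffs / compared if compared else math.nan


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3) for 0 <= p < 0.75."""
    if math.isnan(p):
        return math.nan
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond JC saturation (0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _jc_or_nan(p: float) -> float:
    try:
        return jc_distance(p)
    except SaturationError:
        return math.nan


# ---------------------------------------------------------------------------
# Sliding-window nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityProfile:
    gene: str
    windows: pd.DataFrame  # columns: start, mid, pi
    gene_pi: float
    mean_p_distance: float
    mean_jc_distance: float


def _mean_pairwise_p(rows: list[str], start: int, end: int) -> float:
    ps = [pairwise_p_distance(a[start:end], b[start:end])
          for a, b in itertools.combinations(rows, 2)]
    ps = [p for p in ps if not math.isnan(p)]
    return float(np.mean(ps)) if ps else math.nan


def sliding_pi(aln: GeneAlignment, window: int = 200, step: int = 20) -> DiversityProfile:
    """Pi in sliding windows plus whole-gene Pi and mean pairwise distances.

    Pi per window is the unweighted mean over all sequence pairs of the
    proportion of differing comparable sites in that window (for n=2 this
    reduces to the p-distance).  Windows start every ``step`` bp and only
    full-length windows are emitted; with window = alignment length the
    single window equals the whole-gene Pi.
    """
    if len(aln.rows) < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    L = aln.length
    if window > L:
        raise ValueError(f"window ({window}) exceeds alignment length ({L})")
    recs = []
    for start in range(0, L - window + 1, step):
        pi = _mean_pairwise_p(aln.rows, start, start + window)
        recs.append({"start": start, "mid": start + window / 2.0, "pi": pi})
    gene_pi = _mean_pairwise_p(aln.rows, 0, L)
    jcs = [_jc_or_nan(pairwise_p_distance(a, b))
           for a, b in itertools.combinations(aln.rows, 2)]
    jcs = [d for d in jcs if not math.isnan(d)]
    return DiversityProfile(
        gene=aln.gene, windows=pd.DataFrame(recs), gene_pi=gene_pi,
        mean_p_distance=gene_pi,
        mean_jc_distance=float(np.mean(jcs)) if jcs else math.nan)


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class NGPairResult:
    pN: float
    pS: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    compared_codons: int
    skipped_codons: int


def _codon_syn_sites(codon: str, code: GeneticCode) -> float:
    return sum(code.synonymous_changes(codon, p) for p in range(3)) / 3.0


def _pathway_counts(a: str, b: str, code: GeneticCode) -> tuple[float, float] | None:
    """(syn, nonsyn) difference counts between codons a and b, averaged with
    equal weight over all substitution pathways that avoid stop codons;
    None if every pathway passes through a stop."""
    diff_pos = [p for p in range(3) if a[p] != b[p]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for perm in itertools.permutations(diff_pos):
        cur = a
        syn = nonsyn = 0
        ok = True
        for p in perm:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.aa(nxt) == code.aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def nei_gojobori(a: str, b: str, code: GeneticCode | None = None) -> NGPairResult:
    """Nei-Gojobori proportions of synonymous/non-synonymous differences.

    Codons containing gaps or N in either sequence are skipped pairwise, as
    are codon pairs whose every substitution pathway passes through a stop
    codon (both tallied in ``skipped_codons``).  Site totals are averaged
    between the two sequences; N + S = 3 x compared codons exactly.
    """
    code = code or GeneticCode()
    a, b = _dna(a), _dna(b)
    if len(a) != len(b):
        raise ValueError("sequences must be equally long")
    if len(a) % 3:
        raise ValueError("sequence length must be divisible by 3")
    S = N = Sd = Nd = 0.0
    compared = skipped = 0
    for i in range(len(a) // 3):
        ca, cb = a[3 * i: 3 * i + 3], b[3 * i: 3 * i + 3]
        if set(ca) - set(BASES) or set(cb) - set(BASES):
            skipped += 1
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            skipped += 1
            continue
        counts = _pathway_counts(ca, cb, code)
        if counts is None:
            skipped += 1
            continue
        sa = _codon_syn_sites(ca, code)
        sb = _codon_syn_sites(cb, code)
        s_sites = (sa + sb) / 2.0
        S += s_sites
        N += 3.0 - s_sites
        Sd += counts[0]
        Nd += counts[1]
        compared += 1
    pN = Nd / N if N > 0 else math.nan
    pS = Sd / S if S > 0 else math.nan
    return NGPairResult(pN, pS, N, S, Nd, Sd, compared, skipped)


# ---------------------------------------------------------------------------
# Per-gene substitution rates over a taxon set
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionRates:
    """Per-gene Ka/Ks averaged over all unordered taxon pairs, raw and
    Jukes-Cantor adjusted; ratios are formed after averaging and left NaN
    when the denominator is 0."""

    gene: str
    Ka: float
    Ks: float
    ka_ks: float
    JKa: float
    JKs: float
    jka_jks: float
    n_pairs: int


def _ratio(num: float, den: float) -> float:
    if math.isnan(num) or math.isnan(den) or den == 0:
        return math.nan
    return num / den


def gene_rates(alignments: dict[str, GeneAlignment],
               code: GeneticCode | None = None,
               adjust_before_averaging: bool = True) -> pd.DataFrame:
    """Ka, Ks and their JC-adjusted counterparts per gene.

    Raw Ka/Ks are the across-pair means of pN/pS.  With
    ``adjust_before_averaging`` (default) the JC correction is applied to
    each pair's pN and pS and the corrected values averaged; otherwise the
    correction is applied once to the averaged proportions.  Saturated
    pairs (p >= 0.75) are dropped from the adjusted mean with a warning.
    Genes are returned ranked by decreasing JKa/JKs (the evolutionary-rate
    ordering); all-gap rows are dropped per gene with a warning.
    """
    code = code or GeneticCode()
    out = []
    for gene in alignments:
        aln = alignments[gene]
        keep = [t for t, r in zip(aln.taxa, aln.rows) if set(r) - {"-", "N"}]
        if len(keep) < len(aln.taxa):
            dropped = sorted(set(aln.taxa) - set(keep))
            warnings.warn(f"{gene}: dropping taxa with no sequence data: {dropped}")
        if len(keep) < 2:
            warnings.warn(f"{gene}: fewer than 2 usable taxa; skipped")
            continue
        sub = aln.subset(keep)
        pNs, pSs, jkas, jkss = [], [], [], []
        for a, b in itertools.combinations(sub.rows, 2):
            r = nei_gojobori(a, b, code)
            pNs.append(r.pN)
            pSs.append(r.pS)
            jka, jks = _jc_or_nan(r.pN), _jc_or_nan(r.pS)
            if math.isnan(jks) and not math.isnan(r.pS):
                warnings.warn(f"{gene}: a pair is JC-saturated; dropped from JK means")
            jkas.append(jka)
            jkss.append(jks)
        Ka, Ks = float(np.nanmean(pNs)), float(np.nanmean(pSs))
        if adjust_before_averaging:
            JKa = float(np.nanmean(jkas)) if not all(map(math.isnan, jkas)) else math.nan
            JKs = float(np.nanmean(jkss)) if not all(map(math.isnan, jkss)) else math.nan
        else:
            JKa, JKs = _jc_or_nan(Ka), _jc_or_nan(Ks)
        out.append(SubstitutionRates(gene, Ka, Ks, _ratio(Ka, Ks),
                                     JKa, JKs, _ratio(JKa, JKs),
                                     len(sub.rows) * (len(sub.rows) - 1) // 2))
    frame = pd.DataFrame([vars(r) for r in out])
    if not frame.empty:
        frame = frame.sort_values("jka_jks", ascending=False, na_position="last",
                                  kind="mergesort").reset_index(drop=True)
    return frame
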