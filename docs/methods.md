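# Methods

This note records the models and conventions behind `mitocomp`, the
parameters that matter, and the choices made where the design was
genuinely open.

## Coordinates and the data model

All coordinates are 0-based half-open on the linearized majority (J)
strand; GenBank's 1-based inclusive convention is converted at the I/O
boundary. This makes every spacer/overlap computation a plain subtraction
(`next.start − prev.end`) with no off-by-one cases. Features on the
minority (N) strand keep J-strand coordinates with `strand='-'`; their
coding-sense sequence is the reverse complement of the J-strand slice.

Circular genomes may carry origin-spanning features, encoded with
`end > genome length` and interpreted modulo the length, so
`end − start` is always the feature length. In GenBank output these
become two-part `join` locations and are folded back on reading. The
linearization origin is the first base of trnI when present (the
conventional insect presentation); otherwise position 0 of the input.
Gene-name synonyms (COB/CYTB, ND4L/nad4l, 12S/rrnS, ...) are resolved
through an editable data table shipped with the package, not code;
unknown names are preserved with `ftype='other'` and a warning.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), computed from exact integer
counts. Whole-genome values are taken on the J-strand (the convention for
cross-taxon skew comparisons); per-class and per-gene values use
coding-sense sequences. Ambiguous bases (N) are excluded from every
denominator — this keeps skews well-defined and means percentages refer
to counted A/C/G/T, not sequence length. A zero denominator (e.g. A+T = 0)
yields NaN ("undefined"), never 0. Outputs print percentages at 1 decimal
place and skews at 4 (full precision is retained internally).

## Codon usage

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser giving an 8-codon Ser family, AUA = Met,
UGA = Trp) and is injectable for other mitochondrial tables. Counting
walks frame 0 of each CDS. Conventions, chosen once:

- Start codons are included in counts; a complete terminal stop codon is
  recorded but excluded from counts and RSCU denominators; a trailing
  1–2 bp remainder is recorded as an incomplete stop (T/TT, completed to
  UAA by polyadenylation in vivo) and excluded likewise.
- Internal stop codons warn (with codon index) but do not abort — real
  annotations occasionally produce them; codons containing non-ACGT
  symbols are skipped and tallied.
- RSCU(c) = count(c) × family size / family total; a family with zero
  total leaves RSCU undefined (NaN), not 0. RSCU is invariant under
  uniform scaling, so raw totals and per-gene means give identical RSCU.

Fold degeneracy classifies each codon site by s = the number of the three
single-base substitutions that preserve the amino acid, with
stop-creating substitutions counted as non-preserving: s = 0 → 0-fold,
s = 3 → 4-fold, otherwise 2-fold. Classical 2-fold and 3-fold sites are
pooled into the 2-fold class (the common three-class convention). Sites
in codons containing N, and terminal stop codons, are excluded.
Across-taxon spreads use the sample SD (ddof = 1).

## Architecture

Rearrangement is measured as a circular, strand-aware breakpoint count:
the adjacency multiset of the query order minus that of the reference.
An adjacency read on the opposite strand (`a→b` vs `rev(b)→rev(a)`)
denotes the same junction and is canonicalized; copy indices are ignored
so duplicated genes match greedily by surrounding context, with surplus
copies surfacing as novel junctions. This identifies rearranged blocks
without committing to an inversion/DCJ scenario, which is out of scope.

Spacer/overlap accounting walks consecutive features on the circle
(including the wrap junction): gap ≥ 1 is a spacer, gap < 0 an overlap,
0 abutting. Features nested inside another feature are excluded from the
walk and listed separately, which keeps the tiling identity
Σ lengths + Σ spacers − Σ overlaps = genome length testable. The control
region is excluded by default and reported as its length.

Tandem-repeat search is an exhaustive unit scan, O(L × max unit length):
for every unit length in a bounded range (default 5–50 bp) and every
start, consecutive blocks are accreted while they differ from the first
block at no more than a cumulative budget of positions (default 1). This
admits units with one degenerate position — e.g. a (G/A) first base —
which is reported as an IUPAC consensus over the copies. Candidates need
≥ 3 copies; maximal non-overlapping arrays are selected greedily with
ties broken by (more copies, longer span, leftmost). Determinism was
preferred over heuristic speed; at control-region scale (~1.3 kb) the
scan is instantaneous. Poly-T detection returns the longest run of T,
leftmost on ties, and (0, None) on a T-free region.

## Divergence

p-distances use pairwise deletion of gap/N columns (complete deletion
would couple per-window site counts across windows). Jukes–Cantor
d = −(3/4)·ln(1 − 4p/3) raises a saturation error at p ≥ 0.75;
aggregating code converts that to a missing value.

Nucleotide diversity π per window is the unweighted mean over all
sequence pairs of the proportion of differing comparable sites in the
window (for n = 2 this is the p-distance). Windows are full-length only,
starting every `step` bp; defaults are 200/20 bp and configurable — a
conventional choice, since sliding-window parameters are rarely reported.
A window with no comparable sites yields NaN but is kept.

Ka/Ks follows Nei–Gojobori (1986): per-codon synonymous site counts are
the summed per-position synonymous fractions (stop-creating changes count
as non-synonymous), averaged between the two sequences, so
N + S = 3 × compared codons exactly. Observed differences are apportioned
by equal weighting over all substitution pathways; pathways through stop
codons are excluded with renormalization, and a codon pair whose every
pathway hits a stop is skipped and tallied. Multi-taxon per-gene values
are unweighted means over all unordered pairs. The Jukes–Cantor-adjusted
JKa/JKs applies the correction to each pair's pN and pS *before*
averaging (default); the alternative — correct the averaged proportions —
is available behind `adjust_before_averaging=False`, since published
tables do not always say which convention their software used. Ratios are
formed after averaging and are NaN when the denominator is 0. Genes are
ranked by JKa/JKs for the evolutionary-rate ordering.

## Phylogenetic preparation

The supermatrix concatenates the 13 PCGs in the fixed PCG123 order
(nad2, cox1, cox2, atp8, atp6, cox3, nad3, nad5, nad4, nad4l, nad6,
cytb, nad1) regardless of input order, taxa sorted lexicographically;
missing gene/taxon combinations are an error unless gap-filling is
requested. Partitions are recorded 1-based inclusive (gene blocks tile
the matrix; codon-position blocks carry stride 3) and written in RAxML
style (`DNA, nad2_pos1 = 1-300\3`).

Neighbor joining is implemented directly so its behavior is pinned:
Q-criterion ties resolve to the smallest index pair, negative branch
lengths are clamped to 0 with a warning, and the returned tree is
unrooted (trifurcating root closed by three-point formulas). NJ is exact
on additive matrices, which is what the recovery tests exercise. ML
inference, model selection and bootstrapping are deliberately external:
the package emits their inputs (supermatrix, partitions) bit-exactly.
An outgroup id roots the written Newick only; the in-memory tree stays
unrooted.

## Synthetic data

The generator emulates a delphacid-like mitogenome: 37-gene canon plus an
extra trnC copy, N. lugens-like order (trnC–trnW swap and the reversed
nad6–trnP–trnT block relative to the ancestral arrangement), base
composition targeting 77.5% A+T (A 42.6, T 34.9, G 8.8, C 13.7 — the
J-strand proportions of the study organism), a 345 bp spacer between nad2
and trnC among other named spacers, 4 bp of overlap at two tRNA–tRNA
boundaries, characteristic ATN starts, complete TAA stops and incomplete
T/TT stops (TT in nad5; T in atp8, nad3, nad6, cytb, nad1), and a ~1.3 kb
control region holding a 15-copy tandem array of a 20 bp unit whose first
base alternates G/A plus a 24 bp poly-T run. atp8 is 94 bp — one base
above the organism's reported 93 bp — so that its planted incomplete-stop
policy and its length stay mutually consistent.

With `exact_composition` (default), unconstrained positions are filled by
drawing without replacement from the exact residual base multiset, so
whole-genome tallies hit the target to the base; in-frame stop codons
arising in PCG bodies are then repaired by tally-preserving swaps with
non-coding positions (infeasible targets raise). Fixed terminator bases
flank the repeat array and poly-T so planted copy numbers and run lengths
are exact, not merely expected. Everything is deterministic per seed, and
a truth record carries every planted quantity for round-trip tests.

The divergence simulator proposes single-base changes uniformly along a
guide tree (branch lengths = expected proposals per site), rejects
stop-creating changes, accepts synonymous changes always and
non-synonymous ones with probability ω — so realized dN/dS equals ω by
construction without a full codon rate matrix. No indels are simulated;
alignments are gap-free, which keeps the π and Ka/Ks oracles exact. The
recovery tests use 300-codon genes, 4 taxa on a balanced tree with 0.1
and 0.05 proposals/site branches, and 20 seeds — enough divergence for
stable estimates while staying far from JC saturation, and small enough
that the whole suite runs in seconds.

What the generator does **not** emulate: sequencing error, assembly
artifacts, indels and alignment uncertainty, tRNA secondary structure,
heterogeneous composition along the molecule, and context-dependent
mutation. Passing round-trip tests therefore demonstrates correctness of
the statistics on clean annotated input, not robustness to annotation or
alignment error.

## Known limitations

- Ka/Ks is counting-based (NG86); no maximum-likelihood codon models or
  site-specific selection tests.
- Breakpoint counts quantify disruption, not rearrangement distance.
- The repeat finder's degeneracy budget is positional (default one
  variable position per unit), not a general edit distance.
- Published per-gene divergence tables from multi-accession datasets
  depend on external alignment/trimming pipelines and are not reproduced
  by this package; its divergence stages operate on user-supplied or
  simulated codon alignments.
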