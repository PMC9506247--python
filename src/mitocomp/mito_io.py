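"""Reading, writing and the circular-coordinate data model for annotated mitogenomes.

All coordinates are 0-based half-open on the linearized majority (J) strand.
Features may span the sequence origin on a circular genome; these are encoded
with ``end > genome length`` and interpreted modulo the length, so that
``end - start`` is always the feature length.  GenBank's 1-based inclusive
coordinates (and Biopython's compound "join" locations for origin-spanning
features) are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control_region", "other")

#: The 37-gene metazoan mitochondrial canon: 13 protein-coding genes,
#: 22 tRNAs (two each for Leu and Ser) and the two rRNA subunits.
CANONICAL_PCGS = (
    "cox1", "cox2", "cox3", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6", "cytb",
)
CANONICAL_TRNAS = tuple(
    "trn" + aa for aa in
    ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2", "M",
     "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
CANONICAL_RRNAS = ("rrnS", "rrnL")
CANONICAL_GENES = CANONICAL_PCGS + CANONICAL_TRNAS + CANONICAL_RRNAS


class MitoFormatError(ValueError):
    """Raised when an input file cannot be parsed under the named dialect."""


class MitoValidationError(ValueError):
    """Raised when parsed content violates the data-model invariants."""


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("mitocomp.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_synonym_map() -> dict[str, str]:
    """Alias -> canonical gene symbol map (case-insensitive keys)."""
    return {alias.lower(): canon for alias, canon in _load_table("gene_synonyms.tsv")}


def canonical_gene_name(raw: str, synonyms: dict[str, str] | None = None) -> str | None:
    """Map a raw feature name to its canonical symbol, or None if unknown."""
    if synonyms is None:
        synonyms = load_synonym_map()
    return synonyms.get(raw.strip().lower())


def ancestral_insect_order() -> list[tuple[str, str, str]]:
    """The putative ancestral arthropod gene order as (name, ftype, strand) rows."""
    return [tuple(r) for r in _load_table("ancestral_order.tsv")]


@dataclass
class GeneFeature:
    """A typed, stranded feature on the linearized J-strand.

    ``start``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length to encode an origin-spanning feature on a circular genome.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise MitoValidationError(f"unknown ftype {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise MitoValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise MitoValidationError(
                f"feature {self.name}: end ({self.end}) must exceed start ({self.start})")
        if self.copy_index < 1:
            raise MitoValidationError("copy_index must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def spans_origin(self) -> bool:
        return False  # refined once genome length is known; see Mitogenome

    def label(self) -> str:
        """Display label: gene symbol, with copy index when duplicated."""
        return self.name if self.copy_index == 1 else f"{self.name}.{self.copy_index}"


@dataclass
class Mitogenome:
    """An annotated (usually circular) mitochondrial genome.

    The feature list is kept sorted by start coordinate on the linearized
    J-strand; N-strand genes keep J-strand coordinates with strand '-'.
    """

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise MitoValidationError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: GeneFeature) -> None:
        L = self.length
        if f.length > L:
            raise MitoValidationError(
                f"feature {f.name} longer ({f.length}) than genome ({L})")
        if f.start < 0 or f.start >= L:
            raise MitoValidationError(f"feature {f.name} start {f.start} outside [0,{L})")
        if f.end > L and not self.circular:
            raise MitoValidationError(
                f"feature {f.name} spans the origin of a linear genome")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def feature_by_name(self, name: str, copy_index: int = 1) -> GeneFeature | None:
        for f in self.features:
            if f.name == name and f.copy_index == copy_index:
                return f
        return None


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_gene(genome: Mitogenome, feature: GeneFeature) -> str:
    """Coding-sense sequence of a feature: J-strand slice for '+',
    reverse complement for '-'; origin-spanning features are unwrapped."""
    if feature not in genome.features:
        raise MitoValidationError(f"feature {feature.name} does not belong to {genome.id}")
    L = genome.length
    if feature.end <= L:
        raw = genome.sequence[feature.start:feature.end]
    else:
        raw = genome.sequence[feature.start:] + genome.sequence[: feature.end - L]
    return raw if feature.strand == "+" else revcomp(raw)


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_GB_TYPE_TO_FTYPE = {
    "CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
    "D-loop": "control_region",
}
_FTYPE_TO_GB_TYPE = {
    "PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
    "control_region": "D-loop", "other": "misc_feature",
}


def _feature_name_from_qualifiers(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _location_to_interval(loc, length: int) -> tuple[int, int]:
    """Convert a (possibly compound, origin-spanning) Biopython location to
    the internal (start, end) with end > length encoding a wrap."""
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end)
    if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
        return int(parts[1].start), length + int(parts[0].end)
    raise MitoFormatError(f"unsupported compound location {loc}")


def read_genbank(path: str | Path, synonyms: dict[str, str] | None = None) -> Mitogenome:
    if synonyms is None:
        synonyms = load_synonym_map()
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted types on bad input
        raise MitoFormatError(f"cannot parse {path} as GenBank: {exc}") from exc
    circular = record.annotations.get("topology", "circular") == "circular"
    features: list[GeneFeature] = []
    counts: dict[str, int] = {}
    for feat in record.features:
        if feat.type == "source" or feat.type == "gene":
            continue
        ftype = _GB_TYPE_TO_FTYPE.get(feat.type)
        raw = _feature_name_from_qualifiers(feat)
        if ftype is None and raw is not None and canonical_gene_name(raw, synonyms) == "CR":
            ftype = "control_region"
        if raw is None:
            continue
        name = canonical_gene_name(raw, synonyms)
        if name is None:
            warnings.warn(f"unknown gene name {raw!r}; kept with ftype='other'")
            name, ftype = raw, "other"
        elif ftype is None:
            ftype = "other"
        if name == "CR":
            ftype = "control_region"
        start, end = _location_to_interval(feat.location, len(record.seq))
        counts[name] = counts.get(name, 0) + 1
        if "copy_index" in feat.qualifiers:
            ci = int(feat.qualifiers["copy_index"][0])
        else:
            ci = counts[name]
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GeneFeature(name, ftype, start, end, strand, ci))
    return Mitogenome(record.id or record.name, str(record.seq), circular, features)


def write_genbank(genome: Mitogenome, path: str | Path) -> None:
    record = SeqRecord(
        Seq(genome.sequence), id=genome.id, name=genome.id[:16], description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    L = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.end <= L:
            loc = FeatureLocation(f.start, f.end, strand=strand)
        else:
            p1 = FeatureLocation(f.start, L, strand=strand)
            p2 = FeatureLocation(0, f.end - L, strand=strand)
            loc = CompoundLocation([p1, p2] if strand == 1 else [p2, p1])
        quals = {"gene": [f.name]}
        if f.copy_index != 1 or any(
                g is not f and g.name == f.name for g in genome.features):
            quals["copy_index"] = [str(f.copy_index)]
        record.features.append(SeqFeature(loc, type=_FTYPE_TO_GB_TYPE[f.ftype],
                                          qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + tab-delimited feature table
# ---------------------------------------------------------------------------

def feature_table_path(fasta_path: str | Path) -> Path:
    return Path(fasta_path).with_suffix(".features.tsv")


def read_fasta_table(path: str | Path, table: str | Path | None = None,
                     synonyms: dict[str, str] | None = None) -> Mitogenome:
    if synonyms is None:
        synonyms = load_synonym_map()
    path = Path(path)
    table = feature_table_path(path) if table is None else Path(table)
    try:
        record = SeqIO.read(str(path), "fasta")
    except Exception as exc:
        raise MitoFormatError(f"cannot parse {path} as FASTA: {exc}") from exc
    features = []
    for row in _parse_tsv(table):
        name, ftype, start, end, strand, ci = row
        canon = canonical_gene_name(name, synonyms)
        if canon is None:
            warnings.warn(f"unknown gene name {name!r}; kept with ftype='other'")
            canon, ftype = name, "other"
        if canon == "CR":
            ftype = "control_region"
        features.append(GeneFeature(canon, ftype, int(start), int(end), strand, int(ci)))
    return Mitogenome(record.id, str(record.seq), True, features)


def _parse_tsv(table: Path) -> Iterable[list[str]]:
    if not table.exists():
        raise MitoFormatError(f"feature table {table} not found")
    with open(table) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise MitoFormatError(f"feature table row has {len(parts)} columns: {line!r}")
            yield parts


def write_fasta_table(genome: Mitogenome, path: str | Path,
                      table: str | Path | None = None) -> None:
    path = Path(path)
    table = feature_table_path(path) if table is None else Path(table)
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")
    with open(table, "w") as fh:
        fh.write("name\tftype\tstart\tend\tstrand\tcopy_index\n")
        for f in genome.features:
            fh.write(f"{f.name}\t{f.ftype}\t{f.start}\t{f.end}\t{f.strand}\t{f.copy_index}\n")


def read_mitogenome(path: str | Path, format: str = "genbank", **kwargs) -> Mitogenome:
    """Read an annotated mitogenome; ``format`` is 'genbank' or 'fasta+table'."""
    if format == "genbank":
        return read_genbank(path, **kwargs)
    if format == "fasta+table":
        return read_fasta_table(path, **kwargs)
    raise MitoFormatError(f"unknown format {format!r}")


def write_mitogenome(genome: Mitogenome, path: str | Path,
                     format: str = "genbank", **kwargs) -> None:
    if format == "genbank":
        write_genbank(genome, path)
    elif format == "fasta+table":
        write_fasta_table(genome, path, **kwargs)
    else:
        raise MitoFormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class GeneAlignment:
    """A per-gene multiple alignment: equal-length rows over {ACGTN-}."""

    gene: str
    taxa: list[str]
    rows: list[str]
    codon_aligned: bool = False

    def __post_init__(self) -> None:
        self.rows = [r.upper() for r in self.rows]
        if len(self.taxa) != len(self.rows):
            raise MitoValidationError("taxa and rows differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MitoValidationError(f"duplicate taxon ids: {dupes}")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise MitoValidationError("ragged alignment rows")
            if self.codon_aligned and n % 3 != 0:
                raise MitoValidationError("codon-aligned length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset(self, taxa: Sequence[str]) -> "GeneAlignment":
        return GeneAlignment(self.gene, list(taxa), [self.row(t) for t in taxa],
                             self.codon_aligned)


def read_alignment(path: str | Path, gene: str | None = None,
                   codon_aligned: bool = False) -> GeneAlignment:
    """Read a FASTA alignment; ``codon_aligned`` is declared by the caller,
    not inferred from content."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MitoFormatError(f"no sequences in {path}")
    gene = gene if gene is not None else Path(path).stem
    return GeneAlignment(gene, [r.id for r in records],
                         [str(r.seq) for r in records], codon_aligned)


def write_alignment(aln: GeneAlignment, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(row), id=taxon, description="")
         for taxon, row in zip(aln.taxa, aln.rows)],
        str(path), "fasta")
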