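"""Genome and feature I/O plus basic sequence utilities.

Reads/writes multi-record FASTA and GFF3 (the formats every downstream stage
consumes), and provides GC content, GC skew, and bacterial (table 11) CDS
translation.  Coordinates are 1-based inclusive at the file boundary (GFF3
dialect) and converted to 0-based half-open exactly once, inside the helpers
that slice sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data import CodonTable

__all__ = [
    "Contig",
    "Genome",
    "Feature",
    "ProteinSeq",
    "GenomeIOError",
    "read_genome",
    "write_genome",
    "read_protein_fasta",
    "write_protein_fasta",
    "gc_content",
    "gc_skew",
    "translate",
    "feature_sequence",
]

_DNA_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


class GenomeIOError(ValueError):
    """Raised for malformed files or coordinate violations."""


@dataclass
class Contig:
    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"contig {self.contig_id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            # IUPAC ambiguity codes other than N are squashed to N so that
            # downstream base counts stay deterministic.
            warnings.warn(
                f"contig {self.contig_id!r}: normalizing ambiguous bases "
                f"{sorted(bad)} to N"
            )
            seq = "".join(c if c in _DNA_ALPHABET else "N" for c in seq)
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    genome_id: str
    contigs: list[Contig] = field(default_factory=list)
    clade_label: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise GenomeIOError(f"genome {self.genome_id!r}: duplicate contig ids")

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class Feature:
    """An annotated gene feature; start/end are 1-based inclusive."""

    feature_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""
    is_pseudo: bool = False
    is_partial: bool = False
    pseudo_source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise GenomeIOError(
                f"feature {self.feature_id!r}: bad coordinates "
                f"{self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise GenomeIOError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinSeq:
    protein_id: str
    residues: str
    source_feature: Optional[str] = None
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise GenomeIOError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.residues) - _AA_ALPHABET
        if bad:
            raise GenomeIOError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}"
            )
        internal = self.residues[:-1]
        if "*" in internal:
            self.partial = True
        if self.residues.count("*") > 1 or (
            "*" in internal and not self.residues.endswith("*")
        ):
            # more than one stop, or a stop that is not trailing: keep the
            # sequence but make sure it is flagged rather than rejected
            self.partial = True

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _parse_gff3_line(line: str, lineno: int, genome_id: str) -> Optional[Feature]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise GenomeIOError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
    contig_id, _source, ftype, start, end, _score, strand, _phase, attrs = cols
    kind = ftype if ftype in {"CDS", "rRNA", "tRNA"} else "other"
    if ftype in {"gene", "region", "exon"}:
        return None  # container rows; CDS/RNA rows carry the coordinates we use
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise GenomeIOError(f"GFF3 line {lineno}: non-integer coordinates") from exc
    attr_map: dict[str, str] = {}
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attr_map[k.strip()] = v.strip()
    pseudo_source = None
    if attr_map.get("pseudo", "").lower() == "true":
        pseudo_source = "pseudo=true"
    elif "pseudogene" in attr_map:
        pseudo_source = "pseudogene attribute"
    fid = attr_map.get("ID") or attr_map.get("locus_tag") or f"feat_{lineno}"
    return Feature(
        feature_id=fid,
        genome_id=genome_id,
        contig_id=contig_id,
        start=start_i,
        end=end_i,
        strand=strand if strand in {"+", "-"} else "+",
        kind=kind,
        product=attr_map.get("product", ""),
        is_pseudo=pseudo_source is not None,
        is_partial=attr_map.get("partial", "").lower() == "true",
        pseudo_source=pseudo_source,
    )


def read_genome(
    fasta_path: str | Path,
    gff_path: Optional[str | Path] = None,
    genome_id: Optional[str] = None,
) -> tuple[Genome, list[Feature]]:
    """Read a genome FASTA and (optionally) its GFF3 feature table.

    Coordinates are preserved exactly as in the GFF3 (1-based inclusive) and
    validated against the contig lengths.
    """
    fasta_path = Path(fasta_path)
    gid = genome_id or fasta_path.stem
    contigs: list[Contig] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        contigs.append(Contig(contig_id=rec.id, sequence=str(rec.seq)))
    if not contigs:
        raise GenomeIOError(f"{fasta_path}: no FASTA records")
    genome = Genome(genome_id=gid, contigs=contigs)

    features: list[Feature] = []
    if gff_path is not None:
        lengths = {c.contig_id: len(c) for c in contigs}
        with open(gff_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                feat = _parse_gff3_line(line, lineno, gid)
                if feat is None:
                    continue
                if feat.contig_id not in lengths:
                    raise GenomeIOError(
                        f"GFF3 line {lineno}: contig {feat.contig_id!r} not in FASTA"
                    )
                if feat.end > lengths[feat.contig_id]:
                    raise GenomeIOError(
                        f"GFF3 line {lineno}: end {feat.end} beyond contig "
                        f"{feat.contig_id!r} length {lengths[feat.contig_id]}"
                    )
                features.append(feat)
        seen: set[str] = set()
        for f in features:
            if f.feature_id in seen:
                raise GenomeIOError(f"duplicate feature id {f.feature_id!r}")
            seen.add(f.feature_id)
    return genome, features


def write_genome(
    genome: Genome,
    features: Iterable[Feature],
    fasta_path: str | Path,
    gff_path: Optional[str | Path] = None,
) -> None:
    with open(fasta_path, "w") as fh:
        for c in genome.contigs:
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")
    if gff_path is None:
        return
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.contigs:
            fh.write(f"##sequence-region {c.contig_id} 1 {len(c)}\n")
        for f in features:
            attrs = [f"ID={f.feature_id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.is_pseudo:
                attrs.append("pseudo=true")
            if f.is_partial:
                attrs.append("partial=true")
            ftype = f.kind if f.kind != "other" else "misc_feature"
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "dehalopan",
                        ftype,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_protein_fasta(path: str | Path) -> list[ProteinSeq]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ProteinSeq(protein_id=rec.id, residues=str(rec.seq).upper()))
    return out


def write_protein_fasta(proteins: Iterable[ProteinSeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n{p.residues}\n")


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def gc_content(genome: Genome | Contig | str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from numerator and denominator."""
    if isinstance(genome, Genome):
        seq = "".join(c.sequence for c in genome.contigs)
    elif isinstance(genome, Contig):
        seq = genome.sequence
    else:
        seq = genome.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise GenomeIOError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


def gc_skew(
    contig: Contig, window: int = 10000, step: Optional[int] = None
) -> tuple[list[tuple[float, float]], list[float]]:
    """Windowed (G-C)/(G+C) skew plus its cumulative running sum.

    Returns ``([(midpoint, skew), ...], cumulative)``.  Windows with no G or
    C report 0 skew.
    """
    if window <= 0:
        raise GenomeIOError("window must be positive")
    if window > len(contig):
        raise GenomeIOError("window exceeds contig length")
    if step is None:
        step = window
    if step <= 0:
        raise GenomeIOError("step must be positive")
    seq = contig.sequence
    points: list[tuple[float, float]] = []
    cumulative: list[float] = []
    running = 0.0
    for start in range(0, len(seq) - window + 1, step):
        win = seq[start : start + window]
        g, c = win.count("G"), win.count("C")
        skew = 0.0 if g + c == 0 else (g - c) / (g + c)
        running += skew
        points.append((start + window / 2, skew))
        cumulative.append(running)
    return points, cumulative


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def feature_sequence(feature: Feature, genome: Genome) -> str:
    """Strand-aware nucleotide sequence of a feature (5'->3')."""
    contig = genome.contig(feature.contig_id)
    # single 1-based -> 0-based half-open conversion point
    sub = contig.sequence[feature.start - 1 : feature.end]
    if feature.strand == "-":
        sub = reverse_complement(sub)
    return sub


def translate(feature: Feature, genome: Genome) -> ProteinSeq:
    """Translate a CDS with the bacterial genetic code (table 11).

    Minus-strand features are reverse complemented first.  A length not
    divisible by 3 or an internal stop sets the partial flag; nothing raises.
    Alternative start codons are rendered as M only at position 1.
    """
    nt = feature_sequence(feature, genome)
    partial = len(nt) % 3 != 0
    nt_trim = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt_trim).translate(table=11))
    first_codon = nt_trim[:3]
    if aa and first_codon in _TABLE11.start_codons:
        aa = "M" + aa[1:]
    if aa.endswith("*"):
        body = aa[:-1]
    else:
        body = aa
        partial = True  # no terminal stop: annotation is likely truncated
    if "*" in body:
        partial = True
    prot = ProteinSeq(
        protein_id=feature.feature_id,
        residues=aa if aa else "X",
        source_feature=feature.feature_id,
        partial=partial,
    )
    prot.partial = prot.partial or partial or feature.is_partial
    return prot
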