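"""Circular mitochondrial genome model and feature annotation.

Animal mitochondrial genomes are small (~16 kb), circular molecules densely
packed with protein-coding genes (PCGs), two rRNA genes, ~22 tRNA genes, and
unassigned regions (URs) in between.  This module provides a wrap-aware
coordinate model (1-based, inclusive, GFF3 convention), re-annotation of URs
as the exact complement of the gene features, and the midpoint rule used to
categorize a small-RNA locus as ribosomal ('r'), tRNA ('t') or non-coding
('nc').

Wrap-around features on a circular genome are represented with ``end <
start`` and expanded internally to two arcs for coverage arithmetic.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

__all__ = [
    "CircularGenome",
    "GenomeFeature",
    "AnnotationSet",
    "reverse_complement",
    "circular_subseq",
    "reannotate_urs",
    "locus_category",
    "read_fasta_genome",
    "read_gff3",
    "read_bed",
    "write_gff3",
]

GENE_TYPES = ("PCG", "rRNA", "tRNA")
REGION_TYPES = ("PCG", "rRNA", "tRNA", "UR", "smithRNA", "pre_smithRNA")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    """Reverse complement; U is accepted and complemented like T (output is
    always in the DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and normalize U -> T (all internal sequences are DNA)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class CircularGenome:
    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_count(self) -> int:
        return self.sequence.count("N")


@dataclass(frozen=True)
class GenomeFeature:
    """A feature in 1-based inclusive coordinates; end < start means the
    feature wraps the origin of a circular genome."""

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.ftype not in REGION_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates are 1-based (>= 1)")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def arcs(self, genome_length: int) -> list[tuple[int, int]]:
        """Expand to non-wrapping (start, end) arcs."""
        if self.wraps:
            return [(self.start, genome_length), (1, self.end)]
        return [(self.start, self.end)]

    def span(self, genome_length: int) -> int:
        return sum(e - s + 1 for s, e in self.arcs(genome_length))

    def contains(self, pos: int, genome_length: int) -> bool:
        return any(s <= pos <= e for s, e in self.arcs(genome_length))


@dataclass
class AnnotationSet:
    genome_id: str
    features: list[GenomeFeature] = field(default_factory=list)

    def by_type(self, *ftypes: str) -> list[GenomeFeature]:
        return [f for f in self.features if f.ftype in ftypes]

    @property
    def has_urs(self) -> bool:
        return any(f.ftype == "UR" for f in self.features)

    def features_at(self, pos: int, genome_length: int) -> list[GenomeFeature]:
        return [f for f in self.features if f.contains(pos, genome_length)]


def circular_subseq(genome: CircularGenome, start: int, end: int, strand: str = "+") -> str:
    """Wrap-aware subsequence in 1-based inclusive coordinates.

    With ``end < start`` the subsequence wraps the origin (circular genomes
    only).  On the minus strand the reverse complement of the plus-strand
    subsequence is returned.
    """
    L = genome.length
    if not (1 <= start <= L and 1 <= end <= L):
        raise IndexError(f"positions ({start}, {end}) out of range 1..{L}")
    if strand not in "+-":
        raise ValueError("strand must be + or -")
    if end >= start:
        sub = genome.sequence[start - 1 : end]
    else:
        if not genome.circular:
            raise ValueError("wrap-around subsequence requested on a non-circular genome")
        sub = genome.sequence[start - 1 :] + genome.sequence[:end]
    return reverse_complement(sub) if strand == "-" else sub


def interval_midpoint(start: int, end: int, genome_length: int) -> int:
    """Midpoint of a (possibly wrapping) 1-based inclusive interval, computed
    on the unrolled arc."""
    if end >= start:
        ilen = end - start + 1
    else:
        ilen = genome_length - start + 1 + end
    return (start - 1 + (ilen - 1) // 2) % genome_length + 1


def _covered_positions(features, genome_length: int) -> set[int]:
    covered: set[int] = set()
    for f in features:
        for s, e in f.arcs(genome_length):
            covered.update(range(s, e + 1))
    return covered


def reannotate_urs(annotation: AnnotationSet, genome: CircularGenome) -> AnnotationSet:
    """Add UR features covering exactly the positions not covered by any
    PCG/rRNA/tRNA gene feature.

    smithRNA / pre_smithRNA features are overlays and do not mask URs.
    Existing UR features are discarded and recomputed, so the operation is
    idempotent.  An empty gene set yields a single genome-spanning UR.
    """
    L = genome.length
    genes = annotation.by_type(*GENE_TYPES)
    overlays = annotation.by_type("smithRNA", "pre_smithRNA")

    # warn on overlapping gene features (permitted but suspicious)
    cov_count: dict[int, int] = {}
    for f in genes:
        for s, e in f.arcs(L):
            for p in range(s, e + 1):
                cov_count[p] = cov_count.get(p, 0) + 1
    if any(c > 1 for c in cov_count.values()):
        warnings.warn("overlapping gene features in annotation", stacklevel=2)

    covered = set(cov_count)
    gaps = sorted(set(range(1, L + 1)) - covered)

    urs: list[GenomeFeature] = []
    if not gaps:
        pass
    elif len(gaps) == L:
        urs.append(GenomeFeature("UR1", "UR", 1, L, "+"))
    else:
        # maximal runs of consecutive uncovered positions
        runs: list[list[int]] = []
        run = [gaps[0], gaps[0]]
        for p in gaps[1:]:
            if p == run[1] + 1:
                run[1] = p
            else:
                runs.append(run)
                run = [p, p]
        runs.append(run)
        # merge a run ending at L with a run starting at 1 into a wrapping UR
        if genome.circular and len(runs) > 1 and runs[0][0] == 1 and runs[-1][1] == L:
            first = runs.pop(0)
            runs[-1] = [runs[-1][0], first[1]]
        urs = [
            GenomeFeature(f"UR{i}", "UR", s, e, "+")
            for i, (s, e) in enumerate(sorted(runs), start=1)
        ]

    return AnnotationSet(annotation.genome_id, genes + urs + overlays)


#: midpoint category per covering feature type
_CATEGORY = {"rRNA": "r", "tRNA": "t", "UR": "nc", "PCG": "cds"}
#: when the midpoint is covered by several base features, narrow beats broad
_CATEGORY_PRECEDENCE = ("tRNA", "rRNA", "UR", "PCG")


def locus_category(
    annotation: AnnotationSet, start: int, end: int, strand: str, genome_length: int
) -> str:
    """Category of a candidate locus by the feature covering its midpoint:
    'r' (rRNA), 't' (tRNA), 'nc' (UR), or 'cds' (inside a protein-coding
    gene; an internal label, the naming scheme only prints r/t/nc)."""
    if not annotation.has_urs:
        raise ValueError("annotation has no URs; run reannotate_urs first")
    mid = interval_midpoint(start, end, genome_length)
    hits = {
        f.ftype
        for f in annotation.features_at(mid, genome_length)
        if f.ftype in _CATEGORY
    }
    for ftype in _CATEGORY_PRECEDENCE:
        if ftype in hits:
            return _CATEGORY[ftype]
    raise ValueError(
        f"midpoint {mid} covered by no base feature (is the annotation re-annotated?)"
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta_genome(path, circular: bool = True) -> CircularGenome:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return CircularGenome(rec.id, str(rec.seq), circular=circular)


def read_gff3(path, genome_id: str | None = None) -> AnnotationSet:
    """Minimal GFF3 reader: seqid, type, start, end, strand and a Name/ID
    attribute.  Feature types are matched case-insensitively against the six
    region types."""
    type_map = {t.lower(): t for t in REGION_TYPES}
    type_map.update({"gene": "PCG", "cds": "PCG", "trna": "tRNA", "rrna": "rRNA",
                     "region": "UR", "ur": "UR"})
    feats = []
    gid = genome_id
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                continue
            seqid, _source, ftype, start, end, _score, strand, _phase = cols[:8]
            attrs = cols[8] if len(cols) > 8 else ""
            if gid is None:
                gid = seqid
            ftype_norm = type_map.get(ftype.lower())
            if ftype_norm is None:
                continue
            name = seqid
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k.strip() in ("Name", "ID", "gene"):
                        name = v.strip()
                        break
            feats.append(
                GenomeFeature(name, ftype_norm, int(start), int(end),
                              strand if strand in "+-" else "+")
            )
    return AnnotationSet(gid or "genome", feats)


def read_bed(path, genome_id: str = "genome", ftype_col: int | None = None) -> AnnotationSet:
    """3- or 6-column BED (0-based half-open) -> 1-based inclusive features.

    The feature type is taken from the name column when it matches a region
    type (e.g. ``tRNA``), otherwise from ``ftype_col`` if given, else 'PCG'.
    """
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            start = int(cols[1]) + 1
            end = int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{cols[0]}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            if ftype_col is not None and len(cols) > ftype_col:
                ftype = cols[ftype_col]
            elif name in REGION_TYPES:
                ftype = name
            else:
                ftype = "PCG"
            feats.append(GenomeFeature(name, ftype, start, end, strand))
    return AnnotationSet(genome_id, feats)


_GFF_SOURCE = "smithrna"


def write_gff3(annotation: AnnotationSet, path, genome_length: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome_length:
            fh.write(f"##sequence-region {annotation.genome_id} 1 {genome_length}\n")
        for f in sorted(annotation.features, key=lambda f: (f.start, f.end, f.ftype)):
            fh.write(
                f"{annotation.genome_id}\t{_GFF_SOURCE}\t{f.ftype}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\tName={f.name}\n"
            )


def write_bed(annotation: AnnotationSet, path, genome_length: int) -> None:
    """6-column BED export (0-based half-open); wrapping features are split
    into two arcs."""
    with open(path, "w") as fh:
        for f in sorted(annotation.features, key=lambda f: (f.start, f.end)):
            if f.wraps:
                print(f"wrapping feature {f.name} split into two BED rows",
                      file=sys.stderr)
            for s, e in f.arcs(genome_length):
                fh.write(
                    f"{annotation.genome_id}\t{s - 1}\t{e}\t{f.name}\t0\t{f.strand}\n"
                )
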