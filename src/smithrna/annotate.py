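"""Assembly of surviving read clusters and their target hits into named
smithRNA candidates, with pre-smithRNA genomic context and standard-format
outputs.

Naming follows the ``<species>_<sex>_smithRNA<number><category>`` scheme:
the number is the 100-based genomic position of the candidate's 5' end
(floor(start / 100)) and the category suffix is 'r' (ribosomal gene), 't'
(tRNA gene) or 'nc' (unassigned region), decided by the midpoint rule.  Name
collisions (distinct candidates mapping within the same 100-bp bin) receive
letter suffixes a, b, ...

The pre-smithRNA region is the 70-bp window centered on the mature candidate
(wrap-aware; uneven overhang goes to the 5' flank), except for tRNA-category
candidates, where it is the whole containing tRNA gene extended through any
flanking unassigned nucleotides up to the neighboring gene features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .energy import EnergyModel, TURNER_LIKE, fold_mfe, to_rna
from .genome import (
    AnnotationSet,
    CircularGenome,
    GenomeFeature,
    circular_subseq,
    interval_midpoint,
    locus_category,
)
from .pipeline import ReadCluster, SharpnessReport
from .targets import TargetHit

__all__ = [
    "CandidateSmithRNA",
    "extract_pre_region",
    "name_candidate",
    "fold_context",
    "assemble_candidates",
    "write_outputs",
]


@dataclass
class CandidateSmithRNA:
    species: str  # 4-letter tag, e.g. DaRe
    sex: str      # F or M
    name: str
    sequence: str  # mature candidate, RNA alphabet
    start: int
    end: int
    strand: str
    category: str
    cluster_size: int
    sharpness: SharpnessReport | None
    targets: list[TargetHit] = field(default_factory=list)
    pre_start: int = 0
    pre_end: int = 0
    pre_sequence: str = ""
    fold: str | None = None


def name_candidate(species: str, sex: str, start: int, category: str) -> str:
    """Candidate name from the 100-based position of its 5' genomic
    coordinate: e.g. (DaRe, F, 1020, r) -> DaRe_F_smithRNA10r."""
    if sex not in ("F", "M"):
        raise ValueError("sex tag must be F or M")
    return f"{species}_{sex}_smithRNA{start // 100}{category}"


def _interval_length(start: int, end: int, L: int) -> int:
    return end - start + 1 if end >= start else L - start + 1 + end


def extract_pre_region(
    start: int,
    end: int,
    strand: str,
    category: str,
    annotation: AnnotationSet,
    genome: CircularGenome,
    pre_length: int = 70,
) -> tuple[int, int, str]:
    """Pre-smithRNA region (start, end, sequence) for a candidate locus.

    Default: the ``pre_length`` window centered on the candidate, wrap-aware;
    the candidate sits centrally with any odd overhang on the 5' flank.  The
    window may extend into neighboring gene features (e.g. the 3' region of
    an upstream tRNA when the candidate maps at the very start of a gene).
    For tRNA-category candidates: the whole containing tRNA feature extended
    through adjacent UR nucleotides up to the next gene features.
    """
    L = genome.length
    cand_len = _interval_length(start, end, L)
    if pre_length < cand_len:
        raise ValueError(f"pre_length {pre_length} shorter than candidate ({cand_len})")

    if category == "t":
        mid = interval_midpoint(start, end, L)
        trnas = [f for f in annotation.by_type("tRNA") if f.contains(mid, L)]
        if trnas:
            t = trnas[0]
            ur_positions = set()
            for f in annotation.by_type("UR"):
                for s, e in f.arcs(L):
                    ur_positions.update(range(s, e + 1))
            p_start, p_end = t.start, t.end
            # extend 5' through unassigned nucleotides
            while ((p_start - 2) % L + 1) in ur_positions:
                p_start = (p_start - 2) % L + 1
                if _interval_length(p_start, p_end, L) >= L:
                    break
            while (p_end % L + 1) in ur_positions:
                p_end = p_end % L + 1
                if _interval_length(p_start, p_end, L) >= L:
                    break
            seq = circular_subseq(genome, p_start, p_end, strand)
            return p_start, p_end, seq

    extra = pre_length - cand_len
    left = (extra + 1) // 2  # odd overhang goes 5' of the + strand arc
    p_start = (start - 1 - left) % L + 1
    p_end = (p_start - 1 + pre_length - 1) % L + 1
    seq = circular_subseq(genome, p_start, p_end, strand)
    return p_start, p_end, seq


def fold_context(
    pre_sequence: str,
    min_hairpin: int = 3,
    temperature: float = 25.0,
    model: EnergyModel = TURNER_LIKE,
) -> tuple[str, int]:
    """Illustrative secondary structure (dot-bracket) of a pre-smithRNA
    region and its base-pair count.  ``temperature`` is recorded metadata:
    the simplified score table is temperature-fixed."""
    if len(pre_sequence) < 10:
        raise ValueError("sequence too short to fold")
    _, db = fold_mfe(pre_sequence, min_hairpin=min_hairpin, model=model)
    return db, db.count("(")


def assemble_candidates(
    survivors: list[tuple[ReadCluster, SharpnessReport]],
    hits_by_centroid: dict[str, list[TargetHit]],
    annotation: AnnotationSet,
    genome: CircularGenome,
    species: str,
    sex: str,
    pre_length: int = 70,
    fold: bool = True,
) -> list[CandidateSmithRNA]:
    """Build named candidates from clusters that passed the size and
    sharpness filters; candidates without surviving targets are dropped."""
    cands: list[CandidateSmithRNA] = []
    for cluster, report in survivors:
        targets = hits_by_centroid.get(cluster.centroid, [])
        if not targets:
            continue
        category = locus_category(
            annotation, cluster.start, cluster.end, cluster.strand, genome.length
        )
        five_prime = cluster.start if cluster.strand == "+" else cluster.end
        name = name_candidate(species, sex, five_prime, category)
        p_start, p_end, p_seq = extract_pre_region(
            cluster.start, cluster.end, cluster.strand, category,
            annotation, genome, pre_length,
        )
        cand = CandidateSmithRNA(
            species=species, sex=sex, name=name,
            sequence=to_rna(cluster.centroid),
            start=cluster.start, end=cluster.end, strand=cluster.strand,
            category=category, cluster_size=cluster.size, sharpness=report,
            targets=targets, pre_start=p_start, pre_end=p_end,
            pre_sequence=to_rna(p_seq),
        )
        if fold:
            cand.fold = fold_context(cand.pre_sequence)[0]
        cands.append(cand)

    # letter suffixes for name collisions, in locus order
    cands.sort(key=lambda c: (c.start, c.end, c.strand))
    by_name: dict[str, list[CandidateSmithRNA]] = {}
    for c in cands:
        by_name.setdefault(c.name, []).append(c)
    for name, group in by_name.items():
        if len(group) > 1:
            for suffix, c in zip("abcdefghijklmnopqrstuvwxyz", group):
                c.name = f"{name}{suffix}"
    return cands


def write_outputs(
    candidates: list[CandidateSmithRNA],
    genome_id: str,
    prefix: str,
    bed12: bool = False,
) -> dict[str, str]:
    """GFF3 (mature + pre features), FASTA (mature and pre, RNA alphabet) and
    a TSV report, deterministically ordered by locus.  Returns the paths."""
    cands = sorted(candidates, key=lambda c: (c.start, c.end, c.strand))
    paths = {"gff3": f"{prefix}.gff3", "fasta": f"{prefix}.fasta",
             "tsv": f"{prefix}.tsv"}

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for c in cands:
            fh.write(f"{genome_id}\tsmithrna\tsmithRNA\t{c.start}\t{c.end}\t.\t"
                     f"{c.strand}\t.\tID={c.name}\n")
            fh.write(f"{genome_id}\tsmithrna\tpre_smithRNA\t{c.pre_start}\t"
                     f"{c.pre_end}\t.\t{c.strand}\t.\tID=pre_{c.name}\n")

    with open(paths["fasta"], "w") as fh:
        for c in cands:
            fh.write(f">{c.name}\n{c.sequence}\n")
            fh.write(f">pre_{c.name}\n{c.pre_sequence}\n")

    with open(paths["tsv"], "w") as fh:
        fh.write("name\tstart\tend\tstrand\tcategory\tcluster_size\t"
                 "frac5\tfrac3\tn_targets\tbest_dG\tbest_ddG\tfold\n")
        for c in cands:
            best_dg = min((t.dg_duplex for t in c.targets), default=float("nan"))
            best_ddg = min((t.ddg for t in c.targets), default=float("nan"))
            f5 = f"{c.sharpness.frac_five:.4f}" if c.sharpness else "NA"
            f3 = f"{c.sharpness.frac_three:.4f}" if c.sharpness else "NA"
            fh.write(
                f"{c.name}\t{c.start}\t{c.end}\t{c.strand}\t{c.category}\t"
                f"{c.cluster_size}\t{f5}\t{f3}\t{len(c.targets)}\t"
                f"{best_dg:.2f}\t{best_ddg:.2f}\t{c.fold or '.'}\n"
            )

    if bed12:
        paths["bed12"] = f"{prefix}.bed12"
        with open(paths["bed12"], "w") as fh:
            for c in cands:
                if c.end >= c.start:
                    fh.write(
                        f"{genome_id}\t{c.start - 1}\t{c.end}\t{c.name}\t0\t"
                        f"{c.strand}\t{c.start - 1}\t{c.end}\t0\t1\t"
                        f"{c.end - c.start + 1},\t0,\n"
                    )
    return paths
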