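"""Synthetic data generators for every pipeline stage, with ground truth.

The generators emulate the statistical structure of the study system:

* a ~16-kb annotated circular mitogenome with protein-coding, rRNA and tRNA
  genes on both strands and interspersed unassigned regions (URs);
* population amplicon alignments in which URs evolve several-fold faster
  than coding regions (per-site, per-sequence substitutions at rate
  mu x region multiplier; Jukes-Cantor-like, no indels);
* small-RNA libraries with sharply ended read pileups at chosen loci plus a
  diffuse uniform background;
* 3' UTR collections with planted target sites (perfect complement,
  seed-only, or none);
* assay measurement tables with group shifts, a sex effect and Gaussian
  noise.

All generators are pure functions of their seed and parameters and return a
truth record sufficient to score sensitivity/specificity of each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import SequenceAlignment
from .genome import (
    AnnotationSet,
    CircularGenome,
    GenomeFeature,
    circular_subseq,
    reannotate_urs,
    reverse_complement,
)
from .pipeline import SmallRead

__all__ = [
    "PlantedLocus",
    "PlantedTarget",
    "SyntheticTruth",
    "default_gene_plan",
    "plant_loci",
    "region_labels",
    "simulate_conservation_system",
    "simulate_genome",
    "simulate_population",
    "simulate_reads",
    "simulate_utrome",
    "simulate_assay",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedLocus:
    start: int
    end: int
    strand: str
    sequence: str
    depth: int
    end_noise: float


@dataclass
class PlantedTarget:
    utr_id: str
    site_start: int
    site_end: int
    plant_type: str  # perfect | seed_only | none
    centroid: str


@dataclass
class SyntheticTruth:
    loci: list[PlantedLocus] = field(default_factory=list)
    targets: list[PlantedTarget] = field(default_factory=list)
    region_multipliers: dict[str, float] = field(default_factory=dict)
    assay_effects: dict[str, float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def default_gene_plan(length: int = 16000) -> list[tuple[str, str, int, str]]:
    """A compact animal-mitogenome-like plan: 13 PCGs, 2 rRNAs, 22 tRNAs on
    both strands, scaled to fill ~85% of ``length`` (URs fill the rest --
    generous UR abundance, as in bivalve mtDNAs)."""
    pcg_lens = [1540, 1140, 780, 680, 1370, 520, 890, 680, 230, 290, 350, 160, 560]
    plan: list[tuple[str, str, int, str]] = []
    for i, ln in enumerate(pcg_lens):
        plan.append((f"pcg{i + 1}", "PCG", ln, "+" if i % 3 else "-"))
    plan.append(("rrnS", "rRNA", 830, "+"))
    plan.append(("rrnL", "rRNA", 1290, "+"))
    for i in range(22):
        plan.append((f"trn{i + 1}", "tRNA", 66 + (i % 3) * 3, "+" if i % 2 else "-"))
    total = sum(p[2] for p in plan)
    scale = (0.85 * length) / total
    plan = [(n, t, max(30, int(ln * scale)), s) for n, t, ln, s in plan]
    if sum(p[2] for p in plan) > length:
        raise ValueError(f"length {length} too short for the default plan")
    return plan


def simulate_genome(
    seed: int,
    length: int = 16000,
    gene_plan: list[tuple[str, str, int, str]] | None = None,
    ur_concentration: float = 0.5,
) -> tuple[CircularGenome, AnnotationSet]:
    """Random circular genome with the plan's features placed in order,
    separated by UR gaps sized to fill the remaining length; URs are then
    re-annotated as the exact complement of the genes.

    ``ur_concentration`` is the Dirichlet concentration for splitting the
    inter-gene slack: values < 1 give a few large URs and many tiny ones, the
    pattern typical of bivalve mtDNAs.
    """
    rng = np.random.default_rng(seed)
    plan = gene_plan if gene_plan is not None else default_gene_plan(length)
    total_genes = sum(p[2] for p in plan)
    if total_genes > length:
        raise ValueError(f"gene plan ({total_genes} bp) exceeds genome length {length}")
    slack = length - total_genes
    gaps = rng.multinomial(slack, rng.dirichlet([ur_concentration] * len(plan)))
    seq = _random_seq(rng, length)
    feats: list[GenomeFeature] = []
    pos = 1
    for (name, ftype, ln, strand), gap in zip(plan, gaps):
        pos += int(gap)
        feats.append(GenomeFeature(name, ftype, pos, pos + ln - 1, strand))
        pos += ln
    genome = CircularGenome(f"sim_mt_{seed}", seq)
    annotation = reannotate_urs(AnnotationSet(genome.id, feats), genome)
    return genome, annotation


# ---------------------------------------------------------------------------
# population alignments
# ---------------------------------------------------------------------------

def region_labels(annotation: AnnotationSet, length: int) -> list[tuple[int, int, str]]:
    """(start, end, ftype) blocks covering the genome, for window labeling."""
    out = []
    for f in annotation.features:
        for s, e in f.arcs(length):
            out.append((s, e, f.ftype))
    return sorted(out)


def simulate_population(
    genome: CircularGenome,
    annotation: AnnotationSet,
    n_seqs: int = 40,
    mu: float = 0.005,
    multipliers: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[SequenceAlignment, SyntheticTruth]:
    """Alignment of ``n_seqs`` haplotypes derived from the genome sequence by
    independent per-site substitutions at rate mu x multiplier(region).

    ``multipliers`` maps region types to rate multipliers (default 1
    everywhere; the study-like contrast uses {"UR": 5}).  Substitutions are
    Jukes-Cantor-like: a mutated site takes one of the three other bases
    uniformly.  No indels.
    """
    if mu >= 0.05:
        raise ValueError("mu must be small (< 0.05)")
    rng = np.random.default_rng(seed)
    mult = {t: 1.0 for t in ("PCG", "rRNA", "tRNA", "UR", "smithRNA", "pre_smithRNA")}
    if multipliers:
        mult.update(multipliers)
    L = genome.length
    from .diversity import REGION_PRECEDENCE

    site_rate = np.full(L, mu)
    # precedence: overlays (smithRNA/pre) override base features
    blocks = region_labels(annotation, L)
    rank = {t: i for i, t in enumerate(REGION_PRECEDENCE)}
    site_label = [""] * L
    for s, e, t in sorted(blocks, key=lambda b: -rank.get(b[2], 99)):
        for p in range(s - 1, e):
            site_label[p] = t
    for p in range(L):
        site_rate[p] = mu * mult.get(site_label[p], 1.0)

    base = np.array(list(genome.sequence))
    base_codes = np.searchsorted(_BASES, base)
    rows = []
    for _ in range(n_seqs):
        hit = rng.random(L) < site_rate
        row = base_codes.copy()
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            row[hit] = (row[hit] + shift) % 4
        rows.append("".join(_BASES[row]))
    ids = [f"hap{i + 1}" for i in range(n_seqs)]
    truth = SyntheticTruth(region_multipliers={k: mult[k] for k in mult})
    return SequenceAlignment(ids, rows), truth


# ---------------------------------------------------------------------------
# small-RNA reads
# ---------------------------------------------------------------------------

def plant_loci(
    genome: CircularGenome,
    annotation: AnnotationSet,
    n_loci: int = 3,
    length_range: tuple[int, int] = (20, 24),
    min_separation: int = 200,
    seed: int = 0,
) -> list[tuple[int, int, str]]:
    """Choose ``n_loci`` well-separated small-RNA loci inside rRNA, tRNA and
    UR features (cycling through the three categories), away from feature
    boundaries, alternating strands.  Returns (start, end, strand) tuples."""
    rng = np.random.default_rng(seed)
    pools = {
        "rRNA": annotation.by_type("rRNA"),
        "tRNA": annotation.by_type("tRNA"),
        "UR": [f for f in annotation.by_type("UR")
               if f.span(genome.length) >= length_range[1] + 4],
    }
    order = ["rRNA", "tRNA", "UR"]
    chosen: list[tuple[int, int, str]] = []
    attempts = 0
    while len(chosen) < n_loci and attempts < 1000:
        attempts += 1
        ftype = order[len(chosen) % 3]
        feats = pools[ftype]
        if not feats:
            continue
        f = feats[int(rng.integers(len(feats)))]
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        arcs = [(s, e) for s, e in f.arcs(genome.length) if e - s + 1 >= ln + 2]
        if not arcs:
            continue
        s, e = arcs[int(rng.integers(len(arcs)))]
        margin = max(1, (e - s + 1 - ln) // 2)
        start = int(rng.integers(s + 1, max(s + 2, e - ln)))
        end = start + ln - 1
        if end > genome.length:
            continue
        if any(abs(start - c[0]) < min_separation for c in chosen):
            continue
        strand = "+" if len(chosen) % 2 == 0 else "-"
        chosen.append((start, end, strand))
    if len(chosen) < n_loci:
        raise ValueError("could not place the requested loci; relax constraints")
    return chosen

def simulate_reads(
    genome: CircularGenome,
    loci: list[tuple[int, int, str]],
    depth: int = 250,
    end_noise: float = 0.0,
    n_background: int = 500,
    background_lengths: tuple[int, int] = (15, 40),
    seed: int = 0,
) -> tuple[list[SmallRead], SyntheticTruth]:
    """Reads for each planted locus (start, end, strand) at the given depth,
    with 5'/3' ends independently jittered (each end shifted by +/-1 with
    probability ``end_noise``), plus ``n_background`` reads drawn uniformly
    from both strands of the genome.  Qualities are constant when written as
    FASTQ."""
    rng = np.random.default_rng(seed)
    L = genome.length
    reads: list[SmallRead] = []
    truth = SyntheticTruth()
    for li, (start, end, strand) in enumerate(loci):
        seq = circular_subseq(genome, start, end, strand)
        truth.loci.append(PlantedLocus(start, end, strand, seq, depth, end_noise))
        for ri in range(depth):
            s, e = start, end
            if end_noise > 0:
                if rng.random() < end_noise:
                    s = (s - 1 + rng.choice([-1, 1])) % L + 1
                if rng.random() < end_noise:
                    e = (e - 1 + rng.choice([-1, 1])) % L + 1
            reads.append(
                SmallRead(f"locus{li + 1}_r{ri + 1}",
                          circular_subseq(genome, s, e, strand))
            )
    lo, hi = background_lengths
    for bi in range(n_background):
        ln = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, L + 1))
        end = (start - 1 + ln - 1) % L + 1
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(
            SmallRead(f"bg_r{bi + 1}", circular_subseq(genome, start, end, strand))
        )
    return reads, truth


def write_fastq(reads: list[SmallRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def simulate_conservation_system(
    seed: int,
    length: int = 6000,
    n_loci: int = 6,
) -> tuple[CircularGenome, AnnotationSet, list[tuple[int, int, str]]]:
    """Genome + annotation carrying all six region types, for conservation
    analyses: planted smithRNA loci and their pre-smithRNA context windows
    are overlaid on the gene/UR annotation.  Returns (genome, annotation,
    region blocks) with blocks as (start, end, label) for window labeling."""
    from .annotate import extract_pre_region
    from .simulate import default_gene_plan  # self-import safe at call time

    genome, ann = simulate_genome(seed, length, default_gene_plan(length))
    loci = plant_loci(genome, ann, n_loci, seed=seed)
    feats = list(ann.features)
    categories = ("r", "t", "nc")
    for i, (s, e, st) in enumerate(loci):
        feats.append(GenomeFeature(f"smith{i + 1}", "smithRNA", s, e, st))
        ps, pe, _ = extract_pre_region(
            s, e, st, categories[i % 3], ann, genome
        )
        feats.append(GenomeFeature(f"pre_smith{i + 1}", "pre_smithRNA", ps, pe, st))
    full = AnnotationSet(genome.id, feats)
    return genome, full, region_labels(full, genome.length)


# ---------------------------------------------------------------------------
# UTRome
# ---------------------------------------------------------------------------

def simulate_utrome(
    n_utrs: int = 50,
    mean_length: int = 500,
    plants: list[tuple[str, str]] | None = None,
    seed: int = 0,
) -> tuple[list, SyntheticTruth]:
    """Random 3' UTR records with planted sites.

    ``plants`` is a list of (centroid_sequence, plant_type) with plant_type
    in {"perfect", "seed_only", "none"}: perfect embeds the full reverse
    complement of the centroid; seed_only embeds only the reverse complement
    of centroid nt 4-10; none plants nothing.  Each plant goes into its own
    UTR (the first len(plants) records); lengths are geometric-ish around
    ``mean_length`` with a floor of 200 nt.
    """
    from .targets import UTRRecord

    rng = np.random.default_rng(seed)
    plants = plants or []
    if len(plants) > n_utrs:
        raise ValueError("more plants than UTRs")
    utrs: list[UTRRecord] = []
    truth = SyntheticTruth()
    for i in range(n_utrs):
        ln = max(200, int(rng.normal(mean_length, mean_length / 4)))
        seq = _random_seq(rng, ln)
        uid = f"utr{i + 1}"
        if i < len(plants):
            centroid, ptype = plants[i]
            centroid = centroid.upper().replace("U", "T")
            if ptype == "perfect":
                insert = reverse_complement(centroid)
            elif ptype == "seed_only":
                insert = reverse_complement(centroid[3:10])
            elif ptype == "none":
                insert = ""
            else:
                raise ValueError(f"unknown plant type {ptype!r}")
            if insert:
                pos = int(rng.integers(40, ln - len(insert) - 40))
                seq = seq[:pos] + insert + seq[pos + len(insert):]
                truth.targets.append(
                    PlantedTarget(uid, pos + 1, pos + len(insert), ptype, centroid)
                )
            else:
                truth.targets.append(PlantedTarget(uid, 0, 0, ptype, centroid))
        utrs.append(UTRRecord(uid, seq))
    return utrs, truth


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

def simulate_assay(
    n_per_group: dict[str, int],
    group_shifts: dict[str, float],
    sex_effect: float = 0.0,
    noise_sd: float = 1.0,
    timepoint: float = 24.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Normalized assay measurements: baseline + group shift + sex effect +
    Gaussian noise; specimens are assigned F/M roughly evenly."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group, n in n_per_group.items():
        shift = group_shifts.get(group, 0.0)
        for _ in range(n):
            i += 1
            sex = "F" if rng.random() < 0.5 else "M"
            value = shift + (sex_effect if sex == "F" else 0.0) + rng.normal(0, noise_sd)
            rows.append(
                {"specimen": f"sp{i}", "group": group, "sex": sex,
                 "timepoint_h": timepoint, "measurement": value}
            )
    truth = SyntheticTruth(assay_effects=dict(group_shifts))
    return pd.DataFrame(rows), truth
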