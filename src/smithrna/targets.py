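"""miRNA-style target prediction for smithRNA candidates against a 3' UTR
collection.

A centroid is tested against each UTR through four gates:

1. seed match -- the reverse complement of centroid nucleotides 4-10 (the
   shifted seed) occurs verbatim in the UTR (Watson-Crick only, no G:U);
2. total complementarity -- the best gapless local alignment between the
   centroid and the reverse complement of the UTR window around the seed
   site, scored +1/-3 (short-query scoring), covers at least ``min_matches``
   matched positions and must contain the seed site;
3. accessibility -- Delta-Delta-G = duplex energy plus the cost of opening
   the target-site secondary structure (single-structure MFE approximation on
   a local fold window) is below ``max_ddg``;
4. duplex stability -- the nearest-neighbor duplex energy, with centroid
   positions 3-10 forced to pair, is below ``max_dg``.

Thresholds are strict inequalities as printed (``n_matches >= 11``,
``ddG < -9``, ``dG < -20``), applied on the energy model's native kcal/mol
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .energy import EnergyModel, TURNER_LIKE, duplex_energy, fold_mfe
from .genome import normalize_sequence, reverse_complement

__all__ = [
    "UTRRecord",
    "SeedMatch",
    "TargetHit",
    "Thresholds",
    "seed_scan",
    "count_matches",
    "accessibility_ddG",
    "evaluate_targets",
    "read_utr_fasta",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class UTRRecord:
    id: str
    sequence: str  # 3' UTR, 5'->3'

    def __post_init__(self):
        seq = normalize_sequence(self.sequence)
        if not seq:
            raise ValueError(f"UTR {self.id}: empty sequence")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedMatch:
    utr_id: str
    start: int  # 1-based inclusive on the UTR
    end: int    # start + 6; the 7-mer complementary to centroid nt 4-10


@dataclass
class TargetHit:
    utr_id: str
    seed: SeedMatch
    n_matches: int
    dg_duplex: float
    ddg: float
    flags: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class Thresholds:
    min_matches: int = 11
    max_ddg: float = -9.0
    max_dg: float = -20.0
    seed: tuple[int, int] = (4, 10)
    forced_helix: tuple[int, int] = (3, 10)
    context: int = 30
    flank5: int = 3
    flank3: int = 15
    fold_window: int = 140


def read_utr_fasta(path) -> list[UTRRecord]:
    from Bio import SeqIO

    return [UTRRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def seed_scan(
    centroid: str, utr: UTRRecord, seed: tuple[int, int] = (4, 10)
) -> list[SeedMatch]:
    """All occurrences in the UTR of the reverse complement of the centroid
    seed (positions ``seed``, 1-based inclusive; default nt 4-10).

    Watson-Crick matching only; overlapping occurrences are all reported.
    """
    c = normalize_sequence(centroid)
    lo, hi = seed
    if len(c) < hi:
        raise ValueError(f"centroid shorter than {hi} nt")
    motif = reverse_complement(c[lo - 1 : hi])
    out = []
    pos = utr.sequence.find(motif)
    while pos != -1:
        out.append(SeedMatch(utr.id, pos + 1, pos + len(motif)))
        pos = utr.sequence.find(motif, pos + 1)
    return out


def _best_local_containing(scores: list[int], lo: int, hi: int) -> tuple[int, int, int]:
    """Best-scoring contiguous segment of ``scores`` that contains columns
    [lo, hi] (0-based inclusive); returns (score, seg_lo, seg_hi)."""
    base = sum(scores[lo : hi + 1])
    # best extension leftward from lo-1
    best_left, run, arg_left = 0, 0, lo
    for i in range(lo - 1, -1, -1):
        run += scores[i]
        if run > best_left:
            best_left, arg_left = run, i
    best_right, run, arg_right = 0, 0, hi
    for i in range(hi + 1, len(scores)):
        run += scores[i]
        if run > best_right:
            best_right, arg_right = run, i
    return base + best_left + best_right, arg_left, arg_right


def count_matches(
    centroid: str,
    utr: UTRRecord,
    seed_match: SeedMatch,
    context: int = 30,
    seed: tuple[int, int] = (4, 10),
) -> int:
    """Matched positions in the best gapless local alignment (match +1,
    mismatch -3) between the centroid and the reverse complement of the UTR
    window centered on the seed site.

    The window spans the centroid length plus ``context`` on each side of the
    site.  Only alignments whose matched segment covers the seed site are
    considered, so the reported matches always include the seed.
    """
    c = normalize_sequence(centroid)
    margin = len(c) + context
    w_start = max(1, seed_match.start - margin)  # 1-based on UTR
    w_end = min(len(utr.sequence), seed_match.end + margin)
    window_rc = reverse_complement(utr.sequence[w_start - 1 : w_end])
    # seed site columns in window_rc coordinates (reverse complement flips)
    seed_lo_rc = w_end - seed_match.end        # 0-based
    seed_hi_rc = w_end - seed_match.start
    n = len(window_rc)
    best_score = -math.inf
    best_matches = 0
    for offset in range(-(len(c) - 1), n):
        # centroid position i (0-based) aligns window_rc position i + offset
        lo = max(0, -offset)
        hi = min(len(c), n - offset)
        if lo >= hi:
            continue
        # require the aligned span to cover the seed columns
        if offset + lo > seed_lo_rc or offset + hi - 1 < seed_hi_rc:
            continue
        cols = [1 if c[i] == window_rc[i + offset] else -3 for i in range(lo, hi)]
        s_lo = seed_lo_rc - offset - lo
        s_hi = seed_hi_rc - offset - lo
        score, a, b = _best_local_containing(cols, s_lo, s_hi)
        if score > best_score:
            best_score = score
            best_matches = sum(1 for v in cols[a : b + 1] if v == 1)
    return best_matches


def accessibility_ddG(
    utr: UTRRecord,
    seed_match: SeedMatch,
    dg_duplex: float,
    flank5: int = 3,
    flank3: int = 15,
    fold_window: int = 140,
    model: EnergyModel = TURNER_LIKE,
    site_span: tuple[int, int] | None = None,
) -> float:
    """Target-site accessibility score Delta-Delta-G = dG_duplex + dG_open.

    dG_open is the difference between the MFE of the local fold window with
    the site (plus ``flank5`` nucleotides 5' and ``flank3`` nucleotides 3' of
    it) constrained unpaired and the unconstrained MFE; it is >= 0 by
    construction.  The fold window (default 140 nt) is centered on the site
    and truncated at the UTR boundaries.  ``site_span`` widens the considered
    site beyond the seed heptamer (1-based UTR coordinates).
    """
    if not math.isfinite(dg_duplex):
        raise ValueError("dG_duplex must be finite")
    s_lo, s_hi = site_span if site_span else (seed_match.start, seed_match.end)
    L = len(utr.sequence)
    center = (s_lo + s_hi) // 2
    w_lo = max(1, center - fold_window // 2)
    w_hi = min(L, w_lo + fold_window - 1)
    w_lo = max(1, w_hi - fold_window + 1)
    sub = utr.sequence[w_lo - 1 : w_hi]
    # constrained-unpaired region on the window, 0-based
    b_lo = max(0, s_lo - flank5 - w_lo)
    b_hi = min(len(sub) - 1, s_hi + flank3 - w_lo)
    blocked = set(range(b_lo, b_hi + 1))
    mfe_free, _ = fold_mfe(sub, model=model, structure=False)
    mfe_blocked, _ = fold_mfe(sub, blocked=blocked, model=model, structure=False)
    dg_open = mfe_blocked - mfe_free
    return dg_duplex + dg_open


def _site_region(centroid_len: int, seed_match: SeedMatch, seed: tuple[int, int],
                 utr_len: int) -> tuple[int, int]:
    """UTR region opposite the full centroid when its seed pairs the site:
    centroid position i pairs UTR position seed_end + seed_lo - i."""
    lo, _hi = seed
    # centroid position i (1-based) pairs utr position seed_match.end + lo - i
    u_hi = seed_match.end + lo - 1
    u_lo = seed_match.end + lo - centroid_len
    return max(1, u_lo), min(utr_len, u_hi)


def evaluate_targets(
    centroid: str,
    utrome: list[UTRRecord],
    thresholds: Thresholds = Thresholds(),
    model: EnergyModel = TURNER_LIKE,
) -> list[TargetHit]:
    """Evaluate a centroid against every UTR; emit only hits passing all four
    gates (seed site present, n_matches >= min_matches, ddG < max_ddg,
    dG_duplex < max_dg).  A centroid may hit multiple UTRs and a UTR may
    carry multiple sites.
    """
    c = normalize_sequence(centroid)
    th = thresholds
    hits: list[TargetHit] = []
    for utr in utrome:
        for sm in seed_scan(c, utr, th.seed):
            n_match = count_matches(c, utr, sm, th.context, th.seed)
            if n_match < th.min_matches:
                continue
            u_lo, u_hi = _site_region(len(c), sm, th.seed, len(utr.sequence))
            site_seq = utr.sequence[u_lo - 1 : u_hi]
            dg = duplex_energy(c, site_seq, model, th.forced_helix)
            if not math.isfinite(dg):
                continue
            ddg = accessibility_ddG(
                utr, sm, dg, th.flank5, th.flank3, th.fold_window, model,
                site_span=(u_lo, u_hi),
            )
            flags = {
                "seed": True,
                "matches": n_match >= th.min_matches,
                "ddg": ddg < th.max_ddg,
                "dg": dg < th.max_dg,
            }
            if all(flags.values()):
                hits.append(TargetHit(utr.id, sm, n_match, dg, ddg, flags))
    return hits


def write_hits_tsv(hits_by_centroid: dict[str, list[TargetHit]], path) -> None:
    with open(path, "w") as fh:
        fh.write("centroid_id\tutr_id\tsite_start\tsite_end\tn_matches\t"
                 "dG_duplex\tddG\tflags\n")
        for cid in sorted(hits_by_centroid):
            for h in hits_by_centroid[cid]:
                flagtxt = ",".join(k for k, v in sorted(h.flags.items()) if v)
                fh.write(
                    f"{cid}\t{h.utr_id}\t{h.seed.start}\t{h.seed.end}\t"
                    f"{h.n_matches}\t{h.dg_duplex:.2f}\t{h.ddg:.2f}\t{flagtxt}\n"
                )
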