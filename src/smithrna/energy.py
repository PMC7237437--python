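"""Nearest-neighbor RNA thermodynamics: duplex hybridization energy and a
simplified single-sequence folding dynamic program.

The duplex model scores a gapless, bulge-free antiparallel pairing of a small
RNA against a target site: one helix-initiation term plus the sum of
nearest-neighbor stack terms over adjacent paired columns.  Watson-Crick
stacks carry standard Turner-style 37 degC parameters (kcal/mol); G:U wobble
stacks are assigned deliberately conservative (weak) values so that a wobble
stack is always less stabilizing than any Watson-Crick stack.  This keeps the
model strictly monotone: disrupting any base pair of a perfect-complement
duplex always raises the energy.

The folding DP is a stack-scored Nussinov/Zuker hybrid over nested structures
(no multiloop or loop-length penalties): the energy of a structure is the sum
of the stack terms of its helices, so unpaired sequences score 0 and lone
pairs are energetically neutral.  It is used for the target-site
accessibility penalty (the opening cost Delta-G_open) and for illustrative
folds of candidate genomic contexts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EnergyModel",
    "TURNER_LIKE",
    "duplex_energy",
    "fold_mfe",
]

#: base pairs allowed in a helix (Watson-Crick + G:U wobble), RNA alphabet
PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _wc_stacks() -> dict[tuple[str, str], float]:
    # 5'PQ3'/3'P'Q'5' keyed as (P+P', Q+Q'); the ten canonical parameters,
    # completed by 180-degree rotational symmetry E(p,q) = E(flip q, flip p).
    base = {
        ("AU", "AU"): -0.93,
        ("AU", "UA"): -1.10,
        ("UA", "AU"): -1.33,
        ("CG", "UA"): -2.08,
        ("CG", "AU"): -2.11,
        ("GC", "UA"): -2.24,
        ("GC", "AU"): -2.35,
        ("CG", "GC"): -2.36,
        ("GC", "GC"): -3.26,
        ("GC", "CG"): -3.42,
    }
    full = dict(base)
    for (p, q), e in base.items():
        full.setdefault((q[::-1], p[::-1]), e)
    return full


def _gu_stacks() -> dict[tuple[str, str], float]:
    # weak wobble parameters: one G:U in the step -0.6, tandem wobbles -0.25
    out = {}
    pair_strs = ["AU", "UA", "CG", "GC", "GU", "UG"]
    for p in pair_strs:
        for q in pair_strs:
            n_gu = (p in ("GU", "UG")) + (q in ("GU", "UG"))
            if n_gu == 1:
                out[(p, q)] = -0.60
            elif n_gu == 2:
                out[(p, q)] = -0.25
    return out


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameter set.

    ``temperature`` is recorded metadata: the simplified stack table is
    temperature-fixed, so changing it does not rescale the parameters.
    ``unit`` is a configurable label; thresholds in this package are applied
    on the model's native scale.
    """

    table_id: str = "turner-like-wc+weak-wobble"
    temperature: float = 25.0
    unit: str = "kcal/mol"
    initiation: float = 4.09
    stacks: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.stacks:
            table = _wc_stacks()
            table.update(_gu_stacks())
            object.__setattr__(self, "stacks", table)

    def stack(self, pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
        return self.stacks[(pair1[0] + pair1[1], pair2[0] + pair2[1])]


TURNER_LIKE = EnergyModel()


def _pairs_at_offset(query: str, target_rev: str, offset: int) -> list[bool]:
    """Pairing mask for query position i against target_rev position i+offset."""
    mask = []
    for i, c in enumerate(query):
        j = i + offset
        if 0 <= j < len(target_rev):
            mask.append((c, target_rev[j]) in PAIRS)
        else:
            mask.append(False)
    return mask


def _stack_sum(query: str, target_rev: str, offset: int, mask: list[bool],
               model: EnergyModel) -> float:
    e = 0.0
    for i in range(len(query) - 1):
        if mask[i] and mask[i + 1]:
            p1 = (query[i], target_rev[i + offset])
            p2 = (query[i + 1], target_rev[i + 1 + offset])
            e += model.stack(p1, p2)
    return e


def duplex_energy(
    centroid: str,
    site: str,
    model: EnergyModel = TURNER_LIKE,
    forced_helix: tuple[int, int] = (3, 10),
) -> float:
    """Minimum free energy (kcal/mol) of a gapless antiparallel duplex between
    a small RNA (5'->3') and a target site (UTR region, 5'->3').

    The energy of one offset alignment is the helix initiation plus the sum
    of nearest-neighbor stacks over adjacent paired columns; pairing is
    Watson-Crick or G:U.  Offsets where centroid positions ``forced_helix``
    (1-based, inclusive) are not all paired are rejected; ``math.inf`` is
    returned when no offset satisfies the constraint.
    """
    q = to_rna(centroid)
    t_rev = to_rna(site)[::-1]  # antiparallel: site 3'->5' against query 5'->3'
    h_lo, h_hi = forced_helix
    if len(q) < h_hi:
        raise ValueError(f"centroid shorter than forced helix end {h_hi}")
    if len(t_rev) < (h_hi - h_lo + 1):
        raise ValueError("site shorter than the forced helix")
    best = math.inf
    for offset in range(-(len(q) - 1), len(t_rev)):
        mask = _pairs_at_offset(q, t_rev, offset)
        if not all(mask[h_lo - 1 : h_hi]):
            continue
        e = model.initiation + _stack_sum(q, t_rev, offset, mask, model)
        best = min(best, e)
    return best


# ---------------------------------------------------------------------------
# single-sequence folding
# ---------------------------------------------------------------------------

def fold_mfe(
    seq: str,
    min_hairpin: int = 3,
    blocked: set[int] | None = None,
    model: EnergyModel = TURNER_LIKE,
    structure: bool = True,
    helix_init: float | None = None,
) -> tuple[float, str]:
    """Minimum free energy and dot-bracket structure over nested secondary
    structures of ``seq`` (RNA or DNA text).

    Scoring is the sum of nearest-neighbor stack terms of all helices plus
    one initiation penalty per helix (default: the model's duplex initiation
    term), standing in for the destabilizing loop terms of a full loop-based
    model; without it every random sequence would fold into a dense tangle
    of one-stack helices.  The MFE is <= 0 and an unpairable sequence scores
    exactly 0.  ``blocked`` is a set of 0-based positions forbidden to pair
    (used for the accessibility constraint).  Hairpin loops have at least
    ``min_hairpin`` unpaired nucleotides.
    """
    s = to_rna(seq)
    n = len(s)
    blocked = blocked or set()
    if helix_init is None:
        helix_init = model.initiation

    def pairable(i: int, j: int) -> bool:
        return (
            j - i - 1 >= min_hairpin
            and i not in blocked
            and j not in blocked
            and (s[i], s[j]) in PAIRS
        )

    # V[i][j]: best energy of [i, j] given i..j paired; W[i][j]: best of [i, j]
    W = [[0.0] * n for _ in range(n)]
    V = [[math.inf] * n for _ in range(n)]

    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable(i, j):
                v = W[i + 1][j - 1]
                if pairable(i + 1, j - 1):
                    v = min(v, model.stack((s[i], s[j]), (s[i + 1], s[j - 1]))
                            + V[i + 1][j - 1])
                V[i][j] = v
            w = W[i + 1][j]
            for k in range(i + min_hairpin + 1, j + 1):
                if V[i][k] < math.inf:
                    cand = V[i][k] + helix_init + (W[k + 1][j] if k + 1 <= j else 0.0)
                    # strict improvement only: avoid energetically neutral pairs
                    if cand < w - 1e-12:
                        w = cand
            W[i][j] = w

    mfe = W[0][n - 1] if n else 0.0
    if not structure:
        return mfe, ""

    db = ["."] * n

    def trace_W(i: int, j: int):
        while i < j:
            if W[i][j] == W[i + 1][j]:
                i += 1
                continue
            for k in range(i + min_hairpin + 1, j + 1):
                if V[i][k] < math.inf:
                    rest = W[k + 1][j] if k + 1 <= j else 0.0
                    if abs(V[i][k] + helix_init + rest - W[i][j]) < 1e-9:
                        trace_V(i, k)
                        i = k + 1
                        break
            else:
                return

    def trace_V(i: int, j: int):
        db[i], db[j] = "(", ")"
        if pairable(i + 1, j - 1) and V[i + 1][j - 1] < math.inf:
            st = model.stack((s[i], s[j]), (s[i + 1], s[j - 1]))
            if abs(st + V[i + 1][j - 1] - V[i][j]) < 1e-9:
                trace_V(i + 1, j - 1)
                return
        trace_W(i + 1, j - 1)

    if n:
        trace_W(0, n - 1)
    return mfe, "".join(db)
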