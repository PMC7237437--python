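"""Sliding-window nucleotide diversity and the nonparametric tests used for
the conservation and assay analyses.

Nucleotide diversity is estimated per window as

    pi_hat = N/(N-1) * sum_i sum_{j>i} p_i p_j pi_ij

where N is the number of sequences, p_i the frequency of the i-th haplotype
and pi_ij the uncorrected (p) distance between haplotypes i and j.  Note the
sum runs over unordered haplotype pairs; the conventional (Nei) estimator
doubles it.  Both conventions are exposed (``ordered_pairs=True`` doubles the
value); rank-based test conclusions are unaffected by the constant factor.

Gap/ambiguity handling is pairwise deletion by default: a site with a gap or
non-ACGT symbol in either of the two rows being compared is excluded from
both numerator and denominator for that pair (complete deletion available by
flag).

The tests (tie-corrected Kruskal-Wallis, two-tailed Dunn's post hoc with
Bonferroni correction, and exact/approximate Mann-Whitney) are implemented
from their rank formulas, with scipy providing only the reference
distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SequenceAlignment",
    "DiversityWindow",
    "TestResult",
    "pairwise_p_distance",
    "nucleotide_diversity",
    "sliding_window_diversity",
    "assign_regions",
    "kruskal_wallis",
    "dunn_test",
    "mann_whitney",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_MISSING = -1  # gaps and ambiguity codes


@dataclass
class SequenceAlignment:
    """Equal-length aligned nucleotide sequences (gaps allowed)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """Integer-coded alignment; gaps/ambiguities coded as -1."""
        m = np.full((self.n, self.length), _MISSING, dtype=np.int8)
        for i, row in enumerate(self.rows):
            m[i] = [_CODE.get(c, _MISSING) for c in row]
        return m

    @classmethod
    def from_fasta(cls, path) -> "SequenceAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids, rows)


@dataclass
class DiversityWindow:
    start: int  # 1-based inclusive on the alignment
    end: int
    pi_hat: float
    region: str | None = None


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    df: int | None = None
    pairwise: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def pairwise_p_distance(seq_i: str, seq_j: str) -> float:
    """Uncorrected p distance: mismatches / compared sites, excluding sites
    with a gap or ambiguity in either sequence; 0 when nothing is comparable."""
    if len(seq_i) != len(seq_j):
        raise ValueError("sequences differ in length")
    diffs = compared = 0
    for a, b in zip(seq_i.upper(), seq_j.upper()):
        ca, cb = _CODE.get(a, _MISSING), _CODE.get(b, _MISSING)
        if ca == _MISSING or cb == _MISSING:
            continue
        compared += 1
        diffs += ca != cb
    return diffs / compared if compared else 0.0


def nucleotide_diversity(
    alignment: SequenceAlignment | list[str],
    ordered_pairs: bool = False,
    complete_deletion: bool = False,
) -> float:
    """Mean nucleotide diversity of an alignment (window).

    Haplotypes are the distinct row strings; the estimator sums p_i p_j pi_ij
    over unordered haplotype pairs with the N/(N-1) correction.  With
    ``ordered_pairs=True`` the doubled (Nei) convention is returned.  With
    ``complete_deletion=True`` columns containing any gap/ambiguity are
    dropped for all rows before computing distances.
    """
    rows = alignment.rows if isinstance(alignment, SequenceAlignment) else [r.upper() for r in alignment]
    N = len(rows)
    if N < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    if complete_deletion and rows:
        keep = [
            k
            for k in range(len(rows[0]))
            if all(_CODE.get(r[k], _MISSING) != _MISSING for r in rows)
        ]
        rows = ["".join(r[k] for k in keep) for r in rows]

    counts: dict[str, int] = {}
    for r in rows:
        counts[r] = counts.get(r, 0) + 1
    haps = list(counts)
    total = 0.0
    for a, b in itertools.combinations(haps, 2):
        p_i = counts[a] / N
        p_j = counts[b] / N
        total += p_i * p_j * pairwise_p_distance(a, b)
    pi = N / (N - 1) * total
    return 2.0 * pi if ordered_pairs else pi


def _window_pi_matrix(m: np.ndarray, size: int, step: int,
                      ordered_pairs: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-window pi_hat over an integer-coded alignment.

    Uses the row-pair identity pi_hat = sum_{r<s} pi_rs / (N (N-1) / 2) / 2
    ... i.e. N/(N-1) * (1/N^2) * sum over ordered row pairs of pi_rs, which
    equals the haplotype form because within-haplotype distances are zero.
    """
    N, L = m.shape
    starts = np.arange(0, L - size + 1, step)
    valid = m != _MISSING
    # per-site, per-pair comparisons
    iu, ju = np.triu_indices(N, k=1)
    neq = (m[iu] != m[ju]) & valid[iu] & valid[ju]      # (npairs, L)
    comp = valid[iu] & valid[ju]
    cs_neq = np.concatenate([np.zeros((len(iu), 1)), np.cumsum(neq, axis=1)], axis=1)
    cs_cmp = np.concatenate([np.zeros((len(iu), 1)), np.cumsum(comp, axis=1)], axis=1)
    w_neq = cs_neq[:, starts + size] - cs_neq[:, starts]
    w_cmp = cs_cmp[:, starts + size] - cs_cmp[:, starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        pdist = np.where(w_cmp > 0, w_neq / np.maximum(w_cmp, 1), 0.0)
    pi = pdist.sum(axis=0) / (N * (N - 1))
    if ordered_pairs:
        pi = 2.0 * pi
    return starts + 1, pi


def sliding_window_diversity(
    alignment: SequenceAlignment,
    size: int = 10,
    step: int = 5,
    ordered_pairs: bool = False,
) -> list[DiversityWindow]:
    """pi_hat over sliding windows at starts 1, 1+step, ...; only full-size
    windows are emitted and zero-diversity windows are included."""
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    if alignment.length < size:
        return []
    if alignment.n < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    starts, pis = _window_pi_matrix(alignment.matrix(), size, step, ordered_pairs)
    return [
        DiversityWindow(int(s), int(s) + size - 1, float(p))
        for s, p in zip(starts, pis)
    ]


#: narrower/overlay features win when a window midpoint is covered by several
REGION_PRECEDENCE = ("smithRNA", "pre_smithRNA", "tRNA", "rRNA", "PCG", "UR")


def assign_regions(
    windows: list[DiversityWindow],
    regions: list[tuple[int, int, str]],
) -> list[DiversityWindow]:
    """Label each window by the region type at its midpoint.

    ``regions`` are (start, end, label) in 1-based inclusive alignment
    coordinates; overlapping labels are resolved by ``REGION_PRECEDENCE``.
    Raises if a midpoint is uncovered.
    """
    for w in windows:
        mid = (w.start + w.end) // 2
        labels = {lab for s, e, lab in regions if s <= mid <= e}
        if not labels:
            raise ValueError(f"window midpoint {mid} not covered by any region")
        for lab in REGION_PRECEDENCE:
            if lab in labels:
                w.region = lab
                break
        else:
            w.region = sorted(labels)[0]
    return windows


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: list[np.ndarray | list[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis rank sum test; p from chi-squared with
    k-1 df.  H is defined as 0 (p = 1) when all pooled values are equal."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    df = len(groups) - 1
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (N**3 - N) if N > 1 else 0.0
    if denom <= 0:
        return TestResult("kruskal-wallis", 0.0, 1.0, df)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx : idx + g.size]
        idx += g.size
        h += r.sum() ** 2 / g.size
    h = (12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)) / denom
    p = float(sps.chi2.sf(h, df))
    return TestResult("kruskal-wallis", float(h), p, df)


def dunn_test(
    groups: list[np.ndarray | list[float]],
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
    two_tailed: bool = True,
) -> pd.DataFrame:
    """Dunn's post hoc test on joint ranks for all k(k-1)/2 group pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tied values; two-tailed p from the standard
    normal; Bonferroni-adjusted p capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("Dunn's test requires at least 2 groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    idx = 0
    for g in groups:
        mean_ranks.append(ranks[idx : idx + g.size].mean())
        idx += g.size
    tie = _tie_term(pooled)
    var_base = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * float(sps.norm.sf(abs(z))) if two_tailed else float(sps.norm.sf(z))
        p_adj = min(1.0, m * p) if adjust == "bonferroni" else p
        rows.append(
            {"group_i": labels[i], "group_j": labels[j], "z": z, "p": p,
             "p_adjusted": p_adj}
        )
    return pd.DataFrame(rows)


def _mw_exact_cdf(u: float, n1: int, n2: int) -> float:
    """P(U <= u) for the tie-free Mann-Whitney U distribution, by the standard
    counting recurrence."""
    # f[n][u] built incrementally: number of arrangements with statistic u
    max_u = n1 * n2
    u = math.floor(u + 1e-9)
    if u < 0:
        return 0.0
    if u >= max_u:
        return 1.0
    f: dict[tuple[int, int, int], float] = {}

    def rec(a: int, b: int, uu: int) -> float:
        if uu < 0:
            return 0.0
        if a == 0 or b == 0:
            return 1.0 if uu >= 0 else 0.0
        key = (a, b, uu)
        if key in f:
            return f[key]
        val = rec(a - 1, b, uu - b) + rec(a, b - 1, uu)
        f[key] = val
        return val

    # rec(a, b, uu) counts arrangements with U <= uu (cumulative form)
    total = math.comb(n1 + n2, n1)
    return rec(n1, n2, u) / total


def mann_whitney(
    x: list[float] | np.ndarray,
    y: list[float] | np.ndarray,
    alternative: str = "two-sided",
    method: str = "auto",
) -> TestResult:
    """Mann-Whitney U test (W = U of the first sample, the R convention).

    Exact enumeration p when n_x * n_y <= 400 and the data are tie-free;
    otherwise a normal approximation with tie and continuity corrections.
    ``method`` forces a branch ("exact" / "normal"); exact with ties is
    refused.  ``alternative='less'`` tests that x tends to be smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # number of (x, y) pairs with x > y (+ ties/2)
    u2 = n1 * n2 - u1
    has_ties = np.unique(pooled).size < pooled.size
    if method == "exact" and has_ties:
        raise ValueError("exact Mann-Whitney p is undefined with ties")
    use_exact = (method == "exact") or (
        method == "auto" and n1 * n2 <= 400 and not has_ties
    )

    if use_exact:
        p_less = _mw_exact_cdf(u1, n1, n2)
        p_greater = _mw_exact_cdf(u2, n1, n2)
        method = "exact"
    else:
        tie = _tie_term(pooled)
        n = n1 + n2
        mu = n1 * n2 / 2.0
        sigma = math.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1))))
        if sigma == 0:
            p_less = p_greater = 1.0
        else:
            # continuity correction of 0.5 toward the mean
            p_less = float(sps.norm.cdf((u1 - mu + 0.5) / sigma))
            p_greater = float(sps.norm.sf((u1 - mu - 0.5) / sigma))
        method = "normal"
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    res = TestResult(f"mann-whitney ({method})", float(u1), float(p))
    return res
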