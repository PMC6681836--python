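"""Pairwise alignment, progressive MSA and JTT distances.

The homology engine behind the census, phylogeny, PPD and HGT stages.
Pairwise local/global alignment is full Smith-Waterman / Needleman-Wunsch
with affine gaps (Bio.Align.PairwiseAligner); defaults are the classic
BLASTP settings (BLOSUM62, gap open 11, extend 1). E-values follow the
Karlin-Altschul form E = K*m*n*exp(-lambda*s) with (K, lambda) estimated
once per scoring scheme by a Gumbel fit to the local scores of shuffled
random pairs.

Conventions (documented and tested):
  * identity = identical columns / aligned columns (gap-gap columns, which
    cannot occur pairwise, would be excluded) - the usual BLAST report;
  * coverage is query-relative: aligned query residues / query length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.stats import gumbel_r

from ._jtt import AA_INDEX, AA_ORDER, JTT_FREQS, transition_matrix

# residues PairwiseAligner cannot score with BLOSUM62 get mapped first
_SANITIZE = str.maketrans({"U": "C", "O": "K", "J": "X"})
_ACCEPTED = set("ACDEFGHIKLMNPQRSTVWYBJXZUO*")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    identity: float
    query_coverage: float
    evalue: float = math.inf

    @property
    def is_hit(self) -> bool:
        return len(self.aligned_query) > 0


@dataclass
class KarlinAltschul:
    K: float
    lam: float

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


def _check_protein(seq: str, name: str) -> str:
    bad = set(seq.upper()) - _ACCEPTED
    if bad:
        raise AlignmentError(f"{name}: residues outside accepted set: {sorted(bad)}")
    if not seq:
        raise AlignmentError(f"{name}: empty sequence")
    return seq.upper().translate(_SANITIZE)


@lru_cache(maxsize=8)
def _make_aligner(matrix: str, gap_open: int, gap_extend: int, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


@lru_cache(maxsize=8)
def calibrate_matrix(
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    n_pairs: int = 10_000,
    length: int = 150,
    seed: int = 20190715,
) -> KarlinAltschul:
    """Estimate (K, lambda) from the Gumbel fit to shuffled-pair local scores.

    The tail of the Gumbel gives P(S >= s) ~ exp(mu/beta) exp(-s/beta), so
    lambda = 1/beta and K = exp(mu/beta) / (m0*n0).
    """
    rng = np.random.default_rng(seed)
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    aas = np.array(list(AA_ORDER))
    scores = np.empty(n_pairs)
    for i in range(n_pairs):
        a = "".join(rng.choice(aas, size=length, p=JTT_FREQS))
        b = "".join(rng.choice(aas, size=length, p=JTT_FREQS))
        scores[i] = aligner.score(a, b)
    mu, beta = gumbel_r.fit(scores)
    return KarlinAltschul(K=math.exp(mu / beta) / (length * length), lam=1.0 / beta)


def _stats(aq: str, asub: str, qlen: int) -> tuple[float, float]:
    cols = ident = qres = 0
    for x, y in zip(aq, asub):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x != "-":
            qres += 1
        if x == y and x != "-":
            ident += 1
    identity = ident / cols if cols else 0.0
    coverage = qres / qlen if qlen else 0.0
    return identity, coverage


def _align(
    query: str, subject: str, query_id: str, subject_id: str, mode: str,
    matrix: str, gap_open: int, gap_extend: int, calibration: KarlinAltschul | None,
) -> PairwiseAlignment:
    q = _check_protein(query, query_id or "query")
    s = _check_protein(subject, subject_id or "subject")
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode)
    score = aligner.score(q, s)
    if mode == "local" and score <= 0:
        return PairwiseAlignment(query_id, subject_id, "", "", 0.0, 0.0, 0.0, math.inf)
    aln = aligner.align(q, s)[0]
    aq, asub = str(aln[0]), str(aln[1])
    identity, coverage = _stats(aq, asub, len(q))
    if calibration is None:
        calibration = calibrate_matrix(matrix, gap_open, gap_extend)
    ev = calibration.evalue(score, len(q), len(s))
    return PairwiseAlignment(query_id, subject_id, aq, asub, float(score),
                             identity, coverage, ev)


def local_align(
    query: str, subject: str, *, query_id: str = "query", subject_id: str = "subject",
    matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1,
    calibration: KarlinAltschul | None = None,
) -> PairwiseAlignment:
    """Optimal affine-gap Smith-Waterman local alignment with E-value."""
    return _align(query, subject, query_id, subject_id, "local",
                  matrix, gap_open, gap_extend, calibration)


def global_align(
    query: str, subject: str, *, query_id: str = "query", subject_id: str = "subject",
    matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1,
    calibration: KarlinAltschul | None = None,
) -> PairwiseAlignment:
    return _align(query, subject, query_id, subject_id, "global",
                  matrix, gap_open, gap_extend, calibration)


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise AlignmentError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace("-", "")

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows.values()]

    def subset(self, ids: list[str]) -> "MultipleAlignment":
        return MultipleAlignment({i: self.rows[i] for i in ids})


def sp_score(msa: MultipleAlignment, matrix: str = "BLOSUM62", gap_cost: float = 8.0) -> float:
    """Sum-of-pairs score: res/res from the matrix, res/gap -gap_cost, gap/gap 0."""
    m = substitution_matrices.load(matrix)
    rows = list(msa.rows.values())
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            for x, y in zip(rows[i], rows[j]):
                if x == "-" and y == "-":
                    continue
                total += -gap_cost if (x == "-" or y == "-") else m[x, y]
    return total


def _column_counts(rows: list[str]) -> np.ndarray:
    """(n_cols, 21) counts; index 20 is the gap symbol."""
    n = len(rows[0])
    counts = np.zeros((n, 21))
    for r in rows:
        for j, ch in enumerate(r):
            counts[j, AA_INDEX.get(ch, 20) if ch != "-" else 20] += 1
    return counts


@lru_cache(maxsize=4)
def _pair_score_21(matrix: str, gap_cost: float) -> np.ndarray:
    m = substitution_matrices.load(matrix)
    s = np.zeros((21, 21))
    for a in range(20):
        for b in range(20):
            s[a, b] = m[AA_ORDER[a], AA_ORDER[b]]
    s[20, :20] = s[:20, 20] = -gap_cost
    return s


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], matrix: str, gap_cost: float,
) -> tuple[list[str], list[str]]:
    """Profile-profile Needleman-Wunsch maximizing cross-group SP score."""
    ca, cb = _column_counts(rows_a), _column_counts(rows_b)
    pair = _pair_score_21(matrix, gap_cost)
    s = ca @ pair @ cb.T  # (La, Lb) column-pair cross scores
    na, nb = len(rows_a), len(rows_b)
    nongap_a = ca[:, :20].sum(axis=1)
    nongap_b = cb[:, :20].sum(axis=1)
    cost_a = -gap_cost * nongap_a * nb  # consume A column against all-gap B column
    cost_b = -gap_cost * nongap_b * na
    la, lb = s.shape
    h = np.full((la + 1, lb + 1), -np.inf)
    back = np.zeros((la + 1, lb + 1), dtype=np.int8)
    h[0, 0] = 0.0
    for i in range(1, la + 1):
        h[i, 0] = h[i - 1, 0] + cost_a[i - 1]
        back[i, 0] = 1
    for j in range(1, lb + 1):
        h[0, j] = h[0, j - 1] + cost_b[j - 1]
        back[0, j] = 2
    for i in range(1, la + 1):
        diag = h[i - 1, :-1] + s[i - 1]
        for j in range(1, lb + 1):
            best, move = diag[j - 1], 0
            up = h[i - 1, j] + cost_a[i - 1]
            if up > best:
                best, move = up, 1
            left = h[i, j - 1] + cost_b[j - 1]
            if left > best:
                best, move = left, 2
            h[i, j] = best
            back[i, j] = move
    # traceback
    ops: list[int] = []
    i, j = la, lb
    while i or j:
        mv = back[i, j]
        ops.append(mv)
        if mv == 0:
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for mv in ops:
        if mv in (0, 1):
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            ia += 1
        else:
            for r in range(na):
                out_a[r] += "-"
        if mv in (0, 2):
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
        else:
            for r in range(nb):
                out_b[r] += "-"
    return out_a, out_b


def progressive_msa(
    seqs: dict[str, str], matrix: str = "BLOSUM62", gap_cost: float = 8.0,
    gap_open: int = 11, gap_extend: int = 1,
) -> MultipleAlignment:
    """Progressive multiple alignment.

    Guide tree: UPGMA on pairwise (1 - identity) distances from global
    alignments; groups merged by profile-profile DP in guide-tree order.
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise AlignmentError("progressive_msa needs at least 2 sequences")
    for sid, s in seqs.items():
        _check_protein(s, sid)
    n = len(ids)
    if n == 2:
        a, b = ids
        rows_a, rows_b = _merge_profiles([seqs[a].upper()], [seqs[b].upper()],
                                         matrix, gap_cost)
        return MultipleAlignment({a: rows_a[0], b: rows_b[0]})
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[ids[i]], seqs[ids[j]], matrix=matrix,
                               gap_open=gap_open, gap_extend=gap_extend,
                               calibration=KarlinAltschul(1.0, 1.0))
            dist[i, j] = dist[j, i] = 1.0 - aln.identity
    condensed = dist[np.triu_indices(n, k=1)]
    z = linkage(condensed, method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]].upper()]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(z):
        ga, gb = clusters.pop(int(a)), clusters.pop(int(b))
        rows_a, rows_b = _merge_profiles(ga[1], gb[1], matrix, gap_cost)
        clusters[n + step] = (ga[0] + gb[0], rows_a + rows_b)
    merged_ids, merged_rows = clusters.popitem()[1]
    aligned = dict(zip(merged_ids, merged_rows))
    return MultipleAlignment({i: aligned[i] for i in ids})


# ---------------------------------------------------------------------------
# JTT maximum-likelihood distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise AlignmentError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise AlignmentError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise AlignmentError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise AlignmentError("negative distances")


def jtt_distance(
    row_a: str, row_b: str, max_distance: float = 10.0, return_flag: bool = False,
) -> float | tuple[float, bool]:
    """ML substitutions/site between two aligned rows under the JTT model.

    Maximizes prod over shared non-gap columns of pi_a * P_JTT(a->b | t) by
    bounded scalar optimization (coarse grid bracket + Brent refinement).
    Saturated pairs are capped at max_distance and flagged.
    """
    if len(row_a) != len(row_b):
        raise AlignmentError("aligned rows differ in length")
    counts = np.zeros((20, 20))
    for x, y in zip(row_a.upper(), row_b.upper()):
        ia, ib = AA_INDEX.get(x), AA_INDEX.get(y)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    n_shared = counts.sum()
    if n_shared == 0:
        raise AlignmentError("no shared non-gap columns")
    if counts.trace() == n_shared:  # identical over shared columns
        return (0.0, False) if return_flag else 0.0

    def negll(t: float) -> float:
        p = transition_matrix(max(t, 1e-9))
        with np.errstate(divide="ignore"):
            lp = np.log(np.clip(JTT_FREQS[:, None] * p, 1e-300, None))
        return -(counts * lp).sum()

    grid = np.concatenate([[1e-6], np.geomspace(1e-3, max_distance, 64)])
    vals = np.array([negll(t) for t in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    t_hat, best = (res.x, res.fun) if res.fun <= vals[k] else (grid[k], vals[k])
    saturated = t_hat >= 0.99 * max_distance
    if saturated:
        t_hat = max_distance
    return (float(t_hat), saturated) if return_flag else float(t_hat)


def jtt_distance_matrix(msa: MultipleAlignment, max_distance: float = 10.0) -> DistanceMatrix:
    ids = msa.ids
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_distance(msa.rows[ids[i]], msa.rows[ids[j]],
                                             max_distance=max_distance)
    return DistanceMatrix(ids, d)
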