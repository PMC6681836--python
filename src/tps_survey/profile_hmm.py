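"""Profile hidden Markov models for protein domain search.

A compact Plan-7-style architecture scores a domain anywhere inside a longer
protein. The generative model, spelled out so scores can be checked by
explicit path enumeration on toy cases:

  * Flanks: state N (before) and C (after) emit background residues with a
    self-loop probability p_loop = l/(l+2) for a target of length l; the
    null model emits l background residues with length term
    (l/(l+1))^l * 1/(l+1).
  * Entry: Start -> N -> B; B -> M_k with probability 1/L for every match
    state k (uniform local entry).
  * Core: match states M_1..M_L with 20-way emissions; insert states
    I_1..I_{L-1}; delete states D_2..D_L (silent). Stored transition rows
    (M_k -> {M,I,D}, I_k -> {M,I}, D_k -> {M,D}) each sum to 1.
  * Exit: from each M_k (k<L) the model exits to E with probability p_exit,
    otherwise follows its stored transition row scaled by (1-p_exit);
    M_L -> E and D_L -> E with probability 1. E -> C -> ... -> T.

The reported bit score is log2 P(seq|model) - log2 P(seq|null); emissions of
N, C and the null cancel, so the DP runs in log-odds space. Residues outside
the 20-letter alphabet (X and other ambiguity codes) score log-odds 0 in
every state. E-values come from a Gumbel fit to forward scores of background
sequences whose lengths are resampled from the scanned database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gumbel_r

from ._jtt import AA_INDEX, AA_ORDER
from .align_core import MultipleAlignment

LOG0 = -np.inf
_AMBIGUOUS = set("XBZJUO*")


class ProfileError(ValueError):
    pass


@dataclass
class ProfileHMM:
    label: str
    match_emissions: np.ndarray          # (L, 20)
    insert_emissions: np.ndarray         # (L+1, 20); rows 0 and L are padding
    t_mm: np.ndarray                     # (L-1,) M_k -> M_{k+1}
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray                     # (L-1,) I_k -> M_{k+1}
    t_ii: np.ndarray
    t_dm: np.ndarray                     # (L-1,) D_k -> M_{k+1} at index k-1 (slot 0 inert)
    t_dd: np.ndarray                     # (L-1,) D_k -> D_{k+1} at index k-1 (slot 0 inert)
    background: np.ndarray               # (20,)
    p_exit: float = 0.05
    calibration: tuple[float, float] | None = None   # Gumbel (mu, beta)

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ProfileError("profile needs at least one match state")
        for name in ("match_emissions", "insert_emissions"):
            rows = getattr(self, name)
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ProfileError(f"{name} rows must sum to 1")
        if self.L > 1:
            for trip in (self.t_mm + self.t_mi + self.t_md,
                         self.t_im + self.t_ii, self.t_dm + self.t_dd):
                if not np.allclose(trip, 1.0, atol=1e-9):
                    raise ProfileError("transition rows must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-9):
            raise ProfileError("background must sum to 1")

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.match_emissions.argmax(axis=1))

    # ---- serialization (plain text) ----
    def to_text(self) -> str:
        lines = [f"TPSPROFILE {self.label} L={self.L} p_exit={self.p_exit!r}"]
        if self.calibration:
            lines.append(f"CALIB {self.calibration[0]!r} {self.calibration[1]!r}")
        def dump(tag, arr):
            flat = np.asarray(arr).ravel()
            lines.append(tag + " " + " ".join(repr(float(x)) for x in flat))
        dump("BG", self.background)
        dump("MAT", self.match_emissions)
        dump("INS", self.insert_emissions)
        for tag in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            dump(tag.upper(), getattr(self, tag))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ProfileHMM":
        lines = [l for l in text.strip().splitlines() if l.strip()]
        head = lines[0].split()
        label = head[1]
        L = int(head[2].split("=")[1])
        p_exit = float(head[3].split("=")[1])
        calibration = None
        vals: dict[str, np.ndarray] = {}
        for line in lines[1:]:
            tag, *rest = line.split()
            if tag == "CALIB":
                calibration = (float(rest[0]), float(rest[1]))
            else:
                vals[tag] = np.array([float(x) for x in rest])
        return cls(
            label=label,
            match_emissions=vals["MAT"].reshape(L, 20),
            insert_emissions=vals["INS"].reshape(L + 1, 20),
            t_mm=vals["T_MM"], t_mi=vals["T_MI"], t_md=vals["T_MD"],
            t_im=vals["T_IM"], t_ii=vals["T_II"],
            t_dm=vals["T_DM"], t_dd=vals["T_DD"],
            background=vals["BG"], p_exit=p_exit, calibration=calibration,
        )


@dataclass(frozen=True)
class DomainHit:
    seq_id: str
    domain_label: str
    env_start: int            # 1-based inclusive
    env_end: int
    bit_score: float
    evalue: float
    partial: bool
    match_span: int = 0       # match columns covered by the best path

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ProfileError("invalid hit envelope")
        if self.evalue < 0:
            raise ProfileError("negative E-value")


# ---------------------------------------------------------------------------
# Construction from a seed alignment
# ---------------------------------------------------------------------------

def build_profile(
    msa: MultipleAlignment, label: str = "domain", pseudocount: float = 1.0,
    match_fraction: float = 0.5, p_exit: float = 0.05,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Build a profile from an aligned seed.

    Columns with at least ``match_fraction`` non-gap residues become match
    states; other columns are modeled as inserts. Laplace pseudocounts are
    added to all emission and transition counts. The background distribution
    defaults to the residue frequency of the training alignment
    (pseudocounted); pass an explicit distribution for short motif profiles,
    whose training composition is too biased to serve as a null.
    """
    rows = list(msa.rows.values())
    if len(rows) < 2:
        raise ProfileError("seed alignment needs at least 2 rows")
    ncol = msa.n_columns
    nrow = len(rows)
    occupancy = [sum(1 for r in rows if r[j] != "-") / nrow for j in range(ncol)]
    is_match = [occ >= match_fraction for occ in occupancy]
    L = sum(is_match)
    if L == 0:
        raise ProfileError("no column passes the match_fraction threshold")
    col_to_state = np.cumsum(is_match)  # match index (1-based) at each column

    mat = np.full((L, 20), pseudocount)
    ins = np.full((L + 1, 20), pseudocount)
    # allowed transitions, pseudocounted
    c_mm = np.full(max(L - 1, 1), pseudocount); c_mi = np.full(max(L - 1, 1), pseudocount)
    c_md = np.full(max(L - 1, 1), pseudocount); c_im = np.full(max(L - 1, 1), pseudocount)
    c_ii = np.full(max(L - 1, 1), pseudocount); c_dm = np.full(max(L - 1, 1), pseudocount)
    c_dd = np.full(max(L - 1, 1), pseudocount)
    bg = np.full(20, pseudocount)

    for r in rows:
        prev: tuple[str, int] | None = None  # (state type, match index k)
        for j, ch in enumerate(r):
            k = int(col_to_state[j])
            if is_match[j]:
                if ch != "-":
                    ai = AA_INDEX.get(ch)
                    if ai is not None:
                        mat[k - 1, ai] += 1
                        bg[ai] += 1
                    state = ("M", k)
                else:
                    state = ("D", k)
            else:
                if ch == "-":
                    continue
                ai = AA_INDEX.get(ch)
                kk = min(max(k, 1), L - 1) if L > 1 else 1
                if ai is not None:
                    ins[kk, ai] += 1
                    bg[ai] += 1
                state = ("I", kk)
            if prev is not None and L > 1:
                pt, pk = prev
                st, sk = state
                i = pk - 1  # transition array index for source state k=pk
                if pt == "M" and 1 <= pk <= L - 1:
                    if st == "M" and sk == pk + 1:
                        c_mm[i] += 1
                    elif st == "I" and sk == pk:
                        c_mi[i] += 1
                    elif st == "D" and sk == pk + 1:
                        c_md[i] += 1
                elif pt == "I" and 1 <= pk <= L - 1:
                    if st == "M" and sk == pk + 1:
                        c_im[i] += 1
                    elif st == "I" and sk == pk:
                        c_ii[i] += 1
                elif pt == "D" and 2 <= pk <= L - 1:
                    if st == "M" and sk == pk + 1:
                        c_dm[i] += 1
                    elif st == "D" and sk == pk + 1:
                        c_dd[i] += 1
            prev = state

    mat /= mat.sum(axis=1, keepdims=True)
    ins /= ins.sum(axis=1, keepdims=True)
    if background is not None:
        bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    if L > 1:
        s = c_mm + c_mi + c_md
        t_mm, t_mi, t_md = c_mm / s, c_mi / s, c_md / s
        s = c_im + c_ii
        t_im, t_ii = c_im / s, c_ii / s
        s = c_dm + c_dd
        t_dm, t_dd = c_dm / s, c_dd / s
    else:
        z = np.zeros(0)
        t_mm = t_mi = t_md = t_im = t_ii = t_dm = t_dd = z
    return ProfileHMM(
        label=label, match_emissions=mat, insert_emissions=ins,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd, background=bg, p_exit=p_exit,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _encode(seq: str) -> list[int | None]:
    out: list[int | None] = []
    for ch in seq.upper():
        idx = AA_INDEX.get(ch)
        if idx is None and ch not in _AMBIGUOUS:
            raise ProfileError(f"residue {ch!r} outside protein alphabet")
        out.append(idx)
    return out


def _log_odds(profile: ProfileHMM) -> tuple[np.ndarray, np.ndarray]:
    """(L, 21) match and insert log-odds; column 20 is ambiguity (0)."""
    lbg = np.log(profile.background)
    lo_m = np.zeros((profile.L, 21))
    lo_m[:, :20] = np.log(profile.match_emissions) - lbg[None, :]
    lo_i = np.zeros((profile.L + 1, 21))
    lo_i[:, :20] = np.log(profile.insert_emissions) - lbg[None, :]
    return lo_m, lo_i


def _length_terms(n: int) -> tuple[float, float, float]:
    """(log p_loop, log(1-p_loop), null length log-probability)."""
    p_loop = n / (n + 2.0)
    null_len = n * math.log(n / (n + 1.0)) + math.log(1.0 / (n + 1.0))
    return math.log(p_loop), math.log1p(-p_loop), null_len


def forward(profile: ProfileHMM, seq: str) -> float:
    """Forward bit score (log-odds versus the background null)."""
    xs = _encode(seq)
    n = len(xs)
    if n == 0:
        raise ProfileError("empty sequence")
    L = profile.L
    lo_m, lo_i = _log_odds(profile)
    lp, lq, null_len = _length_terms(n)
    pe = profile.p_exit
    with np.errstate(divide="ignore"):
        if L > 1:
            a_mm = np.log((1 - pe) * profile.t_mm)
            a_mi = np.log((1 - pe) * profile.t_mi)
            a_md = np.log((1 - pe) * profile.t_md)
            a_im = np.log(profile.t_im)
            a_ii = np.log(profile.t_ii)
            a_dm = np.log(profile.t_dm)
            a_dd = np.log(profile.t_dd)
        exit_lo = np.full(L, math.log(pe) if pe > 0 else LOG0)
        exit_lo[L - 1] = 0.0
    entry = -math.log(L)

    M = np.full(L, LOG0)
    I = np.full(L, LOG0)  # noqa: E741 - I_k, k=1..L-1 at indices 0..L-2
    D = np.full(L, LOG0)  # D_k, k=2..L at indices 1..L-1
    lc = LOG0
    for i in range(1, n + 1):
        x = xs[i - 1] if xs[i - 1] is not None else 20
        lb_prev = (i - 1) * lp + lq  # B after i-1 flank emissions
        newM = np.full(L, lb_prev + entry)
        if L > 1:
            core = np.logaddexp(M[:-1] + a_mm, I[:-1] + a_im)
            # D[0] is the nonexistent D_1 and stays -inf, so a_dm[0] is inert
            core = np.logaddexp(core, D[:-1] + a_dm)
            newM[1:] = np.logaddexp(newM[1:], core)
        newM += lo_m[:, x]
        if L > 1:
            newI = np.full(L, LOG0)
            newI[:-1] = np.logaddexp(M[:-1] + a_mi, I[:-1] + a_ii) + lo_i[1:L, x]
            # silent D chain within this position:
            #   D_{k+1} = logaddexp(M_k + t_md[k-1], D_k + t_dd[k-1])
            # solved by a prefix log-sum with the cumulative dd weights
            newD = np.full(L, LOG0)
            b = newM[:-1] + a_md
            ca = np.cumsum(a_dd)
            f = np.logaddexp.accumulate(b - ca)
            newD[1:] = f + ca
        else:
            newI = np.full(L, LOG0)
            newD = np.full(L, LOG0)
        M, I, D = newM, newI, newD
        e_i = _lse(M + exit_lo)
        if L > 1:
            e_i = np.logaddexp(e_i, D[L - 1])
        lc = np.logaddexp(lc + lp, e_i)
    total = lc + lq
    return float((total - null_len) / math.log(2))


def _lse(v: np.ndarray) -> float:
    m = v.max()
    if m == LOG0:
        return LOG0
    return float(m + np.log(np.exp(v - m).sum()))


def viterbi(profile: ProfileHMM, seq: str) -> tuple[float, list[tuple[str, int, int]], tuple[int, int]]:
    """Best-path bit score, state path and envelope.

    Returns (bits, path, (env_start, env_end)); the path lists
    (state_type, match_index, residue_position) for emitting core states,
    residue positions 1-based; the envelope spans the residues emitted by
    match/insert states. For sequences with no positive-scoring path the
    envelope may be a single low-scoring residue.
    """
    xs = _encode(seq)
    n = len(xs)
    if n == 0:
        raise ProfileError("empty sequence")
    L = profile.L
    lo_m, lo_i = _log_odds(profile)
    lp, lq, null_len = _length_terms(n)
    pe = profile.p_exit
    log = math.log
    a_mm = [log((1 - pe) * t) if t > 0 else LOG0 for t in profile.t_mm]
    a_mi = [log((1 - pe) * t) if t > 0 else LOG0 for t in profile.t_mi]
    a_md = [log((1 - pe) * t) if t > 0 else LOG0 for t in profile.t_md]
    a_im = [log(t) if t > 0 else LOG0 for t in profile.t_im]
    a_ii = [log(t) if t > 0 else LOG0 for t in profile.t_ii]
    a_dm = [log(t) if t > 0 else LOG0 for t in profile.t_dm]
    a_dd = [log(t) if t > 0 else LOG0 for t in profile.t_dd]
    entry = -log(L)
    exit_lo = [log(pe) if pe > 0 else LOG0] * (L - 1) + [0.0]

    NEG = LOG0
    Vm = [[NEG] * (L + 1) for _ in range(n + 1)]
    Vi = [[NEG] * (L + 1) for _ in range(n + 1)]
    Vd = [[NEG] * (L + 1) for _ in range(n + 1)]
    Pm: dict[tuple[int, int], tuple[str, int, int]] = {}
    Pi: dict[tuple[int, int], tuple[str, int, int]] = {}
    Pd: dict[tuple[int, int], tuple[str, int, int]] = {}
    best_end = (NEG, None)  # (score up to E + C tail, (i, state, k))

    for i in range(1, n + 1):
        x = xs[i - 1] if xs[i - 1] is not None else 20
        lb_prev = (i - 1) * lp + lq
        for k in range(1, L + 1):
            cands = [(lb_prev + entry, ("B", 0, i - 1))]
            if k > 1:
                cands.append((Vm[i - 1][k - 1] + a_mm[k - 2], ("M", k - 1, i - 1)))
                cands.append((Vi[i - 1][k - 1] + a_im[k - 2], ("I", k - 1, i - 1)))
                cands.append((Vd[i - 1][k - 1] + a_dm[k - 2], ("D", k - 1, i - 1)))
            sc, ptr = max(cands, key=lambda c: c[0])
            Vm[i][k] = sc + lo_m[k - 1][x]
            Pm[(i, k)] = ptr
        for k in range(1, L):
            sc_m = Vm[i - 1][k] + a_mi[k - 1]
            sc_i = Vi[i - 1][k] + a_ii[k - 1]
            if sc_m >= sc_i:
                Vi[i][k] = sc_m + lo_i[k][x]
                Pi[(i, k)] = ("M", k, i - 1)
            else:
                Vi[i][k] = sc_i + lo_i[k][x]
                Pi[(i, k)] = ("I", k, i - 1)
        for k in range(2, L + 1):
            sc_m = Vm[i][k - 1] + a_md[k - 2]
            sc_d = Vd[i][k - 1] + (a_dd[k - 2] if k > 2 else NEG)
            if sc_m >= sc_d:
                Vd[i][k] = sc_m
                Pd[(i, k)] = ("M", k - 1, i)
            else:
                Vd[i][k] = sc_d
                Pd[(i, k)] = ("D", k - 1, i)
        # close the model at position i and absorb the C-flank tail
        tail = (n - i) * lp + lq
        for k in range(1, L + 1):
            sc = Vm[i][k] + exit_lo[k - 1] + tail
            if sc > best_end[0]:
                best_end = (sc, (i, "M", k))
        sc = Vd[i][L] + tail
        if sc > best_end[0]:
            best_end = (sc, (i, "D", L))

    bits = (best_end[0] - null_len) / log(2)
    if best_end[1] is None:
        raise ProfileError("no viterbi path found")
    i, st, k = best_end[1]
    path: list[tuple[str, int, int]] = []
    while st != "B":
        if st == "M":
            path.append(("M", k, i))
            st, k, i = Pm[(i, k)]
        elif st == "I":
            path.append(("I", k, i))
            st, k, i = Pi[(i, k)]
        else:
            st, k, i = Pd[(i, k)]
    path.reverse()
    positions = [p for _, _, p in path]
    envelope = (min(positions), max(positions))
    return float(bits), path, envelope


# ---------------------------------------------------------------------------
# Calibration and scanning
# ---------------------------------------------------------------------------

def calibrate(
    profile: ProfileHMM, lengths: list[int] | np.ndarray, n_samples: int = 1000,
    seed: int = 0, frequencies: np.ndarray | None = None,
) -> tuple[float, float]:
    """Fit a Gumbel to forward scores of random null sequences.

    Null lengths are resampled from ``lengths`` (typically the lengths of the
    scanned database) and residues drawn i.i.d. from ``frequencies``
    (defaults to the profile background; pass the database's own residue
    frequencies to calibrate against its composition). Sets
    ``profile.calibration`` and returns (mu, beta).
    """
    if n_samples < 1000:
        raise ProfileError("calibration needs at least 1000 samples")
    lengths = np.asarray(lengths)
    if lengths.size == 0 or lengths.min() < 1:
        raise ProfileError("invalid null length distribution")
    freqs = profile.background if frequencies is None else np.asarray(frequencies)
    rng = np.random.default_rng(seed)
    aas = np.array(list(AA_ORDER))
    scores = np.empty(n_samples)
    for i in range(n_samples):
        m = int(rng.choice(lengths))
        s = "".join(rng.choice(aas, size=m, p=freqs))
        scores[i] = forward(profile, s)
    if scores.std() < 1e-9:
        raise ProfileError("degenerate null score distribution")
    # Gumbel fit by quantile matching (median + 95th percentile): under a
    # length-mixture null the ML fit drifts off the empirical median, which
    # is the quantity E-values must reproduce (E at the median ~ db/2).
    q50, q95 = np.quantile(scores, [0.5, 0.95])
    z50 = -math.log(-math.log(0.5))
    z95 = -math.log(-math.log(0.95))
    beta = (q95 - q50) / (z95 - z50)
    if beta <= 0:
        raise ProfileError("degenerate null score distribution")
    mu = q50 - beta * z50
    profile.calibration = (float(mu), float(beta))
    return profile.calibration


def calibrate_for_database(
    profile: ProfileHMM, seqs, n_samples: int = 1000, seed: int = 0,
) -> tuple[float, float]:
    """Calibrate against a database: null lengths and residue frequencies
    are both taken from the sequences about to be scanned."""
    lengths = [len(s.residues) for s in seqs]
    counts = np.zeros(20)
    for s in seqs:
        for ch in s.residues:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ProfileError("database has no standard residues")
    return calibrate(profile, lengths, n_samples=n_samples, seed=seed,
                     frequencies=counts / counts.sum())


def evalue(profile: ProfileHMM, bit_score: float, database_size: int) -> float:
    if profile.calibration is None:
        raise ProfileError("profile is not calibrated")
    mu, beta = profile.calibration
    return float(database_size * gumbel_r.sf(bit_score, loc=mu, scale=beta))


def scan_proteome(
    profile: ProfileHMM, seqs, e_cutoff: float = 1.0,
    partial_fraction: float = 0.6, max_domains_per_seq: int = 4,
) -> list[DomainHit]:
    """Scan sequences for domain hits at the given per-sequence E-value cutoff.

    The best envelope per sequence is located by Viterbi; to find further
    non-overlapping domains the envelope is masked (scored as background) and
    the sequence rescanned. A hit is flagged partial when its best path
    covers fewer than ``partial_fraction`` of the match columns.
    """
    if profile.calibration is None:
        raise ProfileError("profile must be calibrated before scanning")
    db_size = len(seqs)
    hits: list[DomainHit] = []
    for rec in seqs:
        residues = list(rec.residues)
        for _ in range(max_domains_per_seq):
            masked = "".join(residues)
            bits = forward(profile, masked)
            e = evalue(profile, bits, db_size)
            if e > e_cutoff:
                break
            _, path, env = viterbi(profile, masked)
            ks = [k for st, k, _ in path if st == "M"]
            span = (max(ks) - min(ks) + 1) if ks else 0
            hits.append(DomainHit(
                seq_id=rec.id, domain_label=profile.label,
                env_start=env[0], env_end=env[1], bit_score=bits, evalue=e,
                partial=span < partial_fraction * profile.L, match_span=span,
            ))
            for p in range(env[0] - 1, env[1]):
                residues[p] = "X"
    return hits
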