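"""Ka/Ks, the PPD motif pipeline, conserved columns, and the HGT rule engine.

Ka/Ks is the Nei-Gojobori (1986) pairwise estimator: fractional
synonymous/nonsynonymous site counting per codon (averaged over both
sequences), difference counting averaged over all minimal substitution
pathways that avoid stop codons, and Jukes-Cantor multiple-hit correction.

The PPD ("partial PF03936 domain") pipeline scans isoprenyl diphosphate
synthase (IDS) proteins with the TPS C-terminal-domain profile at a relaxed
E-value, deduplicates the recovered envelopes into a unique seed set, builds
a dedicated PPD profile, and reports per-set hit fractions (half-up rounding
to one decimal, matching the convention of published percentages).

The HGT screen flags a bacterial protein as a candidate plant-to-bacterium
transfer when it aligns to plant family members at >70% coverage and >80%
identity in at least two plant species while no other bacterial panel
carries a homolog above 50% identity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from Bio.Data.CodonTable import standard_dna_table

from .align_core import KarlinAltschul, MultipleAlignment, local_align
from .io_formats import SequenceRecord
from .profile_hmm import DomainHit, ProfileHMM, build_profile, scan_proteome


class MolEvoError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986
# ---------------------------------------------------------------------------

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_NTS = "ACGT"
SATURATION_P = 0.75


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None          # None when Ks == 0 (undefined flag)
    n_sites: float               # nonsynonymous sites (averaged)
    s_sites: float
    nd: float                    # nonsynonymous differences (pathway-averaged)
    sd: float
    n_codons: int
    saturated_ka: bool = False
    saturated_ks: bool = False

    @property
    def undefined_ratio(self) -> bool:
        return self.ratio is None


def _codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one codon.

    At each position the three alternative nucleotides are considered;
    changes creating stop codons are excluded from the denominator. The two
    counts always sum to 3.
    """
    aa = _CODON_TABLE[codon]
    n = s = 0.0
    for pos in range(3):
        syn = allowed = 0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in _STOPS:
                continue
            allowed += 1
            if _CODON_TABLE[alt] == aa:
                syn += 1
        if allowed:
            s += syn / allowed
            n += 1.0 - syn / allowed
        else:
            n += 1.0
    return n, s


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """(Nd, Sd) for one codon pair, averaged over minimal substitution
    pathways; pathways through stop codons are excluded unless all are."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        cur = ca
        nd = sd = 0.0
        valid = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                valid = False
            aa_cur = _CODON_TABLE.get(cur)
            aa_nxt = _CODON_TABLE.get(nxt)
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (paths if valid else blocked).append((nd, sd))
    use = paths or blocked
    nd = sum(p[0] for p in use) / len(use)
    sd = sum(p[1] for p in use) / len(use)
    return nd, sd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= SATURATION_P:
        return float("inf"), True
    if p == 0:
        return 0.0, False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Pairwise NG86 Ka/Ks on two aligned coding sequences.

    Sequences must be equal length and a multiple of 3; codons containing
    gaps in either sequence are dropped pairwise; internal stops are errors.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise MolEvoError("aligned CDS lengths differ")
    if len(cds_a) % 3:
        raise MolEvoError("aligned CDS length not divisible by 3")
    pairs = []
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        for c, name in ((ca, "first"), (cb, "second")):
            if c in _STOPS:
                if i + 3 < len(cds_a):
                    raise MolEvoError(f"internal stop codon in {name} sequence")
                break
        else:
            pairs.append((ca, cb))
            continue
        break  # trailing stop: drop it and stop consuming
    if not pairs:
        raise MolEvoError("no comparable codons")
    n_sites = s_sites = nd = sd = 0.0
    for ca, cb in pairs:
        na, sa = _codon_sites(ca)
        nb, sb = _codon_sites(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        d_n, d_s = _pathway_diffs(ca, cb)
        nd += d_n
        sd += d_s
    p_n = nd / n_sites if n_sites else 0.0
    p_s = sd / s_sites if s_sites else 0.0
    ka, sat_ka = _jukes_cantor(p_n)
    ks, sat_ks = _jukes_cantor(p_s)
    ratio = None
    if ks > 0 and math.isfinite(ks) and math.isfinite(ka):
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, n_sites=n_sites, s_sites=s_sites,
                      nd=nd, sd=sd, n_codons=len(pairs),
                      saturated_ka=sat_ka, saturated_ks=sat_ks)


# ---------------------------------------------------------------------------
# PPD motif pipeline
# ---------------------------------------------------------------------------

def percent_half_up(numerator: int, denominator: int) -> float:
    """Exact rational percentage, rounded half-up to one decimal."""
    if denominator <= 0:
        raise MolEvoError("denominator must be positive")
    frac = Fraction(numerator * 100, denominator)
    d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PpdDiscovery:
    hits: list[DomainHit]
    seeds: list[str]             # unique envelope subsequences
    n_raw: int
    n_unique: int
    seed_length_range: tuple[int, int]


def discover_ppd(
    ids_proteins: list[SequenceRecord], ctd_profile: ProfileHMM,
    relaxed_e: float = 100.0, expected_len: int = 33,
) -> PpdDiscovery:
    """Partial C-terminal-domain envelopes on IDS proteins at a relaxed
    E-value; extracted subsequences are exact-string-deduplicated.

    One best envelope is taken per protein; envelopes far from the expected
    motif length (outside 0.6-1.5x) are discarded as spurious relaxed-
    threshold pickups.
    """
    hits = scan_proteome(ctd_profile, ids_proteins, e_cutoff=relaxed_e,
                         max_domains_per_seq=1)
    by_id = {r.id: r.residues for r in ids_proteins}
    lo, hi = 0.6 * expected_len, 1.5 * expected_len
    kept = [h for h in hits if lo <= h.env_end - h.env_start + 1 <= hi]
    raw = [by_id[h.seq_id][h.env_start - 1:h.env_end] for h in kept]
    seeds = sorted(set(raw))
    lens = [len(s) for s in seeds] or [0]
    return PpdDiscovery(hits=kept, seeds=seeds, n_raw=len(raw),
                        n_unique=len(seeds), seed_length_range=(min(lens), max(lens)))


def build_ppd_profile(seeds: list[str], label: str = "PPD") -> ProfileHMM:
    """PPD profile from the unique seed set (aligned progressively first
    when lengths differ).

    The profile background is the standard amino acid composition rather
    than the seed frequencies: a 33-residue motif set is far too small and
    biased to define its own null."""
    from ._jtt import JTT_FREQS
    from .align_core import progressive_msa
    if len(seeds) < 2:
        raise MolEvoError("need at least 2 PPD seeds")
    named = {f"ppd{i:03d}": s for i, s in enumerate(seeds)}
    if len({len(s) for s in seeds}) == 1:
        msa = MultipleAlignment(named)
    else:
        msa = progressive_msa(named)
    return build_profile(msa, label=label, background=JTT_FREQS)


@dataclass(frozen=True)
class PpdProfileReport:
    set_name: str
    n_hits: int
    set_size: int
    percentage: float            # one decimal, half-up

    def __post_init__(self) -> None:
        if not 0 <= self.percentage <= 100:
            raise MolEvoError("percentage out of range")


def ppd_scan_report(
    ppd_profile: ProfileHMM, target_sets: dict[str, list[SequenceRecord]],
    e_cutoff: float = 1.0,
) -> dict[str, PpdProfileReport]:
    reports = {}
    for name, seqs in target_sets.items():
        if not seqs:
            raise MolEvoError(f"empty target set {name!r}")
        hits = scan_proteome(ppd_profile, seqs, e_cutoff=e_cutoff,
                             max_domains_per_seq=1)
        n = len({h.seq_id for h in hits})
        reports[name] = PpdProfileReport(name, n, len(seqs),
                                         percent_half_up(n, len(seqs)))
    return reports


def conserved_columns(
    msa: MultipleAlignment, identity_threshold: float = 1.0,
    subset: set[str] | None = None,
) -> list[int]:
    """0-based indices of columns whose non-gap residues agree across all
    rows (or across ``subset``) at the given fraction (1.0 = fully
    conserved, the "100% homolog" convention)."""
    if not 0 < identity_threshold <= 1:
        raise MolEvoError("identity_threshold must be in (0, 1]")
    ids = [i for i in msa.ids if subset is None or i in subset]
    if not ids:
        raise MolEvoError("empty row subset")
    out = []
    for j in range(msa.n_columns):
        residues = [msa.rows[i][j] for i in ids if msa.rows[i][j] != "-"]
        if not residues:
            continue
        top = max(residues.count(c) for c in set(residues))
        if top / len(residues) >= identity_threshold:
            out.append(j)
    return out


# ---------------------------------------------------------------------------
# HGT rule engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HgtCandidate:
    bacterial_protein: str
    best_plant_hit: tuple[str, float, float]   # (plant id, identity, coverage)
    n_plant_species_high_similarity: int
    n_other_bacteria_with_homolog: int
    verdict: str                               # HGT_candidate | rejected
    failed_rules: tuple[str, ...]


def hgt_verdict(
    coverage: float, identity: float, n_plant_species_high: int, n_other_bacteria: int,
    min_coverage: float = 0.70, min_identity: float = 0.80,
    min_species: int = 2, max_other_identity_hits: int = 0,
) -> tuple[str, tuple[str, ...]]:
    """Pure four-predicate verdict used by the screen (and by its oracle)."""
    failed = []
    if not coverage > min_coverage:
        failed.append("coverage")
    if not identity > min_identity:
        failed.append("identity")
    if not n_plant_species_high >= min_species:
        failed.append("multiple_species")
    if not n_other_bacteria <= max_other_identity_hits:
        failed.append("bacterial_homolog")
    return ("HGT_candidate" if not failed else "rejected", tuple(failed))


def screen_hgt(
    bacterial_proteins: list[SequenceRecord],
    plant_panels: dict[str, list[SequenceRecord]],
    other_bacteria_panels: dict[str, list[SequenceRecord]],
    candidate_e: float = 0.01,
    candidate_coverage: float = 0.70,
    high_identity: float = 0.80,
    bacterial_identity: float = 0.50,
    calibration: KarlinAltschul | None = None,
) -> list[HgtCandidate]:
    """Two-stage screen for plant-to-bacterium transfer candidates.

    Stage 1 keeps bacterial queries with any plant alignment at
    >= ``candidate_coverage`` query coverage and E <= ``candidate_e``.
    Stage 2 applies the verdict rule on the best plant hit, the number of
    plant species with a high-similarity hit, and homolog presence in the
    other-bacteria panels.
    """
    if not plant_panels or not bacterial_proteins:
        raise MolEvoError("panels must be non-empty")
    out: list[HgtCandidate] = []
    for query in bacterial_proteins:
        best = ("", 0.0, 0.0, -math.inf)  # (id, identity, coverage, score)
        species_high = set()
        stage1 = False
        for species, panel in plant_panels.items():
            for target in panel:
                aln = local_align(query.residues, target.residues,
                                  query_id=query.id, subject_id=target.id,
                                  calibration=calibration)
                if not aln.is_hit:
                    continue
                if aln.query_coverage >= candidate_coverage and aln.evalue <= candidate_e:
                    stage1 = True
                if aln.score > best[3]:
                    best = (target.id, aln.identity, aln.query_coverage, aln.score)
                if aln.query_coverage > candidate_coverage and aln.identity > high_identity:
                    species_high.add(species)
        if not stage1:
            out.append(HgtCandidate(query.id, (best[0], best[1], best[2]), 0, 0,
                                    "rejected", ("candidate_stage",)))
            continue
        n_other = 0
        for panel in other_bacteria_panels.values():
            for target in panel:
                aln = local_align(query.residues, target.residues,
                                  query_id=query.id, subject_id=target.id,
                                  calibration=calibration)
                if aln.is_hit and aln.identity > bacterial_identity:
                    n_other += 1
        verdict, failed = hgt_verdict(best[2], best[1], len(species_high), n_other,
                                      min_coverage=candidate_coverage,
                                      min_identity=high_identity)
        out.append(HgtCandidate(query.id, (best[0], best[1], best[2]),
                                len(species_high), n_other, verdict, failed))
    return out
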