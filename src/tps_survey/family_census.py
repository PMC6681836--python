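"""Per-gene domain architectures and the family census.

A gene is a family member when it carries the N-terminal domain, the
C-terminal domain, or both; full-length members carry both. The census
identities (n_ntd_only = n_ntd_total - n_full, etc.) are the "domain loss"
arithmetic reported per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import KarlinAltschul, local_align
from .io_formats import SequenceRecord
from .profile_hmm import DomainHit, ProfileHMM, scan_proteome

NTD = "NTD"
CTD = "CTD"
CATEGORIES = ("full_length", "ntd_only", "ctd_only", "none")


class CensusError(ValueError):
    pass


@dataclass
class DomainArchitecture:
    gene_id: str
    has_ntd: bool
    has_ctd: bool
    evidence: list[DomainHit] = field(default_factory=list)
    pseudogene: bool = False     # premature stop upstream; kept in the census

    @property
    def category(self) -> str:
        if self.has_ntd and self.has_ctd:
            return "full_length"
        if self.has_ntd:
            return "ntd_only"
        if self.has_ctd:
            return "ctd_only"
        return "none"


@dataclass(frozen=True)
class CensusSummary:
    species: str
    n_ntd_total: int
    n_ctd_total: int
    n_full: int

    @property
    def n_ntd_only(self) -> int:
        return self.n_ntd_total - self.n_full

    @property
    def n_ctd_only(self) -> int:
        return self.n_ctd_total - self.n_full

    @property
    def n_members(self) -> int:
        return self.n_full + self.n_ntd_only + self.n_ctd_only

    def __post_init__(self) -> None:
        if self.n_ntd_only < 0 or self.n_ctd_only < 0:
            raise CensusError("full-length count exceeds a domain total")


def classify_architecture(
    gene_id: str, hits: list[DomainHit], known_genes: set[str] | None = None,
) -> DomainArchitecture:
    """Collapse deduplicated per-domain hits into one architecture per gene."""
    if known_genes is not None and gene_id not in known_genes:
        raise CensusError(f"hit references unknown gene {gene_id!r}")
    for h in hits:
        if h.seq_id != gene_id:
            raise CensusError(f"hit for {h.seq_id!r} passed to gene {gene_id!r}")
    labels = {h.domain_label for h in hits}
    return DomainArchitecture(gene_id, NTD in labels, CTD in labels, list(hits))


def census(architectures: list[DomainArchitecture], species: str = "") -> CensusSummary:
    n_ntd = sum(1 for a in architectures if a.has_ntd)
    n_ctd = sum(1 for a in architectures if a.has_ctd)
    n_full = sum(1 for a in architectures if a.category == "full_length")
    return CensusSummary(species, n_ntd, n_ctd, n_full)


def census_from_totals(
    n_ntd_total: int, n_ctd_total: int, n_full: int, species: str = "",
) -> CensusSummary:
    """Census from the per-domain totals and the full-length count, as
    reported in published per-species tables."""
    return CensusSummary(species, n_ntd_total, n_ctd_total, n_full)


def supplemental_homology_search(
    representatives: list[SequenceRecord],
    proteome: list[SequenceRecord],
    profiles: dict[str, ProfileHMM],
    hmm_hit_genes: set[str],
    e_cutoff: float = 0.01,
    rescan_e_cutoff: float = 1.0,
    calibration: KarlinAltschul | None = None,
) -> tuple[list[str], list[str]]:
    """Recover family members missed by the profile search.

    Each representative (an HMM-confirmed member) is aligned locally against
    every proteome sequence not already in the HMM hit set; proteins hitting
    at E <= ``e_cutoff`` become candidates and are admitted only if a domain
    rescan at ``rescan_e_cutoff`` confirms either domain. Returns
    (admitted gene ids, rejected-candidate gene ids); rejected candidates
    are reported but never counted.
    """
    if not representatives:
        raise CensusError("empty representative set")
    candidates: list[SequenceRecord] = []
    seen: set[str] = set()
    for target in proteome:
        if target.id in hmm_hit_genes or target.id in seen:
            continue
        for rep in representatives:
            aln = local_align(rep.residues, target.residues,
                              query_id=rep.id, subject_id=target.id,
                              calibration=calibration)
            if aln.is_hit and aln.evalue <= e_cutoff:
                candidates.append(target)
                seen.add(target.id)
                break
    admitted: set[str] = set()
    for profile in profiles.values():
        if candidates:
            for hit in scan_proteome(profile, candidates, e_cutoff=rescan_e_cutoff):
                admitted.add(hit.seq_id)
    rejected = [c.id for c in candidates if c.id not in admitted]
    return sorted(admitted), sorted(rejected)


def has_premature_stop(cds: str) -> bool:
    """Internal stop codon check; such genes stay in the census but are
    excluded from phylogenetic analysis."""
    from Bio.Seq import Seq
    if len(cds) % 3:
        cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate())
    return "*" in aa[:-1]
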