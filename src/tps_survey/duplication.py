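"""Expansion-mechanism classification: tandem, segmental, mobile-element.

Tandem duplication is a conjunction of four rules evaluated on a
child/parent gene pair: alignable coverage >= 30% of the child at E <= 0.01,
amino acid identity >= 70%, rank distance <= 10 genes, and midpoint bp
distance within a genome-size-dependent window (100 kb for genomes under
200 Mb, 350 kb otherwise). Segmental duplication is collinear anchor
chaining (DAGchainer-style sparse DP) keeping blocks of at least five gene
pairs. Mobile-element association is interval arithmetic on 50 kb flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import PairwiseAlignment
from .io_formats import FeatureInterval, GeneModel, GenomeAnnotation

SMALL_GENOME_BP = 200_000_000
SMALL_WINDOW = 100_000
LARGE_WINDOW = 350_000
FLANK_WINDOW = 50_000
MIN_BLOCK_PAIRS = 5


def tandem_window(genome_size: int) -> int:
    """bp window for the tandem proximity rule (100 kb below 200 Mb, else 350 kb)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return SMALL_WINDOW if genome_size < SMALL_GENOME_BP else LARGE_WINDOW


@dataclass(frozen=True)
class TandemCall:
    child: str
    parent: str
    identity: float
    coverage: float
    rank_distance: int
    bp_distance: float
    window: int
    rule_flags: dict[str, bool]
    verdict: bool

    def __post_init__(self) -> None:
        assert self.verdict == all(self.rule_flags.values())


def call_tandem(
    a: GeneModel, b: GeneModel, aln: PairwiseAlignment, annotation: GenomeAnnotation,
    min_coverage: float = 0.30, min_identity: float = 0.70, max_rank_distance: int = 10,
) -> TandemCall:
    """Evaluate the tandem-duplication rules for child ``b`` against parent ``a``.

    ``aln`` must be the child-as-query local alignment (coverage is
    child-relative). Genes on different chromosomes simply fail the
    proximity rule; that is a negative verdict, not an error. Rank distance
    is |rank_a - rank_b| and bp distance is midpoint-to-midpoint.
    """
    same_chrom = a.chrom == b.chrom
    rank_distance = abs(a.rank - b.rank) if same_chrom else -1
    bp_distance = abs(a.midpoint - b.midpoint) if same_chrom else float("inf")
    window = tandem_window(annotation.genome_size)
    flags = {
        "coverage": aln.query_coverage >= min_coverage,
        "identity": aln.identity >= min_identity,
        "proximity": (
            same_chrom
            and rank_distance <= max_rank_distance
            and bp_distance <= window
        ),
    }
    return TandemCall(
        child=b.gene_id, parent=a.gene_id, identity=aln.identity,
        coverage=aln.query_coverage, rank_distance=rank_distance,
        bp_distance=bp_distance, window=window, rule_flags=flags,
        verdict=all(flags.values()),
    )


# ---------------------------------------------------------------------------
# Collinear anchor chaining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    pos_a: float          # coordinate (or rank) on genome/chromosome A
    pos_b: float


@dataclass
class SyntenyBlock:
    anchor_pairs: list[tuple[str, str]]
    chain_score: float
    orientation: int      # +1 collinear, -1 inverted
    chrom_a: str = ""
    chrom_b: str = ""
    min_pairs: int = MIN_BLOCK_PAIRS

    def __post_init__(self) -> None:
        if len(self.anchor_pairs) < self.min_pairs:
            raise ValueError(f"synteny block needs >= {self.min_pairs} anchor pairs")


def _best_chain(
    anchors: list[Anchor], max_gap: float, gap_penalty: float, orientation: int,
) -> tuple[float, list[int]]:
    """Max-score increasing chain (DAGchainer-style DP over sorted anchors)."""
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].pos_a, anchors[i].pos_b))
    score = [1.0] * len(order)
    prev = [-1] * len(order)
    for oi, i in enumerate(order):
        for oj in range(oi):
            j = order[oj]
            da = anchors[i].pos_a - anchors[j].pos_a
            db = (anchors[i].pos_b - anchors[j].pos_b) * orientation
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            cand = score[oj] + 1.0 - gap_penalty * (da + db)
            if cand > score[oi]:
                score[oi] = cand
                prev[oi] = oj
    best = max(range(len(order)), key=lambda oi: score[oi])
    chain = []
    oi = best
    while oi != -1:
        chain.append(order[oi])
        oi = prev[oi]
    chain.reverse()
    return score[best], chain


def chain_anchors(
    anchors: list[Anchor], max_gap: float = 10.0, min_pairs: int = MIN_BLOCK_PAIRS,
    gap_penalty: float = 0.01,
) -> list[SyntenyBlock]:
    """Greedy extraction of maximum-score collinear chains in both orientations.

    Positions are gene ranks by default (max_gap 10 genes); any monotone
    coordinate works if max_gap and gap_penalty are rescaled.
    Anchors score 1 each with a linear penalty on the coordinate gaps; the
    best chain is removed and the search repeated; chains shorter than
    ``min_pairs`` are discarded. Translation of coordinates leaves scores
    unchanged (only gaps enter the score).
    """
    remaining = list(dict.fromkeys(anchors))
    blocks: list[SyntenyBlock] = []
    while len(remaining) >= min_pairs:
        cands = [(_best_chain(remaining, max_gap, gap_penalty, o), o) for o in (1, -1)]
        ((sc, chain), orient) = max(cands, key=lambda c: (c[0][0], c[1]))
        if len(chain) < min_pairs:
            break
        chosen = [remaining[i] for i in chain]
        blocks.append(SyntenyBlock(
            anchor_pairs=[(a.gene_a, a.gene_b) for a in chosen],
            chain_score=sc, orientation=orient, min_pairs=min_pairs,
        ))
        chosen_set = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in chosen_set]
    return blocks


# ---------------------------------------------------------------------------
# Mobile-element flank overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementOverlap:
    gene_id: str
    element: FeatureInterval | None
    relation: str                 # contained | partial | flank_only | none
    flank_window: int = FLANK_WINDOW


def _relation(gene: GeneModel, e: FeatureInterval, window: int) -> str:
    if e.chrom != gene.chrom:
        return "none"
    if e.start <= gene.start and gene.end <= e.end:
        return "contained"
    if e.start <= gene.end and gene.start <= e.end:
        return "partial"
    if e.start <= gene.end + window and gene.start - window <= e.end:
        return "flank_only"
    return "none"


_RANKING = {"contained": 3, "partial": 2, "flank_only": 1, "none": 0}


def flank_overlap(
    gene: GeneModel, elements: list[FeatureInterval], window: int = FLANK_WINDOW,
) -> ElementOverlap:
    """Strongest relation between a gene and any element within 50 kb flanks."""
    best: tuple[int, FeatureInterval | None] = (0, None)
    for e in elements:
        r = _relation(gene, e, window)
        if _RANKING[r] > best[0]:
            best = (_RANKING[r], e)
    relation = [k for k, v in _RANKING.items() if v == best[0]][0]
    return ElementOverlap(gene.gene_id, best[1], relation, window)
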