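"""Domain-wise phylogenies and subfamily assignment.

Trees are neighbor-joining on JTT maximum-likelihood distances with
nonparametric bootstrap supports. Subfamily assignment (TPS-a..h) anchors a
query domain sequence in a labeled reference panel: the query joins a joint
NJ tree and inherits the label of its smallest enclosing reference group
when that group is label-pure; ties and label-mixed groups stay unassigned.
When the two domains of a full-length gene disagree, the N-terminal-domain
call wins and the conflict is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .align_core import (
    AlignmentError, DistanceMatrix, MultipleAlignment, jtt_distance_matrix,
    progressive_msa,
)
from .io_formats import SequenceRecord

SUBFAMILIES = ("a", "b", "c", "d", "e/f", "g", "h")


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class SubfamilyAssignment:
    gene_id: str
    subfamily: str               # one of SUBFAMILIES or "unassigned"
    domain_used: str             # NTD | CTD
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.conflict and self.domain_used != "NTD":
            raise PhyloError("conflicting assignments must use the NTD tree")


@dataclass
class ReferencePanel:
    """Labeled reference domain sequences, per domain."""
    references: dict[str, list[tuple[str, str, str]]]  # domain -> (id, subfamily, seq)

    def __post_init__(self) -> None:
        for domain, refs in self.references.items():
            if not refs:
                raise PhyloError(f"empty reference panel for {domain}")

    @classmethod
    def from_fasta(cls, records_by_domain: dict[str, list[SequenceRecord]]) -> "ReferencePanel":
        """Headers carry the label as 'subfamily=<x>' in the description."""
        refs: dict[str, list[tuple[str, str, str]]] = {}
        for domain, records in records_by_domain.items():
            out = []
            for r in records:
                label = None
                for tok in r.description.split():
                    if tok.startswith("subfamily="):
                        label = tok.split("=", 1)[1]
                if label is None:
                    raise PhyloError(f"reference {r.id} lacks a subfamily= tag")
                out.append((r.id, label, r.residues))
            refs[domain] = out
        return cls(refs)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero
    (tree attribute ``negative_branches_clamped`` records how many)."""
    if len(dm.ids) < 3:
        raise PhyloError("NJ needs at least 3 taxa")
    tree = _skbio_nj(_SkbioDM(dm.d, ids=dm.ids))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    tree.negative_branches_clamped = clamped
    return tree


def _canonical_bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the side not containing the reference
    taxon (lexicographically smallest leaf), so rooting is irrelevant."""
    anchor = min(taxa)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def bootstrap(
    msa: MultipleAlignment, n_reps: int = 100, seed: int = 0,
    max_distance: float = 10.0,
) -> TreeNode:
    """Column-resampling bootstrap.

    Returns the NJ tree of the full alignment with ``support`` attributes
    (fraction of replicate trees containing each original bipartition) on
    internal nodes.
    """
    if n_reps < 1:
        raise PhyloError("need at least one bootstrap replicate")
    if msa.n_columns < 2:
        raise PhyloError("cannot resample a single-column alignment")
    ids = msa.ids
    taxa = frozenset(ids)
    tree = nj_tree(jtt_distance_matrix(msa, max_distance=max_distance))
    counts: dict[frozenset[str], int] = {
        bp: 0 for bp in _canonical_bipartitions(tree, taxa)
    }
    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    rows = {i: msa.rows[i] for i in ids}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = MultipleAlignment({i: "".join(rows[i][c] for c in cols) for i in ids})
        try:
            rep_tree = nj_tree(jtt_distance_matrix(rep, max_distance=max_distance))
        except AlignmentError:
            continue  # a replicate can lose all shared columns for some pair
        rep_bps = _canonical_bipartitions(rep_tree, taxa)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    anchor = min(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if side in counts:
            node.support = counts[side] / n_reps
            node.name = f"{node.support:.3f}"
    return tree


def to_newick(tree: TreeNode) -> str:
    import io
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def classify_query(
    query_id: str, query_seq: str, refs: list[tuple[str, str, str]],
    max_distance: float = 10.0,
) -> str:
    """Label of the smallest label-pure reference group enclosing the query.

    A joint NJ tree of query + references is built; among all bipartition
    sides containing the query and at least one reference, the smallest is
    examined: if its references all share one subfamily, that subfamily is
    returned, otherwise "unassigned" (ties/paraphyly contract).
    """
    if not refs:
        raise PhyloError("empty panel")
    labels = {rid: lab for rid, lab, _ in refs}
    seqs = {rid: seq for rid, _, seq in refs}
    if query_id in seqs:
        raise PhyloError(f"query id {query_id!r} collides with a reference")
    seqs[query_id] = query_seq
    if len(seqs) < 3:
        # degenerate panel: nearest reference by distance
        ref_id = refs[0][0]
        return labels[ref_id]
    msa = progressive_msa(seqs)
    tree = nj_tree(jtt_distance_matrix(msa, max_distance=max_distance))
    taxa = frozenset(seqs)
    sides: list[frozenset[str]] = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if query_id not in side:
            side = taxa - side
        if any(r in side for r in labels):
            sides.append(side)
    sides.append(taxa)  # fallback: the whole panel
    min_size = min(len(s) for s in sides)
    found: set[str] = set()
    for side in sides:
        if len(side) == min_size:  # all minimal sides must agree (tie contract)
            found |= {labels[r] for r in side if r in labels}
    return found.pop() if len(found) == 1 else "unassigned"


def assign_subfamily(
    gene_id: str, panel: ReferencePanel,
    ntd_seq: str | None = None, ctd_seq: str | None = None,
) -> SubfamilyAssignment:
    """Per-gene subfamily from one or both domain sequences.

    With both domains available the NTD-tree call takes precedence; a
    disagreement with an assigned CTD call sets the conflict flag.
    """
    if ntd_seq is None and ctd_seq is None:
        raise PhyloError(f"{gene_id}: no domain sequence provided")
    ntd_call = (
        classify_query(f"{gene_id}__q", ntd_seq, panel.references["NTD"])
        if ntd_seq is not None else None
    )
    ctd_call = (
        classify_query(f"{gene_id}__q", ctd_seq, panel.references["CTD"])
        if ctd_seq is not None else None
    )
    if ntd_call is None:
        return SubfamilyAssignment(gene_id, ctd_call, "CTD", False)
    conflict = (
        ctd_call is not None
        and ctd_call != "unassigned"
        and ntd_call != "unassigned"
        and ctd_call != ntd_call
    )
    return SubfamilyAssignment(gene_id, ntd_call, "NTD", conflict)
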