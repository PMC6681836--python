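import itertools

import numpy as np
import pytest

from tps_survey.align_core import DistanceMatrix, MultipleAlignment
from tps_survey.phylo_classify import (
    PhyloError, ReferencePanel, SubfamilyAssignment, assign_subfamily,
    bootstrap, classify_query, nj_tree, to_newick,
)


# ---------------------------------------------------------------------------
# minimum-evolution enumeration oracle
# ---------------------------------------------------------------------------

def _all_unrooted_topologies(n_leaves):
    """Edge lists of every unrooted binary topology (3 leaves -> 1 tree,
    4 -> 3, 5 -> 15). Internal nodes get negative ids."""
    trees = [[(-1, 0), (-1, 1), (-1, 2)]]
    next_internal = [-2]
    for leaf in range(3, n_leaves):
        out = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal[0]
                new = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, leaf)]
                out.append(new)
        next_internal[0] -= 1
        trees = out
    return trees


def _path_edges(edges, a, b):
    adj = {}
    for i, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, i))
        adj.setdefault(v, []).append((u, i))
    stack = [(a, [])]
    seen = {a}
    while stack:
        node, path = stack.pop()
        if node == b:
            return path
        for nxt, ei in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append((nxt, path + [ei]))
    raise AssertionError("disconnected tree")


def _ols_tree_length(edges, d, n_leaves):
    pairs = list(itertools.combinations(range(n_leaves), 2))
    a = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for ei in _path_edges(edges, i, j):
            a[r, ei] = 1.0
        y[r] = d[i, j]
    x, residuals, *_ = np.linalg.lstsq(a, y, rcond=None)
    fit = float(((a @ x - y) ** 2).sum())
    return float(x.sum()), fit


def _bipartitions_from_edges(edges, names):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for u, v in edges:
        if u >= 0 or v >= 0:
            continue  # leaf edge -> trivial split
        # leaves on the v side when edge (u, v) is removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node >= 0:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        names_side = frozenset(names[i] for i in side)
        anchor = min(names)
        if anchor in names_side:
            names_side = frozenset(names) - names_side
        out.add(names_side)
    return out


def _tree_bipartitions(tree, names):
    taxa = frozenset(names)
    anchor = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def _additive_matrix(edges, lengths, n_leaves):
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = sum(lengths[e] for e in _path_edges(edges, i, j))
    return d


class TestNjTree:
    def test_three_taxa_closed_form(self):
        # x = (dab + dac - dbc)/2 and cyclic analogues
        d = np.array([[0, 0.5, 0.7], [0.5, 0, 0.8], [0.7, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].distance(tips["B"]) == pytest.approx(0.5)
        assert tips["A"].distance(tips["C"]) == pytest.approx(0.7)
        assert tips["B"].distance(tips["C"]) == pytest.approx(0.8)

    def test_four_taxon_additive_exact_recovery(self):
        edges = [(-1, 0), (-1, 1), (-1, -2), (-2, 2), (-2, 3)]
        lengths = [1.0, 2.0, 1.5, 3.0, 4.0]
        names = ["A", "B", "C", "D"]
        d = _additive_matrix(edges, lengths, 4)
        tree = nj_tree(DistanceMatrix(names, d))
        assert _tree_bipartitions(tree, names) == _bipartitions_from_edges(edges, names)
        tips = {t.name: t for t in tree.tips()}
        for i, j in itertools.combinations(range(4), 2):
            assert tips[names[i]].distance(tips[names[j]]) == pytest.approx(d[i, j])

    def test_five_taxon_nj_matches_minimum_evolution_enumeration(self):
        edges = [(-1, 0), (-1, 1), (-1, -2), (-2, 2), (-2, -3), (-3, 3), (-3, 4)]
        lengths = [0.8, 1.2, 0.6, 2.0, 0.9, 1.1, 1.7]
        names = ["A", "B", "C", "D", "E"]
        d = _additive_matrix(edges, lengths, 5)
        topologies = _all_unrooted_topologies(5)
        assert len(topologies) == 15
        scored = [(_ols_tree_length(t, d, 5), t) for t in topologies]
        # minimum evolution: shortest total OLS length (perfect fit included)
        (best_len, best_fit), best_topo = min(scored, key=lambda s: s[0][0])
        assert best_fit == pytest.approx(0.0, abs=1e-18)
        tree = nj_tree(DistanceMatrix(names, d))
        assert (_tree_bipartitions(tree, names)
                == _bipartitions_from_edges(best_topo, names))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_negative_branches_clamped(self):
        # a non-additive matrix known to induce a negative NJ branch
        d = np.array([
            [0.0, 0.1, 0.6, 0.6],
            [0.1, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.05],
            [0.6, 0.6, 0.05, 0.0]])
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert all((n.length or 0) >= 0 for n in tree.traverse())

    def test_newick_output_parses(self):
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        nwk = to_newick(nj_tree(DistanceMatrix(["A", "B", "C"], d)))
        assert nwk.endswith(";") and "A" in nwk


class TestBootstrap:
    def _two_clade_msa(self):
        s1 = "AAAAAAAAAACCCCCCCCCC"
        s2 = "WWWWWWWWWWYYYYYYYYYY"
        rows = {f"x{i}": s1 for i in range(3)} | {f"y{i}": s2 for i in range(3)}
        return MultipleAlignment(rows)

    def test_clean_central_split_has_full_support(self):
        tree = bootstrap(self._two_clade_msa(), n_reps=50, seed=1)
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")]
        assert supports and max(supports) == 1.0

    def test_same_seed_reproducible(self):
        t1 = bootstrap(self._two_clade_msa(), n_reps=30, seed=7)
        t2 = bootstrap(self._two_clade_msa(), n_reps=30, seed=7)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False)
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False)
                    if hasattr(n, "support"))
        assert s1 == s2

    def test_star_like_data_has_weak_supports(self):
        rng = np.random.default_rng(11)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        rows = {f"r{i}": "".join(rng.choice(aas, size=60)) for i in range(6)}
        tree = bootstrap(MultipleAlignment(rows), n_reps=60, seed=2)
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")]
        assert supports and np.mean(supports) < 0.8

    def test_single_column_rejected(self):
        with pytest.raises(PhyloError):
            bootstrap(MultipleAlignment({"a": "M", "b": "K", "c": "T"}), 10, 0)


class TestSubfamilyAssignment:
    def test_query_identical_to_reference_inherits_its_label(self, subfamily_panels):
        refs, _ = subfamily_panels["NTD"]
        c_ref = next(r for r in refs if r[1] == "c")
        assert classify_query("q", c_ref[2], refs) == "c"

    def test_equidistant_query_is_unassigned(self):
        a = "AAAAAAAAAAAAAAAAAAAACCCCCCCCCCCCCCCCCCCC"
        b = "WWWWWWWWWWWWWWWWWWWWYYYYYYYYYYYYYYYYYYYY"
        chimera = a[:20] + b[20:]
        refs = [("ra1", "a", a), ("ra2", "a", a), ("rb1", "b", b), ("rb2", "b", b)]
        assert classify_query("q", chimera, refs) == "unassigned"

    def test_accuracy_on_held_out_queries(self, subfamily_panels):
        refs, queries = subfamily_panels["NTD"]
        correct = sum(classify_query(qid, seq, refs) == label
                      for qid, label, seq in queries)
        assert correct == len(queries)

    def test_invariant_to_reference_order_and_duplication(self, subfamily_panels):
        refs, queries = subfamily_panels["NTD"]
        qid, label, seq = queries[0]
        shuffled = list(reversed(refs))
        duplicated = refs + [(r[0] + "_dup", r[1], r[2]) for r in refs[:3]]
        assert classify_query(qid, seq, shuffled) == label
        assert classify_query(qid, seq, duplicated) == label

    def test_domain_conflict_keeps_ntd_call(self, subfamily_panels):
        refs_ntd, queries_ntd = subfamily_panels["NTD"]
        refs_ctd, queries_ctd = subfamily_panels["CTD"]
        panel = ReferencePanel({"NTD": refs_ntd, "CTD": refs_ctd})
        ntd_a = next(seq for _, label, seq in queries_ntd if label == "a")
        ctd_g = next(seq for _, label, seq in queries_ctd if label == "g")
        call = assign_subfamily("gene1", panel, ntd_seq=ntd_a, ctd_seq=ctd_g)
        assert call.subfamily == "a" and call.conflict and call.domain_used == "NTD"

    def test_ctd_only_gene_uses_ctd_tree(self, subfamily_panels):
        refs_ctd, queries_ctd = subfamily_panels["CTD"]
        panel = ReferencePanel({"NTD": subfamily_panels["NTD"][0], "CTD": refs_ctd})
        qid, label, seq = queries_ctd[0]
        call = assign_subfamily("gene2", panel, ctd_seq=seq)
        assert call.domain_used == "CTD" and call.subfamily == label

    def test_conflict_invariant_enforced(self):
        with pytest.raises(PhyloError):
            SubfamilyAssignment("g", "a", "CTD", conflict=True)

    def test_empty_panel_rejected(self):
        with pytest.raises(PhyloError):
            ReferencePanel({"NTD": []})
        with pytest.raises(PhyloError):
            classify_query("q", "MKT", [])
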