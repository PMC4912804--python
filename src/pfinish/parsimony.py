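"""Parsimony matrix statistics: informative-site counting, Fitch tree
length, and ensemble consistency / retention indices.

The step count uses the Hartigan generalization of the Fitch pass so
multifurcations (including the basal trifurcation of an unrooted
binary tree) are scored exactly. Gap and ambiguity characters are
treated as missing data: a missing leaf may take any state and never
forces a step on its pendant edge.

Per site, for n_eff taxa with non-missing states:
  min steps = (#distinct states) - 1          (attainable on some tree)
  max steps = n_eff - (largest state class)   (steps on the star tree)
Ensemble CI = sum(min) / sum(obs); RI = (sum(max) - sum(obs)) /
(sum(max) - sum(min)). By the PAUP* convention, parsimony-uninformative
sites are excluded from the CI sums (they always have min = obs = max,
so the RI is unaffected).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import FormatError, ParameterError, SizeError

_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8}
_MISSING = 15
_BIT_STATE = {1: "A", 2: "C", 4: "G", 8: "T"}


def state_bits(ch: str) -> int:
    """4-bit state mask for one matrix character; anything that is not
    an unambiguous nucleotide counts as missing."""
    return _STATE_BITS.get(ch.upper(), _MISSING)


def is_missing(ch: str) -> bool:
    return state_bits(ch) == _MISSING


@dataclass
class CharacterMatrix:
    """Rectangular aligned matrix over {A,C,G,T, gap, missing}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise FormatError("one row per taxon required")
        if len({len(r) for r in self.rows} or {0}) > 1:
            raise FormatError("matrix is not rectangular")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def site(self, i: int) -> dict[str, str]:
        return {t: r[i] for t, r in zip(self.taxa, self.rows)}

    @classmethod
    def from_fasta(cls, path) -> "CharacterMatrix":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=taxa, rows=rows)

    @classmethod
    def from_phylip(cls, path) -> "CharacterMatrix":
        """Relaxed sequential PHYLIP (name and sequence whitespace-
        separated on each line)."""
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) < 2:
                raise FormatError("missing PHYLIP header")
            taxa, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                taxa.append(parts[0])
                rows.append("".join(parts[1:]).upper())
        return cls(taxa=taxa, rows=rows)


@dataclass
class TreeTopology:
    """Unrooted tree as an adjacency map; leaves are taxon-name strings,
    internal nodes integers."""

    adjacency: dict

    @property
    def leaves(self) -> set[str]:
        return {u for u in self.adjacency if isinstance(u, str)}

    @classmethod
    def from_newick(cls, newick: str) -> "TreeTopology":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        adj: dict = {}
        ids: dict = {}
        next_id = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                ids[node] = node.taxon.label.replace(" ", "_")
            else:
                ids[node] = next_id
                next_id += 1
        for node in tree.preorder_node_iter():
            u = ids[node]
            adj.setdefault(u, [])
            for child in node.child_nodes():
                v = ids[child]
                adj[u].append(v)
                adj.setdefault(v, []).append(u)
        # suppress a degree-2 artificial root
        root = ids[tree.seed_node]
        if len(adj.get(root, [])) == 2:
            a, b = adj.pop(root)
            adj[a] = [x for x in adj[a] if x != root] + [b]
            adj[b] = [x for x in adj[b] if x != root] + [a]
        return cls(adjacency=adj)

    def to_newick(self) -> str:
        root = next(u for u in self.adjacency if not isinstance(u, str))

        def sub(u, parent) -> str:
            if isinstance(u, str):
                return u
            parts = [sub(v, u) for v in self.adjacency[u] if v != parent]
            return "(" + ",".join(parts) + ")"

        return sub(root, None) + ";"


# ---------------------------------------------------------------------------
# core step count (Hartigan)


def _postorder(adj: dict, root):
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                stack.append(v)
    return order, parent


def _site_steps(adj: dict, leaf_masks: dict, root=None) -> int:
    if root is None:
        root = next(u for u in adj if not isinstance(u, str))
    order, parent = _postorder(adj, root)
    sets: dict = {}
    steps = 0
    for u in reversed(order):
        children = [v for v in adj[u] if v != parent[u]]
        if not children:
            sets[u] = leaf_masks[u]
            continue
        counts = [0, 0, 0, 0]
        for v in children:
            mask = sets[v]
            for b in range(4):
                if mask & (1 << b):
                    counts[b] += 1
        k = max(counts)
        sets[u] = sum(1 << b for b in range(4) if counts[b] == k)
        steps += len(children) - k
    return steps


def _check_tree(m: CharacterMatrix, t: TreeTopology) -> None:
    if t.leaves != set(m.taxa):
        raise ParameterError("tree leaf set does not match matrix taxa")
    if m.n_taxa < 3:
        raise ParameterError("tree statistics require >= 3 taxa")


def fitch_steps(m: CharacterMatrix, t: TreeTopology) -> int:
    """Minimum number of state changes of the whole matrix on the tree
    (sum of per-site Fitch/Hartigan counts)."""
    _check_tree(m, t)
    total = 0
    for i in range(m.n_sites):
        leaf_masks = {t_: state_bits(r[i]) for t_, r in zip(m.taxa, m.rows)}
        total += _site_steps(t.adjacency, leaf_masks)
    return total


# ---------------------------------------------------------------------------
# per-site bookkeeping


def _site_classes(column: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ch in column.values():
        if not is_missing(ch):
            s = _BIT_STATE[state_bits(ch)]
            counts[s] = counts.get(s, 0) + 1
    return counts


def site_min_steps(column: dict[str, str]) -> int:
    return max(0, len(_site_classes(column)) - 1)


def site_max_steps(column: dict[str, str]) -> int:
    counts = _site_classes(column)
    if not counts:
        return 0
    return sum(counts.values()) - max(counts.values())


def site_informative(column: dict[str, str]) -> bool:
    counts = _site_classes(column)
    return sum(1 for c in counts.values() if c >= 2) >= 2


def count_informative(m: CharacterMatrix) -> int:
    """Number of parsimony-informative sites: at least two states each
    present in at least two taxa (gap/missing excluded)."""
    return sum(site_informative(m.site(i)) for i in range(m.n_sites))


@dataclass
class ParsimonyStats:
    obs_steps: int
    min_steps: int
    max_steps: int
    ci: float | None
    ri: float | None
    informative_count: int


def compute_ci_ri(
    m: CharacterMatrix, t: TreeTopology, exclude_uninformative: bool = True
) -> ParsimonyStats:
    """Ensemble CI and RI of the matrix on the tree.

    obs/min/max step totals are over all sites; the CI sums exclude
    parsimony-uninformative sites when ``exclude_uninformative`` is
    set. CI is None when no included site varies; RI is None when
    sum(max) == sum(min).
    """
    _check_tree(m, t)
    tot_obs = tot_min = tot_max = 0
    ci_min = ci_obs = 0
    informative = 0
    for i in range(m.n_sites):
        col = m.site(i)
        leaf_masks = {t_: state_bits(col[t_]) for t_ in m.taxa}
        obs = _site_steps(t.adjacency, leaf_masks)
        mn, mx = site_min_steps(col), site_max_steps(col)
        info = site_informative(col)
        informative += info
        tot_obs += obs
        tot_min += mn
        tot_max += mx
        if info or not exclude_uninformative:
            ci_min += mn
            ci_obs += obs
    ci = (ci_min / ci_obs) if ci_obs else None
    ri = ((tot_max - tot_obs) / (tot_max - tot_min)) if tot_max != tot_min else None
    return ParsimonyStats(
        obs_steps=tot_obs, min_steps=tot_min, max_steps=tot_max,
        ci=ci, ri=ri, informative_count=informative,
    )


# ---------------------------------------------------------------------------
# exhaustive search (small-instance oracle for heuristic MP search)


def enumerate_topologies(taxa: list[str]) -> list[TreeTopology]:
    """All unrooted binary topologies over the taxa (3, 15, 105, 945
    for 4-7 taxa), built by stepwise edge insertion."""
    if len(taxa) < 3:
        raise SizeError("need >= 3 taxa")

    base = {0: [taxa[0], taxa[1], taxa[2]],
            taxa[0]: [0], taxa[1]: [0], taxa[2]: [0]}
    trees = [base]
    next_internal = 1
    for leaf in taxa[3:]:
        new_trees = []
        for adj in trees:
            edges = {
                tuple(sorted((u, v), key=str))
                for u in adj for v in adj[u]
            }
            for u, v in sorted(edges, key=str):
                new = {k: list(vs) for k, vs in adj.items()}
                w = next_internal
                new[u] = [x if x != v else w for x in new[u]]
                new[v] = [x if x != u else w for x in new[v]]
                new[w] = [u, v, leaf]
                new[leaf] = [w]
                new_trees.append(new)
        next_internal += 1
        trees = new_trees
    return [TreeTopology(adjacency=t) for t in trees]


def brute_force_best_tree(
    m: CharacterMatrix,
) -> tuple[list[TreeTopology], int]:
    """Exhaustive maximum-parsimony search for 4-7 taxa.

    Returns (all optimal topologies, minimal step count)."""
    if not 4 <= m.n_taxa <= 7:
        raise SizeError("exhaustive search supports 4-7 taxa only")
    best_trees: list[TreeTopology] = []
    best = None
    for t in enumerate_topologies(list(m.taxa)):
        steps = fitch_steps(m, t)
        if best is None or steps < best:
            best, best_trees = steps, [t]
        elif steps == best:
            best_trees.append(t)
    return best_trees, int(best)
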