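"""Parsimony statistics against exhaustive ancestral-labeling oracles."""

import itertools

import numpy as np
import pytest

from pfinish import (
    CharacterMatrix,
    ParameterError,
    SizeError,
    TreeTopology,
    brute_force_best_tree,
    compute_ci_ri,
    count_informative,
    enumerate_topologies,
    fitch_steps,
)
from pfinish.parsimony import site_informative, site_max_steps, site_min_steps

STATES = "ACGT"
MISSING = {"-", "?", "N"}


# ---------------------------------------------------------------------------
# oracles


def oracle_site_steps(adj, leaf_states):
    """Minimum changes over ALL assignments of internal node states and
    of free (missing) leaves, counted edge by edge."""
    internals = [u for u in adj if not isinstance(u, str)]
    free_leaves = [u for u in adj if isinstance(u, str) and leaf_states[u] in MISSING]
    edges = {tuple(sorted((u, v), key=str)) for u in adj for v in adj[u]}
    best = None
    nodes = internals + free_leaves
    for combo in itertools.product(STATES, repeat=len(nodes)):
        assign = dict(zip(nodes, combo))
        for u in adj:
            if isinstance(u, str) and leaf_states[u] not in MISSING:
                assign[u] = leaf_states[u]
        steps = sum(1 for u, v in edges if assign[u] != assign[v])
        best = steps if best is None else min(best, steps)
    return best


def oracle_max_steps(column):
    """Star-tree steps: enumerate every possible center state."""
    present = [s for s in column.values() if s not in MISSING]
    if not present:
        return 0
    return min(sum(1 for s in present if s != c) for c in STATES)


def random_matrix(rng, n_taxa, n_sites, missing_frac=0.1):
    taxa = [f"t{i}" for i in range(n_taxa)]
    rows = []
    for _ in range(n_taxa):
        row = "".join(
            "-" if rng.random() < missing_frac else STATES[rng.integers(4)]
            for _ in range(n_sites)
        )
        rows.append(row)
    return CharacterMatrix(taxa=taxa, rows=rows)


def random_topology(rng, taxa):
    tops = enumerate_topologies(list(taxa))
    return tops[rng.integers(len(tops))]


# ---------------------------------------------------------------------------


class TestCountInformative:
    def test_constant_matrix_has_none(self):
        m = CharacterMatrix(taxa=["a", "b", "c", "d"], rows=["AAA"] * 4)
        assert count_informative(m) == 0

    def test_hand_crafted_five_site_matrix(self):
        # sites: AATT informative, AATG not, ACGT not, CCGG informative,
        # A-TT not (only one state occurs twice among non-missing)
        rows = ["AAACA", "AACC-", "TTGGT", "TGTGT"]
        m = CharacterMatrix(taxa=["a", "b", "c", "d"], rows=rows)
        assert count_informative(m) == 2

    def test_matches_per_site_definition_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_matrix(rng, int(rng.integers(4, 8)), 12)
            expected = 0
            for i in range(m.n_sites):
                col = [r[i] for r in m.rows if r[i] not in MISSING]
                counts = {s: col.count(s) for s in set(col)}
                expected += sum(1 for v in counts.values() if v >= 2) >= 2
            assert count_informative(m) == expected


class TestFitchSteps:
    def test_textbook_four_taxon_cases(self):
        m = CharacterMatrix(taxa=["A1", "A2", "T1", "T2"],
                            rows=["A", "A", "T", "T"])
        grouped = TreeTopology.from_newick("((A1,A2),(T1,T2));")
        crossed = TreeTopology.from_newick("((A1,T1),(A2,T2));")
        assert fitch_steps(m, grouped) == 1
        assert fitch_steps(m, crossed) == 2

    def test_taxon_mismatch_rejected(self):
        m = CharacterMatrix(taxa=["a", "b", "c", "d"], rows=["A"] * 4)
        t = TreeTopology.from_newick("((a,b),(c,x));")
        with pytest.raises(ParameterError):
            fitch_steps(m, t)

    def test_equals_exhaustive_labeling_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n_taxa = int(rng.integers(4, 7))
            m = random_matrix(rng, n_taxa, 6)
            t = random_topology(rng, m.taxa)
            expected = sum(
                oracle_site_steps(
                    t.adjacency, {u: m.site(i)[u] for u in m.taxa}
                )
                for i in range(m.n_sites)
            )
            assert fitch_steps(m, t) == expected


class TestCiRi:
    def test_homoplasy_free_matrix_scores_perfectly(self):
        # one clean synapomorphy per internal edge of ((a,b),(c,d),(e,f))
        m = CharacterMatrix(
            taxa=["a", "b", "c", "d", "e", "f"],
            rows=["AAC", "AAC", "CAA", "CAA", "CCA", "CCA"],
        )
        t = TreeTopology.from_newick("((a,b),(c,d),(e,f));")
        stats = compute_ci_ri(m, t)
        assert stats.ci == 1.0 and stats.ri == 1.0

    def test_hand_computed_homoplasious_site(self):
        m = CharacterMatrix(taxa=["A1", "A2", "T1", "T2"],
                            rows=["A", "A", "T", "T"])
        t = TreeTopology.from_newick("((A1,T1),(A2,T2));")
        stats = compute_ci_ri(m, t)
        assert stats.min_steps == 1 and stats.obs_steps == 2
        assert stats.max_steps == 2
        assert stats.ci == 0.5 and stats.ri == 0.0

    def test_constant_sites_do_not_change_ci(self):
        base = CharacterMatrix(
            taxa=["a", "b", "c", "d"], rows=["AC", "AC", "TA", "TG"]
        )
        padded = CharacterMatrix(
            taxa=["a", "b", "c", "d"],
            rows=[r + "GGGG" for r in base.rows],
        )
        t = TreeTopology.from_newick("((a,b),(c,d));")
        s1 = compute_ci_ri(base, t, exclude_uninformative=True)
        s2 = compute_ci_ri(padded, t, exclude_uninformative=True)
        assert s1.ci == s2.ci and s1.ri == s2.ri

    def test_formulas_match_oracle_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n_taxa = int(rng.integers(4, 7))
            m = random_matrix(rng, n_taxa, 8)
            t = random_topology(rng, m.taxa)
            obs = mins = maxs = 0
            ci_min = ci_obs = 0
            for i in range(m.n_sites):
                col = m.site(i)
                o = oracle_site_steps(
                    t.adjacency, {u: col[u] for u in m.taxa}
                )
                present = {s for s in col.values() if s not in MISSING}
                mn = max(0, len(present) - 1)
                mx = oracle_max_steps(col)
                obs += o
                mins += mn
                maxs += mx
                if site_informative(col):
                    ci_min += mn
                    ci_obs += o
            stats = compute_ci_ri(m, t)
            assert stats.obs_steps == obs
            assert stats.min_steps == mins
            assert stats.max_steps == maxs
            if ci_obs:
                assert stats.ci == pytest.approx(ci_min / ci_obs)
            if maxs != mins:
                assert stats.ri == pytest.approx((maxs - obs) / (maxs - mins))


class TestSiteBounds:
    def test_star_steps_match_center_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            col = {
                f"t{i}": ("-" if rng.random() < 0.2 else STATES[rng.integers(4)])
                for i in range(n)
            }
            assert site_max_steps(col) == oracle_max_steps(col)
            present = {s for s in col.values() if s not in MISSING}
            assert site_min_steps(col) == max(0, len(present) - 1)


class TestBruteForceSearch:
    def test_topology_counts(self):
        assert len(enumerate_topologies(list("abcd"))) == 3
        assert len(enumerate_topologies(list("abcde"))) == 15
        assert len(enumerate_topologies(list("abcdef"))) == 105

    def test_recovers_generating_topology_without_homoplasy(self):
        m = CharacterMatrix(
            taxa=["a", "b", "c", "d", "e", "f"],
            rows=["AAC", "AAC", "CAA", "CAA", "CCA", "CCA"],
        )
        best, steps = brute_force_best_tree(m)
        assert steps == 3
        target = {frozenset("ab"), frozenset("cd"), frozenset("ef")}
        for t in best:
            splits = set()
            for u in t.adjacency:
                if isinstance(u, str):
                    continue
                for v in t.adjacency[u]:
                    if isinstance(v, str):
                        continue
                    side = leaves_on_side(t.adjacency, v, u)
                    splits.add(frozenset(side))
            assert any(s in splits or frozenset(m.taxa) - s in splits
                       for s in target)

    def test_size_limits_enforced(self):
        m8 = CharacterMatrix(taxa=[f"t{i}" for i in range(8)], rows=["A"] * 8)
        with pytest.raises(SizeError):
            brute_force_best_tree(m8)
        m3 = CharacterMatrix(taxa=["a", "b", "c"], rows=["A"] * 3)
        with pytest.raises(SizeError):
            brute_force_best_tree(m3)


def leaves_on_side(adj, start, blocked):
    """Leaf labels reachable from ``start`` without crossing ``blocked``."""
    seen, stack, leaves = {blocked, start}, [start], set()
    while stack:
        u = stack.pop()
        if isinstance(u, str):
            leaves.add(u)
            continue
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return leaves
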