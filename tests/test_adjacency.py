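"""Projection, displacement, the two-Gaussian score and graph construction."""

import math
import random
from itertools import combinations

import pytest

from phyloscaffold import (
    Match,
    PhyloTree,
    ScoringParams,
    apply_constraints,
    build_graph,
    displacement,
    project,
    score,
)
from phyloscaffold.adjacency import supported_edge


def mk_match(cid, sb, se, tb, te, genome="R", record="rec", qhits=10):
    return Match(cid, genome, record, sb, se, tb, te, qhits)


class TestProject:
    def test_paper_raw_formula(self):
        """The uncorrected projection of ((3,10),(100,107)) for a 20-base
        contig is (97, 117)."""
        p = project(mk_match("c", 3, 10, 100, 107), 20, raw=True)
        assert (p.pb, p.pe) == (97, 117)

    def test_full_length_forward_projects_onto_itself(self):
        p = project(mk_match("c", 1, 20, 100, 119), 20)
        assert (p.pb, p.pe) == (100, 119)
        assert p.orientation == "forward"

    def test_full_length_reverse_projects_onto_itself(self):
        p = project(mk_match("c", 20, 1, 100, 119), 20)
        assert (p.pb, p.pe) == (100, 119)
        assert p.orientation == "reverse"

    def test_partial_interior_match(self):
        # contig of 20, matched 3..10 at reference 100..107 (+1 convention)
        p = project(mk_match("c", 3, 10, 100, 107), 20)
        assert (p.pb, p.pe) == (98, 117)

    def test_projection_may_run_off_the_record(self):
        p = project(mk_match("c", 50, 69, 1, 20), 100)
        assert p.pb < 1


class TestDisplacement:
    def _proj(self, cid, pb, pe, genome="R", record="rec"):
        from phyloscaffold import ProjectedContig

        m = mk_match(cid, 1, 2, 1, 2, genome=genome, record=record)
        return ProjectedContig(
            contig_id=cid, ref_genome=genome, ref_record=record,
            pb=pb, pe=pe, orientation="forward", source_match=m,
        )

    def test_abutting_is_zero(self):
        assert displacement(self._proj("a", 1, 100), self._proj("b", 101, 200)) == 0

    def test_gap_counts_bases_between(self):
        assert displacement(self._proj("a", 1, 100), self._proj("b", 151, 250)) == 50

    def test_overlap_is_negative(self):
        assert displacement(self._proj("a", 1, 100), self._proj("b", 81, 180)) == -20

    def test_order_independent(self):
        a, b = self._proj("a", 1, 100), self._proj("b", 151, 250)
        assert displacement(a, b) == displacement(b, a)

    def test_undefined_across_genomes(self):
        a = self._proj("a", 1, 100, genome="g1")
        b = self._proj("b", 151, 250, genome="g2")
        assert displacement(a, b) is None

    def test_undefined_across_records(self):
        a = self._proj("a", 1, 100, record="chr")
        b = self._proj("b", 151, 250, record="plasmid")
        assert displacement(a, b) is None


class TestScore:
    def test_even_in_d_at_phi_zero(self):
        p = ScoringParams(phi=0.0)
        for d in (0, 1, 500, 12_345, 99_999):
            assert score(d, 1.5, p) == pytest.approx(score(-d, 1.5, p), rel=1e-15)

    def test_monotone_decay_at_phi_zero(self):
        p = ScoringParams(phi=0.0)
        values = [score(d, 2.0, p) for d in range(0, 100_000, 1000)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_dynamic_range_at_defaults(self):
        p = ScoringParams()
        assert score(0, 1.0, p, tau_min=1.0) / score(50_000, 1.0, p, tau_min=1.0) > 1e3

    def test_tau_prefactor_halves_at_double_distance(self):
        p = ScoringParams(phi=0.0)
        assert score(0, 2.0, p, tau_min=1.0) == pytest.approx(
            0.5 * score(0, 1.0, p, tau_min=1.0)
        )

    def test_tau_scaling_widens_sigma1(self):
        p = ScoringParams(phi=0.0)
        # at double tau the same d is relatively smaller: more tolerance
        far = 25_000
        ratio_near = score(far, 1.0, p, tau_min=1.0) / score(0, 1.0, p, tau_min=1.0)
        ratio_far = score(far, 2.0, p, tau_min=1.0) / score(0, 2.0, p, tau_min=1.0)
        assert ratio_far > ratio_near

    def test_closed_form(self):
        p = ScoringParams()
        d, tau, tau_min = 7_000.0, 2.5, 1.25
        sigma1 = p.sigma1 * tau / tau_min
        expected = (1 / tau) * (
            0.9 * math.exp(-(d**2) / (2 * sigma1**2))
            + 0.1 * math.exp(-((d - 2000.0) ** 2) / (2 * 1000.0**2))
        )
        assert score(d, tau, p, tau_min=tau_min) == pytest.approx(expected, rel=1e-14)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            score(0, 0.0)
        with pytest.raises(ValueError):
            score(0, -1.0)


class TestBuildGraph:
    def _abutting_instance(self, second_reverse=False):
        """Two 100-base contigs fully matching one reference, abutting."""
        lengths = {"c1": 100, "c2": 100}
        m1 = mk_match("c1", 1, 100, 1, 100)
        if second_reverse:
            m2 = mk_match("c2", 100, 1, 101, 200)
        else:
            m2 = mk_match("c2", 1, 100, 101, 200)
        matches = {("c1", "R"): [m1], ("c2", "R"): [m2]}
        tree = PhyloTree.from_newick("(S:1.0,R:1.0);")
        return matches, tree, lengths

    def test_abutting_pair_scores_facing_connectors_only(self, two_leaf_tree):
        matches, tree, lengths = self._abutting_instance()
        g = build_graph(matches, tree, "S", lengths)
        tau = 2.0
        expected = (1 / tau) * (0.9 + 0.1 * math.exp(-(2000.0**2) / (2 * 1000.0**2)))
        assert g.weight(("c1", "R"), ("c2", "L")) == pytest.approx(expected)
        assert g.weight(("c1", "L"), ("c2", "L")) == 0.0
        assert g.weight(("c1", "R"), ("c2", "R")) == 0.0
        assert g.weight(("c1", "L"), ("c2", "R")) == 0.0

    def test_reverse_complemented_second_contig_swaps_connector(self):
        matches, tree, lengths = self._abutting_instance(second_reverse=True)
        g = build_graph(matches, tree, "S", lengths)
        assert g.weight(("c1", "R"), ("c2", "R")) > 0.0
        assert g.weight(("c1", "R"), ("c2", "L")) == 0.0

    def test_two_equal_references_double_the_weight(self):
        lengths = {"c1": 100, "c2": 100}
        matches = {}
        for genome in ("R1", "R2"):
            matches[("c1", genome)] = [mk_match("c1", 1, 100, 1, 100, genome=genome)]
            matches[("c2", genome)] = [mk_match("c2", 1, 100, 101, 200, genome=genome)]
        tree2 = PhyloTree.from_newick("(S:1.0,(R1:0.5,R2:0.5):0.5);")
        g2 = build_graph(matches, tree2, "S", lengths)
        one = {k: v for k, v in matches.items() if k[1] == "R1"}
        g1 = build_graph(one, tree2, "S", lengths)
        assert g2.weight(("c1", "R"), ("c2", "L")) == pytest.approx(
            2 * g1.weight(("c1", "R"), ("c2", "L"))
        )

    def test_intra_edges_zero_and_edge_counts(self, two_leaf_tree):
        matches, tree, lengths = self._abutting_instance()
        g = build_graph(matches, tree, "S", lengths)
        assert g.weight(("c1", "L"), ("c1", "R")) == 0.0
        n = g.n
        assert len(g.intra_edges()) == n
        assert len(g.adjacency_edges()) + n == (2 * n) * (2 * n - 1) // 2

    def test_reference_must_be_tree_leaf(self, two_leaf_tree):
        matches = {("c1", "NOT_THERE"): [mk_match("c1", 1, 100, 1, 100, genome="NOT_THERE")]}
        with pytest.raises(ValueError, match="NOT_THERE"):
            build_graph(matches, two_leaf_tree, "S", {"c1": 100})

    def test_contig_species_cannot_be_reference(self, two_leaf_tree):
        matches = {("c1", "S"): [mk_match("c1", 1, 100, 1, 100, genome="S")]}
        with pytest.raises(ValueError, match="own reference"):
            build_graph(matches, two_leaf_tree, "S", {"c1": 100})

    def test_no_matches_gives_zero_graph(self, two_leaf_tree, caplog):
        with caplog.at_level("WARNING"):
            g = build_graph({("c1", "R"): []}, two_leaf_tree, "S", {"c1": 100, "c2": 50})
        assert g.max_adjacency_weight() == 0.0

    def test_deleting_a_reference_never_increases_weights(self):
        rng = random.Random(0)
        matches, tree, lengths = _random_micro_instance(rng)
        g_all = build_graph(matches, tree, "S", lengths)
        kept = {k: v for k, v in matches.items() if k[1] != "R2"}
        g_less = build_graph(kept, tree, "S", lengths)
        for e in g_all.adjacency_edges():
            u, v = tuple(e)
            assert g_less.weight(u, v) <= g_all.weight(u, v) + 1e-12

    def test_strand_coherence(self):
        """Reverse-complementing a contig in the input permutes its two
        connectors in every edge and leaves the weight multiset intact."""
        rng = random.Random(4)
        matches, tree, lengths = _random_micro_instance(rng)
        g = build_graph(matches, tree, "S", lengths)
        flipped = {}
        for (cid, genome), ms in matches.items():
            if cid != "c1":
                flipped[(cid, genome)] = ms
                continue
            L = lengths["c1"]
            flipped[(cid, genome)] = [
                Match(m.contig_id, m.ref_genome, m.ref_record,
                      L - m.sb + 1, L - m.se + 1, m.tb, m.te, m.qhits)
                for m in ms
            ]
        g2 = build_graph(flipped, tree, "S", lengths)
        swap = {("c1", "L"): ("c1", "R"), ("c1", "R"): ("c1", "L")}
        for e in g.adjacency_edges():
            u, v = tuple(e)
            assert g2.weight(swap.get(u, u), swap.get(v, v)) == pytest.approx(
                g.weight(u, v)
            )


def _random_micro_instance(rng, genomes=("R1", "R2")):
    """<= 3 contigs, <= 2 references, <= 4 matches per (contig, genome)."""
    tree = PhyloTree.from_newick("(S:1.0,(R1:0.5,R2:1.5):0.5);")
    contigs = ["c1", "c2", "c3"][: rng.randint(2, 3)]
    lengths = {c: rng.randint(50, 200) for c in contigs}
    matches = {}
    for c in contigs:
        for g in genomes:
            ms = []
            for _ in range(rng.randint(0, 4)):
                L = lengths[c]
                a = rng.randint(1, L - 10)
                b = rng.randint(a + 5, min(L, a + 120))
                tb = rng.randint(1, 5000)
                te = tb + (b - a)
                if rng.random() < 0.5:
                    ms.append(Match(c, g, "rec", b, a, tb, te, rng.randint(1, 50)))
                else:
                    ms.append(Match(c, g, "rec", a, b, tb, te, rng.randint(1, 50)))
            matches[(c, g)] = ms
    return matches, tree, lengths


def brute_force_edge_weights(matches, tree, species, lengths, params, d_cutoff):
    """Exhaustive oracle: every match pair, formulas written out inline."""
    taus = {g: tree.distance(species, g) for (_, g) in matches}
    tau_min = min(taus.values())
    weights = {}
    keys = sorted(matches)
    for (ci, gi), msi in matches.items():
        for (cj, gj), msj in matches.items():
            if gi != gj or ci >= cj:
                continue
            tau = taus[gi]
            for m in msi:
                for m2 in msj:
                    if m.ref_record != m2.ref_record:
                        continue
                    ps = []
                    for mm, cl in ((m, lengths[ci]), (m2, lengths[cj])):
                        if mm.sb <= mm.se:
                            pb, pe = mm.tb - mm.sb + 1, mm.te + cl - mm.se
                            rc = False
                        else:
                            pb = mm.tb - (cl - mm.sb)
                            pe = mm.te + (mm.se - 1)
                            rc = True
                        ps.append((pb, pe, rc, mm.contig_id))
                    first, second = sorted(ps)[0], sorted(ps)[1]
                    d = second[0] - first[1] - 1
                    if abs(d) > d_cutoff:
                        continue
                    u = (first[3], "L" if first[2] else "R")
                    v = (second[3], "R" if second[2] else "L")
                    sigma1 = params.sigma1 * tau / tau_min
                    s = (1 / tau) * (
                        (1 - params.phi) * math.exp(-d * d / (2 * sigma1**2))
                        + params.phi
                        * math.exp(-((d - params.mu) ** 2) / (2 * params.sigma2**2))
                    )
                    edge = frozenset((u, v))
                    per = weights.setdefault(edge, {})
                    per[gi] = max(per.get(gi, 0.0), s)
    return {e: sum(per.values()) for e, per in weights.items()}


def test_brute_force_oracle_micro_instances():
    """On random micro-instances the graph weights equal an exhaustive,
    independently coded enumeration of all match pairs."""
    params = ScoringParams()
    for seed in range(30):
        rng = random.Random(seed)
        matches, tree, lengths = _random_micro_instance(rng)
        g = build_graph(matches, tree, "S", lengths, params)
        expected = brute_force_edge_weights(
            matches, tree, "S", lengths, params, 200_000
        )
        for e in g.adjacency_edges():
            u, v = tuple(e)
            assert g.weight(u, v) == pytest.approx(expected.get(e, 0.0), abs=1e-12)


class TestConstraints:
    def _graph(self):
        matches, tree, lengths = TestBuildGraph()._abutting_instance()
        lengths = dict(lengths, c3=100)
        matches[("c3", "R")] = [mk_match("c3", 1, 100, 205, 304)]
        return build_graph(matches, tree, "S", lengths)

    def test_forbid_zeroes_edge(self):
        g = apply_constraints(self._graph(), [(("c1", "R"), ("c2", "L"), "forbid")])
        assert g.weight(("c1", "R"), ("c2", "L")) == 0.0

    def test_force_sets_to_max(self):
        g0 = self._graph()
        max_w = g0.max_adjacency_weight()
        g = apply_constraints(g0, [(("c1", "L"), ("c3", "R"), "force")])
        assert g.weight(("c1", "L"), ("c3", "R")) == pytest.approx(max_w)
        assert g.max_adjacency_weight() == pytest.approx(max_w)

    def test_forbid_applied_before_force(self):
        g0 = self._graph()
        strongest = g0.nonzero_edges()[0]
        u, v = tuple(strongest[0])
        g = apply_constraints(
            g0, [(("c1", "L"), ("c3", "R"), "force"), (u, v, "forbid")]
        )
        # the forced edge matches the max computed *after* the forbid
        assert g.weight(("c1", "L"), ("c3", "R")) < strongest[1]

    def test_intra_constraint_rejected(self):
        with pytest.raises(ValueError, match="intra"):
            apply_constraints(self._graph(), [(("c1", "L"), ("c1", "R"), "forbid")])

    def test_original_graph_untouched(self):
        g0 = self._graph()
        before = g0.weight(("c1", "R"), ("c2", "L"))
        apply_constraints(g0, [(("c1", "R"), ("c2", "L"), "forbid")])
        assert g0.weight(("c1", "R"), ("c2", "L")) == before


def test_supported_edge_facing_rule():
    m1 = mk_match("a", 1, 100, 1, 100)
    m2 = mk_match("b", 100, 1, 151, 250)
    p1, p2 = project(m1, 100), project(m2, 100)
    # second contig reverse: its leftward-facing connector is R
    assert supported_edge(p1, p2) == frozenset((("a", "R"), ("b", "R")))
    assert supported_edge(p1, project(m1, 100)) is None  # same contig
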