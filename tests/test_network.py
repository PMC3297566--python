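"""Leader clustering, microstate codes, CSN building and gradient basins."""

import numpy as np
import pytest

from pdznet.contacts import ContactRecord, ContactSpec, contact_timeseries
from pdznet.network import (
    ConformationSpaceNetwork,
    build_csn,
    coarse_grain,
    contact_pattern,
    discard_equilibration,
    encode_microstates,
    gradient_cluster,
    leader_cluster,
)
from pdznet.trajectory import Trajectory, backbone_selection, superpose
from pdznet import synthetic


def _record(name, formed):
    spec = ContactSpec(name=name, kind="ionic", side_a="*:*:*", side_b="*:*:*")
    return ContactRecord(spec=spec, formed=np.asarray(formed, dtype=bool))


# ---------------------------------------------------------------------------
# leader clustering
# ---------------------------------------------------------------------------

class TestLeaderCluster:
    def _traj(self, frames):
        frames = np.asarray(frames, dtype=float)
        atoms = synthetic.toy_topology()
        return Trajectory(atoms, frames, np.arange(float(len(frames))))

    def test_identical_frames_single_cluster(self):
        coords = synthetic.build_state_template(set())
        traj = self._traj(np.repeat(coords[None], 8, axis=0))
        sel = backbone_selection(traj.atoms, chain="P")
        cl = leader_cluster(traj, sel)
        assert cl.n_clusters == 1
        assert cl.leaders == [0]
        assert set(cl.assignments) == {0}

    def test_two_alternating_conformers(self, rng):
        base = synthetic.build_state_template(set())
        other = base.copy()
        sel_template = backbone_selection(synthetic.toy_topology(), chain="P")
        other[sel_template] += rng.normal(size=(len(sel_template), 3)) * 4.0
        # verify the two conformers truly are > 2 A apart after fitting
        inter = superpose(other[sel_template], base[sel_template]).rmsd
        assert inter > 2.0
        frames = np.stack([base, other] * 5)
        traj = self._traj(frames)
        cl = leader_cluster(traj, sel_template)
        assert cl.n_clusters == 2
        assert list(cl.assignments) == [0, 1] * 5

    def test_single_frame(self):
        coords = synthetic.build_state_template(set())
        traj = self._traj(coords[None])
        sel = backbone_selection(traj.atoms, chain="P")
        cl = leader_cluster(traj, sel)
        assert cl.n_clusters == 1 and list(cl.assignments) == [0]

    def test_every_frame_within_cutoff_of_leader(self, rng):
        base = synthetic.build_state_template(set())
        frames = base[None] + rng.normal(size=(40, len(base), 3)) * 1.2
        traj = self._traj(frames)
        sel = backbone_selection(traj.atoms, chain="P")
        cl = leader_cluster(traj, sel, cutoff=1.5)
        coords = traj.frames[:, sel]
        for f in range(traj.n_frames):
            lead = cl.leaders[cl.assignments[f]]
            assert superpose(coords[f], coords[lead]).rmsd <= 1.5 + 1e-9
        for k, lead in enumerate(cl.leaders):
            assert cl.assignments[lead] == k  # leader assigned to itself

    def test_empty_selection(self):
        traj = self._traj(synthetic.build_state_template(set())[None])
        with pytest.raises(ValueError, match="empty"):
            leader_cluster(traj, [])


# ---------------------------------------------------------------------------
# microstate encoding
# ---------------------------------------------------------------------------

class TestEncode:
    def _clustering(self, assignments):
        from pdznet.network import LeaderClustering

        return LeaderClustering(cutoff=2.0, leaders=[0],
                                assignments=np.asarray(assignments))

    def test_contact_bits_and_cluster_digit(self):
        recs = [_record("-7:331", [1]), _record("-7:332", [1]),
                _record("-4:331", [0])]
        codes = encode_microstates(recs, self._clustering([2]))
        assert codes == ["110|2"]
        assert contact_pattern(codes[0]) == "110"

    def test_no_contacts(self):
        recs = [_record(n, [0]) for n in "abc"]
        assert encode_microstates(recs, self._clustering([0])) == ["000|0"]

    def test_length_mismatch(self):
        recs = [_record("a", [0, 1])]
        with pytest.raises(ValueError, match="frames"):
            encode_microstates(recs, self._clustering([0]))

    def test_ground_truth_recovery_low_noise(self, markov_run):
        spec, traj, states = markov_run
        recs = contact_timeseries(traj, synthetic.default_contact_specs())
        sel = backbone_selection(traj.atoms, chain="P")
        cl = leader_cluster(traj, sel)
        codes = encode_microstates(recs, cl)
        truth = synthetic.ground_truth_codes(states, spec.state_contact_maps)
        match = np.mean([contact_pattern(c) == t
                         for c, t in zip(codes, truth)])
        assert match >= 0.99


# ---------------------------------------------------------------------------
# CSN construction
# ---------------------------------------------------------------------------

class TestBuildCSN:
    def test_direct_counts(self):
        csn = build_csn([["A", "A", "B", "A"]])
        assert csn.populations == {"A": 3, "B": 1}
        assert csn.edges == {("A", "A"): 1, ("A", "B"): 1, ("B", "A"): 1}
        assert csn.total_frames == 4

    def test_no_cross_run_edges(self):
        csn = build_csn([["A", "B"], ["A", "B"]])
        assert csn.edges == {("A", "B"): 2}
        assert csn.populations == {"A": 2, "B": 2}

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_csn([[]])

    def test_flow_conservation(self, rng):
        runs = [[str(s) for s in rng.integers(0, 4, size=50)]
                for _ in range(3)]
        csn = build_csn(runs)
        assert sum(csn.populations.values()) == csn.total_frames
        # outgoing edges = population minus appearances as run-final frame
        finals = {r[-1] for r in runs}
        out = {c: 0 for c in csn.populations}
        for (u, _v), cnt in csn.edges.items():
            out[u] += cnt
        for code, pop in csn.populations.items():
            n_final = sum(1 for r in runs if r[-1] == code)
            assert out[code] == pop - n_final

    def test_markov_transition_recovery(self, rng):
        # 3-state chain, row-normalized counts ~ transition matrix
        spec = synthetic.three_state_spec(n_frames=30_000, seed=11, stay=0.9)
        _traj, states = synthetic.gen_markov_trajectory(spec)
        codes = [str(s) for s in states]
        csn = build_csn([codes])
        t = spec.transition_matrix
        for i in range(3):
            n_i = sum(c for (u, _v), c in csn.edges.items() if u == str(i))
            for j in range(3):
                phat = csn.edges.get((str(i), str(j)), 0) / n_i
                se = np.sqrt(t[i, j] * (1 - t[i, j]) / n_i)
                assert abs(phat - t[i, j]) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# gradient clustering
# ---------------------------------------------------------------------------

def steepest_ascent_oracle(populations, edges):
    """Exhaustive independent re-derivation of the basin partition.

    For every node, repeatedly move to the best candidate (undirected
    neighbors + self, maximal population; ties: stay if the node attains
    the maximum, else smallest code) until stationary.
    """
    def neighbors(c):
        ns = set()
        for (u, v) in edges:
            if u == c and v != c:
                ns.add(v)
            if v == c and u != c:
                ns.add(u)
        return ns

    def step(c):
        cands = sorted(neighbors(c))
        top = max([populations[n] for n in cands] + [populations[c]])
        if populations[c] == top:
            return c
        return min(n for n in cands if populations[n] == top)

    basins = {}
    for c in populations:
        cur = c
        while True:
            nxt = step(cur)
            if nxt == cur:
                break
            cur = nxt
        basins.setdefault(cur, set()).add(c)
    return basins


def _csn_from(populations, edges):
    return ConformationSpaceNetwork(
        populations=dict(populations), edges=dict(edges),
        total_frames=sum(populations.values()),
        n_runs=1)


class TestGradientCluster:
    def test_linear_chain_single_maximum(self):
        csn = _csn_from({"a": 5, "b": 3, "c": 1},
                        {("a", "b"): 1, ("b", "c"): 1})
        basins = gradient_cluster(csn)
        assert len(basins) == 1
        assert basins[0].attractor == "a"
        assert basins[0].members == {"a", "b", "c"}

    def test_two_joined_chains(self):
        # 5-3-1 and 4-2 joined through the low-population tails
        pops = {"p5": 5, "p3": 3, "p1": 1, "q4": 4, "q2": 2}
        edges = {("p5", "p3"): 1, ("p3", "p1"): 1,
                 ("q4", "q2"): 1, ("p1", "q2"): 1}
        basins = gradient_cluster(_csn_from(pops, edges))
        got = {b.attractor: set(b.members) for b in basins}
        assert set(got) == {"p5", "q4"}
        assert got == steepest_ascent_oracle(pops, edges)

    def test_all_equal_populations_every_node_own_basin(self):
        pops = {c: 2 for c in "abcd"}
        edges = {("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1}
        basins = gradient_cluster(_csn_from(pops, edges))
        assert len(basins) == 4

    def test_attractors_are_local_maxima(self, rng):
        csn = _random_csn(rng, 10)
        for b in gradient_cluster(csn):
            for n in csn.neighbors(b.attractor):
                assert csn.populations[b.attractor] >= csn.populations[n]

    def test_matches_exhaustive_oracle_on_random_networks(self, rng):
        for _ in range(150):
            csn = _random_csn(rng, int(rng.integers(2, 13)))
            got = {b.attractor: set(b.members) for b in gradient_cluster(csn)}
            want = steepest_ascent_oracle(csn.populations, csn.edges)
            assert got == want

    def test_basins_partition_nodes(self, rng):
        csn = _random_csn(rng, 12)
        basins = gradient_cluster(csn)
        seen = set()
        for b in basins:
            assert not (seen & b.members)
            seen |= b.members
        assert seen == set(csn.populations)
        assert sum(b.population for b in basins) == pytest.approx(1.0)


def _random_csn(rng, n):
    codes = [f"n{i:02d}" for i in range(n)]
    pops = {c: int(rng.integers(1, 20)) for c in codes}
    edges = {}
    # random connected-ish digraph: a spine plus random extra edges
    order = list(rng.permutation(codes))
    for u, v in zip(order[:-1], order[1:]):
        edges[(u, v)] = int(rng.integers(1, 5))
    for _ in range(n):
        u, v = rng.choice(codes, size=2, replace=True)
        edges[(str(u), str(v))] = int(rng.integers(1, 5))
    return _csn_from(pops, edges)


# ---------------------------------------------------------------------------
# coarse graining
# ---------------------------------------------------------------------------

class TestCoarseGrain:
    def test_single_basin(self):
        csn = _csn_from({"a": 3, "b": 1}, {("a", "b"): 2, ("b", "a"): 1})
        basins = gradient_cluster(csn)
        coarse = coarse_grain(csn, basins)
        assert len(coarse.basins) == 1
        assert coarse.basins[0].population == pytest.approx(1.0)
        assert coarse.edge_weights == {}

    def test_hand_counted_six_node_fixture(self):
        # two basins: {A:9, b:4, c:2} and {D:7, e:3, f:1}, bridged at c-f
        pops = {"A": 9, "b": 4, "c": 2, "D": 7, "e": 3, "f": 1}
        edges = {
            ("A", "A"): 5, ("A", "b"): 2, ("b", "A"): 2, ("b", "c"): 1,
            ("D", "D"): 4, ("D", "e"): 2, ("e", "D"): 1, ("e", "f"): 1,
            ("c", "f"): 3, ("f", "c"): 2,  # inter-basin traffic
        }
        csn = _csn_from(pops, edges)
        basins = gradient_cluster(csn)
        got = {b.attractor: set(b.members) for b in basins}
        assert got == {"A": {"A", "b", "c"}, "D": {"D", "e", "f"}}
        coarse = coarse_grain(csn, basins)
        total = sum(edges.values())  # 23
        assert coarse.edge_weights[("A", "D")] == pytest.approx(3 / total)
        assert coarse.edge_weights[("D", "A")] == pytest.approx(2 / total)

    def test_labels_use_contact_patterns(self):
        csn = build_csn([["110|0", "110|0", "100|0", "110|1", "110|0"]])
        basins = gradient_cluster(csn)
        coarse = coarse_grain(csn, basins)
        assert coarse.basins[0].label == "110"

    def test_non_partition_rejected(self):
        csn = _csn_from({"a": 3, "b": 1}, {("a", "b"): 2})
        basins = gradient_cluster(csn)
        with pytest.raises(ValueError, match="partition"):
            coarse_grain(csn, basins[:0])

    def test_end_to_end_mode_recovery(self, markov_run):
        spec, traj, _states = markov_run
        recs = contact_timeseries(traj, synthetic.default_contact_specs())
        sel = backbone_selection(traj.atoms, chain="P")
        cl = leader_cluster(traj, sel)
        csn = build_csn([encode_microstates(recs, cl)])
        basins = gradient_cluster(csn)
        assert len(basins) == 3
        pi = synthetic.stationary_distribution(spec.transition_matrix)
        # the gateway joins the most populated mode's basin
        expected = {"110": pi[0] + pi[3], "001": pi[1], "100": pi[2]}
        lam = sorted(abs(np.linalg.eigvals(spec.transition_matrix)))[-2]
        n_eff = traj.n_frames * (1 - lam) / (1 + lam)
        coarse = coarse_grain(csn, basins)
        for b in coarse.basins:
            exp = expected[b.label]
            se = np.sqrt(exp * (1 - exp) / n_eff)
            assert abs(b.population - exp) < 3 * se


# ---------------------------------------------------------------------------
# equilibration discard
# ---------------------------------------------------------------------------

class TestDiscardEquilibration:
    def _traj(self, n, dt=1.0):
        atoms = synthetic.toy_topology()
        frames = np.zeros((n, len(atoms), 3)) + np.arange(3)
        return Trajectory(atoms, frames, np.arange(n) * dt)

    def test_arithmetic(self):
        # 200 ps at 1 frame/ps with 50 ps burn-in keeps 150 frames
        out = discard_equilibration(self._traj(200), burn_in_ps=50.0)
        assert out.n_frames == 150
        assert out.frame_times[0] == 50.0

    def test_zero_burn_in_is_identity(self):
        traj = self._traj(10)
        out = discard_equilibration(traj, burn_in_ps=0.0)
        assert out.n_frames == 10
        np.testing.assert_array_equal(out.frames, traj.frames)

    def test_burn_in_covering_everything_rejected(self):
        with pytest.raises(ValueError, match="entire"):
            discard_equilibration(self._traj(100), burn_in_ps=100.0)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=80, deadline=None)
@given(st.lists(st.lists(st.sampled_from("ABCD"), min_size=1, max_size=40),
                min_size=1, max_size=4))
def test_csn_conservation_properties(runs):
    """Population and flow conservation hold for arbitrary code sequences."""
    csn = build_csn(runs)
    assert sum(csn.populations.values()) == csn.total_frames
    assert csn.total_transitions == csn.total_frames - len(runs)
    out = {c: 0 for c in csn.populations}
    for (u, _v), cnt in csn.edges.items():
        out[u] += cnt
    for code, pop in csn.populations.items():
        n_final = sum(1 for r in runs if r[-1] == code)
        assert out[code] == pop - n_final
    # basins always partition the node set with total fraction 1
    basins = gradient_cluster(csn)
    members = [m for b in basins for m in b.members]
    assert sorted(members) == sorted(csn.populations)
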