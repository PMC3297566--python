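"""Microstates, conformation-space networks and gradient-clustered basins.

Each saved snapshot is labelled by a microstate code combining a binary
contact pattern (one digit per monitored contact, ``1`` = formed) with a
peptide-conformation cluster id from single-pass leader clustering of the
ligand backbone (C, CA, N; 2 A RMSD cutoff).  Because the cluster id may
exceed 9 the internal representation is delimited, ``"110|2"``; the
contact part matches the compact ``"110"``-style labels used in reports.

The conformation-space network (CSN) has one node per observed microstate
and a directed edge counting each transition between consecutive frames
of a run (self-transitions included; no edges across run boundaries).
Gradient clustering assigns every node to the neighbor of maximal
population, steepest-ascent paths terminate in local population maxima,
and the nodes draining to one maximum form a basin — a metastable binding
mode.  Basins and their total inter-basin transition probabilities form
the coarse-grained network.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from pdznet.contacts import ContactRecord
from pdznet.trajectory import Trajectory, superpose

__all__ = [
    "LeaderClustering",
    "Microstate",
    "ConformationSpaceNetwork",
    "Basin",
    "CoarseNetwork",
    "leader_cluster",
    "encode_microstates",
    "contact_pattern",
    "build_csn",
    "gradient_cluster",
    "coarse_grain",
    "discard_equilibration",
    "csn_to_networkx",
    "write_network_tables",
]

LEADER_CUTOFF = 2.0  # A, ligand-backbone RMSD


# ---------------------------------------------------------------------------
# leader clustering
# ---------------------------------------------------------------------------

@dataclass
class LeaderClustering:
    """Single-pass leader clustering of trajectory frames.

    ``leaders[k]`` is the frame index founding cluster ``k``;
    ``assignments[f]`` is the cluster id of frame ``f``.  Every frame is
    within ``cutoff`` (superposed RMSD) of its leader; each leader is
    assigned to itself.
    """

    cutoff: float
    leaders: list[int]
    assignments: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.leaders)


def leader_cluster(traj: Trajectory, selection: Sequence[int],
                   cutoff: float = LEADER_CUTOFF,
                   fit: bool = True) -> LeaderClustering:
    """Leader clustering on the selected atoms (ligand backbone).

    Frames are scanned in time order; a frame founds a new cluster iff its
    RMSD (after Kabsch superposition when ``fit``) to every existing
    leader exceeds ``cutoff``, otherwise it joins the FIRST leader within
    ``cutoff``.
    """
    sel = list(selection)
    if not sel:
        raise ValueError("empty atom selection")
    coords = traj.frames[:, sel, :]
    leaders: list[int] = []
    assignments = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        x = coords[f]
        assigned = False
        for k, lead in enumerate(leaders):
            if fit:
                r = superpose(x, coords[lead]).rmsd
            else:
                r = float(np.sqrt(((x - coords[lead]) ** 2).sum(axis=1).mean()))
            if r <= cutoff:
                assignments[f] = k
                assigned = True
                break
        if not assigned:
            leaders.append(f)
            assignments[f] = len(leaders) - 1
    return LeaderClustering(cutoff=cutoff, leaders=leaders,
                            assignments=assignments)


# ---------------------------------------------------------------------------
# microstate encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Microstate:
    """A microstate code with its frame population."""

    code: str
    population: int

    @property
    def contact_pattern(self) -> str:
        return contact_pattern(self.code)

    @property
    def cluster_id(self) -> int:
        return int(self.code.rsplit("|", 1)[1])


def contact_pattern(code: str) -> str:
    """The binary contact part of a ``"110|2"``-style code."""
    return code.rsplit("|", 1)[0]


def encode_microstates(records: Sequence[ContactRecord],
                       clustering: LeaderClustering) -> list[str]:
    """Per-frame codes: contact bits (record order) + cluster id."""
    if not records:
        raise ValueError("need at least one contact record")
    n = len(clustering.assignments)
    for rec in records:
        if len(rec.formed) != n:
            raise ValueError(
                f"contact {rec.name!r} has {len(rec.formed)} frames, "
                f"clustering has {n}"
            )
    bits = np.stack([r.formed.astype(int) for r in records])  # (D, F)
    return [
        "".join(str(b) for b in bits[:, f]) + f"|{clustering.assignments[f]}"
        for f in range(n)
    ]


# ---------------------------------------------------------------------------
# conformation-space network
# ---------------------------------------------------------------------------

@dataclass
class ConformationSpaceNetwork:
    """Directed transition-count graph over microstates."""

    populations: dict[str, int]
    edges: dict[tuple[str, str], int]
    total_frames: int
    n_runs: int

    @property
    def nodes(self) -> list[Microstate]:
        return [Microstate(code=c, population=p)
                for c, p in sorted(self.populations.items())]

    @property
    def total_transitions(self) -> int:
        return sum(self.edges.values())

    def neighbors(self, code: str) -> set[str]:
        """Undirected neighbor set, self excluded."""
        out = set()
        for (u, v) in self.edges:
            if u == code and v != code:
                out.add(v)
            elif v == code and u != code:
                out.add(u)
        return out

    def validate(self) -> None:
        if sum(self.populations.values()) != self.total_frames:
            raise ValueError("node populations must sum to total_frames")
        out_counts: Counter[str] = Counter()
        for (u, _v), c in self.edges.items():
            out_counts[u] += c
        # each run contributes population-1 outgoing transitions overall
        if sum(out_counts.values()) != self.total_frames - self.n_runs:
            raise ValueError("edge counts inconsistent with frame count")


def build_csn(code_sequences: Sequence[Sequence[str]] | Sequence[str],
              ) -> ConformationSpaceNetwork:
    """Count populations and consecutive-frame transitions.

    ``code_sequences`` is a list of per-run code sequences (a single flat
    sequence of strings is treated as one run).  Self-transitions are
    recorded; no edge crosses a run boundary.
    """
    if code_sequences and isinstance(code_sequences[0], str):
        runs: list[Sequence[str]] = [code_sequences]  # type: ignore[list-item]
    else:
        runs = [r for r in code_sequences]  # type: ignore[union-attr]
    runs = [list(r) for r in runs if len(r) > 0]
    if not runs:
        raise ValueError("need at least one non-empty code sequence")
    populations: Counter[str] = Counter()
    edges: Counter[tuple[str, str]] = Counter()
    for run in runs:
        populations.update(run)
        for u, v in zip(run[:-1], run[1:]):
            edges[(u, v)] += 1
    csn = ConformationSpaceNetwork(
        populations=dict(populations),
        edges=dict(edges),
        total_frames=sum(len(r) for r in runs),
        n_runs=len(runs),
    )
    csn.validate()
    return csn


# ---------------------------------------------------------------------------
# gradient clustering
# ---------------------------------------------------------------------------

@dataclass
class Basin:
    """A gradient-clustering basin of attraction."""

    attractor: str
    members: frozenset[str]
    population: float  # summed node fraction
    label: str         # contact pattern of the most populated member
    minor_patterns: tuple[str, ...] = ()


def _ascent_target(csn: ConformationSpaceNetwork, code: str,
                   weight: str = "population") -> str:
    """Steepest-ascent pointer of one node.

    ``weight="population"``: the candidate set is the undirected neighbor
    set plus the node itself; the target is the candidate of maximal
    population.  Ties: the node itself wins whenever it attains the
    maximum (hence all-equal populations leave every node a fixed point),
    otherwise the lexicographically smallest code.

    ``weight="transition"``: among the strictly higher-populated
    neighbors, point to the one with the largest symmetrized transition
    count (fastest interconversion); no such neighbor -> fixed point.
    Attractors are population local maxima in both modes.
    """
    best = csn.populations[code]
    cands = [n for n in csn.neighbors(code) if csn.populations[n] >= best]
    if not cands:
        return code
    if weight == "population":
        top = max(csn.populations[n] for n in cands)
        if top <= best:
            return code  # self attains the maximum
        return min(n for n in cands if csn.populations[n] == top)
    if weight == "transition":
        higher = [n for n in cands if csn.populations[n] > best]
        if not higher:
            return code
        flux = {n: csn.edges.get((code, n), 0) + csn.edges.get((n, code), 0)
                for n in higher}
        top = max(flux.values())
        return min(n for n in higher if flux[n] == top)
    raise ValueError(f"unknown gradient weight {weight!r}")


def gradient_cluster(csn: ConformationSpaceNetwork,
                     weight: str = "population") -> list[Basin]:
    """Lump microstates into basins by steepest ascent on the CSN.

    Every node follows its pointer (see :func:`_ascent_target`) to a
    fixed point — a local population maximum; nodes sharing a fixed point
    form one basin.  Basins are returned sorted by population, largest
    first.
    """
    if not csn.populations:
        raise ValueError("empty network")
    pointer = {c: _ascent_target(csn, c, weight=weight)
               for c in csn.populations}
    attractor: dict[str, str] = {}

    def root(c: str) -> str:
        path = []
        while pointer[c] != c:
            if c in attractor:
                break
            path.append(c)
            c = pointer[c]
        a = attractor.get(c, c)
        for p in path:
            attractor[p] = a
        attractor[c] = a
        return a

    members: dict[str, set[str]] = defaultdict(set)
    for c in csn.populations:
        members[root(c)].add(c)
    total = csn.total_frames
    basins = []
    for att, mem in members.items():
        pop = sum(csn.populations[m] for m in mem) / total
        ordered = sorted(mem, key=lambda m: (-csn.populations[m], m))
        patterns = []
        for m in ordered:
            p = contact_pattern(m)
            if p not in patterns:
                patterns.append(p)
        basins.append(Basin(
            attractor=att,
            members=frozenset(mem),
            population=pop,
            label=patterns[0],
            minor_patterns=tuple(patterns[1:]),
        ))
    basins.sort(key=lambda b: (-b.population, b.attractor))
    return basins


# ---------------------------------------------------------------------------
# coarse-grained network
# ---------------------------------------------------------------------------

@dataclass
class CoarseNetwork:
    """Basins with population fractions and inter-basin edge weights.

    Edge weight = total inter-basin transition count / total transitions.
    """

    basins: list[Basin]
    edge_weights: dict[tuple[str, str], float]  # keyed by attractor codes


def coarse_grain(csn: ConformationSpaceNetwork,
                 basins: Sequence[Basin]) -> CoarseNetwork:
    """Aggregate the CSN over a basin partition."""
    owner: dict[str, str] = {}
    for b in basins:
        for m in b.members:
            if m in owner:
                raise ValueError(f"basins overlap at node {m!r}")
            owner[m] = b.attractor
    if set(owner) != set(csn.populations):
        raise ValueError("basins do not partition the network's nodes")
    total = csn.total_transitions
    weights: Counter[tuple[str, str]] = Counter()
    for (u, v), c in csn.edges.items():
        if owner[u] != owner[v]:
            weights[(owner[u], owner[v])] += c
    edge_weights = {k: c / total for k, c in weights.items()}
    return CoarseNetwork(basins=list(basins), edge_weights=edge_weights)


# ---------------------------------------------------------------------------
# equilibration discard
# ---------------------------------------------------------------------------

def discard_equilibration(traj: Trajectory,
                          burn_in_ps: float = 50_000.0) -> Trajectory:
    """Drop all frames with time < ``burn_in_ps`` (default 50 ns).

    The initial transient of a run is biased toward its starting
    configuration; analyses operate on the remainder.
    """
    if burn_in_ps < 0:
        raise ValueError("burn_in must be non-negative")
    keep = traj.frame_times >= burn_in_ps
    if not keep.any():
        raise ValueError(
            f"burn-in {burn_in_ps} ps covers the entire trajectory "
            f"({traj.frame_times[-1]} ps)"
        )
    return traj.with_frames(traj.frames[keep], traj.frame_times[keep])


def discard_equilibration_codes(codes: Sequence[str], times: Sequence[float],
                                burn_in_ps: float = 50_000.0) -> list[str]:
    """Same rule applied to a per-frame code sequence with known times."""
    times = np.asarray(times, dtype=float)
    if len(codes) != len(times):
        raise ValueError("codes and times must have equal length")
    keep = times >= burn_in_ps
    if not keep.any():
        raise ValueError("burn-in covers the entire sequence")
    return [c for c, k in zip(codes, keep) if k]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def csn_to_networkx(csn: ConformationSpaceNetwork):
    """The CSN as a networkx DiGraph (counts + probabilities on edges)."""
    import networkx as nx

    g = nx.DiGraph(total_frames=csn.total_frames)
    for code, pop in csn.populations.items():
        g.add_node(code, population=pop,
                   fraction=pop / csn.total_frames,
                   contact_pattern=contact_pattern(code))
    out_tot: Counter[str] = Counter()
    for (u, _v), c in csn.edges.items():
        out_tot[u] += c
    for (u, v), c in csn.edges.items():
        g.add_edge(u, v, count=c, probability=c / out_tot[u])
    return g


def write_network_tables(outdir: str | Path, csn: ConformationSpaceNetwork,
                         basins: Sequence[Basin] | None = None,
                         coarse: CoarseNetwork | None = None) -> None:
    """GraphML + edge-list TSV for the CSN, basin membership TSV."""
    import networkx as nx
    import pandas as pd

    from pdznet import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = csn_to_networkx(csn)
    nx.write_graphml(g, outdir / "csn.graphml")
    header = f"# pdznet v{__version__}\n"
    out_tot: Counter[str] = Counter()
    for (u, _v), c in csn.edges.items():
        out_tot[u] += c
    rows = [{"source": u, "target": v, "count": c,
             "probability": c / out_tot[u]}
            for (u, v), c in sorted(csn.edges.items())]
    with open(outdir / "csn_edges.tsv", "w") as fh:
        fh.write(header)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    if basins is not None:
        brows = []
        for i, b in enumerate(basins):
            for m in sorted(b.members):
                brows.append({"basin": i, "attractor": b.attractor,
                              "label": b.label, "member": m,
                              "basin_population": b.population})
        with open(outdir / "basins.tsv", "w") as fh:
            fh.write(header)
            pd.DataFrame(brows).to_csv(fh, sep="\t", index=False)
    if coarse is not None:
        cg = nx.DiGraph()
        for b in coarse.basins:
            cg.add_node(b.attractor, label=b.label, population=b.population,
                        minor_patterns=",".join(b.minor_patterns))
        for (u, v), w in coarse.edge_weights.items():
            cg.add_edge(u, v, weight=w)
        nx.write_graphml(cg, outdir / "coarse_network.graphml")
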