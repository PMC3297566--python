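"""Seeded synthetic generators for every input the analyses consume.

No trajectories or curated alignments ship with the package, so testing
and demonstration run on generated stand-ins that reproduce the
statistical structure the analyses assume:

* a peptide + loop toy system whose three monitored contacts follow a
  known Markov chain, with per-frame Gaussian coordinate jitter — the
  hidden state sequence is returned so recovery can be scored;
* alignments with planted paralog groups and a planted D/E enrichment in
  loop columns;
* per-domain helix-propensity tables with planted class means and early
  C-terminal truncation (exercising the zero-padding rule).

The toy geometry carries only the atoms the detectors need (backbone
C/CA/N, contact carbons, charged atoms, one donor/hydrogen/acceptor
triad); there is no force-field realism and none is intended.  All
generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from pdznet.contacts import ContactSpec, contact_timeseries
from pdznet.trajectory import AtomRecord, Trajectory

__all__ = [
    "TrajectoryGeneratorSpec",
    "MSAGeneratorSpec",
    "toy_topology",
    "build_state_template",
    "default_contact_specs",
    "default_trajectory_spec",
    "three_state_spec",
    "stationary_distribution",
    "gen_markov_trajectory",
    "gen_msa",
    "gen_propensity_tables",
    "labels_to_wmsa",
]

#: the three monitored peptide-loop contacts, in code-digit order
CONTACT_NAMES = ("-7:331", "-7:332", "-4:331")


# ---------------------------------------------------------------------------
# toy peptide + loop geometry
# ---------------------------------------------------------------------------

def toy_topology() -> list[AtomRecord]:
    """Atoms of the 4-residue peptide (chain P) + 3-residue loop (chain L).

    Peptide residues -7..-4 carry backbone N/CA/C; residue -7 has a
    lysine-like side chain (CD/CE contact carbons, NZ charged), residue
    -4 a donor ND with hydrogen HD.  Loop residue 331 is glutamate-like
    (CG/CD contact carbons, OE1 charged acceptor), 332 aspartate-like
    (CB/CG contact carbons, OD1 charged); 333 is backbone-only filler.
    """
    atoms: list[AtomRecord] = []

    def add(name, resnum, resname, chain, tags=()):
        atoms.append(AtomRecord(
            atom_id=len(atoms), name=name, residue_number=resnum,
            residue_name=resname, chain_id=chain,
            role_tags=frozenset(tags)))

    for i, rn in enumerate((-7, -6, -5, -4)):
        resname = "LYS" if rn == -7 else ("ASN" if rn == -4 else "GLY")
        add("N", rn, resname, "P")
        add("CA", rn, resname, "P")
        add("C", rn, resname, "P")
    add("CD", -7, "LYS", "P", {"contact_carbon"})
    add("CE", -7, "LYS", "P", {"contact_carbon"})
    add("NZ", -7, "LYS", "P", {"charged", "donor"})
    nd_id = len(atoms)
    add("ND", -4, "ASN", "P", {"donor"})
    add("HD", -4, "ASN", "P", {f"hydrogen_of:{nd_id}"})
    for rn, resname in ((331, "GLU"), (332, "ASP"), (333, "GLY")):
        add("N", rn, resname, "L")
        add("CA", rn, resname, "L")
        add("C", rn, resname, "L")
    add("CG", 331, "GLU", "L", {"contact_carbon"})
    add("CD", 331, "GLU", "L", {"contact_carbon"})
    add("OE1", 331, "GLU", "L", {"charged", "acceptor"})
    add("CB", 332, "ASP", "L", {"contact_carbon"})
    add("CG", 332, "ASP", "L", {"contact_carbon"})
    add("OD1", 332, "ASP", "L", {"charged", "acceptor"})
    return atoms


def build_state_template(formed: set[str]) -> np.ndarray:
    """Coordinates (A) satisfying exactly the named contacts at zero jitter.

    Contact geometries are spatially decoupled: each contact is switched
    by moving only loop-side atoms, with >= 2 A margin to the cutoffs so
    that small jitter cannot flip a detector.
    """
    unknown = formed - set(CONTACT_NAMES)
    if unknown:
        raise ValueError(f"unknown contact names: {sorted(unknown)}")
    atoms = toy_topology()
    pos = {}

    # rigid peptide backbone: CA along x, N/C staggered in y and z
    for i, rn in enumerate((-7, -6, -5, -4)):
        x = 3.8 * i
        pos[("P", rn, "N")] = (x - 1.2, 0.8, 0.5)
        pos[("P", rn, "CA")] = (x, 0.0, 0.0)
        pos[("P", rn, "C")] = (x + 1.2, 0.8, -0.5)
    # -7 lysine-like side chain, fixed
    pos[("P", -7, "CD")] = (0.0, 5.0, 0.0)
    pos[("P", -7, "CE")] = (0.0, 6.0, 0.0)
    pos[("P", -7, "NZ")] = (0.0, 7.0, 0.0)
    # -4 donor + hydrogen, fixed
    pos[("P", -4, "ND")] = (11.4, 5.0, 0.0)
    pos[("P", -4, "HD")] = (11.4, 6.0, 0.0)
    # loop backbone, fixed, off to the side
    for i, rn in enumerate((331, 332, 333)):
        x = 3.8 * i
        pos[("L", rn, "N")] = (x - 1.2, 21.0, 0.5)
        pos[("L", rn, "CA")] = (x, 20.2, 0.0)
        pos[("L", rn, "C")] = (x + 1.2, 21.0, -0.5)
    # contact -7:331 — 331 carbons approach the -7 carbons (min 3.0 A) or
    # retreat (min 11.0 A); cutoff 5 A
    y331 = 9.0 if "-7:331" in formed else 17.0
    pos[("L", 331, "CD")] = (0.0, y331, 0.0)
    pos[("L", 331, "CG")] = (0.0, y331 + 0.8, 0.0)
    # contact -7:332 — 332 carbons approach from -x
    x332 = -3.0 if "-7:332" in formed else -12.0
    pos[("L", 332, "CB")] = (x332, 6.0, 0.0)
    pos[("L", 332, "CG")] = (x332 - 0.8, 6.0, 0.0)
    pos[("L", 332, "OD1")] = (x332 - 1.6, 6.0, 0.0)
    # contact -4:331 — acceptor OE1 sits collinear past the -4 donor's
    # hydrogen at d(D,A)=2.8 A, or 8 A away; cutoffs 3.6 A / 30 deg
    yoe1 = 7.8 if "-4:331" in formed else 13.0
    pos[("L", 331, "OE1")] = (11.4, yoe1, 0.0)

    coords = np.array([pos[(a.chain_id, a.residue_number, a.name)]
                       for a in atoms], dtype=float)
    return coords


def default_contact_specs() -> list[ContactSpec]:
    """The three monitored contacts in code-digit order."""
    return [
        ContactSpec(name="-7:331", kind="ionic", side_a="P:-7:*", side_b="L:331:*"),
        ContactSpec(name="-7:332", kind="ionic", side_a="P:-7:*", side_b="L:332:*"),
        ContactSpec(name="-4:331", kind="hbond", side_a="P:-4:*", side_b="L:331:OE1"),
    ]


# ---------------------------------------------------------------------------
# Markov trajectory generator
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryGeneratorSpec:
    """A hidden Markov chain over contact states emitting jittered frames."""

    transition_matrix: np.ndarray
    state_contact_maps: list[set[str]]
    jitter_sigma: float = 0.1  # A per coordinate
    n_frames: int = 20_000
    dt: float = 1.0            # ps between snapshots
    seed: int = 0
    run_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        t = self.transition_matrix
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must be stochastic")
        if len(self.state_contact_maps) != t.shape[0]:
            raise ValueError("one contact map per state required")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def three_state_spec(n_frames: int = 20_000, seed: int = 0,
                     jitter_sigma: float = 0.1,
                     stay: float = 0.98) -> TrajectoryGeneratorSpec:
    """Three binding modes (contact patterns 110/001/100), direct switching.

    The chain interconverts on a timescale of ~1/(1-stay) snapshots
    (tens of ns at the default stay probability and 1 ps saving
    interval, scaled down with n_frames for desk-size runs).  Modes
    exchange directly, so this preset probes population/transition
    recovery, not basin separation.
    """
    off = (1.0 - stay) / 2.0
    t = np.full((3, 3), off)
    np.fill_diagonal(t, stay)
    # break the symmetry so the stationary distribution is non-uniform
    t[1, 0] += off / 2
    t[1, 2] -= off / 2
    t[2, 0] += off / 2
    t[2, 1] -= off / 2
    return TrajectoryGeneratorSpec(
        transition_matrix=t,
        state_contact_maps=[{"-7:331", "-7:332"}, {"-4:331"}, {"-7:331"}],
        jitter_sigma=jitter_sigma,
        n_frames=n_frames,
        seed=seed,
    )


def default_trajectory_spec(n_frames: int = 20_000, seed: int = 0,
                            jitter_sigma: float = 0.1,
                            stay: float = 0.98) -> TrajectoryGeneratorSpec:
    """Three metastable modes exchanging through a contact-free gateway.

    Emulates what gradient clustering assumes about binding dynamics:
    metastable contact patterns (110/001/100, populated roughly 3:2:2)
    are not direct neighbors in microstate space — every switch passes
    through a short-lived all-contacts-broken transition state ("000").
    The gateway dwells ~1 frame and holds ~2% of the population, so the
    three modes come out as separate basins of attraction.
    """
    leave = 1.0 - stay
    # states 0..2 = modes, state 3 = gateway
    t = np.zeros((4, 4))
    for i in range(3):
        t[i, i] = stay
        t[i, 3] = leave
    t[3, :3] = np.array([3.0, 2.0, 2.0]) / 7.0
    return TrajectoryGeneratorSpec(
        transition_matrix=t,
        state_contact_maps=[{"-7:331", "-7:332"}, {"-4:331"}, {"-7:331"},
                            set()],
        jitter_sigma=jitter_sigma,
        n_frames=n_frames,
        seed=seed,
    )


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix."""
    t = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(t.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_markov_trajectory(spec: TrajectoryGeneratorSpec,
                          ) -> tuple[Trajectory, np.ndarray]:
    """Simulate the chain and emit jittered frames.

    Returns the trajectory together with the hidden per-frame state
    sequence (ground truth for recovery tests).  At zero jitter each
    frame satisfies exactly its state's mapped contacts.
    """
    rng = np.random.default_rng(spec.seed)
    atoms = toy_topology()
    templates = np.stack([build_state_template(m)
                          for m in spec.state_contact_maps])
    _validate_templates(atoms, templates, spec.state_contact_maps)

    n, k = spec.n_frames, spec.n_states
    pi0 = stationary_distribution(spec.transition_matrix)
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(k, p=pi0)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    u = rng.random(n - 1)
    for f in range(1, n):
        states[f] = int(np.searchsorted(cum[states[f - 1]], u[f - 1]))
    frames = templates[states]
    if spec.jitter_sigma > 0:
        frames = frames + rng.normal(0.0, spec.jitter_sigma, size=frames.shape)
    times = np.arange(n, dtype=float) * spec.dt
    traj = Trajectory(atoms=atoms, frames=frames, frame_times=times,
                      run_id=spec.run_id)
    return traj, states


def _validate_templates(atoms, templates, contact_maps) -> None:
    """Each state template must satisfy exactly its mapped contacts."""
    specs = default_contact_specs()
    traj = Trajectory(atoms=atoms, frames=templates,
                      frame_times=np.arange(len(templates), dtype=float))
    records = contact_timeseries(traj, specs)
    for s, mapped in enumerate(contact_maps):
        got = {r.name for r in records if r.formed[s]}
        if got != set(mapped):
            raise ValueError(
                f"state {s} template realizes contacts {sorted(got)}, "
                f"mapped {sorted(mapped)}"
            )


def ground_truth_codes(states: np.ndarray,
                       contact_maps: Sequence[set[str]]) -> list[str]:
    """The generator's intended contact patterns, one per frame."""
    pats = ["".join("1" if c in m else "0" for c in CONTACT_NAMES)
            for m in contact_maps]
    return [pats[s] for s in states]


# ---------------------------------------------------------------------------
# alignment generator
# ---------------------------------------------------------------------------

@dataclass
class MSAGeneratorSpec:
    """Planted paralog groups with optional loop D/E enrichment.

    Background composition puts ``negative_background`` total probability
    on D/E (the family-wide level) split evenly, the rest uniform over
    the other 18 amino acids; loop columns multiply the D/E probability
    by ``loop_enrichment_factor``.  Group members derive from a common
    ancestor with i.i.d. re-draws at ``mutation_rate``, so within-group
    identity (~``1 - mutation_rate``) exceeds the 50% grouping cutoff by
    construction.
    """

    group_sizes: Sequence[int] = (5, 3, 2, 1, 1, 1, 1, 1)
    n_columns: int = 60
    loop_columns: Sequence[int] = tuple(range(24, 32))
    negative_background: float = 0.116
    loop_enrichment_factor: float = 1.31
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.mutation_rate <= 0.2:
            raise ValueError(
                "mutation_rate must be in [0, 0.2] so that within-group "
                "identity stays above the grouping cutoff"
            )
        p = self.negative_background * self.loop_enrichment_factor
        if not 0 <= p <= 1:
            raise ValueError(
                f"enriched D/E probability {p:.3f} outside [0, 1]"
            )
        if any(c < 0 or c >= self.n_columns for c in self.loop_columns):
            raise ValueError("loop columns out of range")


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _column_dist(neg_total: float) -> np.ndarray:
    p = np.full(20, (1.0 - neg_total) / 18.0)
    for r in "DE":
        p[_AA.index(r)] = neg_total / 2.0
    return p


def gen_msa(spec: MSAGeneratorSpec,
            ) -> tuple[dict[str, str], list[frozenset[str]], list[int]]:
    """Generate an aligned (gapless) family with planted structure.

    Returns (sequences, ground-truth groups, loop column indices).
    """
    rng = np.random.default_rng(spec.seed)
    loop = set(spec.loop_columns)
    p_bg = _column_dist(spec.negative_background)
    p_loop = _column_dist(spec.negative_background * spec.loop_enrichment_factor)
    dists = [p_loop if c in loop else p_bg for c in range(spec.n_columns)]

    seqs: dict[str, str] = {}
    groups: list[frozenset[str]] = []
    aa = np.array(list(_AA))
    for gi, size in enumerate(spec.group_sizes):
        ancestor = np.array([aa[rng.choice(20, p=d)] for d in dists])
        members = []
        for si in range(size):
            member = ancestor.copy()
            mut = rng.random(spec.n_columns) < spec.mutation_rate
            for c in np.nonzero(mut)[0]:
                member[c] = aa[rng.choice(20, p=dists[c])]
            sid = f"g{gi}_s{si}"
            seqs[sid] = "".join(member)
            members.append(sid)
        groups.append(frozenset(members))
    return seqs, groups, sorted(loop)


# ---------------------------------------------------------------------------
# propensity-table generator
# ---------------------------------------------------------------------------

def gen_propensity_tables(class_means: Mapping[str, float] | None = None,
                          n_per_class: int = 30, noise_sd: float = 0.1,
                          truncation_fraction: float = 0.2,
                          truncation_position: int | None = None,
                          seed: int = 0,
                          ) -> tuple[dict[str, list[float]], dict[str, str]]:
    """Per-domain downstream helix-propensity tables with planted classes.

    Each domain gets 20 positions of clipped-Gaussian propensity around
    its class mean; a ``truncation_fraction`` of domains ends early
    (table shorter than 20 — the consumer zero-pads), at
    ``truncation_position`` when given, else at a random position.
    Returns (tables, per-domain class labels).
    """
    if class_means is None:
        class_means = {"ILV": 0.5, "ALA": 0.25}
    if not 0 <= truncation_fraction <= 1:
        raise ValueError("truncation_fraction must be in [0, 1]")
    for lab, mu in class_means.items():
        if not 0 <= mu <= 1:
            raise ValueError(f"class mean {lab}={mu} outside [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    tables: dict[str, list[float]] = {}
    labels: dict[str, str] = {}
    for lab, mu in class_means.items():
        for i in range(n_per_class):
            sid = f"{lab}_{i}"
            length = 20
            if rng.random() < truncation_fraction:
                if truncation_position is not None:
                    if not 0 <= truncation_position < 20:
                        raise ValueError("truncation_position must be in [0, 20)")
                    length = truncation_position
                else:
                    length = int(rng.integers(0, 20))
            vals = np.clip(rng.normal(mu, noise_sd, size=length), 0.0, 1.0)
            tables[sid] = [float(v) for v in vals]
            labels[sid] = lab
    return tables, labels


def labels_to_wmsa(labels: Mapping[str, str], seed: int = 0):
    """A minimal single-column alignment realizing the given class labels.

    Domains labelled ``ILV`` get I/L/V at the classification column,
    ``ALA`` gets A; every domain is its own paralog group (weight 1).
    Useful for feeding :func:`pdznet.seqstats.propensity_profile`.
    """
    from pdznet.seqstats import WeightedMSA

    rng = np.random.default_rng(seed)
    seqs = {}
    for sid, lab in labels.items():
        if lab == "ILV":
            seqs[sid] = str(rng.choice(list("ILV")))
        elif lab == "ALA":
            seqs[sid] = "A"
        else:
            raise ValueError(f"unknown class label {lab!r}")
    return WeightedMSA(sequences=seqs,
                       groups=[frozenset({sid}) for sid in seqs])


def write_ground_truth(path: str | Path, **payload) -> None:
    """JSON dump of generator ground truth (states, groups, parameters)."""
    def default(o):
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(payload, indent=1, default=default))
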