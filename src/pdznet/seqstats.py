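"""Paralog-weighted sequence statistics for PDZ family alignments.

Many human PDZ domains are close paralogs, and raw counts over the family
are dominated by phylogenetic redundancy.  Sequences are therefore
grouped at >= 50% pairwise identity (single-linkage components by
default) and every member of a group of size g contributes weight 1/g to
positional frequencies — a group of 5 paralogs contributes 1/5 each.

On top of the weighting the module offers:

* weighted residue-class frequencies over arbitrary column sets,
* a one-sided Fisher exact test for over-representation of a residue
  class (typically D/E) in loop columns versus the rest of the domain
  (the 2x2 table uses unweighted integer counts, as the exact test
  requires; the weighted frequencies are reported alongside),
* aggregation of per-domain helix-propensity tables for up to 20
  residues downstream of the domain C-terminus, padding positions past a
  protein's C-terminus with propensity 0, split by the residue class at
  a chosen alignment position (e.g. ILE/LEU/VAL vs ALA at position 328),
* permutation (reshuffling) P-values for class-mean differences, with
  labels shuffled at the paralog-group level so the weighting scheme is
  respected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WeightedMSA",
    "EnrichmentResult",
    "PropensityProfile",
    "read_alignment",
    "pairwise_identity",
    "group_paralogs",
    "weighted_frequency",
    "fisher_one_sided",
    "loop_enrichment",
    "propensity_profile",
    "reshuffle_pvalue",
    "read_propensity_tables",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NEGATIVE = frozenset("DE")
ILV = frozenset("ILV")
N_DOWNSTREAM = 20  # positions aggregated past the domain C-terminus


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------

@dataclass
class WeightedMSA:
    """Aligned sequences with paralog-group weights.

    ``groups`` partitions the sequence ids; every member of a group of
    size g has weight 1/g.
    """

    sequences: dict[str, str]
    groups: list[frozenset[str]]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        seen: set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError("groups must be disjoint")
            seen |= g
        if seen != set(self.sequences):
            raise ValueError("groups must partition the sequence ids")
        if not self.weights:
            self.weights = {sid: 1.0 / len(g)
                            for g in self.groups for sid in g}

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def group_of(self, sid: str) -> frozenset[str]:
        for g in self.groups:
            if sid in g:
                return g
        raise KeyError(sid)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Aligned FASTA -> ordered ``{id: sequence}`` (via Biopython)."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_alignment(path: str | Path, seqs: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# paralog grouping
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over positions where neither is a gap.

    A pair with zero non-gap overlap has identity 0 (with a warning).
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    overlap = matches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        overlap += 1
        if x == y:
            matches += 1
    if overlap == 0:
        warnings.warn("sequence pair with all-gap intersection: identity 0")
        return 0.0
    return matches / overlap


def group_paralogs(msa: Mapping[str, str], identity_cutoff: float = 0.5,
                   linkage: str = "single") -> WeightedMSA:
    """Group paralogs at >= ``identity_cutoff`` pairwise identity.

    ``linkage="single"`` (default) takes connected components of the
    graph linking pairs at or above the cutoff; ``"complete"`` uses
    complete-linkage hierarchical clustering on 1 - identity.
    """
    import networkx as nx

    ids = list(msa)
    if not ids:
        raise ValueError("empty alignment")
    n = len(ids)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(msa[ids[i]], msa[ids[j]])
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if ident[i, j] >= identity_cutoff:
                    g.add_edge(i, j)
        comps = [frozenset(ids[i] for i in c) for c in nx.connected_components(g)]
    elif linkage == "complete":
        from scipy.cluster.hierarchy import fcluster
        from scipy.cluster.hierarchy import linkage as sp_linkage
        from scipy.spatial.distance import squareform

        if n == 1:
            comps = [frozenset(ids)]
        else:
            dist = squareform(1.0 - ident, checks=False)
            z = sp_linkage(dist, method="complete")
            labels = fcluster(z, t=1.0 - identity_cutoff, criterion="distance")
            by: dict[int, set[str]] = {}
            for sid, lab in zip(ids, labels):
                by.setdefault(lab, set()).add(sid)
            comps = [frozenset(v) for v in by.values()]
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    comps.sort(key=lambda c: sorted(c))
    return WeightedMSA(sequences=dict(msa), groups=comps)


# ---------------------------------------------------------------------------
# weighted frequencies
# ---------------------------------------------------------------------------

def weighted_frequency(wmsa: WeightedMSA, columns: Iterable[int],
                       residue_class: Iterable[str]) -> float:
    """Paralog-weighted frequency of a residue class over given columns.

    Sum of weights of (sequence, column) cells whose residue is in the
    class, over the summed weight of all non-gap cells in those columns.
    """
    cols = sorted(set(columns))
    if not cols:
        raise ValueError("column set must be non-empty")
    ncol = wmsa.n_columns
    bad = [c for c in cols if c < 0 or c >= ncol]
    if bad:
        raise IndexError(f"columns out of range: {bad}")
    cls = {r.upper() for r in residue_class}
    num = den = 0.0
    for sid, seq in wmsa.sequences.items():
        w = wmsa.weights[sid]
        for c in cols:
            r = seq[c]
            if r == "-":
                continue
            den += w
            if r in cls:
                num += w
    if den == 0:
        raise ValueError("all cells in the requested columns are gaps")
    return num / den


# ---------------------------------------------------------------------------
# loop enrichment (Fisher exact)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Residue-class enrichment of loop columns vs the rest of the domain.

    ``table`` rows: class / other residues; columns: loop / non-loop
    cells (unweighted integer counts over non-gap cells).  ``p_value`` is
    the one-sided Fisher exact probability of at least the observed
    number of class residues in the loop.  Weighted frequencies of the
    class in the loop columns and over the whole alignment are reported
    alongside.
    """

    table: np.ndarray
    p_value: float
    freq_loop: float
    freq_overall: float

    @property
    def odds_ratio(self) -> float:
        a, b = self.table[0]
        c, d = self.table[1]
        return float(np.inf) if b * c == 0 else (a * d) / (b * c)


def fisher_one_sided(table: np.ndarray) -> float:
    """One-sided (over-representation) Fisher exact P for a 2x2 table.

    Rows: class/other residues; columns: loop/non-loop.  This is the
    hypergeometric upper tail P(X >= a) at the observed top-left count.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 integer table")
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def loop_enrichment(wmsa: WeightedMSA, loop_columns: Iterable[int],
                    residue_class: Iterable[str] = NEGATIVE,
                    ) -> EnrichmentResult:
    """One-sided Fisher exact test for class enrichment in loop columns."""
    loop = sorted(set(loop_columns))
    ncol = wmsa.n_columns
    if not loop or any(c < 0 or c >= ncol for c in loop):
        raise ValueError("loop columns must be a non-empty in-range set")
    loop_set = set(loop)
    if len(loop_set) >= ncol:
        raise ValueError("loop columns must be a proper subset of all columns")
    cls = {r.upper() for r in residue_class}
    counts = np.zeros((2, 2), dtype=int)  # rows: class/other, cols: loop/non-loop
    for seq in wmsa.sequences.values():
        for c, r in enumerate(seq):
            if r == "-":
                continue
            i = 0 if r in cls else 1
            j = 0 if c in loop_set else 1
            counts[i, j] += 1
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError(f"degenerate 2x2 table (empty margin): {counts.tolist()}")
    return EnrichmentResult(
        table=counts,
        p_value=fisher_one_sided(counts),
        freq_loop=weighted_frequency(wmsa, loop, cls),
        freq_overall=weighted_frequency(wmsa, range(ncol), cls),
    )


# ---------------------------------------------------------------------------
# helix-propensity aggregation
# ---------------------------------------------------------------------------

@dataclass
class PropensityProfile:
    """Weighted mean helix propensity at 1..20 downstream positions."""

    positions: list[int]
    mean_propensity: np.ndarray
    class_label: str
    n_domains: int = 0

    def __post_init__(self) -> None:
        self.mean_propensity = np.asarray(self.mean_propensity, dtype=float)
        if len(self.positions) != N_DOWNSTREAM:
            raise ValueError(f"profile must cover {N_DOWNSTREAM} positions")
        if np.any((self.mean_propensity < 0) | (self.mean_propensity > 1)):
            raise ValueError("propensities must lie in [0, 1]")


def _padded(table: Sequence[float]) -> np.ndarray:
    """Zero-pad a per-domain table to 20 downstream positions.

    Proteins ending before 20 residues past the domain C-terminus
    contribute propensity 0 at the missing positions.
    """
    arr = np.zeros(N_DOWNSTREAM)
    t = np.asarray(list(table), dtype=float)
    if len(t) > N_DOWNSTREAM:
        raise ValueError(f"propensity table longer than {N_DOWNSTREAM} positions")
    if np.any((t < 0) | (t > 1)):
        raise ValueError("propensities must lie in [0, 1]")
    arr[:len(t)] = t
    return arr


def propensity_profile(tables: Mapping[str, Sequence[float]],
                       wmsa: WeightedMSA, column: int,
                       class_residues: Iterable[str],
                       class_label: str | None = None) -> PropensityProfile:
    """Weighted mean downstream helix propensity for one residue class.

    Domains whose residue at alignment ``column`` is in
    ``class_residues`` are selected; their (zero-padded) per-position
    propensities are averaged with paralog weights.  Domains missing
    from ``tables`` are excluded with a warning.
    """
    cls = {r.upper() for r in class_residues}
    label = class_label or "".join(sorted(cls))
    members: list[str] = []
    for sid, seq in wmsa.sequences.items():
        if seq[column] in cls:
            if sid not in tables:
                warnings.warn(f"domain {sid!r} missing from propensity tables; excluded")
                continue
            members.append(sid)
    if not members:
        raise ValueError(f"no domains with class {label!r} at column {column}")
    w = np.array([wmsa.weights[sid] for sid in members])
    mat = np.stack([_padded(tables[sid]) for sid in members])
    mean = (w[:, None] * mat).sum(axis=0) / w.sum()
    return PropensityProfile(positions=list(range(1, N_DOWNSTREAM + 1)),
                             mean_propensity=mean, class_label=label,
                             n_domains=len(members))


def read_propensity_tables(path: str | Path) -> dict[str, list[float]]:
    """TSV with columns (domain_id, position, propensity) -> per-domain lists."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"domain_id", "position", "propensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"propensity table needs columns {sorted(required)}")
    out: dict[str, list[float]] = {}
    for sid, sub in df.groupby("domain_id", sort=False):
        sub = sub.sort_values("position")
        if list(sub["position"]) != list(range(1, len(sub) + 1)):
            raise ValueError(f"domain {sid!r}: positions must run 1..L contiguously")
        out[str(sid)] = [float(v) for v in sub["propensity"]]
    return out


# ---------------------------------------------------------------------------
# reshuffling P-value
# ---------------------------------------------------------------------------

def _class_mean_diff(tables: Mapping[str, np.ndarray],
                     labels: Mapping[str, str], classes: tuple[str, str],
                     weights: Mapping[str, float],
                     position: int | None) -> float:
    """Weighted class-mean difference of propensity (class0 - class1)."""
    sums = {c: 0.0 for c in classes}
    wsum = {c: 0.0 for c in classes}
    for sid, lab in labels.items():
        if lab not in sums:
            continue
        v = tables[sid] if position is None else tables[sid][position]
        val = float(np.mean(v))
        w = weights[sid]
        sums[lab] += w * val
        wsum[lab] += w
    if wsum[classes[0]] == 0 or wsum[classes[1]] == 0:
        raise ValueError("both classes must be non-empty")
    return sums[classes[0]] / wsum[classes[0]] - sums[classes[1]] / wsum[classes[1]]


def reshuffle_pvalue(tables: Mapping[str, Sequence[float]],
                     labels: Mapping[str, str], wmsa: WeightedMSA,
                     classes: tuple[str, str], n_perm: int = 999,
                     seed: int | np.random.Generator = 0,
                     position: int | None = None,
                     shuffle: str = "group") -> float:
    """Permutation P-value for a class difference in downstream propensity.

    The observed statistic is the weighted difference of class means
    (``classes[0]`` minus ``classes[1]``) of the zero-padded propensity,
    either at one downstream ``position`` (0-based) or averaged over all
    20 (default).  Labels are reshuffled ``n_perm`` times — at the
    paralog-group level by default (each group carries its majority
    label), or per member with ``shuffle="member"`` — and
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    padded = {sid: _padded(tables[sid]) for sid in labels if sid in tables}
    labels = {sid: lab for sid, lab in labels.items() if sid in padded}
    present = [lab for lab in labels.values() if lab in classes]
    if not any(l == classes[0] for l in present) or \
       not any(l == classes[1] for l in present):
        raise ValueError("both classes must be non-empty")
    observed = _class_mean_diff(padded, labels, classes, wmsa.weights, position)

    if shuffle == "group":
        groups = [sorted(g & set(labels)) for g in wmsa.groups]
        groups = [g for g in groups if g]
        group_labels = []
        for g in groups:
            labs = [labels[sid] for sid in g]
            group_labels.append(max(set(labs), key=labs.count))
        units = groups
        unit_labels = np.array(group_labels, dtype=object)
    elif shuffle == "member":
        units = [[sid] for sid in labels]
        unit_labels = np.array([labels[sid] for sid in labels], dtype=object)
    else:
        raise ValueError(f"unknown shuffle mode {shuffle!r}")

    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(unit_labels)
        plabels = {sid: perm[i] for i, unit in enumerate(units) for sid in unit}
        stat = _class_mean_diff(padded, plabels, classes, wmsa.weights, position)
        if stat >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)
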