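"""Topology/trajectory data model, text I/O and rigid-body superposition.

The trajectory container is deliberately small: a list of annotated atoms
plus an ``F x A x 3`` float64 coordinate stack (Angstrom) and per-frame
times (ps).  Two text dialects are supported, a MODEL/ENDMDL-delimited
multi-model PDB subset (only ATOM/HETATM records are read; occupancy and
B-factor are ignored) and plain XYZ.  Role annotations used by the contact
detectors (donor, acceptor, charged atom, contact carbon, hydrogen->donor
bonds) come from a separate topology TSV, so toy systems carry no implicit
chemistry; a convenience preset supplies the standard tags for charged
amino-acid side chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "Trajectory",
    "Superposition",
    "read_trajectory",
    "write_trajectory",
    "load_topology",
    "apply_topology",
    "standard_role_tags",
    "superpose",
    "select_atoms",
    "backbone_selection",
]

#: role tags understood by the contact detectors
ROLE_TAGS = {"donor", "acceptor", "charged", "contact_carbon"}

#: backbone atoms entering RMSD clustering and RMSF
BACKBONE_ATOMS = ("C", "CA", "N")


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with PDB-style naming and optional role tags.

    ``role_tags`` is a frozenset over ``donor``, ``acceptor``, ``charged``,
    ``contact_carbon`` and ``hydrogen_of:<atom_id>`` (marking this atom as
    the polar hydrogen bonded to donor ``<atom_id>``).
    """

    atom_id: int
    name: str
    residue_number: int
    residue_name: str = "UNK"
    chain_id: str = "A"
    role_tags: frozenset[str] = field(default_factory=frozenset)

    def donor_of(self) -> int | None:
        """Donor atom_id if this atom is a tagged polar hydrogen."""
        for tag in self.role_tags:
            if tag.startswith("hydrogen_of:"):
                return int(tag.split(":", 1)[1])
        return None


@dataclass
class Trajectory:
    """Atoms plus a time-ordered coordinate stack.

    frames: ``(F, A, 3)`` float64 Angstrom; frame_times: ``(F,)`` ps,
    strictly increasing.
    """

    atoms: list[AtomRecord]
    frames: np.ndarray
    frame_times: np.ndarray
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, A, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != "
                f"{len(self.atoms)} atom records"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValueError("frame_times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        ids = [a.atom_id for a in self.atoms]
        if ids != list(range(len(self.atoms))):
            raise ValueError("atom_id values must be contiguous from 0")
        id_set = set(ids)
        for a in self.atoms:
            d = a.donor_of()
            if d is not None:
                if d not in id_set:
                    raise ValueError(f"hydrogen_of target {d} does not exist")
                if "donor" not in self.atoms[d].role_tags:
                    raise ValueError(f"hydrogen_of target {d} is not a donor")

    # -- convenience ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_frames(self, frames: np.ndarray, times: np.ndarray) -> "Trajectory":
        return Trajectory(self.atoms, frames, times, run_id=self.run_id)


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid-body fit ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# superposition (Kabsch via scipy)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares optimal proper rotation + translation (Kabsch).

    Returns the transform mapping ``mobile`` onto ``reference`` and the
    minimized RMSD.  Requires >= 3 non-collinear points.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 points, got {n}")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    mob0, ref0 = mob - mc, ref - rc
    for label, x in (("mobile", mob0), ("reference", ref0)):
        s = np.linalg.svd(x, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError(f"degenerate (collinear) {label} coordinates")
    rot, rssd = Rotation.align_vectors(ref0, mob0)
    rmsd = float(rssd) / math.sqrt(n)
    r = rot.as_matrix()
    return Superposition(rotation=r, translation=rc - r @ mc, rmsd=rmsd)


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return superpose(a, b).rmsd


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def select_atoms(
    atoms: Sequence[AtomRecord],
    chain: str | None = None,
    residue_numbers: Iterable[int] | None = None,
    names: Iterable[str] | None = None,
) -> list[int]:
    """Atom ids matching the given (optional) chain / residues / names."""
    res = set(residue_numbers) if residue_numbers is not None else None
    nm = set(names) if names is not None else None
    out = [
        a.atom_id
        for a in atoms
        if (chain is None or a.chain_id == chain)
        and (res is None or a.residue_number in res)
        and (nm is None or a.name in nm)
    ]
    return out


def backbone_selection(
    atoms: Sequence[AtomRecord],
    chain: str | None = None,
    residue_numbers: Iterable[int] | None = None,
) -> list[int]:
    """Backbone C, CA, N atom ids of the stated residues."""
    return select_atoms(atoms, chain=chain, residue_numbers=residue_numbers,
                        names=BACKBONE_ATOMS)


# ---------------------------------------------------------------------------
# topology TSV
# ---------------------------------------------------------------------------

#: ionic-contact roles for the standard charged side chains: the charged
#: atoms and the two last carbons before them, plus side-chain acceptors.
_STANDARD_SIDECHAIN_ROLES: dict[str, dict[str, set[str]]] = {
    "LYS": {"NZ": {"charged", "donor"}, "CE": {"contact_carbon"}, "CD": {"contact_carbon"}},
    "ARG": {"NH1": {"charged", "donor"}, "NH2": {"charged", "donor"},
            "CZ": {"contact_carbon"}, "CD": {"contact_carbon"}},
    "ASP": {"OD1": {"charged", "acceptor"}, "OD2": {"charged", "acceptor"},
            "CG": {"contact_carbon"}, "CB": {"contact_carbon"}},
    "GLU": {"OE1": {"charged", "acceptor"}, "OE2": {"charged", "acceptor"},
            "CD": {"contact_carbon"}, "CG": {"contact_carbon"}},
    "HIS": {"ND1": {"charged", "donor"}, "NE2": {"charged", "acceptor"},
            "CE1": {"contact_carbon"}, "CG": {"contact_carbon"}},
}


def standard_role_tags(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    """Return atoms with standard amino-acid role tags merged in.

    Covers the charged side chains (LYS/ARG/ASP/GLU/HIS) plus backbone
    carbonyl O as acceptor and backbone N as donor.  Tags are only added
    for atoms actually present; existing tags are preserved.
    """
    out: list[AtomRecord] = []
    for a in atoms:
        tags = set(a.role_tags)
        side = _STANDARD_SIDECHAIN_ROLES.get(a.residue_name, {})
        if a.name in side:
            tags |= side[a.name]
        if a.name == "O":
            tags.add("acceptor")
        if a.name == "N":
            tags.add("donor")
        out.append(replace(a, role_tags=frozenset(tags)))
    return out


def load_topology(path: str | Path) -> list[dict[str, str]]:
    """Parse a topology TSV into row dicts.

    Columns: chain, residue_number, atom_name, role_tag and an optional
    partner_atom_name (the donor of a ``hydrogen`` row, same residue).
    Lines starting with '#' are comments.
    """
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            expected = {"chain", "residue_number", "atom_name", "role_tag"}
            if not expected.issubset(header):
                raise ValueError(
                    f"topology file {path} missing columns "
                    f"{sorted(expected - set(header))}"
                )
            continue
        rows.append(dict(zip(header, (p.strip() for p in parts))))
    if header is None:
        raise ValueError(f"empty topology file: {path}")
    return rows


def apply_topology(atoms: Sequence[AtomRecord],
                   rows: Iterable[dict[str, str]]) -> list[AtomRecord]:
    """Attach role tags from topology rows; unknown atoms are a hard error."""
    index: dict[tuple[str, int, str], int] = {
        (a.chain_id, a.residue_number, a.name): a.atom_id for a in atoms
    }
    tags: list[set[str]] = [set(a.role_tags) for a in atoms]
    for row in rows:
        key = (row["chain"], int(row["residue_number"]), row["atom_name"])
        if key not in index:
            raise ValueError(
                f"topology references unknown atom "
                f"{key[0]}:{key[1]}:{key[2]}"
            )
        aid = index[key]
        role = row["role_tag"]
        if role == "hydrogen":
            partner = row.get("partner_atom_name", "")
            if not partner:
                raise ValueError(
                    f"hydrogen row for {key} lacks partner_atom_name"
                )
            dkey = (key[0], key[1], partner)
            if dkey not in index:
                raise ValueError(
                    f"topology references unknown donor atom "
                    f"{dkey[0]}:{dkey[1]}:{dkey[2]}"
                )
            tags[aid].add(f"hydrogen_of:{index[dkey]}")
            tags[index[dkey]].add("donor")
        elif role in ROLE_TAGS:
            tags[aid].add(role)
        else:
            raise ValueError(f"unknown role_tag {role!r} for atom {key}")
    return [replace(a, role_tags=frozenset(t)) for a, t in zip(atoms, tags)]


def write_topology(path: str | Path, atoms: Sequence[AtomRecord]) -> None:
    """Write the role tags of ``atoms`` as a topology TSV."""
    from pdznet import __version__

    lines = [f"# pdznet v{__version__} topology",
             "chain\tresidue_number\tatom_name\trole_tag\tpartner_atom_name"]
    for a in atoms:
        for tag in sorted(a.role_tags):
            if tag.startswith("hydrogen_of:"):
                donor = atoms[int(tag.split(":")[1])]
                lines.append(
                    f"{a.chain_id}\t{a.residue_number}\t{a.name}\thydrogen\t{donor.name}"
                )
            else:
                lines.append(f"{a.chain_id}\t{a.residue_number}\t{a.name}\t{tag}\t")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str | Path,
    format: str | None = None,
    topology_path: str | Path | None = None,
    run_id: str | None = None,
) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory.

    ``format`` is ``"pdb_multimodel"`` or ``"xyz"``; when omitted it is
    inferred from the file suffix.  All frames must carry the same atoms
    in the same order — a mismatch is a hard error naming the offending
    frame.  Role tags are populated from ``topology_path`` when given.
    """
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "pdb_multimodel"
    if format == "pdb_multimodel":
        atoms, frames, times = _read_pdb_multimodel(path)
    elif format == "xyz":
        atoms, frames, times = _read_xyz(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    if topology_path is not None:
        atoms = apply_topology(atoms, load_topology(topology_path))
    return Trajectory(atoms, frames, times, run_id=run_id or path.stem)


def write_trajectory(path: str | Path, traj: Trajectory,
                     format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "pdb_multimodel"
    if format == "pdb_multimodel":
        _write_pdb_multimodel(path, traj)
    elif format == "xyz":
        _write_xyz(path, traj)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def _read_pdb_multimodel(path: Path):
    """MODEL/ENDMDL-delimited PDB; only ATOM/HETATM records are read."""
    frames: list[list[tuple[float, float, float]]] = []
    model_atoms: list[list[tuple[str, int, str, str]]] = []
    cur_coords: list[tuple[float, float, float]] | None = None
    cur_atoms: list[tuple[str, int, str, str]] | None = None
    model_ids: list[int] = []
    saw_model = False

    def flush() -> None:
        nonlocal cur_coords, cur_atoms
        if cur_coords is not None and cur_coords:
            frames.append(cur_coords)
            model_atoms.append(cur_atoms)  # type: ignore[arg-type]
        cur_coords, cur_atoms = None, None

    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
            saw_model = True
            cur_coords, cur_atoms = [], []
            try:
                model_ids.append(int(line[6:].split()[0]))
            except (IndexError, ValueError):
                model_ids.append(len(frames) + 1)
        elif rec == "ENDMDL":
            flush()
        elif rec in ("ATOM", "HETATM"):
            if cur_coords is None:
                cur_coords, cur_atoms = [], []
                if not saw_model:
                    model_ids.append(len(frames) + 1)
            name = line[12:16].strip()
            resname = line[17:20].strip() or "UNK"
            chain = line[21].strip() or "A"
            resnum = int(line[22:26])
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            cur_coords.append(xyz)
            cur_atoms.append((name, resnum, resname, chain))  # type: ignore[union-attr]
    flush()
    if not frames:
        raise ValueError(f"no ATOM records found in {path}")
    ref = model_atoms[0]
    for i, atoms_i in enumerate(model_atoms[1:], start=1):
        mid = model_ids[i] if i < len(model_ids) else i + 1
        if len(atoms_i) != len(ref):
            raise ValueError(
                f"model {mid} of {path} has {len(atoms_i)} atoms, "
                f"expected {len(ref)}"
            )
        if atoms_i != ref:
            raise ValueError(f"model {mid} of {path} has mismatched atom order")
    atoms = [
        AtomRecord(atom_id=i, name=n, residue_number=rn, residue_name=rnm,
                   chain_id=ch)
        for i, (n, rn, rnm, ch) in enumerate(ref)
    ]
    coords = np.asarray(frames, dtype=float)
    times = np.arange(len(frames), dtype=float)
    return atoms, coords, times


def _write_pdb_multimodel(path: Path, traj: Trajectory) -> None:
    from pdznet import __version__

    lines = [f"REMARK   1 pdznet v{__version__}"]
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for a in traj.atoms:
            x, y, z = traj.frames[f, a.atom_id]
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            # columns: serial 7-11, name 13-16, altLoc 17, resName 18-20,
            # chainID 22, resSeq 23-26, coords 31-54 (1-based PDB layout)
            lines.append(
                f"ATOM  {a.atom_id + 1:5d} {name:<4s} "
                f"{a.residue_name:>3s} {a.chain_id}{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _read_xyz(path: Path):
    lines = path.read_text().splitlines()
    frames: list[list[tuple[float, float, float]]] = []
    names_per_frame: list[list[str]] = []
    times: list[float] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"frame {frame_no} of {path}: bad atom-count line {lines[i]!r}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = _parse_xyz_time(comment, default=float(len(frames)))
        body = lines[i + 2: i + 2 + natoms]
        if len(body) < natoms:
            raise ValueError(
                f"frame {frame_no} of {path} truncated: expected {natoms} atoms"
            )
        names, coords = [], []
        for row in body:
            parts = row.split()
            names.append(parts[0])
            coords.append((float(parts[1]), float(parts[2]), float(parts[3])))
        names_per_frame.append(names)
        frames.append(coords)
        times.append(t)
        i += 2 + natoms
    if not frames:
        raise ValueError(f"no frames found in {path}")
    for k, names in enumerate(names_per_frame[1:], start=2):
        if names != names_per_frame[0]:
            raise ValueError(
                f"frame {k} of {path} has mismatched atom names/count"
            )
    atoms = [
        AtomRecord(atom_id=i, name=n, residue_number=i, residue_name="UNK")
        for i, n in enumerate(names_per_frame[0])
    ]
    return atoms, np.asarray(frames, dtype=float), np.asarray(times)


def _parse_xyz_time(comment: str, default: float) -> float:
    if "t=" in comment:
        try:
            return float(comment.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            return default
    return default


def _write_xyz(path: Path, traj: Trajectory) -> None:
    from pdznet import __version__

    out: list[str] = []
    for f in range(traj.n_frames):
        out.append(str(traj.n_atoms))
        out.append(f"pdznet v{__version__} {traj.run_id} "
                   f"t={float(traj.frame_times[f])!r}")
        for a in traj.atoms:
            x, y, z = (float(v) for v in traj.frames[f, a.atom_id])
            # repr keeps the shortest decimal that round-trips to the same
            # float64, so write+read is bit-exact
            out.append(f"{a.name} {x!r} {y!r} {z!r}")
    path.write_text("\n".join(out) + "\n")
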