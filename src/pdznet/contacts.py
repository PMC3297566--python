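"""Geometric hydrogen-bond and salt-bridge detection with occupancies.

A hydrogen bond is formed when the donor-acceptor distance is at most
3.6 A and the angle at the donor between the donor->hydrogen and
donor->acceptor vectors is at most the angle cutoff (default 30 deg).
An ionic contact (salt bridge) is formed when the two last side-chain
carbons before the charged atoms of the two partners approach to less
than 5 A (strict inequality).  Periodic boundary conditions are NOT
applied: inputs are assumed whole and solvent-stripped.

Named contacts (e.g. ``-7:331`` between peptide residue -7 and loop
residue 331) are declared as :class:`ContactSpec` with two atom-selector
expressions ``chain:resnum:atomname`` (``*`` wildcards allowed); a spec
that resolves to several donor/hydrogen/acceptor triads or carbon pairs
is formed in a frame if ANY resolved geometry satisfies the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from pdznet.trajectory import AtomRecord, Trajectory

__all__ = [
    "ContactSpec",
    "ContactRecord",
    "detect_hbond",
    "detect_ionic",
    "contact_timeseries",
    "cumulative_occupancy",
    "resolve_selector",
    "read_contact_specs",
    "write_contact_tables",
]

HBOND_DIST_CUTOFF = 3.6   # A, donor-acceptor
HBOND_ANGLE_CUTOFF = 30.0  # deg at the donor (configurable; see docs)
IONIC_CUTOFF = 5.0        # A, strict, between contact carbons


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def resolve_selector(atoms: Sequence[AtomRecord], selector: str) -> list[int]:
    """Resolve ``chain:resnum:atomname`` (``*`` wildcards) to atom ids."""
    parts = selector.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"selector {selector!r} must have the form chain:resnum:atomname"
        )
    chain, resnum, name = (p.strip() for p in parts)
    out = []
    for a in atoms:
        if chain != "*" and a.chain_id != chain:
            continue
        if resnum != "*" and a.residue_number != int(resnum):
            continue
        if name != "*" and a.name != name:
            continue
        out.append(a.atom_id)
    return out


@dataclass(frozen=True)
class ContactSpec:
    """A named candidate interaction between two atom-selector sets."""

    name: str
    kind: str  # "hbond" | "ionic"
    side_a: str
    side_b: str
    dist_cutoff: float | None = None
    angle_cutoff_deg: float = HBOND_ANGLE_CUTOFF

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "ionic"):
            raise ValueError(f"contact {self.name!r}: unknown kind {self.kind!r}")

    @property
    def distance_cutoff(self) -> float:
        if self.dist_cutoff is not None:
            return self.dist_cutoff
        return HBOND_DIST_CUTOFF if self.kind == "hbond" else IONIC_CUTOFF

    # -- resolution against a topology ---------------------------------
    def resolve(self, atoms: Sequence[AtomRecord]):
        """Resolve to concrete geometries.

        hbond -> list of (donor, hydrogen, acceptor) triads;
        ionic -> (carbons_a, carbons_b) id lists.
        """
        ids_a = resolve_selector(atoms, self.side_a)
        ids_b = resolve_selector(atoms, self.side_b)
        if self.kind == "ionic":
            ca = [i for i in ids_a if "contact_carbon" in atoms[i].role_tags]
            cb = [i for i in ids_b if "contact_carbon" in atoms[i].role_tags]
            if not ca or not cb:
                raise ValueError(
                    f"contact {self.name!r}: selectors do not resolve to "
                    f"contact_carbon atoms on both sides"
                )
            return ca, cb
        triads = _hbond_triads(atoms, ids_a, ids_b)
        if not triads:
            triads = _hbond_triads(atoms, ids_b, ids_a)
        if not triads:
            raise ValueError(
                f"contact {self.name!r}: no (donor, hydrogen) / acceptor "
                f"resolution on either orientation"
            )
        return triads


def _hbond_triads(atoms: Sequence[AtomRecord], donor_side: list[int],
                  acceptor_side: list[int]) -> list[tuple[int, int, int]]:
    donors = {i for i in donor_side if "donor" in atoms[i].role_tags}
    acceptors = [i for i in acceptor_side if "acceptor" in atoms[i].role_tags]
    triads = []
    for h in atoms:
        d = h.donor_of()
        if d is not None and d in donors:
            triads.extend((d, h.atom_id, a) for a in acceptors)
    return triads


@dataclass
class ContactRecord:
    """Per-frame formation record of one contact."""

    spec: ContactSpec
    formed: np.ndarray  # (F,) bool

    def __post_init__(self) -> None:
        self.formed = np.asarray(self.formed, dtype=bool)

    @property
    def occupancy(self) -> float:
        return float(self.formed.mean())

    @property
    def name(self) -> str:
        return self.spec.name


# ---------------------------------------------------------------------------
# single-frame detectors
# ---------------------------------------------------------------------------

def detect_hbond(frame: np.ndarray, donor: int, hydrogen: int, acceptor: int,
                 angle_cutoff_deg: float = HBOND_ANGLE_CUTOFF,
                 dist_cutoff: float = HBOND_DIST_CUTOFF) -> bool:
    """Hydrogen-bond test on a single ``(A, 3)`` frame."""
    if len({donor, hydrogen, acceptor}) != 3:
        raise ValueError("donor, hydrogen and acceptor must be distinct atoms")
    frame = np.asarray(frame, dtype=float)
    d, h, a = frame[donor], frame[hydrogen], frame[acceptor]
    da = a - d
    dh = h - d
    nh = np.linalg.norm(dh)
    if nh < 1e-12:
        raise ValueError("coincident donor/hydrogen coordinates: angle undefined")
    dist = np.linalg.norm(da)
    if dist > dist_cutoff:
        return False
    if dist < 1e-12:
        raise ValueError("coincident donor/acceptor coordinates: angle undefined")
    cosang = np.clip(np.dot(dh, da) / (nh * dist), -1.0, 1.0)
    return bool(math.degrees(math.acos(cosang)) <= angle_cutoff_deg)


def detect_ionic(frame: np.ndarray, carbons_a: Iterable[int],
                 carbons_b: Iterable[int],
                 cutoff: float = IONIC_CUTOFF) -> bool:
    """Salt-bridge test: min pairwise carbon-carbon distance < cutoff."""
    ca, cb = list(carbons_a), list(carbons_b)
    if not ca or not cb:
        raise ValueError("carbon sets must be non-empty")
    frame = np.asarray(frame, dtype=float)
    diff = frame[ca][:, None, :] - frame[cb][None, :, :]
    dmin = np.sqrt((diff ** 2).sum(axis=-1)).min()
    return bool(dmin < cutoff)


# ---------------------------------------------------------------------------
# trajectory-level series (vectorized over frames)
# ---------------------------------------------------------------------------

def _hbond_series(frames: np.ndarray, triads: list[tuple[int, int, int]],
                  angle_cutoff_deg: float, dist_cutoff: float) -> np.ndarray:
    formed = np.zeros(frames.shape[0], dtype=bool)
    cos_cut = math.cos(math.radians(angle_cutoff_deg))
    for d, h, a in triads:
        da = frames[:, a] - frames[:, d]
        dh = frames[:, h] - frames[:, d]
        dist = np.linalg.norm(da, axis=1)
        nh = np.linalg.norm(dh, axis=1)
        if np.any(nh < 1e-12):
            raise ValueError("coincident donor/hydrogen coordinates in trajectory")
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (dh * da).sum(axis=1) / (nh * dist)
        ok = (dist <= dist_cutoff) & (dist > 1e-12) & (cosang >= cos_cut)
        formed |= ok
    return formed


def _ionic_series(frames: np.ndarray, ca: list[int], cb: list[int],
                  cutoff: float) -> np.ndarray:
    diff = frames[:, ca, None, :] - frames[:, None, cb, :]
    dmin = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
    return dmin < cutoff


def contact_timeseries(traj: Trajectory,
                       specs: Sequence[ContactSpec]) -> list[ContactRecord]:
    """Evaluate each spec on every frame (ANY-semantics over resolutions)."""
    records = []
    for spec in specs:
        resolved = spec.resolve(traj.atoms)
        if spec.kind == "hbond":
            formed = _hbond_series(traj.frames, resolved,
                                   spec.angle_cutoff_deg, spec.distance_cutoff)
        else:
            ca, cb = resolved
            formed = _ionic_series(traj.frames, ca, cb, spec.distance_cutoff)
        records.append(ContactRecord(spec=spec, formed=formed))
    return records


def cumulative_occupancy(records: Sequence[ContactRecord],
                         subset: Iterable[str] | None = None) -> float:
    """Fraction of frames with at least one of the named contacts formed."""
    names = list(subset) if subset is not None else [r.name for r in records]
    if not names:
        raise ValueError("subset must be non-empty")
    by_name = {r.name: r for r in records}
    unknown = [n for n in names if n not in by_name]
    if unknown:
        raise KeyError(f"unknown contact name(s): {unknown}")
    stack = np.stack([by_name[n].formed for n in names])
    return float(stack.any(axis=0).mean())


# ---------------------------------------------------------------------------
# config + TSV I/O
# ---------------------------------------------------------------------------

def read_contact_specs(path: str | Path) -> list[ContactSpec]:
    """Load contact specs from a YAML list of mappings."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("contacts", [])
    specs = []
    for entry in data:
        specs.append(ContactSpec(
            name=str(entry["name"]),
            kind=entry["kind"],
            side_a=entry["side_a"],
            side_b=entry["side_b"],
            dist_cutoff=entry.get("dist_cutoff"),
            angle_cutoff_deg=float(entry.get("angle_cutoff_deg",
                                             HBOND_ANGLE_CUTOFF)),
        ))
    return specs


def write_contact_tables(outdir: str | Path, traj: Trajectory,
                         records: Sequence[ContactRecord]) -> None:
    """Per-contact (frame_time, formed) TSVs plus an occupancy summary."""
    import pandas as pd

    from pdznet import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# pdznet v{__version__}\n"
    for rec in records:
        df = pd.DataFrame({"frame_time_ps": traj.frame_times,
                           "formed": rec.formed.astype(int)})
        safe = rec.name.replace(":", "_").replace("-", "m")
        p = outdir / f"contact_{safe}.tsv"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    summary = pd.DataFrame({
        "name": [r.name for r in records],
        "kind": [r.spec.kind for r in records],
        "occupancy": [r.occupancy for r in records],
    })
    with open(outdir / "contacts_summary.tsv", "w") as fh:
        fh.write(header)
        summary.to_csv(fh, sep="\t", index=False)
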