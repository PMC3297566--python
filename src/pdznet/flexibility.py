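"""Windowed per-residue backbone RMSF profiles.

RMSF is computed over backbone atoms C, CA and N.  The trajectory is cut
into consecutive non-overlapping time windows (trailing partial window
dropped); within each window frames are first aligned onto the window's
first frame (making the mean well defined under arbitrary rigid motion),
then every frame is superposed onto the window-mean structure (one
mean/fit iteration), the per-atom RMSF is the
root of the time-averaged squared deviation from the mean position, the
per-residue value averages that residue's backbone atoms, and the profile
averages the windows.  Short windows are blind to motions slower than the
window, so comparing window lengths separates fast from slow flexibility.
Profiles from repeat runs are averaged element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from pdznet.trajectory import Trajectory, superpose

__all__ = [
    "RMSFProfile",
    "compute_rmsf",
    "average_profiles",
    "rmsf_difference",
    "write_rmsf_table",
]


@dataclass
class RMSFProfile:
    """Per-residue RMSF (A) for one window length."""

    residue_numbers: list[int]
    rmsf: np.ndarray
    window_ns: float
    n_runs_averaged: int = 1

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.residue_numbers) != len(self.rmsf):
            raise ValueError("one RMSF value per residue required")
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")


def compute_rmsf(traj: Trajectory, selection: Sequence[int],
                 window_ns: float,
                 fit_selection: Sequence[int] | None = None) -> RMSFProfile:
    """Windowed per-residue RMSF over the selected backbone atoms.

    ``selection`` holds the atom ids whose fluctuations are measured
    (grouped per residue); ``fit_selection`` (default: ``selection``)
    holds the atoms used for the rigid-body fit that removes overall
    translation/rotation before measuring.
    """
    sel = list(selection)
    if not sel:
        raise ValueError("empty atom selection")
    fit_sel = list(fit_selection) if fit_selection is not None else sel
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    dt = float(np.median(np.diff(traj.frame_times)))
    wlen = int(round(window_ns * 1000.0 / dt))
    if wlen < 2:
        raise ValueError(f"window of {window_ns} ns spans <2 frames at dt={dt} ps")
    if wlen > traj.n_frames:
        raise ValueError(
            f"window of {window_ns} ns ({wlen} frames) exceeds trajectory "
            f"length ({traj.n_frames} frames)"
        )
    n_windows = traj.n_frames // wlen
    atom_rmsf = np.zeros((n_windows, len(sel)))
    for w in range(n_windows):
        frames = traj.frames[w * wlen:(w + 1) * wlen]
        meas = frames[:, sel, :]
        fit = frames[:, fit_sel, :]
        # stage 0: remove arbitrary per-frame rigid motion by aligning
        # every frame onto the window's first frame, so the window mean
        # is well defined
        fit0, meas0 = np.empty_like(fit), np.empty_like(meas)
        for f in range(wlen):
            sp = superpose(fit[f], fit[0])
            fit0[f] = sp.apply(fit[f])
            meas0[f] = sp.apply(meas[f])
        # stage 1 (one iteration): re-fit onto the window-mean structure
        mean_fit = fit0.mean(axis=0)
        fitted = np.empty_like(meas)
        for f in range(wlen):
            sp = superpose(fit0[f], mean_fit)
            fitted[f] = sp.apply(meas0[f])
        mean_pos = fitted.mean(axis=0)
        dev2 = ((fitted - mean_pos) ** 2).sum(axis=2)  # (T, n_sel)
        atom_rmsf[w] = np.sqrt(dev2.mean(axis=0))
    atom_rmsf = atom_rmsf.mean(axis=0)

    residues: list[int] = []
    values: list[float] = []
    by_res: dict[int, list[float]] = {}
    for a, v in zip(sel, atom_rmsf):
        by_res.setdefault(traj.atoms[a].residue_number, []).append(v)
    for rn in sorted(by_res):
        residues.append(rn)
        values.append(float(np.mean(by_res[rn])))
    return RMSFProfile(residue_numbers=residues, rmsf=np.array(values),
                       window_ns=window_ns, n_runs_averaged=1)


def average_profiles(profiles: Sequence[RMSFProfile]) -> RMSFProfile:
    """Element-wise mean over repeat runs."""
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.residue_numbers != first.residue_numbers:
            raise ValueError("profiles cover different residues")
        if p.window_ns != first.window_ns:
            raise ValueError("profiles use different window lengths")
    rmsf = np.mean([p.rmsf for p in profiles], axis=0)
    return RMSFProfile(residue_numbers=list(first.residue_numbers), rmsf=rmsf,
                       window_ns=first.window_ns,
                       n_runs_averaged=len(profiles))


def rmsf_difference(a: RMSFProfile, b: RMSFProfile) -> np.ndarray:
    """Signed per-residue difference ``a - b`` (same residues, same window)."""
    if a.residue_numbers != b.residue_numbers:
        raise ValueError("profiles cover different residues")
    if a.window_ns != b.window_ns:
        raise ValueError("profiles use different window lengths")
    return a.rmsf - b.rmsf


def write_rmsf_table(path: str | Path, profile: RMSFProfile) -> None:
    import pandas as pd

    from pdznet import __version__

    df = pd.DataFrame({
        "residue_number": profile.residue_numbers,
        "rmsf": profile.rmsf,
        "window_ns": profile.window_ns,
        "n_runs": profile.n_runs_averaged,
    })
    with open(path, "w") as fh:
        fh.write(f"# pdznet v{__version__}\n")
        df.to_csv(fh, sep="\t", index=False)
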