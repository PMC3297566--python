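"""Windowed backbone RMSF and RMSF-difference profiles.

Builds two synthetic variants of a 30-residue backbone: a reference with
uniform fast jitter, and a "destabilized" variant whose loop residues
(11-16) fluctuate more and additionally carry a slow square-wave motion.
Long windows see both fast and slow flexibility; short windows are blind
to motions slower than the window, so the difference profile shrinks —
the signature separating fast from slow dynamics.
"""

import numpy as np

from pdznet import compute_rmsf, rmsf_difference
from pdznet.trajectory import AtomRecord, Trajectory

rng = np.random.default_rng(5)
n_res, n_frames = 30, 8000
atoms = [AtomRecord(atom_id=3 * r + k, name=nm, residue_number=r + 1)
         for r in range(n_res) for k, nm in enumerate(("N", "CA", "C"))]
ref = rng.normal(size=(len(atoms), 3)) * 10
loop_atoms = [a.atom_id for a in atoms if 11 <= a.residue_number <= 16]


def make_variant(loop_sigma, slow_amplitude):
    frames = ref[None] + rng.normal(0, 0.4, size=(n_frames, len(atoms), 3))
    extra = np.sqrt(max(loop_sigma ** 2 - 0.4 ** 2, 0.0))
    frames[:, loop_atoms] += rng.normal(
        0, extra, size=(n_frames, len(loop_atoms), 3))
    slow = np.where((np.arange(n_frames) // 2000) % 2 == 0, -1.0, 1.0)
    frames[:, loop_atoms, 0] += slow_amplitude * slow[:, None]
    return Trajectory(atoms, frames, np.arange(float(n_frames)))


wt = make_variant(loop_sigma=0.4, slow_amplitude=0.0)
mut = make_variant(loop_sigma=0.8, slow_amplitude=1.0)
sel = list(range(len(atoms)))

for window_ns in (8.0, 0.5):
    d = rmsf_difference(compute_rmsf(mut, sel, window_ns),
                        compute_rmsf(wt, sel, window_ns))
    print(f"window {window_ns:4.1f} ns: "
          f"loop mean diff {d[10:16].mean():.3f} A, "
          f"non-loop mean diff {np.delete(d, range(10, 16)).mean():.3f} A")

print("\nThe loop peak at the full window reflects both the inflated fast")
print("jitter (expected (0.8-0.4)*sqrt(3) ~ 0.69 A) and the slow swing;")
print("the short window suppresses the slow part, shrinking the peak.")
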