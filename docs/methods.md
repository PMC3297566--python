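# Methods

This note records the models and procedures `pdznet` implements, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions that affect results.

## Units and conventions

Coordinates are in Å, frames are 0-indexed, frame times in ps. These are
fixed across the package. Snapshot spacing is assumed uniform (the
default generators save every 1 ps); RMSF window lengths are given in ns
and converted with the median frame spacing.

## Contact detection

*Hydrogen bond*: formed in a frame iff d(donor, acceptor) ≤ 3.6 Å and
the angle at the donor between the donor→hydrogen and donor→acceptor
vectors is ≤ `angle_cutoff_deg`. The distance cutoff of 3.6 Å is the
analysis convention this package follows; the angle default of 30° at
the donor is a common analysis-tool choice and is deliberately exposed
as a parameter rather than hard-wired, since reasonable conventions
range from 20° to 35° and some tools measure at the hydrogen instead.
Coincident donor/hydrogen positions make the angle undefined and raise
an error rather than silently passing.

*Salt bridge (ionic contact)*: formed iff the minimum distance between
any "contact carbon" (the last two side-chain carbons before the charged
atoms, e.g. CD/CE of lysine, CG/CD of glutamate) on one side and any on
the other side is strictly below 5 Å. The comparison is strict (<, not
≤) following the defining phrase "closer than 5 Å"; at 3 printed
decimals this matters only for exactly-5.000 Å fixtures.

Named contacts are declared with two atom-selector expressions
(`chain:resnum:atomname`, `*` wildcards). A spec resolving to several
donor/hydrogen/acceptor triads or carbon pairs (e.g. a carboxylate's two
oxygens) is formed if ANY resolved geometry passes — a salt bridge is
one named interaction regardless of which oxygen is engaged.

Periodic boundary conditions are **not** applied. Inputs are assumed
whole, imaged and solvent-stripped; feeding wrapped coordinates will
produce wrong distances.

## Superposition

Rigid-body fits use the Kabsch algorithm (scipy's
`Rotation.align_vectors`, which includes the reflection correction, so
the rotation is always proper). Degenerate selections (fewer than 3
points, or collinear point sets, detected via the second singular value
of the centered coordinates) are rejected. The test suite validates the
minimized RMSD against an independent quaternion characteristic-
polynomial oracle to 1e-8 Å.

## Leader clustering of peptide conformations

Single-pass leader clustering on the ligand backbone (C, CA, N), cutoff
2.0 Å: frames are scanned in time order; a frame founds a new cluster
iff its RMSD to every existing leader exceeds the cutoff, else it joins
the FIRST leader within the cutoff. RMSD is computed after Kabsch
superposition by default — the common trajectory-clustering practice —
with a no-fit mode available (`fit=False`) since raw-coordinate RMSD is
also used by some tools. The algorithm guarantees every frame is within
the cutoff of its leader and that leaders are assigned to themselves; it
does **not** guarantee leaders are pairwise more than a cutoff apart
(a later leader can be within the cutoff of an earlier frame that was
not a leader), which is inherent to the single-pass scheme.

## Microstates and the conformation-space network

Each frame's code concatenates one binary digit per monitored contact
(in configured order) with the conformation cluster id. Because the
cluster id can exceed 9, the internal representation is delimited
(`"110|2"`); reports use the compact contact pattern (`"110"`). The CSN
counts node populations and directed transitions between consecutive
frames within a run; self-transitions are recorded; no edge crosses a
run boundary. Conservation invariants (populations sum to total frames;
out-edges per node equal population minus run-final appearances) are
checked at construction.

## Gradient clustering

Default gradient: each node points to the element of
{undirected neighbors ∪ itself} with maximal population; pointer chains
terminate at local population maxima, and nodes sharing a fixed point
form one basin. Self-transitions are excluded from the neighbor set.
Tie rule, chosen for determinism: a node stays put whenever it attains
the maximum itself (hence all-equal populations yield singleton basins);
otherwise the lexicographically smallest code wins. An alternative
gradient (`weight="transition"`) points instead to the
strictly-higher-populated neighbor with the largest symmetrized
transition count — "fastest interconversion" — and gives the same
attractor set (population local maxima) but can split ridges
differently; the population gradient is the default because it depends
only on the stationary histogram and is therefore less noisy at short
trajectory lengths.

Coarse-graining sums node fractions per basin; the weight of an edge
between basins is the total inter-basin transition count divided by the
total transition count of the CSN. Each basin is labelled by its most
populated member's contact pattern, with remaining patterns listed as
minor.

## Equilibration discard

`discard_equilibration` removes all frames with time < burn-in (default
50 ns), reflecting the standard practice of dropping the initial
transient biased toward the starting configuration. Removing every
frame is an error.

## Windowed RMSF

The trajectory is split into consecutive, non-overlapping windows of the
requested length; a trailing partial window is dropped (simplest
unbiased choice; overlap is not implemented). Within a window, frames
are first aligned onto the window's first frame — this makes the window
mean well defined even when frames carry arbitrary rigid-body motion —
then re-superposed onto the window-mean structure (one mean/fit
iteration). Per-atom RMSF is the root mean squared deviation from the
mean position; per-residue values average that residue's C, CA, N; the
profile averages windows, and `average_profiles` averages runs
element-wise (pooling windows across equal-length runs gives the same
mean). The fit selection defaults to the measured selection and is
configurable (e.g. fit on the domain, measure the loop).

Two quantitative consequences of the procedure worth knowing: (i) the
rigid-body fit absorbs 6 degrees of freedom, shrinking measured RMSF by
a factor ≈ √(1 − 2/N) for N fitted atoms — negligible for a domain-sized
selection, ~9% for a 12-atom toy peptide; (ii) windows shorter than a
motion's period cannot see it, so expected profiles can only decrease as
the window shrinks for processes with slow components.

## Paralog weighting and enrichment

Pairwise identity = identical residues / positions where neither
sequence is gapped (an all-gap intersection counts as identity 0 with a
warning). Groups are connected components of the ≥ 50%-identity graph
(single linkage, matching the notion of chained "groups of paralogs";
complete linkage available behind a flag). Every member of a group of
size g weighs 1/g; weighted frequencies divide class weight by non-gap
weight over the chosen columns, so per-column frequencies over the 20
amino acids sum to 1.

The loop-enrichment test builds the 2×2 table of **unweighted** integer
counts (class/other × loop/non-loop over all non-gap cells) and computes
the one-sided Fisher exact probability of at least the observed count —
the exact test requires integers, so the weighting cannot enter it
directly; weighted frequencies are reported alongside as the effect-size
summary. The test is one-sided because the hypothesis is directional
(over-representation of D/E). Loop columns are an explicit input (mapped
by homology upstream); no automatic loop detection is attempted. Note
that for a perfectly balanced table the one-sided P is the upper tail at
the hypergeometric mean (≈ 0.67 for margins 10/10/10/10), not 1.

## Helix-propensity aggregation and reshuffling P-values

Per-domain propensity tables cover up to 20 positions downstream of the
domain C-terminus; positions past a protein's end contribute propensity
0 (zero-padding), which deliberately pulls the average down for
early-terminating proteins. Domains are partitioned by the residue class
at a chosen alignment column; per-position means use paralog weights,
renormalized over the domains present in the tables (missing domains are
excluded with a warning).

The reshuffling P-value permutes the class labels `n_perm` times and
reports `(1 + #{permuted ≥ observed}) / (1 + n_perm)` (add-one smoothing
keeps P in (0, 1]). The statistic is the weighted difference of class
means of the zero-padded propensity, by default averaged over all 20
positions (a single-position default would be arbitrary; any position
can be selected). Labels are shuffled at the paralog-group level —
whole groups exchange their (majority) labels — so that the permutation
null respects the same redundancy structure as the weighting;
member-level shuffling is available behind a flag.

## Synthetic generators

The generators produce inputs with exactly the statistical structure the
analyses assume, with ground truth returned for recovery tests; all take
an explicit seed, use one private random stream per call, and are
bit-reproducible.

*Trajectory*: a 4-residue peptide (chain P, residues −7…−4) and
3-residue loop (chain L, residues 331–333) carrying only the atoms the
detectors need. Three monitored contacts — ionic −7:331 and −7:332, and
the hydrogen bond −4:331 — are switched by moving loop-side atoms
between "formed" (3.0 Å carbon minimum / 2.8 Å collinear D–A) and
"broken" (≥ 8 Å) placements, each with ≥ 2 Å margin to its cutoff so the
default 0.1 Å jitter essentially never flips a detector. Contact states
follow a known Markov chain; frames are the state template plus i.i.d.
Gaussian jitter. Two presets: `three_state_spec` (modes 110/001/100
exchanging directly at stay-probability 0.98 — for population and
transition-matrix recovery) and `default_trajectory_spec`, where the
modes exchange only through a ~2%-populated contact-free "000" gateway.
The gateway encodes the physical fact that metastable modes are not
direct neighbors in microstate space — switches pass through transition
states — and is what makes the three modes separate basins under
gradient clustering; with direct mode–mode edges a single basin is the
correct output. The stay probability 0.98 at 1 ps/frame gives ~100-frame
dwell times, a desk-scale stand-in for the tens-of-ns interconversion
regime.

*Alignment*: gapless planted-group families. Background composition
puts 11.6% total probability on D/E (the family-wide level) split
evenly, the rest uniform over the other 18 amino acids; loop columns
multiply the D/E probability by the enrichment factor (default 1.31, the
observed loop/background ratio; planted-effect tests use 2.0). Group
members descend from a common ancestor with i.i.d. re-draws at the
mutation rate (≤ 0.2 enforced so within-group identity stays above the
50% grouping cutoff).

*Propensity tables*: clipped-Gaussian per-position propensities around
class means (defaults 0.5 for ILV, 0.25 for ALA — a two-fold planted
ratio), with a configurable fraction of domains truncated early to
exercise the zero-padding rule.

What the generators do **not** emulate: force-field energetics, real
side-chain geometry, water-mediated contacts, correlated jitter,
alignment gaps, or realistic substitution matrices. Passing tests
demonstrate that the statistical machinery recovers known structure
under its own assumptions, not that those assumptions hold for any
particular real system.

## Problem sizes and tolerances

Stochastic recovery tests compare against closed-form chain statistics
within 3 standard errors, using an effective sample size
n·(1−λ₂)/(1+λ₂) (λ₂ = second eigenvalue of the chain) for
autocorrelated quantities and the conditional transition counts (which
are i.i.d. given the source state) for transition frequencies. The
acceptance runs use 10⁵ frames for chain recovery, 10⁴ frames for the
Gaussian-jitter RMSF closed form (σ√3 within 2%, using 50 residues so
the 6 fit-absorbed degrees of freedom bias the result by < 0.7%),
exhaustive enumeration of all 162,315 2×2 tables with margins ≤ 30 for
the Fisher check, and 200 null datasets for the permutation-uniformity
KS test at α = 0.01. Oracle-agreement checks (detectors, gradient
clustering) are exact by construction and compared for equality.

## Known limitations

- No PBC handling; no binary trajectory formats (text PDB/XYZ only).
- Leader clustering is O(F × leaders) with a per-pair Kabsch fit; fine
  up to ~10⁵ frames and a handful of leaders, slow for fragmented
  conformational spaces.
- The Fisher table pools residues across columns and sequences; cells
  are treated as independent draws, which ignores within-column
  phylogenetic correlation beyond what paralog grouping removes (the
  weighted frequencies, not the P-value, carry the redundancy
  correction).
- No kinetic modelling beyond raw transition counts: no lag-time
  analysis, no implied timescales, no reversibility enforcement.
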