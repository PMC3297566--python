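# pdznet

Post-processing toolkit for molecular-dynamics trajectories of
PDZ-domain/peptide complexes, plus paralog-weighted sequence statistics
over the PDZ family.

PDZ domains bind the C-terminal tails of partner proteins in a shallow
groove, but peptide ligands also make transient electrostatic contacts
with the β2–β3 loop next to the groove. Those contacts are individually
weak and interconvert on nanosecond timescales, so the interesting
observables are statistical: how often each contact is formed, which
combinations of contacts form metastable *binding modes*, how the loop's
backbone flexibility responds to perturbations, and whether the loop's
amino-acid composition is biased toward negative residues across the
whole human PDZ family. `pdznet` computes all four from saved trajectory
snapshots and alignments.

## What it computes

**Contacts.** A hydrogen bond is formed when the donor–acceptor distance
satisfies d(D,A) ≤ 3.6 Å and the angle at the donor between D→H and D→A
is ≤ 30° (configurable). A salt bridge is formed when the two last
side-chain carbons before the charged atoms of the partners approach to
< 5 Å. Occupancy is the fraction of frames a contact (or the OR of a
set) is formed.

**Microstates and networks.** Each frame gets a code combining one
binary digit per monitored contact with a peptide-conformation cluster
id from single-pass leader clustering of the ligand backbone (C, CA, N;
2 Å RMSD cutoff after Kabsch superposition). Microstates are the nodes
of a conformation-space network (CSN) whose directed edges count
transitions between consecutive frames. Gradient clustering — steepest
ascent on node population over the CSN neighbor graph — partitions the
nodes into basins of attraction around local population maxima: the
metastable binding modes. A coarse-grained network reports mode
populations and total inter-mode transition probabilities.

**Flexibility.** Per-residue backbone RMSF over C, CA, N within
consecutive non-overlapping time windows, superposed onto the window
mean; profiles are averaged over windows and runs, and signed
RMSF-difference curves compare variants. Short windows are blind to slow
motions, so scanning the window length separates fast from slow
flexibility.

**Family sequence statistics.** Sequences at ≥ 50% pairwise identity are
grouped (single linkage) and each member of a group of size *g* weighs
1/*g*, removing phylogenetic redundancy: a group of 5 paralogs
contributes 1/5 each. On top of the weighting: positional residue-class
frequencies, a one-sided Fisher exact test for D/E over-representation
in loop columns, aggregation of per-domain helix-propensity tables for
up to 20 residues downstream of the domain C-terminus (zero-padded past
a protein's end), and permutation (reshuffling) P-values with labels
shuffled at the paralog-group level.

Because no trajectories or curated alignments are distributed,
`pdznet.synthetic` generates seeded stand-ins with known ground truth: a
toy peptide+loop system whose contacts follow a known Markov chain with
Gaussian coordinate jitter, alignments with planted paralog groups and
planted loop enrichment, and propensity tables with planted class means.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/02_microstate_network.py` prints:

```
CSN: 4 microstates, 49999 transitions
  microstate 110|0    population  44.4%
  microstate 100|0    population  27.1%
  microstate 001|0    population  26.6%
  microstate 000|0    population   1.9%

3 metastable binding modes (gradient clustering):
  mode 110 (+000): population  46.3%, attractor 110|0
  mode 100: population  27.1%, attractor 100|0
  mode 001: population  26.6%, attractor 001|0

inter-mode transition probabilities (count / total transitions):
  001|0 -> 110|0: 0.52%
  100|0 -> 110|0: 0.56%
  110|0 -> 001|0: 0.52%
  110|0 -> 100|0: 0.56%
```

Reading: a code like `110|0` means contacts −7:331 and −7:332 formed,
−4:331 broken, peptide conformation cluster 0. The three planted contact
patterns come out as separate basins because they exchange through the
short-lived `000` state, and the recovered mode populations (44/27/27%)
match the generator chain's stationary distribution (42/28/28%) to
sampling accuracy.

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
pdznet simulate --out sim --seed 3 --n-frames 20000
pdznet run --config config.yaml --stages contacts,microstates,network,rmsf,seqstats
```

`run` executes stages in dependency order into an output directory and
writes `manifest.json` with parameters and SHA-256 checksums of every
output; re-running with the same config and seed reproduces all outputs
byte-identically. Exit codes: 0 success, 2 validation failure, 3 missing
upstream dependency. Outputs are plain TSV/JSON plus GraphML for the
networks.

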