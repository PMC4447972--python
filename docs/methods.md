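# Methods

This note documents the models, criteria, numerical choices and known
limitations behind `mdain`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Interaction definition

Two residues interact in a frame if either channel fires:

**Contact channel.** Heavy atoms *u* ∈ residue *a*, *v* ∈ residue *b* are in
contact when d(u,v) < r(u) + r(v) + margin, with a strict inequality at the
threshold. The margin defaults to 0.6 Å. Radii come from a Bondi-style
heavy-atom table (C 1.70, N 1.55, O 1.52, S 1.80 Å …) shipped as an
editable YAML file (`data/vdw_radii.yaml`); elements missing from the table
fall back to 1.70 Å. Because results depend on this table, it is data, not
code. Same-chain pairs separated by ≤ 4 positions are excluded from this
channel: nearest-neighbour packing is insensitive to conformational change.
With orthorhombic periodic boxes, minimum-image distances are used; raw
distances otherwise.

**Polar channel.** Donor/acceptor typing per residue comes from
`data/hbond_templates.yaml` (backbone N–H donor and carbonyl O acceptor for
all standard residues except proline's N, plus side-chain groups).
When hydrogens are present the criteria are HBPLUS-style: D–A ≤ 3.9 Å,
H–A ≤ 2.5 Å, D–H–A ≥ 90°. Structures stripped of hydrogens (typical for
analysis-ready MD frames) use a heavy-only fallback of D–A ≤ 3.5 Å. No
sequence-separation exclusion applies — this channel exists precisely to
catch changes in short-range polar interactions such as backbone hydrogen
bonds. One targeted exclusion is applied in both modes: the amide N of
residue *i*+1 versus the carbonyl O of residue *i* (1–3 across the peptide
bond, ~2.25 Å apart covalently) is never counted as a hydrogen bond.
Residues without a template are skipped with a warning. Waters and ions are
retained in frames (observables need them) but excluded from residue-pair
analysis.

## Frequencies and the differential test

Frames are strided to 240 ps, the analysis time resolution, and masked by an
equilibration criterion. Frequency of a pair = fraction of masked-in frames
in which it interacts; per-replica values are retained, and the condition
frequency is the frame-weighted mean. Pairs never observed are implicit
zeros.

Two conditions are compared per pair on H0: Δf = 0.

- `replica_t` (default; requires ≥ 2 replicas per condition): Welch's
  unequal-variance t-test on replica-level frequencies. Treating replicas as
  the independent units is deliberately conservative and robust to
  within-replica frame autocorrelation. Degenerate case: when both sides
  have zero replica variance, p = 1 if the means agree, 0 otherwise.
- `block_bootstrap` (fallback for single-replica conditions): circular
  block bootstrap of the per-frame presence series (default block length 20
  frames ≈ 4.8 ns at the default stride), two-sided p from the centred
  bootstrap distribution of Δf.

q-values are Benjamini–Hochberg over all tested pairs; edges with q ≤ α
(default 0.05) are reported with sign. The Monte-Carlo suite checks both
calibration (family-wise false-report rate on autocorrelated nulls with
Markov persistence 0.9) and power (a planted Δp = 0.5 pair). Whether the
original analysis protocol controlled multiplicity is not reconstructable;
FDR control is this package's choice.

A separate screening filter (`minmax_range_filter`) retains pairs whose
frequency range across ≥ 2 conditions is ≥ 0.3 (inclusive threshold),
optionally restricted to pairs with any atom within 3 Å of anchor residues
(e.g. the intracellular-gate triad Arg5/Tyr268/Asp369) in any supplied
frame.

## Equilibration masking

The upstream study states only that consistent criteria identified
equilibrated segments; the rule here is therefore a documented stand-in,
not a reconstruction. Default `rmsd_plateau`: per replica, compute the Cα
RMSD of every frame to the mean structure of the final 10% of frames
(Kabsch superposition); the plateau starts at the earliest frame from which
the remaining RMSD series stays within a 1.0 Å band. A plateau shorter than
the reference tail (and never shorter than 2 frames) does not count; a
replica with no plateau is flagged entirely unequilibrated with a logged
warning. `fixed_discard` and explicit frame ranges are available as
overrides.

## Subsegment scheme and networks

The packaged LeuT scheme (`data/leut_subsegments.yaml`) has 44 named entries
— each TM helix split into extracellular (e), middle (m), intracellular (i)
sections, plus loops and the N terminus — exactly partitioning residues
1–515; `validate_scheme` checks gaps, overlaps, range and contiguity.
Coarse-graining maps each significant residue pair to its subsegment pair;
edge sign is `increased` if all member pairs are more frequent in the
investigated condition, `decreased` if all less, `mixed` otherwise. Pairs
falling within one subsegment form flagged self-edges (kept, not dropped).
Intersection keeps edges present in both networks regardless of sign, with
members tagged by source condition. Functional-site pseudo-vertices are
configuration-defined and off by default — their exact membership is not
enumerable from the source material. Layout (three horizontal bands by
region) is presentational metadata only. Exports: lossless JSON, GraphML,
DOT.

## Observables

- **Region water counts:** number of water oxygens inside a convex hull of
  lining-residue heavy atoms (Delaunay membership; boundary points count as
  inside — the region is closed) or an explicit cylinder. No default region
  ships: absolute counts depend entirely on the region definition, so a
  `RegionSpec` must be given explicitly.
- **Cation states:** Na1 for d < 8.3 Å, transition for 8.3 ≤ d < 10.7 Å,
  Na1′ for d ≥ 10.7 Å, where d is the distance between the mobile cation
  near the Na1/Na1′ sites and the cation fixed in Na2. The source figure
  legend gives overlapping bounds (transition "<10.7", Na1′ ">10.5"); a
  single 10.7 Å boundary is used so the states partition [0, ∞).
- **χ1 rotamers:** signed N–CA–CB–γ dihedral on the branch (−180°, 180°]
  with −180° mapped to +180°; gauche− on [−120°, 0°), gauche+ on [0°, 120°),
  trans otherwise (the standard convention; the bin edges are this
  package's choice). Glycine/alanine raise a typed "undefined" signal.
- **Conditional occupancy:** pool frames across ensembles, keep the top
  fraction (default 20%) by an openness scalar (e.g. EV water count), drop
  transition frames, report #Na1 / #Na1′ with both counts; infinite ratio
  is reported explicitly when no Na1′ frames remain.

## Umbrella sampling and WHAM

Windows carry a center, harmonic force constant k (bias ½k(z−c)²), and a
sample series; `make_windows(−1.5, 25.0, 0.25)` reproduces the 107-window
reference grid, and `discard_equilibration` drops the first 500 ps of a 2 ns
window by default. The WHAM solver iterates the standard self-consistent
equations over binned samples until the maximum change in window free-energy
shifts falls below 1e-7 kcal/mol (max 10⁵ iterations). Numerical choices:

- bin width 0.05 Å (5 bins per 0.25 Å window spacing), with bin edges
  anchored on a global lattice of the bin width so that subsets of the data
  (blocks, bootstrap draws) histogram onto identical grids;
- temperature default 310 K (k_B = 0.0019872041 kcal mol⁻¹ K⁻¹);
- profiles aligned min-zero by default (the upstream reference convention
  is unstated; a bulk-referenced alignment can be applied by the caller);
- a non-overlap diagnostic (`check_overlap`) flags windows whose histograms
  share no bin with any other window, which leaves fragment offsets
  undetermined.

Errors: each window's series is cut into n contiguous blocks (default 3;
7 supported), WHAM is solved per block, block profiles are aligned by their
count-weighted mean over commonly defined bins — weighting by histogram
counts keeps barely sampled edge bins from dominating the additive constant
— and the standard error across blocks is attached per grid point. Errors
are undefined (NaN) where not all blocks sampled. A Monte-Carlo bootstrap
over blocks is available as an option. The flat-bottom cylindrical
restraint (r = 15 Å) is carried as metadata; no standard-state volume
correction is applied.

## Synthetic generators

- **Toy structures:** ideal backbones built by internal-coordinate (NeRF)
  chain construction; helix torsions φ = −57°, ψ = −47° give i/i+4 N···O
  distances of ~3.08 Å (detectable under the heavy-only polar criterion),
  extended torsions φ = −135°, ψ = 135° give none. Atoms N, CA, C, O, CB;
  no hydrogens.
- **Planted ensembles:** per-frame pair states follow two-state Markov
  chains with stationary probability p and lag-1 autocorrelation equal to
  the persistence parameter. Geometric realization uses single-carbon
  residue beads on a 25 Å grid with pair partners placed at 3.5 Å ("on",
  0.5 Å inside the 4.0 Å carbon-carbon contact threshold) or 4.5 Å ("off",
  0.5 Å outside), so detection is unambiguous. Each residue joins at most
  one planted pair and planted pairs must be > 4 apart in sequence.
  `simulate_frequency_tables` draws the same chains directly into frequency
  tables, bypassing geometry — statistically identical input to the
  differential test at a fraction of the cost, used for the Monte-Carlo
  calibration studies (200 null simulations, 100 power simulations; sizes
  chosen to keep the suite fast while leaving the Monte-Carlo bands tight).
- **Umbrella samples:** exact draws from the biased Boltzmann density —
  closed-form Gaussian for quadratic potentials, dense numerical
  inverse-CDF otherwise. No MD is emulated.
- **Cation traces:** class-center distances (7.0 / 9.5 / 12.5 Å) plus
  Gaussian noise; a warning fires when 3σ crosses the nearest class
  boundary (1.2 Å).

What these fixtures do *not* emulate: real conformational kinetics,
correlated motions of neighbouring pairs, force-field energetics, or actual
LeuT geometry. Passing tests therefore demonstrate correctness of the
detection, statistics and unbiasing machinery under known ground truth, not
biological fidelity.

## Limitations

- The heavy-only polar criterion is a geometric proxy; protonation states
  and bifurcated bonds are not modelled.
- The equilibration plateau rule is a documented stand-in (see above).
- Non-orthorhombic periodic cells fall back to raw distances.
- WHAM is 1-D only; no MBAR generalization, no 2-D profiles.
- Salt-bridge/cation-π interactions receive no special typing: the
  interaction definition is purely geometric.
- The extracellular-vestibule region must be supplied explicitly; absolute
  water counts are region-spec-dependent by construction.
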