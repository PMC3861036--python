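# Methods

This note records the models, conventions and numerical choices behind
`ureamd`, and what its synthetic validation does and does not establish.

## Scope and data model

The package analyses topology + coordinate trajectories of a protein in a
water/urea box. The in-memory model is deliberately small: a
`MolecularSystem` (atoms with element, residue, chain, and classification
flags) plus a `Trajectory` (frames × atoms × 3 in Å, times in ns, optional
orthorhombic box). File I/O goes through MDAnalysis readers/writers
(multi-model PDB, DCD, XTC). Boxes are orthorhombic with the minimum-image
convention; truncated-octahedron cells must be re-wrapped upstream. Distances
without a box are Euclidean. "Heavy atom" means any non-hydrogen, ions
included. Indices are 0-based internally; PDB serials stay 1-based on output.

Residue classification is table-driven and configurable. Defaults:
hydrophobic {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, GLY, CYS}, polar
{SER, THR, ASN, GLN, TYR, HIS}, charged {ASP, GLU, LYS, ARG} — a standard
Kyte–Doolittle-style grouping with HIS polar at neutral pH; water
{HOH, WAT, TIP3, SPC, SOL}, urea {URE, UREA}, common ions. Unknown residue
names are an error, never a silent guess, because a misclassified solvent
corrupts every shell statistic downstream. Ions are excluded from solvent
shell statistics by default (a flag includes them).

## Structure metrics

**Superposition/RMSD.** Kabsch via SVD with the determinant correction, so
the rotation is always proper. Two points are accepted as the degenerate
minimum (the optimal RMSD is still well defined; the rotation is not unique).

**SASA.** Shrake–Rupley on heavy atoms only, with hydrogens absorbed into
heavy-atom radii (Bondi: C 1.70, N 1.55, O 1.52, S 1.80 Å; configurable),
probe 1.4 Å, 960 deterministic golden-spiral sphere points. At 960 points a
lone sphere is exact to ≪1% and random small systems agree with a
4000-point evaluation within 2%. The polar/apolar split is by residue class
(polar + charged vs hydrophobic), not per-atom chemistry. The normalized
variant divides by the mean of a water-condition reference series.

**TM-score.** d₀ = 1.24(L−15)^⅓ − 1.8 (hence L ≥ 16). The superposition is
Kabsch on all CA; with `refine=True` the superposition is recomputed
iteratively on the residues currently closer than max(d₀, 3 Å), keeping the
best score found. This simple iterate-on-close-pairs heuristic is a lower
bound of the exhaustive TM-align optimum; since both traces come from the
same trajectory no sequence alignment is needed. `refine=True` never returns
less than `refine=False`.

**Secondary structure.** A simplified three-state Kabsch–Sander assignment:
backbone H-bond when E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
< −0.5 kcal/mol, with the amide hydrogen reconstructed 1.01 Å from N on the
bisector opposite C(prev) and CA when absent from the file. Helix (H):
residues covered by two consecutive i→i+4 turns; strand (E): residues in
parallel/antiparallel bridge ladders of length ≥ 2 (Kabsch–Sander bridge
rules); everything else coil (C). 3₁₀/π helices fold into H and turns/bends
into C, because only a three-state content is reported downstream. Residues
with missing backbone atoms are labelled C with a warning. Different DSSP
implementations disagree by a few percent at helix/strand termini; users
comparing against another assigner should expect small content shifts.

**S2 and the structure index.** S2 is the fraction of natively H/E residues
that keep their native label (1 when the native has no H/E residues, with a
warning). The global structure index is (S2+S3)/2 by default; an `s3_only`
mode is provided because the combination rule is a modelling choice, and
results should be labelled with the mode used.

## Contact kinetics

A residue–residue contact exists in a frame when at least one heavy-atom
pair across the two residues is closer than 3.5 Å (strict inequality,
exact distances — a k-d tree only prunes candidates). Pairs with |i−j| < 3
are excluded by default: nearest neighbours are trivially always in contact
and would dilute S3; the separation and the cutoff (e.g. a 4.5 Å variant)
are prominent configuration entries, not constants. Native contacts keep
pairs with reference occupancy strictly above 0.80 ("more than 80%").

Opening statistics are maximal runs of absent frames per native contact
(duration = run length × dt; mean 0 when never open). The two-condition
shift classification counts a contact for a condition when its mean opening
time exceeds the other's by strictly more than 0.1 ns. Per-residue lost time
averages, over the native contacts a residue participates in, either the
absolute broken fraction (default — native occupancy is ≥ 0.8 by
construction, so the absolute and reference-relative views nearly coincide)
or the reference-excess variant 100·max(0, occ_ref − occ_now)/occ_ref.
Cross-condition correlation is a Pearson r with the two-sided t-test
p-value.

## Solvation

Shell membership is per solvent molecule through its nearest heavy-atom
distance to the protein: first solvation shell (FSS) ≤ 5 Å, bulk > 6 Å, the
5–6 Å band an intermediate region excluded from both. Ratios are
molecule-count based (atom-wise counting is available as an option). Two
water/urea ratio estimators are reported: the mean of per-frame ratios (with
its sd, frames with zero urea excluded and counted) and the pooled ratio of
summed counts. The per-frame mean carries a small-count Jensen bias of order
ratio/E[n_urea] per frame (~+4% at 25 urea per shell), which the pooled
estimator avoids; validation uses the pooled form.

CC_UW divides the time-averaged count of protein-heavy/urea-heavy atom pairs
below 3.5 Å by the same count against water, per group (residue, polarity
class, backbone/side chain, or core/non-core). It is reported raw; an
optional normalization by the bulk urea:water heavy-atom ratio supports
cross-concentration comparison. Core flags can be set by the caller or
derived from relative side-chain accessibility in the native frame.

Residence events are maximal runs of frames in which one solvent molecule
keeps ≥ 1 heavy-atom contact with the target (default: whole protein), with
an optional gap tolerance that merges runs separated by at most g frames.
The long-residence report ranks urea molecules by their longest event and
exports per-molecule (residue, frame) dot maps.

The nonbonded decomposition is a direct-sum cutoff evaluation (default 9 Å):
Coulomb 332.0636·qᵢqⱼ/r and Lennard-Jones with Lorentz–Berthelot mixing, no
Ewald and no long-range correction. It is a per-molecule diagnostic of
relative energies, not a simulation-grade energy; parameters are a plain
per-atom table (charge, σ, ε).

## Hydrogen bonds

Geometric criterion: donor–acceptor heavy distance ≤ 3.50 Å and
donor–H–acceptor angle ≥ 120° (bonds more linear than 120° accepted). Tools
differ on whether such a cutoff means D–H–A or H–D–A; the convention is a
switch (`angle_convention`), with D–H–A the default and documented
prominently. Donors are N/O atoms with at least one attached hydrogen
(attachment resolved geometrically within the residue, < 1.25 Å); protein
backbone N without an explicit H gets the reconstructed amide hydrogen.
Acceptors are all N/O; sulfur is excluded by default. Occupancy retains
bonds whose total detected time strictly exceeds 0.5 ns; partitions report
urea vs water shares, donor vs acceptor per species, and the
backbone/side-chain split of the protein partner.

## Dynamics and transport

RMSF is computed about the mean structure after two-pass superposition
(align to the first frame, re-align to the mean); per-residue values are
mass-unweighted means over heavy atoms. Pseudo-B-factors use
B = (8π²/3)·RMSF². The side-chain stiffness comparison superposes both
trajectories on the backbone and counts residues whose side-chain RMSF is
strictly smaller in condition a. Time-lag RMSD averages RMSD(t, t+τ) over
all window starts, the first frame of each window being the reference.

MSD uses molecule centers over all overlapping time origins (an
independent-origin mode exists for error estimation); unwrapping accumulates
minimum-image displacements and errors out if any molecule moves more than
half a box per frame. The Einstein coefficient is slope/6 of a least-squares
line over a fraction interval of the maximum lag (default 10–50%), with
slope, intercept and R² always reported so fit-range sensitivity is visible.
The default window avoids the ballistic start and the sparse-origin tail; in
validation the lag list is kept within the first fifth of the trajectory,
where time origins are dense — at 100 molecules × 10³ frames this recovers
a prescribed D within a few percent.

## The synthetic generator

The generator produces data for testing analysis code; the unfolding is
scripted (kinematic) and the solvent is a jump/diffusion process — it is not
an MD engine and must not be used as one.

*Toy proteins* are built from ideal internal coordinates (NeRF chain
construction; helix φ=−57°, ψ=−47°; strands φ=−139°, ψ=135°). The hairpin's
second strand is a rigid copy placed by least squares so the mutual
N–H···O=C pairs sit at 2.9 Å with aligned amide hydrogens; the 4-residue
turn is an interpolated connector and is expected to assign as coil.

*Telegraph contacts* are disjoint residue pairs on a bead protein whose
distance switches between 3.0 Å (closed) and 9.0 Å (open) following a
two-state Markov chain with per-frame transition probabilities
1−exp(−k·dt). Discretization biases the mean open duration upward by about
dt/2, so rates should satisfy k·dt ≲ 0.05 for percent-level recovery.

*Solvent* molecules are rigid pseudo-molecules: water one heavy atom (plus
2 H), urea four heavy atoms placed nearly coincident. The point-like
heavy-atom footprint is deliberate: molecule-level shell boundaries stay
sharp, so a box generated with no urea preference measures identical FSS and
bulk ratios up to counting noise (the null calibration), while atom-count
statistics still see 4 urea atoms vs 1 water atom. Brownian steps are
per-axis N(0, √(2·D·dt)); in full-system scenarios walls are reflective so
solvent stays in the box (minimum-image analyses then see no aliased
images), while free unwrapped walks are used for diffusion studies.

*Sticky urea* is a jump process: on entering the capture zone (default 5 Å,
first-shell entry) a molecule is, with probability p (default 1), tethered
2.8 Å from the nearest target atom with ±0.2 Å clipped jitter — guaranteeing
a 3.5 Å contact every tethered frame — until an exponential escape at rate
k_off, after which it is placed at a validated release point with > 4.2 Å
clearance from every protein atom, so the escape frame is contact-free and
each ground-truth event maps to exactly one measured residence event. With
capture probability 1 the event logs agree exactly; with p < 1 brief
uncaptured contacts can add short measured events not in the log.

*First-shell enrichment* (snapshot-resampling mode) places n_urea molecules
uniformly in the protein-excluded volume plus (f−1)·n_urea·V_shell/V_free
extra molecules uniformly in the shell, the volume ratio estimated once by
Monte Carlo; the expected bulk ratio is then exactly n_water/n_urea and the
FSS ratio n_water/(f·n_urea). Solvent placements respect a 1.5 Å
solvent–solvent spacing; an overfull box errors.

*Hydrogen-bond fixtures* are constructed geometries straddling the cutoffs,
including an exactly-boundary case built on the accepted side of the
criterion.

**What passing tests show — and don't.** Recovery of scripted rates,
diffusion constants, enrichment factors and stiffness ratios demonstrates
that the measurement code is correct under the stated definitions. Real
trajectories add everything the generator omits: correlated protein and
solvent motion, rotational diffusion, finite-size and wrapping artifacts,
protonation ambiguity, non-exponential residence kinetics, and force-field
dependence. Agreement on synthetic data therefore validates the analysis,
not any physical claim about urea.

## Pipeline and reporting

`run_pipeline` drives the battery from one YAML config (topology, condition
trajectory, native/water reference trajectory, analysis list, parameter
overrides), writes per-frame CSVs, and summarizes each metric as mean ± sd
over the last 10 ns (configurable window). Summaries contain no timestamps
and are byte-identical across re-runs; every summary number is re-derivable
from the CSVs. Cross-protein aggregation groups per-protein summaries by
user-supplied fold labels (a convenience PDB-code → fold-group table for 30
reference folds ships with the package; group labels are user input) and
reports mean, sd and n per group, with condition-minus-water deltas.

## Validation problem sizes

The shipped validation uses desk-scale problem sizes chosen so sampling
error sits well inside each tolerance: 40 telegraph contacts × 150 ns at
dt = 0.05 ns (S3 mean sd ≈ 0.007 against a ±0.02 band; ~3×10³ opening
events), 15 contacts × 200 ns at dt = 0.02 ns for the shift classification
(same-rate noise ≈ 0.005 ns against the 0.1 ns threshold; scripted margin
0.4 ns), 900 water/150 urea snapshots × 150 frames for shell ratios, 100
sticky urea × 150 ns (≥ 500 events), 100 Brownian molecules × 10³ frames
for diffusion, and 100 seeds × n = 1000 for the correlation calibration.

## Known limitations

Orthorhombic boxes only; no Ewald electrostatics; the TM-score refinement is
a heuristic lower bound; the SS assigner is three-state and simplified; the
hairpin builder's turn geometry is schematic; solvent pseudo-molecules have
no internal dynamics or rotation; SASA ignores explicit hydrogens by design;
the pipeline assumes one protein per system.
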