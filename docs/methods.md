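# Methods

## Scope and model

`riboscan` analyzes the secondary-structure energy landscapes a nascent RNA
passes through during transcription. The analysis layer (landscape assembly,
clustering, barrier estimation, window segmentation, control inference) is
agnostic to the folding substrate: it consumes Boltzmann samples and
energies from any backend. Two backends ship with the package.

### Built-in folding engine

A deliberately reduced nearest-neighbor model over nested structures:

* **Stacks.** Adjacent pairs (i, j)/(i+1, j−1) contribute
  ΔG(T) = ΔH − TΔS from a table over the six canonical pairs
  (AU/UA/CG/GC/GU/UG). The YAML parameter file lists one entry per symmetry
  orbit as (ΔG37, ΔH); ΔS = (ΔH − ΔG37)/310.15 K. Magnitudes are plausible
  for RNA (pure GC stacks ≈ −3.3 kcal/mol at 37 °C, AU ≈ −1, GU weakest)
  but this is not an experimental parameter set, and absolute energies from
  the built-in engine are not comparable to ViennaRNA outputs.
* **Loops.** Hairpin, bulge and interior loops carry temperature-independent
  free-energy penalties tabulated by size, extrapolated beyond the table as
  P(n) = P(n_max) + 1.75·R·310.15·ln(n/n_max) (Jacobson–Stockmayer).
  Multiloops cost a flat 3.4 kcal/mol; there are no dangles, coaxial stacks,
  or per-branch terms. Interior loops are capped at 30 unpaired nt in the
  dynamic programs (the standard restriction).
* **Pseudoknots.** The engine predicts nested structures only; pseudoknot
  prediction is delegated to an external pknotsRG-compatible program. In
  energy evaluation, pseudoknot-layer pairs add a configurable flat per-pair
  term (default 0) and their positions count as unpaired in nested loops —
  the evaluate-the-nested-layer simplification that mirrors the
  strip/record/restore treatment used for structure comparison.

On this substrate the engine computes the exact MFE (Zuker-style DP with an
unambiguous multiloop grammar), the exhaustive suboptimal list (guarded to
≤ 40 nt; the recursion is complete, so it doubles as the reference for the
DP), the partition function (McCaskill analogue of the same grammar — the
energy decompositions are shared code, so enumeration sums and DP agree to
float precision), i.i.d. Boltzmann samples via seeded stochastic
backtracking, and melting curves.

**Co-optimal ties.** The MFE traceback enumerates all co-optimal structures
(tolerance 1e-7, capped at 4096) and returns the lexicographically smallest
dot-bracket string, making results reproducible across platforms.

**Melting temperature.** Tm is the grid temperature maximizing
C(T) = −T·∂²G/∂T² with G(T) = −RT ln Z(T), central differences on a 1 °C
grid over 0–150 °C, reported to the nearest integer °C. Because G is
measured relative to the open chain (energy 0) and loop penalties carry no
explicit temperature dependence, G(T) rises toward 0 with temperature over
the physical range (non-decreasing on 0–100 °C) and becomes slightly
re-entrant above ~110 °C, where every structure's Boltzmann factor tends to
1; the transition peak is far below this artifact for any sequence that
pairs at all.

### External backend

A subprocess adapter with the same Celsius-level surface drives
ViennaRNA-style executables: `RNAfold` (MFE), `RNAsubopt -p n` (Boltzmann
samples), `RNAeval` (re-evaluation), `RNAheat` (melting curve; maximum of
the printed specific heat), and `pknotsRG -m -s -e 10` for complete
pseudoknot suboptimals within 10 kcal/mol. Output brackets of any dialect
are normalized by the package's greedy layer assignment (first non-crossing
layer is nested). Missing executables raise immediately — there is no
silent fallback. `RNAsubopt` exposes no random seed, so external sampling
is not bit-reproducible run to run.

## Sampling protocol

Per length: 100 structures at 37 °C, then 150 at each of six elevated
temperatures, 1,000 total; every structure's energy is re-evaluated at
37 °C so that structures drawn at different temperatures sit on one
landscape. The elevated schedule is

  T_k = round(T_phys + k·(Tm − T_phys)/9),  k = 1…6.

The divisor 9 (rather than a literal tenth of the interval) is the
convention that reproduces the protocol's defining worked example —
43, 49, 55, 61, 66, 72 °C for Tm = 90 °C — under nearest-integer rounding;
the literal-decile alternative is available as `decile_mode="literal"`.
Duplicate draws are kept with multiplicities at sampling time and collapsed
to unique structures only when the landscape is assembled.

The elongation scan covers ⌈0.64·L⌉ … L in 1-nt steps, 5'-anchored
(transcription order). The 64% start reflects that shorter prefixes hold
only the aptamer and show no two-state behavior; ceiling was chosen for the
start index. Prefixes that cannot pair at all, or whose predicted Tm falls
below 37 °C, are sampled entirely at 37 °C — their landscapes are trivially
single-basin, and the strict schedule preconditions (error on Tm < 37 °C)
still hold for direct calls.

All randomness descends from one top-level seed: per-length sub-seeds via
`SeedSequence(seed, spawn_key=(length,))`, per-stage sub-seeds via
`spawn_key=(stage,)`, each reduced mod 2³¹. Identical configuration and
seed give byte-identical reports with the built-in backend.

## Landscape, clustering, barrier

* **Distance.** Base-pair distance = |nested(a) Δ nested(b)|, a metric.
  Pseudoknot pairs are counted per structure, removed before comparison and
  restored afterwards; they never enter the distance.
* **Reference.** The distance axis is anchored at the lowest-energy unique
  structure of the length's sample (ties by lexicographic dot-bracket).
  Uniqueness is keyed on the nested pair set, so exactly one point sits at
  d = 0; each unique point keeps its lowest-energy representative and
  multiplicity.
* **Clustering.** PAM k = 2 on the unweighted unique-structure distance
  matrix (duplicates have zero mutual distance and would inflate the
  silhouette; a multiplicity-weighted variant is available). BUILD seeds
  greedily, SWAP applies best-improvement single exchanges (monotone
  descent) and finishes with a vectorized scan of all medoid pairs — single
  swaps can strand k = 2 in a local optimum that only a double swap
  escapes, and the pair scan is cheap at k = 2, so the returned cost is
  always the exhaustive two-medoid optimum. The silhouette is the standard
  s = (b − a)/max(a, b) ∈ [−1, 1] with singletons contributing 0; two
  significant clusters require mean SC ≥ 0.4 (inclusive).
* **Envelope and barrier.** The envelope is the per-bin (1 bp bins; the
  distance is integral) minimum energy. Basin minima are the two clusters'
  lowest-energy points; the saddle is the envelope maximum over bins
  strictly between them, linearly interpolating unoccupied interior bins.
  A barrier exists only when the saddle rises above *both* minima —
  otherwise the shallower minimum is a shoulder on a monotone slope, not a
  separated state, and the barrier is 0. When present, the barrier is the
  climb out of the deeper basin (saddle − min of the two minima), a
  worst-case reading; it is invariant under uniform energy shifts.

## Classification, windows, control

Label per length (total in its inputs, thresholds configurable):

* SC < 0.4 or a single basin → **funnel** (the significance gate removes
  two-state labels entirely);
* barrier < 5 kcal/mol → **funnel**;
* barrier > 10 kcal/mol → **cluster**;
* 5 ≤ barrier ≤ 10 (closed band, forced by the strict outer inequalities)
  **and** basin minima within 2.0 kcal/mol **and** funnel-shaped vicinity
  around both minima → **barrier-limited**; failing either extra criterion
  → funnel.

"Funnel-shaped vicinity" means the envelope is non-increasing toward the
basin minimum over the 3 nearest occupied bins on each side (configurable).

Windows are maximal runs of ≥ 5 consecutive lengths with one label —
strictly consecutive, a single interrupting length breaks the run (no
smoothing; a 1-length tolerance exists but defaults off). Barrier-limited
runs are sensing windows, funnel runs downhill-folding windows; cluster
runs become functional windows only when the two cluster medoids match
*different* user-declared motifs (terminator / antiterminator / anti-SD
helices as dot-bracket pair sets, ≥ 80% pair coverage each, and neither
medoid matching the other's motif) at every length of the run. Opposition
requires declared motifs because recognizing functional elements otherwise
needs curated literature structures.

Control: a sensing window whose last length is the full length ⇒
thermodynamic control; sensing windows only before full length ⇒ kinetic;
no sensing window ⇒ ambiguous. The full-length rule is the one stated
operational criterion; "early relative to the aptamer boundary" would need
an aptamer annotation the pipeline does not require.

## Synthetic generators

* **Bistable designs** P·L1·Q·L2·P with Q = revcomp(P): Q pairs upstream or
  downstream, mutually exclusively, and because the two helices are one
  duplex read in opposite directions their stack sums are identical under
  any orientation-symmetric table — with equal loops the two states are
  exactly degenerate. Stems are GC-biased (default 0.8) so the planted
  hairpins dominate desk-scale ensembles; loops are A-runs. These designs
  emulate the two-state expression-platform landscapes, not real riboswitch
  sequence composition, aptamer tertiary contacts, ligand binding, or
  transcriptional pausing — so passing tests demonstrate the pipeline's
  mechanics and statistics, not biological accuracy on natural sequences.
  Across seeds, full-length 5-bp designs always show two significant
  clusters (SC 0.41–0.68) separated by a positive barrier, but the barrier
  height varies with stem composition (≈3–8 kcal/mol), so the specific
  label can be funnel rather than barrier-limited for AU-diluted stems.
* **Planted landscapes** bypass folding entirely: points realize a
  prescribed two-basin envelope (reference basin fixed at d = 0 so the
  reference invariant holds; one on-envelope point per bin, extra points
  scattered strictly above), with the planted partition, saddle bin and
  barrier returned as ground truth. Dissimilarities are |d_i − d_j|.
* **Planted label series** realize arbitrary B/F/C patterns with their
  implied true windows for segmentation tests.

## Numerical choices and limitations

* Gas constant 0.0019872 kcal/mol/K; 37 °C = 310.15 K; minimum hairpin
  loop 3 nt enforced at the type level (every pair satisfies j − i ≥ 4).
* Exhaustive enumeration is guarded to 40 nt; the built-in engine is meant
  for designed toys and protocol validation, not genomic riboswitches —
  full-scale runs go through the external backend.
* Problem sizes in the shipped tests and the acceptance script (23-nt
  bistable designs, 9-length scans, 1,000-structure ensembles, 10-seed
  replicates) were chosen so the complete suite exercises every stage,
  including ten full protocol runs, in well under a minute on one core.
* The pipeline models no ligand, no pause sites, and no tertiary structure;
  window calls on natural sequences inherit every limitation of secondary-
  structure thermodynamics and of sampling at elevated temperatures.
* pk_pair_count is recorded per structure and reported in landscape TSVs
  but feeds no downstream quantity.
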