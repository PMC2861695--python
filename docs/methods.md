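# Methods

This note records the models, algorithms, parameter choices and known
limitations of `polyqmd`, in enough detail to judge what a passing test
suite does and does not establish.

## Chain model and force field

Each residue contributes three beads (N, Cα, C), so a chain of n residues
is a linear sequence of 3n beads. All interactions are stepwise in the pair
distance, which is what makes event-driven dynamics exact:

- **Bonds** (consecutive beads): hard walls at d ± 0.03 Å with
  d ∈ {1.46 (N–Cα), 1.53 (Cα–C), 1.33 (C–N)} Å.
- **Pseudo-angles** (beads i, i+2): hard walls at d₁₃ ± 0.10 Å, where d₁₃
  follows from the bond lengths and standard backbone angles
  (111°, 116°, 121.7°), giving 2.43–2.47 Å. The ±0.10 Å window corresponds
  to roughly ±5° of angular freedom.
- **Nonbonded** (chain separation ≥ 3 beads): a 2.0 Å hard core plus one
  attractive square well out to 4.5 Å, depth 1.5 kcal/mol between
  glutamine Cα beads and 0.1 kcal/mol otherwise.

The same geometric constants drive the internal-coordinate backbone
builder, so conformations constructed with prescribed φ/ψ satisfy the
engine's constraints exactly and dihedral round-trips are exact to
numerical precision.

The well depths are deliberately minimal physics: they are tuned only so
that a short polyQ chain shows a clear coil–globule collapse *inside* the
replica ladder (mean R_g at T = 0.5 below that at T = 0.85, stable across
seeds), because a collapse transition within the sampled temperature range
is what exercises every downstream stage (heat-capacity peak, compact
ensemble, clustering). They are not fitted to any experimental observable,
and no quantitative structural propensity derived from them should be read
as a statement about real huntingtin. Electrostatics, hydrogen bonding,
side chains and solvation are absent by design.

Masses default to 1 (the acceptance surface is mass-independent; unit
masses make velocity scales uniform in tests); united-atom masses
(15/13/28 amu) are available via `ForceField(uniform_mass=False)`.

## Event-driven dynamics

Beads carry per-bead last-update times and move ballistically between
events. For a pair with relative position r and velocity v, the next
boundary crossing is the smallest positive root of |r + vt|² = d², with the
currently occupied potential shell of every pair tracked explicitly (an
int8 matrix) so that which-side-of-the-boundary decisions never depend on
floating-point rounding of a distance that is exactly *at* a boundary.
Collisions exchange an impulse along the separation unit vector:
crossing an energy step ΔU transmits with v_r′ = sign(v_r)√(v_r² − 2ΔU/μ)
when the radial kinetic energy suffices, otherwise reflects (hard walls
always reflect). This conserves linear momentum exactly, angular momentum
about the pair midpoint exactly (central impulse), and total energy to
floating-point accuracy (measured drift ~10⁻¹³ relative over 10⁵
collisions).

Event selection uses a per-bead earliest-event table with an O(N) argmin
rather than a priority queue: every velocity change (collision or
thermostat) recomputes the earliest event of the affected beads and of any
bead whose stored event referenced them, so the table never contains stale
entries. For the chain sizes this package targets (≤ ~350 beads) the O(N)
scan is faster and considerably easier to verify than heap bookkeeping;
the event loop is JIT-compiled with numba (~10⁶ events/s/core).

Periodic boundaries use the minimum-image convention in all pair
computations. Because a straight-line relative trajectory is only valid
until a component of the minimum image crosses ±L/2, each pair's
prediction is capped by a "horizon" event that merely triggers
recomputation. Positions are stored unwrapped (bonded neighbours move
continuously, so the chain never fragments across images), which makes
radius-of-gyration and dihedral computations image-free. The box edge is
1.2× the fully extended contour length (floor of 3 well widths), large
enough to hold the starting conformation with margin.

The Andersen thermostat redraws one uniformly chosen bead's velocity from
the Maxwell–Boltzmann distribution at T at exponentially distributed
intervals, with a default rate of 1 ghost collision per bead per tu —
strong enough that equipartition (⟨KE⟩/dof = T/2) holds to within
statistical error over a few hundred tu, weak enough that collision
dynamics dominate between ghost events. Runs start from the fully
extended conformation (φ = ψ = 180°) with Maxwell–Boltzmann velocities and
zero total momentum; the first 500 tu are flagged as equilibration and
excluded from analysis by default (configurable).

Units: energies kcal/mol, temperature kcal/mol/k_B (1 unit = 503.22 K,
≈500 K), lengths Å, time units of 50 fs (500 tu ≈ 25 ps, 10⁶ tu ≈ 50 ns).

## Replica exchange

Defaults: 8 replicas at
{0.85, 0.75, 0.68, 0.64, 0.6, 0.57, 0.53, 0.5}, swap attempts every 500 tu,
10⁶ tu per replica, one saved frame per 10 tu per replica (8 × 10⁵ frames
in total). Two choices this protocol does not itself determine are fixed as
follows and exposed as configuration: (1) at each swap epoch, *all* adjacent ladder
pairs of one parity are attempted, alternating parity between epochs —
this improves temperature-space mixing over a single random pair and keeps
the attempt schedule deterministic; (2) a swap exchanges *temperatures*
(with velocity rescaling by √(T_new/T_old)), not coordinates, so each
replica is one continuous dynamical trajectory and frames are labelled
with the temperature at which they were recorded. The acceptance rule
min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]) uses potential energies, the
correct criterion when kinetic energy is rescaled on exchange.

## WHAM

Per-temperature energy histograms on a shared grid (Freedman–Diaconis
width on the pooled samples by default; the width is a nuisance parameter
and can be set explicitly) are combined by iterating

    Ω(E) = Σ_k h_k(E) / Σ_k N_k exp(f_k − E/T_k)
    exp(−f_k) = Σ_E Ω(E) exp(−E/T_k)

entirely in log space (log-sum-exp), gauge f₁ = 0, from f_k = 0, until
max|Δf_k| < 10⁻⁷ (max 10⁵ iterations; non-convergence and non-overlapping
histograms raise). Bins with zero pooled counts are excluded — log Ω is
undefined there — so the recovered density of states covers exactly the
sampled energy range. C_V(T) = (⟨E²⟩ − ⟨E⟩²)/T² uses normalised Boltzmann
weights, again via log-sum-exp, and is clipped at zero against rounding.

The transition is the grid argmax refined by a quadratic through the three
surrounding points (ties → lowest temperature; no interior maximum → an
explicit no-peak result). The "non-cooperative" flag marks broad, shallow
peaks: a peak whose half-height width exceeds its own temperature
(FWHM/T_peak > 1, configurable) is non-cooperative. This width criterion
replaces a peak-prominence rule considered first: the prominence of a
curve's *global* maximum is by construction essentially the full curve
range, so a prominence threshold can never distinguish sharp from broad
single-peak curves. Calibration anchors: an ideal two-level system with
degeneracy 1 has FWHM/T_peak ≈ 1.7 (broad), with degeneracy 50 ≈ 0.8
(sharp). The flag is meaningful only when the temperature grid brackets
the peak well beyond its half-height points.

Kelvin conversion uses 503.22 K per unit; the rounded 500 K/unit
convention is also provided (`temperature_to_kelvin(..., rounded=True)`).

## Compact-ensemble screening

The analyses of structure operate on the compact, low-energy
sub-ensemble. "Determined from a histogram" under-specifies a cutoff, so
the package declares reproducible rules and logs the values used (manual
overrides are first-class):

- **R_g cutoff**: pooled R_g histogram at 1 Å bins; the cutoff is the left
  edge of the first bin above the modal bin whose count drops below 10% of
  the modal count. On a unimodal distribution peaked near 16 Å with
  σ ≈ 1.2 Å this lands at 19–21 Å, consistent with the 20 Å worked
  instance.
- **Energy cutoff**: a 2-component Gaussian mixture on the pooled energies;
  cutoff = μ_low + 2σ_low of the lower component. If the fitted mixture has
  no density dip between its component means (an effectively unimodal
  sample — e.g. a tiny homopolymer with one energy basin), the fit is
  degenerate and the lowest-decile value is used instead, with a warning.
- Membership is inclusive: R_g ≤ r* **and** E ≤ E* (a frame exactly at a
  cutoff is compact).

The number of times the energy series crosses E* (entries *and* exits
counted; samples exactly at the cutoff attach to the preceding sign) is
the effective number of independent events n; probabilities over the
compact ensemble carry binomial errors √(p(1−p)/n). Crossings are counted
per replica on the equilibrated series and summed — pooling replicas into
one concatenated series would create spurious crossings at the seams.

## Secondary structure

φ(i) = torsion C(i−1)–N(i)–Cα(i)–C(i), ψ(i) = N(i)–Cα(i)–C(i)–N(i+1),
IUPAC sign convention (validated against an independent implementation).
Terminal residues lack one angle and are excluded from profiles and region
averages (denominators adjusted). Classification uses rectangular basins,
declared here because no standard boundary set exists:

| class | φ (deg) | ψ (deg) |
|---|---|---|
| α | [−100, −30] | [−80, −5] |
| β | [−180, −45] | [90, 180] ∪ (−180, −160] |
| turn (left-handed) | [30, 100] | [−20, 80] |
| PPII (optional) | [−90, −55] | [120, 170] |
| coil | everything else | |

The four-class scheme (PPII off) is the default; enabling PPII carves its
rectangle out of the β basin, so β(off) = β(on) + PPII(on) pointwise.
The rectangles partition the torus (verified by grid scan); the exact
boundary values shift absolute probabilities and any comparison across
boundary sets is invalid — reported profiles are meaningful relative to
the same basin definitions only.

## Clustering

Structures for clustering are drawn from the compact ensemble by greedy
earliest-first subsampling with a ≥50 ps (1000 tu) gap per replica, then
uniformly thinned to a target count (default ≤2000). Pairwise distances
are Cα-bead RMSDs after optimal superposition (Kabsch via batched SVD,
proper rotations only — reflections are excluded, and superposition is
used at all because free simulation frames have arbitrary orientation).
Single-linkage clusters at cutoff c are computed as connected components
of the graph with edges RMSD < c, which is exactly the agglomerative
definition; defaults are 2.0 Å, with 2.5 Å for the XN1Q47-ΔpolyP model.
Cluster order (size desc, then smallest member index) and centroid ties
(lowest index) are deterministic. The centroid minimises the summed
distance to its cluster; the largest cluster's centroid is the model's
representative, reported with the fraction |largest|/n. The
cutoff–cluster-count curve's knee (max distance to the endpoint chord in
the normalised plane) gives a data-driven cutoff suggestion.

## Synthetic data

Every analysis stage is testable without simulation through generators
that return machine-readable ground truth: ideal-dihedral backbones
(α: −57/−47, β: −120/130, PPII: −75/145, coil: uniform) with optional
Gaussian coordinate noise; symmetric telegraph energy series with recorded
true switch counts; i.i.d. Boltzmann-weighted energy draws from a
prescribed discrete density of states at any temperature set; and noisy
copies of template structures with true labels. All generators are
bit-reproducible under a fixed seed. What they deliberately do *not*
emulate: correlated dynamics (telegraph samples are Markovian per step,
simulation energies are autocorrelated), force-field realism, or finite
exchange acceptance — so a passing analysis suite certifies the
*estimators*, not the physics of any particular force field.

## Problem sizes and determinism

The shipped tests and the acceptance script run desk-scale versions of the
protocol: 4–8 residue polyQ chains, 2–3 replicas, 10³–10⁴ tu, ~10⁵
synthetic samples per replica for WHAM recovery, clustering oracles up to
n = 200 — sizes chosen so the whole suite completes in a few minutes while
still crossing every threshold the correctness arguments need (≥10⁴
collisions for conservation, ≥10³ oracle cases, bootstrap bands at 10⁵
samples). The full protocol (8 replicas × 10⁶ tu per model) runs through
the same code paths via `RunConfig` defaults; only wall-clock time
separates the two. All randomness flows from explicit integer seeds
through `numpy` SeedSequences; identical configuration + seed reproduces
byte-identical reports.

## Known limitations

- The force field is a caricature; nothing quantitative about huntingtin
  misfolding should be inferred from its outputs. β-strand content in
  particular is not expected to match all-atom results.
- The engine is single-chain; no aggregation, no inter-chain terms.
- WHAM bins are a nuisance parameter; very sparse histograms (≪10³
  samples per replica) give ragged Ω(E) tails.
- The equilibration discard (500 tu default) is a fixed-time rule, not an
  equilibration test; long chains at low temperature may need more.
- `subsample_frames` thins by time gap only; it does not decorrelate by
  any structural criterion.
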