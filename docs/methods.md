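# Methods

This note records the models behind each analysis, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.
Units everywhere: Å, ps, degrees, kcal/mol.

## The synthetic world

The generators replace excited-state surface-hopping and ground-state MD
engines.  Their defaults *are* the reference conditions of the study the
pipeline targets; they were fixed before any acceptance run and are not
tuning knobs.

**Surface-hopping preset `agp2-sh`.**  n = 3028 trajectories; S1→S0 hop
times drawn from a fast/slow exponential mixture with τ_fast = 0.71 ps
and τ_slow = 4.25 ps, truncated below the 20 ps censoring cutoff;
exactly round(61/3028 · n) = 61 trajectories form an explicitly censored
long-lived subpopulation.  The reported survivor count is a realized
count in a single reference ensemble, so the generator reproduces it
exactly rather than as a Bernoulli expectation.  Two quantities are not
printed anywhere and are package choices: the conditional fast-component
weight (0.6 — sub-picosecond decay dominates an ultrafast-decaying
ensemble) and the per-hopped-trajectory reaction probability
(0.28 · 3028/2967, so that the *expected overall* yield over all 3028
trajectories, censored members counting as non-reactive, equals 28%).

**Chromophore model.**  A six-atom chain realizes the C–D bridge
dihedrals D4/D5/D6 exactly by natural-extension (NeRF) placement; the
D-ring N and carbonyl O ride with the ring, residue probes (His278_NE2,
Tyr165_OH, Gln190_NE2, Trp440_CZ2, Asp196_OD1, water oxygens) are placed
at configured distances along fixed directions.  D1–D3 travel as scalar
frame channels — nothing downstream reads them atomically.  The model
carries no hydrogens, so H-bond detection uses the distance criterion
only (the D–H···A angle applies when hydrogens are modeled).

**Hula-twist kinematics.**  Reactive members ramp D6 from 180° (E)
through 90° — crossing placed exactly at the hop time — to 0° (Z) over
1 ps, with D5 counter-rotating cw by 60° (160° → 220°).  For hops
earlier than the ramp half-width the pre-hop leg steepens so the
crossing stays at the hop and remains observable from the first frame.
Non-reactive members dip D6 to ~130° and return.  Frame noise is 2°
(σ), small against the 45°/frame ramp slope, so crossings stay monotone.
The rotation-sense convention is fixed by the package: **ccw ≡ negative
change of the signed dihedral**, viewed from the C-ring side.  Only
internal consistency of this convention is meaningful; the absolute
handedness of the original trajectories is not testable from printed
material.

**Relaxation preset `lumi-f-63`** (seed 42).  63 members starting at the
Lumi-F entry geometry (D6 ≈ 0, D5 ≈ 220° unwrapped): 20 end in the Pr
window (D5 = 260° ± 12°, i.e. −100° wrapped) with the D-ring carbonyl
approaching His278 or Tyr165 to 2.8 Å (50/50 split); 41 end between the
windows (D5 ∈ 205–228°); 2 end near-planar (D5 = 180° ± 8°, D4 → 0°).
Final frames realize their windows noise-free so the partition is exact
by construction; the classification test is therefore a consistency
loop, not a statistical one.

**Pocket preset `pocket-3`.**  Three Gaussian blobs (σ = 0.25 Å) in the
8-dimensional distance space spanned by D-ring N/O to Asp196, Gln190,
His278, Tyr165, Trp440 and the nearest water — a Gln190-coordinated
pocket, an Asp196+water pocket, and a looser His/Tyr-proximal pocket.
Centers are separated by ≫ 3σ so generative labels are recoverable;
config validation enforces this.

**Lifetime–pocket coupling.**  Slow-component and censored trajectories
carry the Asp196+water pocket, fast ones the Gln190-coordinated pocket.
This is the qualitative lifetime-stratification structure (strong
D-ring-NH–Asp196 plus water on the carbonyl ↔ long lifetimes); it makes
`stratify_lifetimes` meaningfully testable but is binary, not a learned
relationship.

**What the generators do not emulate.**  No forces, energies, solvent,
or real coordinates; dihedral ramps are piecewise-linear, not dynamical;
probe directions are fixed; no Lumi-F BV–Pr ↔ BV–Pr′ interconversion
dynamics.  A green test establishes that the *analysis* recovers the
stated statistical structure — not that the structure is what a real
ensemble would produce.

## Decay kinetics

`fit_exponential_mixture` maximizes the right-censored mixture
likelihood (log-parametrized lifetimes, softmax weights) by L-BFGS-B
with analytic gradients, 8 quantile-spaced jittered starts (fixed seed),
components reported sorted ascending.  k = 1 without plateau uses the
closed form τ = (total time at risk)/(events).  AIC with 2k − 1 (+1 with
plateau) parameters selects k; AIC rather than BIC because the component
count is small and the choice is documented rather than claimed.
Lifetimes are 1/e decay constants of the components.

**The long-lived plateau option.**  A 2% censored subpopulation at 20 ps
is incompatible with any two-exponential mixture at τ ≤ 4.25 ps (whose
maximum censored mass is e^(−20/4.25) ≈ 0.9%): the plain censored MLE
buys censored-mass likelihood by inflating τ_slow to ≈ 6.2 ps (46%
error).  With `long_lived=True` the survival is
S(t) = p + (1 − p)·Σ a_j e^(−t/τ_j) — the correct model for a distinct
never-decaying-on-window subpopulation — and both lifetimes are
recovered within ~10%.  The preset analyses and the acceptance script
use the plateau; the plain spec-form likelihood remains the default and
is the one checked against the grid-search oracle.

Quantum yield: point = n_reactive/n_total over all trajectories
(censored = non-reactive), 95% Wilson score interval (statsmodels),
clamped to [0, 1] against float slop at the boundaries.

## Pocket analysis

Columns are z-scored before PCA (distance columns span different
magnitudes; pass `standardize=False` for centering only).  Components
covering ≥ 90% cumulative variance are kept; Ward linkage
(scipy) is cut at k = 3 by default — k is fixed, with silhouette
diagnostics reported, rather than selected automatically.  Cluster
labels are renumbered by first occurrence, so they are deterministic and
permutation-equivariant.  Ward is greedy: its cut equals the exhaustive
bipartition optimum on separated data but can exceed it on arbitrary
points (the brute-force value is a lower bound; the tests document
both).  Group lifetime summaries use Kaplan–Meier medians (lifelines),
with ∞ for all-censored groups.

## State classification

Windows (wrapped degrees): D6 Pr (Z) window |D6| < 90; D5 Pr window
−100° ± 30° (the synthetic Pr reference); D5 intermediate window
(−170°, −130°); planarity = within 20° of 0° or 180° on D4/D5/D6.
Order: BV_PR (both Pr windows + carbonyl H-bond to His278/Tyr165), then
BV_PR_DPRIME (planar **and** D6 in the Z window — planarity alone would
also match the planar E-configured Pfr resting state, so the taxonomy is
gated on the isomerization having happened), then BV_PR_PRIME (D6 in Z,
D5 intermediate), else PFR.  All windows are config
(`mechanism.StateWindows`); the underlying taxonomy is qualitative and
these defaults make it operational.

The Meta-F signature is an overlay, not a replacement, for the dihedral
label: (i) carbonyl–His278 H-bond, (ii) Gln190 displaced > 4 Å from its
reference (its position in the trajectory's starting Pfr frame), (iii)
Trp440–Gln190 distance > 6 Å (gate open); score = satisfied/3.  The 4 Å
and 6 Å thresholds are declared package choices — no numeric
displacement is printed for the real system.

H-bonds: donor–acceptor ≤ 3.5 Å, D–H···A ≥ 120° when hydrogens exist —
the standard geometric MD-analysis definition.  Detection uses a k-d
tree; the tests hold it equal to an exhaustive double loop.

Spine tilt: principal axis of each CA cloud by SVD; angle folded to
[0°, 90°]; ideal helices are built with 1.5 Å rise, 100°/residue,
2.3 Å radius, 18 residues (≈ 5 full turns, so the finite-length axis
bias is ≪ 0.5°).

## Proton-transfer model

**Surface.**  Tilted quartic U(x̄) = h(x̄² − 1)² + (c/2)(x̄ + 1) in
x̄ = (x − center)/half_width, calibrated by nested Brent solves so the
realized enol−keto minimum difference equals `delta_e` and the realized
forward barrier equals `barrier` to < 1e−9; the keto minimum is the
energy zero.  Exactly two minima are guaranteed (stationary points are
the roots of a cubic); infeasible (delta_e, barrier) pairs raise with
the minimum realizable barrier (≈ 33.1 kcal/mol at delta_e = 27).
Defaults: delta_e = 27, barrier = 36 (a ~9 kcal/mol back-barrier — the
barrier is a model choice, only the 27 is a reference value),
half_width = 1.5 Å (minima near ∓1.5 Å, the physical scale of
d(N−H) − d(O−H)).  Per-well stiffness is derived (≈ 91 and 54
kcal·mol⁻¹·Å⁻² at the defaults), not an input: independent stiffnesses
cannot coexist with exact ΔU and exactly-two-minima guarantees in a
smooth closed form.

**Dynamics.**  Overdamped Euler–Maruyama,
x ← x − (dt/ζ)·U′ + √(2 kT dt/ζ)·ξ, with ζ the drag coefficient in
kcal·mol⁻¹·ps·Å⁻² (default 5, giving D = kT/ζ ≈ 0.12 Å²/ps at 300 K;
this unit reading keeps the dt = 1 fs default stable, which an
inertial "5 ps⁻¹" with proton mass would not).  Forces come from a
2201-point grid with linear interpolation; a step larger than a tenth of
the domain, or leaving the domain, raises with a suggested smaller dt.
Deterministic given the seed.

**Adaptive bias.**  Well-tempered kernel deposition every 500 steps:
height h₀·exp(−V(x)/((γ−1)kT)) with h₀ = 1 kcal/mol, bandwidth 0.05 Å,
γ = 15 (γ → ∞ recovers non-tempered metadynamics).  γ = 15 rather than
a lower factor because the well-tempered cap (1 − 1/γ)·barrier must
leave a thermally crossable residual barrier: at barrier 36 and γ = 10
the ~3.6 kcal/mol ≈ 6 kT residual blocks escape on feasible runs, at
γ = 15 the ~2.4 kcal/mol ≈ 4 kT residual does not.  ΔF is read as
−γ/(γ−1) times the basin bias difference **time-averaged over the
second half of the deposition history** (the instantaneous profile
oscillates around the converged one); a reweighted basin-integral
estimate (weights e^{V/kT}, basins split at the barrier top) is reported
as a cross-check together with the discrepancy.  An error is raised if
the bias never reached both basins.  At the defaults, 4·10⁶ steps
(≈ 10 s) give |ΔF − 27| ≤ 0.8 and agreement with the quadrature oracle
within 0.6 kcal/mol across seeds.  The quadrature oracle integrates
e^(−U/kT) per basin; with near-equal well stiffnesses its entropy
correction to the 27 kcal/mol gap is ≈ 0.16 kcal/mol.

## Numerical conventions

Dihedrals: IUPAC sign, atan2 form, range (−180°, 180°], collinear
triples raise; unwrapping adds 360° multiples for minimal successive
differences (precondition: true per-step change < 180°).  Stereo letters
tie to E/a at exactly ±90°.  Isomerization events are crossings of
unwrapped D6 through the ±90° + 180°k family, located by linear
interpolation; senses are net changes over ±1 ps around the crossing
(shorter than τ_fast, long enough to see the 60° partner rotation);
hula-twist pairing requires opposite senses and ≥ 30° partner rotation.
All random draws flow through `numpy.random.default_rng(seed)`; every
generator, fit, and sampler is a pure function of (config, seed).
Reports serialize with sorted keys so identical runs are byte-identical.

## Known limitations

* The bond-class mapping of D1–D6 (which are double bonds) is config,
  defaulting to D2/D4/D6 double — the graphical definition admits
  alternatives.
* The classifier windows are calibrated to the synthetic world's
  reference angles; applying them to real trajectories would require
  re-centering the D5 windows.
* The plateau mixture treats survivors as never decaying; a third
  finite-lifetime component is distinguishable only with much longer
  censoring windows.
* The 1-D proton-transfer model tests the estimator chain (CV, bias,
  ΔF), not the chemistry; its barrier and friction are model choices.
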