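# phytotraj

Trajectory-ensemble analysis for the photoactivation of bathy
bacteriophytochromes — the phytochromes (such as *Agrobacterium*
Agp2) whose resting state is the far-red-absorbing Pfr form.  Their
biliverdin (BV) chromophore switches from the ZZEssa (Pfr) to the
ZZZssa (Pr) stereochemistry by photoisomerization of the C–D
methine-bridge double bond, and the ensemble-level questions are:

* **Mechanism** — does the D-ring rotate by a *hula twist*, i.e. a
  counterclockwise (ccw) rotation of the bridge double-bond dihedral D6
  with a concomitant clockwise (cw) rotation of the adjacent single-bond
  dihedral D5?
* **Kinetics** — what are the S1 excited-state lifetimes (a fast and a
  slow exponential component, with a long-lived censored subpopulation)
  and the photoisomerization quantum yield Φ = n_reactive / n_total?
* **Heterogeneity** — how do binding-pocket arrangements (D-ring
  distances to Asp196, Gln190, His278, Tyr165, waters) cluster, and how
  do they stratify the excited-state lifetimes?
* **Photoproduct taxonomy** — after the hop, which relaxation members
  reach the Pr-like D5 value with an H-bond to His278/Tyr165 (BV–Pr),
  which stall between Pr and Pfr (BV–Pr′), which become planar (BV–Pr″),
  and which pockets show the Meta-F-like signature (His278-bonded
  carbonyl, displaced Gln190, open Trp440 gate)?
* **Excited-state proton transfer** — is the keto→enol proton transfer
  along x = d(N–H) − d(O–H) competitive?  A 1-D model surface with the
  keto/enol gap ΔE = 27 kcal/mol, sampled by overdamped Langevin
  dynamics under a well-tempered adaptive bias, answers no: the
  transfer is uphill by ≈ 45 kT at 300 K.

The electronic-structure and force-field engines behind the original
ensembles are not desk-reproducible, so the package ships a first-class
**synthetic generator** (`phytotraj.synth`) that emits ensembles with
exactly the statistical structure the analyses assume — biexponential
hop times with 61/3028 censored survivors at 20 ps, hula-twist
kinematics on reactive members, a 20/41/2 relaxation partition, three
pocket clusters, helix pairs at controlled tilt — and every analysis is
validated by recovering the generating values or by independent
brute-force oracles.

## Core statistics

The S1 decay is fit by maximum likelihood of a right-censored
exponential mixture,

    log L = Σ_unc log Σ_j (a_j/τ_j) e^(−t_i/τ_j)
          + Σ_cens log Σ_j a_j e^(−c_i/τ_j),

optionally with a long-lived plateau component
S(t) = p + (1 − p) Σ_j a_j e^(−t/τ_j) for ensembles whose censored mass
exceeds what a finite mixture can carry.  The yield is reported with a
95% Wilson score interval.  Pocket features are z-scored, projected on
the principal components covering ≥ 90% variance, and cut at k = 3 with
Ward's minimum-variance linkage.  The free-energy difference of the
proton-transfer model is read from the converged well-tempered bias,
ΔF = −γ/(γ−1)·ΔV̄ (time-averaged over the deposition tail), with a
reweighted-histogram cross-check and a direct quadrature oracle
−kT ln(Z_enol/Z_keto).

## Worked example

```python
from phytotraj import synth, kinetics

cfg = synth.get_preset("agp2-sh", seed=1)      # n=3028, censor 20 ps
ens = synth.generate_sh_ensemble(cfg, trajectories=False)

y = kinetics.quantum_yield(ens.hop_records)
fit = kinetics.fit_exponential_mixture(ens.hop_records, k=2, long_lived=True)
print(f"yield {100*y.point:.1f}%  [{100*y.ci_low:.1f}, {100*y.ci_high:.1f}]")
print(f"lifetimes {fit.lifetimes[0]:.2f} / {fit.lifetimes[1]:.2f} ps, "
      f"censored {fit.n_censored}")
```

prints

```
yield 27.6%  [26.0, 29.2]
lifetimes 0.74 / 3.92 ps, censored 61
```

i.e. the estimator recovers the generating 28% reaction probability
(inside its Wilson interval), the 0.71 ps / 4.25 ps lifetimes within a
few percent, and the 61 censored survivors exactly.  The same analyses
are available from the shell:

```bash
phytotraj simulate-ensemble --preset agp2-sh --seed 1 --out ens
phytotraj fit-kinetics ens/hop_records.csv --out kinetics.json
phytotraj run-all --seed 1 --out results       # all stages incl. opes-pt
```

## Acceptance script

`scripts/acceptance.py` regenerates the preset ensembles from scratch at
the given seed and recomputes the headline numbers — the quantum yield
(%), the fast and slow fitted lifetimes (ps), the 20 ps survivor count,
and the BV–Pr count of the 63-member relaxation fixture — writing them
as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module      | contents |
|-------------|----------|
| `io`        | extended-XYZ trajectories, hop-record CSV, minimal PDB, JSON reports |
| `synth`     | ensemble generators and presets (`agp2-sh`, `lumi-f-63`, `pocket-3`) |
| `geometry`  | signed dihedrals, unwrapping, Z/E–s/a stereo codes, hula-twist events |
| `kinetics`  | Kaplan–Meier survival, `CensoredExponentialMixture`, Wilson yield, AIC |
| `pocket`    | distance features, `PocketClusterer` (PCA + Ward), lifetime strata |
| `mechanism` | H-bonds, water bridges, BV–Pr/′/″ classifier, Meta-F signature, spine tilt |
| `ptmodel`   | calibrated double-well surface, Langevin integrator, adaptive bias, ΔF |
| `pipeline`/`cli` | staged runs and the `phytotraj` command |

Model choices, parameter defaults, and the limits of what the synthetic
world can establish are documented in `docs/methods.md`.
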