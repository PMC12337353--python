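# panlv

Stochastic Lotka–Volterra dynamics of bacteria–phage coevolution with
horizontal gene transfer (HGT) over combinatorial toxin/antitoxin
genotypes, plus the ensemble theory used to analyze it.

Bacterial and phage genotypes are unordered sets of `g ∈ {2, 3}` genes
from a pool of `L` toxin/antitoxin pairs (`K = C(L, g)` genotypes). Each
matched pair follows antisymmetric predator–prey dynamics with tau-leaped
demographic noise; three HGT channels (bacteria→bacteria,
bacteria→phage, phage→phage) move single individuals between genotypes;
a regulator holds the total population sizes fixed. Depending on the
per-capita transfer rate `r` the community falls into one of three
regimes: unstable coexistence with gene loss (I), gene persistence with
continuous genotype turnover through boom-bust cycles (II), or stable
endemic coexistence (III). The `theory` module carries the closed-form
predictions — Gamma abundance distributions with effective temperatures
`Θ = 1/(2r)` (genotypes) and `θ` up to `2/r` (genes), critical rates
`r_cg ~ L/N` and `r_cG ~ K/N`, diversity carrying capacities
`L_max, K_max ~ rN`, and the inter-bacteria boundary `r_B > L/N_B` —
and the `experiments` module measures them from simulation (scans,
bisection of regime boundaries, temperature sweeps).

## Layout

| module | contents |
| --- | --- |
| `panlv.genotype_space` | gene pools, genotype enumeration, HGT products, interaction matrices |
| `panlv.stochastic_dynamics` | `SimParams`, per-step operations, the `run` simulator, `TrajectoryRecord` |
| `panlv.observables` | Lyapunov energy, persistence times, Gamma fits, regime labels, boom peaks |
| `panlv.theory` | closed-form predictions (`predict`, `critical_hgt_rates`, …) |
| `panlv.experiments` | `scan`, `find_boundary`, `temperature_sweep` |
| `panlv.cli` | the `panlv` command line |

## Library quick start

```python
import panlv

space = panlv.build_space(L=10, g=2)                  # K = 45 genotypes
params = panlv.SimParams(NB_target=10_000, r=2e-3, T=20_000, seed=1)
traj = panlv.run(params, space)

label = panlv.classify_regime(traj)                   # I / II / III
samples = panlv.sample_abundances(traj)
fit = panlv.fit_gamma(samples.genotype_B)             # effective temperature
pred = panlv.predict(L=10, K=45, N=10_000, r=2e-3, regime=label.label)
```

## CLI

All simulation commands read a flat YAML config whose keys mirror
`SimParams` plus `L`, `g`, and the `interaction_*` keys; unknown keys are
rejected. Example `config.yaml`:

```yaml
L: 10
NB_target: 10000
r: 2.0e-3
T: 20000
seed: 1
```

```bash
panlv simulate --config config.yaml --out out/          # trajectory TSVs + meta.json
panlv classify --input out/                             # regime label as JSON
panlv fit-gamma --input out/trajectory.tsv --column genotype
panlv peaks --input out/ --threshold-multiple 5
panlv theory --L 40 --N 1e6 --r 1e-3 --regime III
panlv scan --config config.yaml --param r --values 1e-4,1e-3,1e-2 --replicates 5 --out scan/
panlv find-boundary --config config.yaml --boundary I_II --lo 1e-4 --hi 1e-2
panlv temperature-sweep --config config.yaml --r-values 1e-3,5e-3
```

## Notes on conventions

- Time is in generations (`dt = 1` by default); all rates are per capita
  per generation. Demographic noise carries a baseline turnover of 0.5
  births + 0.5 deaths per individual per generation, so abundance
  variance is ≈ n per generation (Wright–Fisher-like); with phages and
  HGT off the model reduces to neutral drift.
- HGT events that would duplicate a gene are redrawn by default
  (`hgt_collision="resample"`), so `r` counts delivered transfers;
  `"noop"` treats them as lost attempts instead.
- Genotype/gene extinction events are detected at step resolution,
  independent of the snapshot cadence.
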