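# smfe — adsorption free energies from noisy single-molecule data

`smfe` recovers the equilibrium free energy of a molecule adsorbing on a
surface from three independent kinds of measurement, and lets them be
cross-checked against each other:

1. **Single-molecule pulling (AFM force spectroscopy).** Retraction
   force–distance curves are screened automatically for single binding
   events; the external work of each pull feeds estimators of the
   Jarzynski equality.
2. **Adsorption kinetics (SPR coverage traces).** Langmuir fits per analyte
   concentration, then a linear regression of the observed rates, yield
   k_a, k_d, K_D and ΔG = k_BT ln(K_D/c⊖).
3. **Potential-of-mean-force profiles** from biased molecular-dynamics
   sampling, integrated into an adsorption free energy by Boltzmann
   state partitioning.

It is aimed at force-spectroscopy and biointerface labs that own piles of
noisy retraction curves and want reproducible, scriptable free-energy
numbers out of them.

## The statistical core

The Jarzynski equality relates the equilibrium free-energy difference to
the nonequilibrium pulling work W (all energies in units of k_BT):

    e^{-ΔG} = ⟨ e^{-W} ⟩

Three estimators of ΔG from a finite sample {W_i} are provided:

* **Mean estimator** ΔG_MN = −log( (1/N) Σ e^{−W_i} ). Exact in the limit,
  but dominated by the rare smallest work values: with work fluctuations of
  tens of k_BT it fails to converge at any experimentally reachable N.
* **Fluctuation–dissipation estimator** ΔG_FD = ⟨W⟩ − σ²/2. Valid only when
  the work fluctuation is comparable to k_BT; with σ ~ 100 k_BT it returns
  absurd, strongly negative values.
* **Gamma estimator.** When the work follows a gamma law
  ρ(W) = λ^α W^{α−1} e^{−λW}/Γ(α), the exponential average has the exact
  closed form

      ΔG_GA = α · ln( (λ+1)/λ ),

  with (α, λ) obtained by maximum likelihood (profile likelihood in λ and a
  Newton solve of the shape score equation). This stays accurate at a few
  hundred pulls, which is what an experiment actually delivers, and its fit
  quality is testable (Kolmogorov–Smirnov).

Event screening follows five steps per curve: rupture detection from the
windowed-regression derivative of the curve; linear baseline alignment and
noise estimation; binding-minimum detection below −LOD·σ; location of the
bound state A at the zero-force point before the stretch; and a worm-like
chain fit of the stretch segment (persistence length 0.37 nm) whose mean
residual must stay within nlsEr·σ. Accepted curves contribute
W = −∫ F dD_s from A to the rupture.

## Worked example

Everything below is synthetic and seeded, so the numbers reproduce exactly.

```
$ smfe simulate fdc --n 60 --seed 4 --out-dir curves
wrote 60 curves to curves

$ smfe screen --curves curves --out events.json --qc qc.tsv
accepted 21 / 60 curves

$ smfe estimate --events events.json --out report.json
n=21 dg_mean=63.9077 dg_gamma=16.8676 dg_fd=-5424.84
```

The simulated dataset mixes single-event curves (works drawn from
Gamma(α=4.42, λ=0.023), so the true ΔG_GA is 16.77 k_BT) with flat,
double-rupture and drift-only junk curves; the screen keeps only genuine
single events (see `qc.tsv` for the per-curve disposition and failing
step). On the 21 surviving works the gamma estimator lands at 16.87 k_BT —
within 1% of the generating truth — while the mean estimator (63.9) is
biased upward about fourfold by the missing small-work tail, and the
FD value (−5425) is nonphysical because the work fluctuation here is
~100 k_BT, far outside the Gaussian small-fluctuation regime. That
three-way contrast is the package's point.

A screening-parameter scan shows the gamma estimate is also stable against
the screening thresholds:

```
$ printf 'lod: [3.0, 5.5, 9.0]\nmul_base: [2.0, 3.0]\n' > grid.yaml
$ smfe scan --curves curves --grid grid.yaml --out scan.tsv
dg_gamma over 6 cells: 17.7587 +/- 1.38
```

The SPR side of the cross-check:

```
$ smfe simulate kinetics --out-dir spr --seed 2
$ smfe kinetics --traces spr --concentrations spr/concentrations.tsv --out kin.json
K_D = 1.53877e-07 M, dG_ads = -15.6871 kBT
```

and the PMF side:

```
$ smfe simulate pmf --kind square_well --depth 5 --out pmf.tsv
$ smfe pmf --profile pmf.tsv
dg_ads = -4.99801 kBT
```

All of this is equally available as a library (`smfe.screen_dataset`,
`smfe.estimate_all`, `smfe.kinetics_pipeline`, `smfe.dg_ads`, …); the CLI is
a thin wrapper.

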