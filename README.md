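# pgp-transfer

Cell-population dynamics of intercellular P-glycoprotein (P-gp) activity
transfer in breast cancer co-cultures.

P-gp is an ATP-driven efflux pump that exports chemotherapeutics from the
cell; tumours overexpressing it exhibit multidrug resistance.  Beyond genetic
inheritance, functional P-gp can pass *directly from cell to cell*, so
sensitive cells in contact with resistant neighbours can acquire efflux
activity — and drug resistance — extragenetically.  This package implements a
population model of that process for quantitative analysis of
flow-cytometry-style efflux-activity histograms, and uses it to ask what
cell-to-cell transfer does to the outcome of cycled chemotherapy.

It is intended for modellers and quantitative biologists working with
efflux-activity distributions: it generates realistic synthetic list-mode
samples, conditions raw events into normalized logarithmic histograms,
integrates the population model, estimates transfer parameters by least
squares, cross-checks the continuum model against an exact stochastic
simulator, and simulates treatment regimens.

## The model

The population is a density u(t, p) over efflux activity p ∈ [1, 10⁴]
(arbitrary fluorescence units), evolving as

    ∂u/∂t = ρ(p, c(t)) u  +  2τ ( T(û) − û ) U,       û = u / U,  U = ∫ u dp

- **ρ(p, c)** — net growth rate: a Hill sigmoid in activity anchored at the
  measured dose responses (0.63/day drug-free; 0.0316/day at 0.1 µM
  doxorubicin; −0.7492/day at 3 µM for low-activity cells).
- **T** — the pairwise transfer operator: random pairs whose activity
  difference lies strictly inside (δ_min, δ_max) exchange a fraction f = σ of
  the difference, from the higher- to the lower-activity cell.  T(û) is the
  expected post-transfer distribution of a cell involved in one event.
- **τ** — each cell initiates transfer events through an exponential clock of
  rate τ (mean interval 1/τ); including partner selections, each cell
  experiences events at rate 2τ, the factor in the equation.

Estimated transfer law from the MCF-7 / MCF-7-Doxo co-culture experiments
(`default_transfer_params()`): τ = 0.4/day, f = 0.2, δ_min = 10^1.4,
δ_max = 10^1.9 (thresholds applied on the log₁₀ axis; see
`docs/methods.md`).  Sensitive cells are defined as those with negative
growth rate at 1 µM doxorubicin, i.e. activity below p* ≈ 88.8.

## Worked example

Six days of drug-free co-culture from a 50:50 sensitive:resistant seeding of
10⁴ cells:

```python
import pgptransfer as pt

grid = pt.ActivityGrid()                       # 80 log bins over [1, 1e4]
day0 = pt.day0_coculture_template(grid=grid)   # bimodal day-0 density
params = pt.default_transfer_params()          # tau=0.4, f=0.2, delta=10^1.4..10^1.9
gm = pt.GrowthModel()                          # rho(p, c) anchored at measured rates

state0 = pt.ModelState(t=0.0, density=day0, total_cells=1.0e4)
traj = pt.integrate(state0, t_end=6.0, params=params, gm=gm,
                    dt=0.01, snapshot_every=6.0)
day6 = traj.snapshots[-1][1]

mid = (grid.log_midpoints > 1.3) & (grid.log_midpoints < 2.2)
print(f"day-6 population: {traj.total[-1]:.0f} cells")
print(f"intermediate-activity fraction at day 6: {day6.bin_prob[mid].sum():.3f}")
s, r = pt.count_subpopulations(pt.ModelState(6.0, day6, traj.total[-1]), gm)
print(f"sensitive / resistant at day 6 (1 uM criterion): {s:.0f} / {r:.0f}")
```

prints

```
day-6 population: 438160 cells
intermediate-activity fraction at day 6: 0.371
sensitive / resistant at day 6 (1 uM criterion): 264487 / 173673
```

The population grows at the common drug-free rate (10⁴ · e^{0.63·6} ≈
4.4 · 10⁵) while transfers reorganize the activity distribution: 37% of cells
end up at intermediate activities between the two seeded peaks — the third
peak that appears in co-culture cytometry by day 6 — and a share of initially
sensitive cells has crossed the resistance threshold without any drug
exposure.

The same machinery runs from the command line:

```sh
pgp-transfer synth     --out run/       # 10,000 synthetic list-mode events
pgp-transfer condition --out run/       # bin + normalize into densities
pgp-transfer treat     --out run/       # 56-day cycled regimen, transfers on/off
```

Each stage writes its outputs, a log, and a fully resolved config copy for
replay.

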