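# sansfit

Shape modelling of reduced small-angle scattering curves, built for the
solution-shape comparison of cyanobacterial circadian clock proteins and
their reconstructed ancestors — and usable on any reduced 1-D SANS/SAXS
curve (Q, I, σ_I[, σ_Q] ASCII columns).

Hexameric ring proteins such as KaiC form a double ring with a central
channel, a shape no standard scattering model covers.  `sansfit`
implements a bespoke **dumbbell form factor** — two identical coaxial
ellipsoids of revolution (polar semi-axis *a*, equatorial semi-axis
*r_eq*, centers *d* apart) pierced by an axial cylindrical hole of radius
*R_h* — with the orientationally averaged intensity

    I(Q) = scale · ⟨|F(Q, α)|²⟩ / ⟨|F(0)|²⟩ + A_up Q^(−p) + background,

where the reference amplitude is the exact Fourier transform of the
union-minus-hole body (radially analytic, 1-D Gauss–Legendre in z), the
optional power law models the low-Q clustering upturn, and ⟨·⟩ averages
over particle orientation α.  KaiA-like chain/assembly scatterers are
covered by the **polymer excluded-volume model** (Benoit; lower
incomplete gamma functions) with radius of gyration R_g and Porod
exponent m = 1/ν.  Parameters are estimated by **global-best
particle-swarm optimization** of χ² = Σ((I_obs−I_model)/σ_I)² with box
bounds, seeded restarts, and optional Gaussian resolution smearing.
Model-free **Guinier** (R_g) and **Porod** (log–log slope) analyses, and
brute-force **Monte-Carlo / Debye-sum oracles** that validate every model
result, round out the pipeline.  Details: [docs/methods.md](docs/methods.md).

## Worked example

```sh
python examples/fit_dumbbell_curve.py
```

simulates a 100-point, 3%-noise curve from the ancestral-hexamer
(anKaiC) geometry and fits it back by PSO:

```
reduced chi2 = 0.75  (~1 means the fit explains the data at its noise level)
             parameter     true  recovered
       center_distance     53.0      52.90
        polar_semiaxis     35.4      34.71
   equatorial_semiaxis     45.5      45.55
           hole_radius     17.4      17.25
values in Angstrom; recovered geometry should sit within a few percent of the generating one
```

The recovered lobe separation, lobe semi-axes and channel radius sit
within about 2% of the generating values — at 3% noise the dumbbell
geometry is well identified.  The other scripts in `examples/`
cover the polymer model (`fit_polymer_chain.py`), Guinier/Porod analysis
(`guinier_porod_analysis.py`), the Monte-Carlo/Debye oracles
(`oracle_crosscheck.py`) and the extant-vs-ancestral shape report
(`compare_shapes.py`).

The same pipeline is scriptable from the shell:

```sh
sansfit simulate --outdir fixtures --seed 1
sansfit fit fixtures/ankaic.dat --model dumbbell --output fit_ankaic.json
sansfit fit fixtures/kaic.dat   --model dumbbell --output fit_kaic.json
sansfit compare fit_kaic.json fit_ankaic.json --output shapes.json
sansfit analyze fixtures/kaia.dat --output kaia_analysis.json
```

Every command writes a JSON report embedding its resolved configuration
and seed; exit codes are 0 (success), 2 (input error), 3
(convergence/diagnostic failure).

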