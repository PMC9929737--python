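# clampdyn

Desk-scale analysis of an autoinhibitory protein clamp: the intramolecular
interface by which a coiled-coil helix (CC1α1) sequesters the
channel-activating domain (CAD/SOAR) of the ER calcium sensor STIM1 in
resting cells.  Destabilize that clamp and the sensor activates its channel
constitutively; the strength of the clamp is therefore the quantity that
links structure to electrophysiology.

The package implements, as a tested reusable pipeline, the computational
machinery such a study needs:

* **Free energy of domain unbinding** — reconstruction of a well-tempered
  metadynamics free-energy surface over two collective variables
  (interdomain center-of-mass distance and a smooth contact count),
  marginalization to a 1D unbinding profile, and extraction of ΔG_unb with
  replicate statistics (`clampdyn.free_energy`).
* **Metadynamics reweighting** — final-bias, time-dependent (running
  offset c(t)), and balanced-exponential weights, validated by agreement
  between the reweighted-histogram FES and the bias-derived FES
  (`free_energy.reweight`).
* **Per-residue binding scores** — S_i = Σ_j ω_ij, the sum of (reweighted)
  cross-domain contact frequencies, plus pair rankings and the fraction of
  common contacts (FCC) time series (`clampdyn.contact_scoring`).
* **Collective motions** — Kabsch superposition, RMSF, trajectory PCA and
  an anisotropic network model on Cα atoms, with mode-overlap comparison
  (`clampdyn.conformational_dynamics`).
* **smFRET distances** — Förster conversion d = R0·(1/E − 1)^(1/6) with
  R0 = 5.1 nm and a 1 nm linker correction, against model residue-centroid
  distances (`clampdyn.fret_model`).
* **Thermodynamic coupling** — the two-state model
  I0 = c0·(1/(1 + c1·e^{ΔG_unb/RT}))^n relating clamp stability to
  constitutive current density, with ΔG_unb→open = RT·ln c1 and
  cooperativity n fitted by weighted nonlinear least squares
  (`clampdyn.thermo_coupling`).
* **Synthetic ground truth** — every input the pipeline consumes can be
  generated with a planted answer (`clampdyn.synthetic_data`): Langevin
  dynamics under a well-tempered bias on analytic landscapes known by
  quadrature, toy two-domain complexes with planted interfaces and
  detachment schedules, a two-lobe dimer with a planted anti-phase
  "swing-out" mode, and noisy mutant panels drawn from the current model.

Cluster-scale MD of the real protein is out of scope by design; the
synthetic systems exercise every stage at desk scale.  See
`docs/methods.md` for models, assumptions, and numerical choices.

## Worked example

```sh
python examples/01_free_energy_recovery.py
```

```
planted ΔG (quadrature): 3.000 kcal/mol
sampled 100000 CV records, deposited 1999 hills (final height 0.295 kcal/mol — tempering at work)
recovered ΔG_unb from one run: 3.114 kcal/mol
```

A Langevin walker samples an analytic double-well landscape whose bound
basin sits exactly 3 kcal/mol below the unbound plateau (the quadrature
value).  Well-tempered hills (initial height 0.3 kcal/mol, ΔT = 3300 K)
flatten the landscape; summing them back and scaling by −(T+ΔT)/ΔT yields
the free-energy surface, and the plateau-minus-minimum of its distance
marginal recovers the planted 3 kcal/mol to within the single-run noise.
Averaging seven seeded replicates (as `recover_delta_g` does) brings the
mean within ±0.3 kcal/mol, with a standard error of the mean reported
alongside.

The other examples (`examples/02`–`05`) demonstrate binding-score
discrimination of a planted interface (the untouched control residue
scores exactly 0), recovery of a planted anti-phase swing-out mode by both
PCA and the elastic network, the Förster distance table, and the
cooperativity fit (n ≈ 0.49 ± 0.01 recovered from a 13-mutant panel
generated at n = 0.5 with 5% noise).

A thin CLI wraps the same stages:

```sh
clampdyn run --seed 7 --outdir demo_out        # demo pipeline + manifest
clampdyn simulate --preset dimer --outdir out  # synthetic inputs
clampdyn thermo-fit --table out/panel.tsv      # model fit from a TSV
```

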