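# pelletox

Oxygen supply analysis in pellets of filamentous fungi (*Aspergillus
niger* and relatives): from 3D pellet images and microelectrode oxygen
profiles to shell-resolved hyphal fractions, supply metrics, steady-state
reaction–diffusion simulation, and per-pellet estimation of the
oxygen-related biomass yield with AICc model selection.

Submerged fungal cultivations form dense, near-spherical hyphal pellets.
Oxygen reaches the interior by diffusion only, hindered by the hyphal
network, so the productive biomass is confined to an outer shell.
`pelletox` quantifies that shell and connects it to a mechanistic model,
for bioprocess engineers and modellers working on pellet morphology
engineering.

## The model

Radial hyphal fractions ch(r) come from binarized µCT voxel images,
counted in 15 µm shells around a 50 µm central sphere.  Oxygen profiles
(10 µm sensor steps) are aligned with the morphology at the pellet
border — the depth where 95% of the maximum concentration is reached on
the oxygen side, the radius where ch drops to 0.005 on the image side.
The steady oxygen field then follows the spherically symmetric balance

    ∂c/∂t = (1/r²) ∂/∂r [ D_eff(r) r² ∂c/∂r ] − q(c, ch)
    D_eff  = D_bulk (1 − ch)^a
    q      = (ρ_h / Y_X/O₂) · c/(K_XO + c) · µ_max · ch      (growth-only)

with an optional maintenance term.  The model is solved by a
conservative finite-volume method of lines (100 nodes, stiff
integrator), and the yield coefficient Y_X/O₂ is estimated per pellet by
multistart trust-region least squares against the measured profile, with
consumption-law variants ranked by small-sample AICc.  Headline metrics
are the oxygen penetration depth and the active part percentage (APP) —
the share of hyphal volume inside the oxygen-supplied layer.

No measured dataset ships with the package; a seeded synthetic module
(`pelletox.synth`) generates voxel phantoms, shell profiles and noisy
oxygen profiles from the forward model, so the whole pipeline is testable
end to end.

## Worked example

```python
import pelletox as px

# 1. synthesize a strain-typical pellet (hyperbranching preset)
spec, params = px.preset("hyperbranching", seed=7)
shells  = px.gen_radial_hyphal_fraction(spec)
profile = px.gen_oxygen_profile(shells, params, spec)

# 2. align oxygen and morphology at the shared border
aligned = px.align(px.mean_replicate_profile(profile), shells)
metrics = px.supply_metrics(aligned, shells)

# 3. fit the oxygen-related biomass yield
fit = px.fit_parameters(aligned, params,
                        px.FitSpec(("y_xo2",), n_starts=5, seed=1))
```

Printing the results of those three steps gives:

```
border radius      : 455 um
penetration depth  : 108 um
active part        : 71 %
fitted Y_X/O2      : 2.36 kg/kg
MAE of the fit     : 0.033 mg/L
AICc               : -232.0
```

The 455 µm border is recovered exactly from the hyphal-fraction cutoff;
oxygen penetrates 108 µm into this densely rimmed pellet (strain-typical
values span 90–290 µm), which still supplies 71% of the hyphal volume
because the biomass concentrates in the rim.  The fitted yield sits near
the literature value (2.77 kg kg⁻¹) used to generate the data, and the
0.033 mg L⁻¹ MAE is at the sensor-noise level.  Fitting through the
measured-border alignment carries a known low bias of order 10–15% on
sharp synthetic profiles; see `docs/methods.md`.

The same workflow is scriptable from the shell:

```bash
pelletox synth --preset regular --seed 4 --out pellet/
pelletox align --o2 pellet/oxygen.csv --shells pellet/shells.csv --out aligned.csv
pelletox fit --aligned aligned.csv --free y_xo2 --starts 50 --seed 7 --out fit.json
```

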