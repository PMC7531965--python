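# eetkinetics

Kinetic modelling of extracellular electron transfer (EET) in
*Geobacter sulfurreducens* biofilms, for bioelectrochemists who want to
turn two-step chronoamperometry traces — and, optionally, parallel
resonance Raman time series — into rate constants and mediator pool
sizes.

## The model

Electron flow from acetate to the anode is lumped into two redox pools:
an intracellular mediator pool (IM) charged by acetate metabolism, and an
outer-membrane cytochrome pool (Omc) that discharges to the electrode.
Because conduction through the biofilm matrix (e-pili) is much faster
than either transfer step, the spatially distributed cytochromes collapse
into a single well-mixed Omc pool:

```
d[IM_red]/dt  = k_Ac [IM_ox]  −  k_Omc [IM_red][Omc_ox]
d[Omc_red]/dt = k_Omc [IM_red][Omc_ox]  −  k_i* [Omc_red]

i = F · k_i* · [Omc_red] / A          (A·m⁻², amounts in nmol)
```

with conservation `[IM]tot = [IM_ox] + [IM_red]`,
`[Omc]tot = [Omc_ox] + [Omc_red]`.  The interfacial constant `k_i*` is
piecewise constant across the potential step (`k_i_before` → `k_i_after`
at `t_switch`), and its potential dependence follows the anodic
Butler-Volmer branch

```
k_i(E) = k0 · exp[(1−α) nF/(RT) (E − E⁰)]
```

Fitting the six constants `{k_Ac, k_Omc, k_i_before, k_i_after, [IM]tot,
[Omc]tot}` to a current transient is a Nelder-Mead least-squares problem
solved in log-parameter space.  An OmcS-deletion (ΔOmcS) variant replaces
the bimolecular IM→Omc transfer with a saturating logistic flux
(pseudo-zero-order once `[IM_red]` exceeds a threshold θ), which
reproduces the linear decline of reduced cytochromes such mutants show.
The 747 cm⁻¹ resonance Raman band of reduced *c*-type hemes is integrated
over a fixed 22 cm⁻¹ window, AUC-normalized, and aligned to the modelled
`[IM_red] + [Omc_red]` by a single empirical scale factor.

A seeded synthetic-data generator emulates the potentiostat (10 Hz, 1%
multiplicative noise, optional 3-sample artifact spike at the step) and
the spectrometer (Gaussian 747 cm⁻¹ band on a drifting baseline, ~5 s
cadence) so the whole pipeline is testable without instrument data.

## Worked example

```python
import eetkinetics as ek
from eetkinetics.presets import WT_DE1, KI_POINTS

# simulate the first wild-type step profile (-101 mV -> 499 mV)
trace = ek.run_protocol(WT_DE1, protocol=ek.Protocol(-0.101, 0.499))
print(f"steady current after the step: {trace.current[-1]:.3f} A/m^2")

state = ek.steady_state(WT_DE1, WT_DE1.k_i_before)
print(f"pre-step reduced cytochromes:  {state.omc_red:.1f} of {WT_DE1.omc_total:.0f} nmol")

fit = ek.fit_butler_volmer(KI_POINTS)
bv = fit.parameters
print(f"Butler-Volmer: k0={bv.k0:.4f} 1/s, alpha={bv.alpha:.3f}, E0={bv.e0*1e3:.0f} mV vs SHE")
```

prints

```
steady current after the step: 0.718 A/m^2
pre-step reduced cytochromes:  659.6 of 814 nmol
Butler-Volmer: k0=0.0121 1/s, alpha=0.896, E0=-201 mV vs SHE
```

The simulated current relaxes to ≈0.72 A/m² about 100 s after the step —
the steady turnover where acetate supply, transmembrane transfer and
interfacial discharge balance.  Before the step, 81% of the cytochrome
pool sits reduced (electrons stored in the biofilm "capacitor"); the step
releases them as the current spike.  The Butler-Volmer refit of the four
extracted `k_i` values identifies the transfer coefficient α≈0.90
sharply; `k0` and `E⁰` are reported on the fit's flat one-parameter
family anchored near the OmcS formal potential (see
`docs/methods.md` for the identifiability discussion).

A `eetk` command-line tool wraps the same stages
(`simulate`, `fit`, `fit-bv`, `raman`, `synth`, `recover`) around YAML
run configs and CSV artifacts; run `eetk --help`.

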