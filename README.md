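# switchnoise

Stochastic models of ultrasensitive transcriptional switches, built to ask a
design question from synthetic and systems biology: **which repression
architectures give a sharp on/off transcriptional response that is also
robust to molecular noise?**

Four single-gene promoter architectures are implemented as explicit
mass-action reaction networks over discrete molecule counts:

| architecture | repression mechanism |
| --- | --- |
| `cooperative_binding` | repressor R binds three DNA sites with sequential dissociation constants K_r, cK_r, c²K_r (c ≤ 1); transcription unless all sites are occupied |
| `sequestration` | activator A binds free DNA (K_a) to activate transcription; R titrates free A into an inert complex R·A (K_s) |
| `sequestration_blocking` | adds blocking: R binds the DNA-bound activator (K_b), silencing the promoter in place |
| `sequestration_blocking_displacement` | adds displacement: the R·A complex dissociates from the DNA (K_d), evicting the activator |

Two quantities drive every comparison:

- **Sensitivity.** The transcriptional activity a(R̃_T) is the stationary
  probability of a transcribing promoter state versus the normalized
  repressor load (R̃_T = R_T/K_r for cooperative binding, the molar ratio
  R_T/A_T for the sequestration family). Its sharpness is the effective
  Hill coefficient
  `n_eff = log 81 / log(EC10/EC90)`,
  where EC90/EC10 are the loads at activity 0.9/0.1.
- **Noise.** The stationary mRNA copy-number distribution from the chemical
  master equation (CME), summarised by the Fano factor σ²/μ, the CV and the
  mode count, evaluated in the activation phase (TAP, at EC90) and the
  repression phase (TRP, at EC10).

The CME is solved exactly on the truncated state space (sparse null-space
solve); mRNA moments are also available from exact promoter-chain moment
equations at a fraction of the cost. A Gillespie direct-method simulator
(numba-accelerated) provides trajectories, dwell-time statistics and an
independent statistical cross-check of the CME engine. Analysis utilities
cover EC/Hill extraction, Fano-AUC over the TAP/TRP windows, parameter
scans, matched-sensitivity comparisons (calibrating K_b so mean-mRNA curves
coincide), a repressor birth-death (turnover) variant and deterministic-ODE
steady-state/stability analysis.

## Worked example

```python
from switchnoise import Architecture, default_params, build_network
from switchnoise import hill_summary, cme

arch = Architecture.SEQUESTRATION
params = default_params(arch)          # strong activator, A_T = 100

hill = hill_summary(arch, params)
print(f"EC90={hill.EC90:.3f}  EC10={hill.EC10:.3f}  n_eff={hill.n_eff:.1f}")

for tag, load in (("TAP/EC90", hill.EC90), ("TRP/EC10", hill.EC10)):
    network = build_network(arch, params.with_load(arch, load))
    noise = cme.noise_moments(network)
    print(f"{tag}: mean={noise.mean:.1f}  Fano={noise.fano:.2f}")
```

prints

```
EC90=0.947  EC10=1.043  n_eff=45.1
TAP/EC90: mean=45.5  Fano=1.69
TRP/EC10: mean=4.5  Fano=31.89
```

i.e. the sequestration-only switch flips from on to off over a ~10% change
in the molar ratio (n_eff ≈ 45, a strongly ultrasensitive response), but
pays for it with a thirty-fold super-Poissonian mRNA noise in the repressed
phase — noise-induced activation events persist because the tightly bound
activator has no repression route once on the DNA. Adding blocking and
displacement (see `switchnoise report`) removes exactly these excursions.

The same computations are exposed on the command line:

```bash
switchnoise activity --arch sequestration --out curve.tsv   # + EC/n_eff sidecar
switchnoise noise    --arch sequestration --at ec90,ec10
switchnoise simulate --arch sequestration --load 1.05 --t-end 1000 --seed 7
switchnoise scan     --out scan.tsv
switchnoise report   --recipes all        # pass/fail table of the claims
```

Every run writes a JSON manifest with the fully resolved parameters, seed
and output checksums; identical seeds reproduce identical outputs.

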