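# sleepwave

A wave model of human sleep dynamics: the alternation of NREM and REM sleep
over a night is modelled as a semiclassical wavepacket relaxing through the
bound levels of a Morse potential, with a Lorentzian resonance at the
sleep–wake crossing. The package is aimed at computational sleep
physiologists and chronobiology modellers who want to predict, fit, and test
the four primary per-cycle sleep measures — NREM episode duration and
intensity, REM episode duration and intensity — from group polysomnographic
tables or epoch-coded hypnograms.

## The model

The regulating parameter of state stability *x* (a one-dimensional reduction
of the physiological variables that stabilise the sleep state) moves in a
unit-depth Morse well

```
U(x) = exp(-2x/σ) - 2 exp(-x/σ),        ε_j = -(1 - (j + ½)/(2σ))²
```

with bound levels `j = 0 … ⌊2σ - ½⌋`. Sleep begins at level `j_in` and each
sleep cycle drops the wavepacket one level, `j(n) = j_in - n + 1`. The four
measures of cycle *n* follow from the well's kinematics:

| measure | model quantity | formula |
|---|---|---|
| NREM duration | oscillation period | `T_NR(n) = A_NR · 2π/Δε(j(n)) = A_NR · 4πσ²/(2σ - j(n))` |
| NREM intensity | wave intensity `κL²`, `κ ∝ 1/\|ε\|` | `I_NR(n)/I_NR(1) = (\|ε_in\|/\|ε_n\|)(L_n/L_1)²` |
| REM intensity | energy gap released | `I_R(n)/I_R(1) = 1 + (n-1)/(2σ - j_in)` (exactly linear) |
| REM duration | Lorentzian resonance delay | `T_REM(n) = A_REM · (1/π)(Γ/2)/((ε_n - ε_res)² + (Γ/2)²)` |

where `L(ε) = σ ln[(1+s)/(1-s)]`, `s = √(1-|ε|)`, is the turning-point
distance and `ε_res = U(x_c)` is the homeostatic energy threshold at the
sleep–wake crossing. Because the period is `2π/Δε` and REM intensity is
`∝ Δε`, their product — the **sleep-cycle invariant (SCI)** — is the same in
every cycle (`T · Δε = 2π`). The observed first NREM episode is curtailed to
~¾ of a period by the onset position between the walls, so SCI computations
multiply the observed cycle-1 duration by 4/3.

Modules: `sleepwave.morse` (spectrum, classical trajectories, two-state
mixing), `sleepwave.model` (per-cycle predictions, deprivation/abundance
scenarios), `sleepwave.fitting` (χ² estimation of `σ, j_in, ε_res, Γ` and
the time scales), `sleepwave.hypnogram` (stage-file IO, cycle segmentation,
per-cycle measures), `sleepwave.sci` (invariant products and constancy
tests), `sleepwave.synthetic` (group-data generator), `sleepwave.cli`
(`sleepwave` command).

## Worked example

```python
import sleepwave as sw

params = sw.default_params()        # sigma=10, j_in=16, eps_res=eps_14, gamma=0.05
print(sw.predict_cycles(params, 5).round(4).to_string(index=False))
```

```
 n  j  t_nrem_min  t_rem_min  i_nrem_rel  i_rem_rel  sci_rel
 1 16     91.1062     6.0058      1.0000       1.00      1.0
 2 15     72.8849    12.7324      0.4839       1.25      1.0
 3 14     60.7375    25.4648      0.2651       1.50      1.0
 4 13     52.0607    10.4364      0.1575       1.75      1.0
 5 12     45.5531     3.2815      0.0989       2.00      1.0
```

NREM durations fall as the period shrinks (91 → 46 min); NREM intensity
falls much faster (to 10% of cycle 1 by cycle 5); REM intensity climbs the
exact line with slope `1/(2σ - j_in) = 0.25`; and REM duration is
bell-shaped, peaking at cycle 3 where the ladder energy `ε_14` sits on the
resonance. The `sci_rel` column is the invariant: the product of NREM
duration and REM intensity, normalised to cycle 1, equals 1 in every cycle.

The same pipeline runs end to end from the shell:

```
sleepwave run --seed 1 --out-dir out/
```

which simulates a 40-night group, segments the generated hypnograms, fits
the model back (recovering `j_in = 16`, `σ ≈ 10`), evaluates the SCI, and
writes a manifest plus JSON reports under `out/`.

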