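# dnatwist

Torsional mechanics of double-stranded DNA from twist-restrained ensembles:
umbrella sampling along the end-to-end helical twist of a DNA fragment,
WHAM reconstruction of the twisting free-energy profile, torsional force
constants and rod-model torsional moduli, and the structural readouts that
accompany them (per-step twist partition, axis bending, groove geometry,
Watson–Crick integrity, protein–DNA contacts, and harmonic+Ising
deformation energies).

The package is aimed at people studying how torsional stress — the over-
and underwinding that RNA polymerase injects around transcription sites —
propagates through naked and protein-bound DNA, for example a 23-mer
carrying the E-box element `CACGTG` bound by basic helix–loop–helix
transcription-factor dimers.  Because microsecond atomistic MD is far
outside desk scale, the package ships its own synthetic-data stage: a
rigid-base-pair Gaussian-mixture Monte Carlo model whose pyrimidine–purine
"twist capacitor" steps carry two twist substates up to 20° apart,
reproducing the statistical features the analysis pipeline is built to
measure.

## The model and the statistic

A fragment of `n` bp steps is restrained through its end-to-end twist
`T = Σ twist_i` with the quadratic bias

```
E_bias = K_tw (T − T_ref)²,   K_tw = 0.06 kcal mol⁻¹ deg⁻²  (no ½ factor)
```

A cascade of 21 windows moves `T_ref` by ±0.5°/bp step per window
(±6.5° per window for the 13 restrained steps) out to ±5°/bp — in
twist-only supercoiling-density terms, σ = Δtw/tw₀ ≈ ±0.15.  WHAM combines
the biased histograms into the unbiased potential of mean force `F(δ)` on
the average-twist-change-per-bp axis; a free-centre quadratic fit over
δ = ±2°/bp gives the torsional force constant `K` (kcal mol⁻¹ deg⁻²), and
the homogeneous rod model converts it to a torsional modulus expressed as a
length,

```
C = 2 K_rad L / (n k_B T)     [nm],  L = 0.34 nm per bp step
```

which for a chain of independent Gaussian steps is identical to
`C = L / Var(twist_step in rad²)` — the package uses that identity as the
independent ground truth for validating the entire pipeline.

## Worked example

```python
from dnatwist.pipeline import RunConfig, run_all

config = RunConfig(
    model={"kind": "homogeneous", "twist_sd": 3.171},  # deg per bp step
    sampling={"n_frames": 30_000, "seed": 17},
)
summary = run_all(config, output_dir="demo_run")
```

prints (abridged `summary.json`):

```
"n_windows": 21,
"window_shift_deg": 6.5,
"total_sampling_time_us": 10.5,
"K_kcal_mol_deg2": 0.3844,
"R2": 0.9983,
"C_nm": 110.7,
"ground_truth_C_nm": 111.0
```

A per-step twist SD of 3.171° corresponds analytically to a torsional
modulus of 111.0 nm; the full umbrella + WHAM + fit pipeline recovers
110.7 nm (0.3 % off) from 21 windows of 30 000 snapshots.  The run
directory also contains the PMF (`pmf.csv`), the window-by-step twist
partition, per-window axis-bending and groove-geometry tables, the
window-averaged deformation energies (a U-shaped profile, minimal at the
relaxed window: 22.9 kcal/mol at 0°/bp vs 30.2 at ±4.5°/bp in this run)
and a human-readable `report.md`.

The same stages are available from the shell:

```
dnatwist umbrella --config run.yaml --out windows.h5
dnatwist wham     --windows windows.h5 --bin-width 0.25
dnatwist fit      --pmf pmf.csv --pmf-meta pmf.json --half-range 2.0
dnatwist modulus  --fit fit.json --n-steps 13
dnatwist contacts --pdb complex.pdb
```

## Documentation

`docs/methods.md` describes the sampling model and its assumptions, every
tunable parameter with units and defaults, the numerical choices inside
WHAM and the fits, and what the synthetic generator does and does not
emulate about real MD ensembles.
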