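# aortatear

Reduced-order mechanics of **aortic dissection onset**: at what true/false-lumen
pressure does a pre-existing tear inside the medial layer of the aorta start to
propagate, and how does that critical pressure depend on the tear's size, depth,
orientation and the vessel's diameter?

The package is aimed at cardiovascular biomechanics researchers who want a
desk-scale, scriptable counterpart to full 3-D finite-element dissection
studies: idealised two-layer cylinders stand in for imaged aortas, and an
explicit-interface tear model replaces XFEM, while keeping the constitutive
model, the prestress-recovery procedure and the cohesive onset criterion.

## The model

**Wall.** Media (1.5 mm) and adventitia (0.5 mm) are incompressible
Gasser–Ogden–Holzapfel (GOH) solids with two dispersed collagen-fibre families
at ±θ from the circumferential direction:

    Ψ = C10 (Ī₁ − 3) + k₁/(2k₂) Σ_α [exp(k₂⟨Ē_α⟩²) − 1],
    Ē_α = κ(Ī₁ − 3) + (1 − 3κ)(Ī₄α − 1),   ⟨x⟩ = max(x, 0),

so fibres stiffen exponentially in tension and switch off in compression.
Vessels are thick-walled cylinders in plane strain (λ_z = 1, restrained ends);
equilibrium reduces to the inflation integral P = ∫(σ_θθ − σ_rr)/r dr.

**Prestress.** Imaged geometries are pressure-loaded (80 mmHg diastole).  The
zero-load reference is recovered by forward-and-backward iteration — inflate
the candidate, subtract the nodal displacements from the image — until the
maximum nodal L2 residue drops below 0.01 mm.

**Onset.** The medial interface is a cohesive surface, t = Kδ, with
maximum-nominal-stress initiation f = max(⟨t_n⟩/t_n^cr, |t_s|/t_s^cr,
|t_t|/t_t^cr) and linear softening that dissipates the fracture energy
G = 50 N/m.  The reduced-order tear model converts a tear configuration
(orientation θz or θr, extent 3–12 mm, depth 0.25–1.25 mm in the media) into
front tractions, and bisects for the pressure at which f = 1 — the **critical
pressure** P_cr.

## Worked example

```bash
python examples/critical_pressure_one_tear.py
```

```text
front traction at the 80 mmHg baseline: t_n = 65.1 kPa, t_s = 1.6 kPa (critical t_n = 131.0 kPa)
critical pressure : 168.1 mmHg (limited by the normal traction component)
```

A 6 mm × 6 mm tear at the middle of the media of the smallest catalogued aorta
(16.444 mm descending fixture) holds at diastole — the normal traction at its
front is half the interface strength — and starts to propagate when both
lumens reach 168 mmHg.  `examples/depth_size_trends.py` sweeps depth, size and
diameter:

```text
  diameter  size (mm) | d=0.25   d=0.75   d=1.25
    16.444        3.0 |   129.1   204.5   296.9  mmHg
    16.444       12.0 |   127.0   166.8   192.6  mmHg
    41.381        3.0 |    80.0   125.5   291.3  mmHg
    41.381       12.0 |    80.0    80.0    86.1  mmHg
```

Deeper tears need higher pressures, larger tears lower ones (most strongly at
depth), and larger-diameter vessels tear at lower pressures — 80 mmHg entries
are at onset already at the diastolic baseline.

The same pipeline is scriptable from the shell:

```bash
aortatear sweep --out-dir results/        # all 228 default cases, one CSV row each
aortatear report results/sweep_results.csv --out-dir results/
```

## Layout

| path | content |
| --- | --- |
| `src/aortatear/material.py` | GOH strain energy, invariants, Cauchy stress |
| `src/aortatear/inflation.py` | thick-walled two-layer inflation, Laplace check |
| `src/aortatear/recovery.py` | forward-and-backward zero-load recovery |
| `src/aortatear/cohesive.py` | traction–separation law, onset ratio, damage |
| `src/aortatear/tear.py` | reduced-order tear-front tractions, critical pressure, sweeps |
| `src/aortatear/geometry.py` | aorta fixture catalogue, synthetic cylinders, grids, YAML I/O |
| `src/aortatear/data/` | per-layer material and fracture parameters (YAML) |
| `examples/` | one narrative script per capability |
| `docs/methods.md` | model derivations, calibration and limitations |
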