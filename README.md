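# oriscat

Simulation toolkit for small- and wide-angle X-ray scattering from
hierarchically assembled structures: solution curves, structure factors and
radial distribution functions, reciprocal-space amplitude grids, and 2D
scattering patterns from single orientations and fibers.

## Who this is for

Scattering practitioners who model a sample as repeating subunits placed on a
docking list (a plain-text list of positions and Tait–Bryan orientations) and
want to compute, from that model:

- the **oriented structure factor** S(**q**) = |Σᵢ exp(i**q**·**r**ᵢ)|²/N and its
  isotropic average via the Debye sum, S(q) = (1/N) Σᵢⱼ sinc(q·rᵢⱼ), so that
  I(q) = N·|f(q)|²·S(q) for identical, spherically symmetric subunits;
- the **radial distribution function** g(r) = N(r)/(4πr²Δr·ρ_b) by shell
  binning with periodic minimum-image distances, and the coordination number
  nn = 4πρ_b ∫ r² g(r) dr over a shell window;
- the **bidirectional Fourier pair** between them,
  S(q) = 1 + (4πρ_b/q)∫ r[g−1] sin(qr) dr and
  g(r) = 1 + 1/(2π²ρ_b r)∫ q[S−1] sin(qr) dq, by Simpson quadrature or a
  type-I discrete sine transform;
- **reciprocal-space amplitude grids** F(q, θ_q, φ_q) with hierarchical
  assembly F(**q**) = Σⱼₘₖ Fⱼ(A⁻¹ⱼₘ**q**)·exp(i**q**·**R**ⱼₘₖ), grid algebra,
  local interpolation, and Monte Carlo orientation averaging over the solid
  angle;
- **2D detector images**: the Ewald-plane slice at a fixed azimuth
  (q = (q⊥² + q_z²)^½, θ_q = arccos(q_z/q)) and fiber diffraction as a Monte
  Carlo average over the reciprocal azimuth φ_q;
- **instrument effects**: Gaussian resolution smearing of 1D curves and
  Gaussian size polydispersity (15 weighted model evaluations).

Thermal disorder enters through uniform (Δr = 2uv − u) or Gaussian
fluctuations and through a Metropolis Monte Carlo simulator with harmonic or
Lennard-Jones nearest-neighbor potentials under periodic boundary conditions.

All lengths are nm, reciprocal lengths nm⁻¹; amplitudes are in electron units
(the Thomson-length-squared prefactor is a constant overall scale and is left
out).

## Worked example

Coordination number of a simple cubic crystal (a = 3.5 nm, 10×10×10 subunits)
from its binned radial distribution function, and a few Debye structure-factor
values:

```python
import numpy as np
import oriscat as osc

crystal = osc.cubic_crystal(3.5, (10, 10, 10))
rdf = osc.g_r_from_model(crystal, dr=0.05, r_max=8.0, subunit_radius=0.1)
nn = osc.coordination_number(rdf, 3.4, 3.6)
print(f"first-shell coordination number: {nn:.2f}")

sq = osc.s_q_from_model(crystal, np.linspace(0.0, 3.0, 4))
for qi, si in zip(sq.q, sq.S):
    print(f"S({qi:.1f}) = {si:8.3f}")
```

prints

```
first-shell coordination number: 5.93
S(0.0) = 1000.000
S(1.0) =    0.143
S(2.0) =    0.222
S(3.0) =    0.639
```

The coordination number is slightly below the ideal 6 because the first shell,
spread over 0.05 nm bins by the 0.1 nm subunit radius, loses a little mass to
the quadrature at the window edges. S(0) equals the number of subunits; at
higher q the curve oscillates about 1 (Bragg peaks sit at multiples of
2π/3.5 ≈ 1.795 nm⁻¹).

A command-line surface mirrors the library:

```sh
oriscat build-crystal --constants 3.5 3.5 3.5 90 90 90 --repeats 10 10 10 --out crystal.dol
oriscat gr --from model --dol crystal.dol --r-max 8 --subunit-radius 0.1 --out gr.txt
oriscat sq --from model --dol crystal.dol --q-max 10 --n-q 1000 --out sq.txt
```

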