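# surfwet

Analysis pipeline for surfactant adsorption at water–vapor and solid–water
interfaces and its consequence for the contact angle of sessile droplets.

Short-chained amphiphiles (the archetypes here are methanol, 1-propanol and
1-pentanol) preferentially bind to interfaces, lower their tensions, and
thereby shift the Young balance of a droplet sitting on a solid. `surfwet`
implements the full post-processing chain that turns molecular-simulation-style
observables — 1-D density profiles c(z), radial distribution functions g(r),
adsorption series (c₀, Γ) — into wetting predictions, together with a
synthetic-data module that emulates those observables with known ground truth
so every step is testable end to end.

## The model

**Surface excess.** Adsorption is quantified as the excess of the surfactant
profile over its bulk value across the Gibbs dividing surface z₀ of water
(the plane where the excess water adsorption vanishes):

    Γ = ∫ [c(z) − c₀·H(liquid side)] dz        (nm⁻²)

integrated by the trapezoidal rule at 0.1 nm subintervals.

**Langmuir/Henry.** Γ(c₀) = Γ∞·k_c·c₀/(1 + k_c·c₀), fitted by orthogonal
distance regression when both coordinates carry uncertainty. The dilute limit
is Henry's law Γ = K·c₀ with the adsorption coefficient K = k_c·Γ∞, a length:
K_v at the water–vapor interface, K_s at the solid.

**Tension reduction.** Integrating the Gibbs adsorption equation
dγ = −Γ dμ along the Langmuir isotherm with the constant-Kirkwood–Buff
chemical potential βμ = ln c₀ − ln(1 + (G_mm − G_mw)c₀) gives, exactly,

    Δγ(Γ) = (k_B T Γ∞ / ξ) · ln(1 − ξΓ/Γ∞),      ξ = 1 − Γ∞(G_mm − G_mw)/K,

which reduces to Δγ = −k_B T·Γ for Γ ≪ ξ⁻¹Γ∞ and to the Szyszkowski equation
at ξ = 1. G_mm and G_mw are the molecule–molecule and molecule–water
Kirkwood–Buff integrals G = ∫4πr²(g(r) − 1)dr.

**Wetting-coefficient law.** On a soft surface the continuum adsorption free
energy ΔG_s = A_c*(γ_sm − γ_sw) − A_c·γ_mw becomes, via the Young equation,
affine in the wetting coefficient, so

    K_s(cos θ) = K_s⁽⁰⁾ · exp(−βγA_c* cos θ),     A_c* = A_m/4 (sphere),

and both reference coefficients scale exponentially with the molecular
surface area, K_i = b_i·exp(βγ̃_i·A_m), which couples the two interfaces:
ln K_s is linear in ln K_v with a slope that decreases linearly in cos θ.

**Droplet.** With the solid–vapor tension unaffected, the surfactant-laden
Young equation

    [γ + Δγ_v(c₀)]·cos(θ + Δθ) = γ·cos θ − Δγ_s(c₀)

is solved for Δθ, with explicit complete-wetting/dewetting flags; its
linearization Δθ = −k_B T c₀ (K_s + K_v cos θ)/(γ sin θ) exposes the
competition between the two interfaces.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(raw profiles land in `scratch/`, derived tables in `results/`):

```
python analysis/01_generate_synthetic.py
python analysis/02_surface_excess.py
...
python analysis/07_droplet_predictions.py
```

Representative output (propanol-like parameters, k_c = 4.15 nm³,
Γ∞ = 5.06 nm⁻²):

```
water_vapor: k_c = 4.1474 nm^3 (truth 4.15), Gamma_inf = 5.0595 nm^-2 (truth 5.06),
             K = 20.984 nm (truth 20.999)
ODR recovery over 100 noisy series: median |dK|/K = 0.022, 90th pct = 0.058
xi(water_vapor) = 0.9370  [Gamma_inf = 5.059 nm^-2, K = 20.984 nm]
closed form vs Gibbs-path quadrature: worst relative deviation 2.22e-16
theta = 97 deg: Dtheta(0.2 mol/l) = -1.48 deg (ok), linearized -1.25 deg
landscape (pentanol-like, c0 = 0.016 mol/l): least sensitive at theta = 96.0 deg
```

Reading: the surface-excess → ODR-fit chain recovers the generating Langmuir
parameters to 0.1% on noise-free profiles and the Henry coefficient to a
median 2.2% under 5% biaxial noise; the closed-form tension law is
numerically identical to direct Gibbs-isotherm quadrature; adding surfactant
always lowers the contact angle, least strongly for surfaces near θ = 90°
and divergently so toward complete wetting (Δθ ∝ −cot θ on the hydrophilic
branch).

The same pipeline is scriptable (`surfwet all --demo`, or
`surfwet droplet --config model.yaml --c0-grid 0:0.5:50 --theta 97 --out
curve.csv`) and configurable through a single YAML document; see
`surfwet.workbench.demo_config` for a complete example.

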