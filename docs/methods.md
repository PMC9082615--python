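# Methods

This note records the models implemented in `surfwet`, the conventions and
numerical choices behind them, and what the synthetic-data tests do and do
not establish.

## Units and constants

Internal units are nm, nm⁻³ (number density), nm⁻² (surface excess), mN/m
(tension) and radians; degrees and mol/l appear only at public interfaces.
1 mol/l = 0.602214 nm⁻³, applied exactly once at the I/O boundary.
Thermal energy is carried as k_BT = 0.0138065·T mN·m⁻¹·nm² (4.14 at the
default T = 300 K), so that tension × area is directly an energy.

## Surface excess from density profiles

The effective interface is the Gibbs dividing surface of water: the plane z₀
at which the excess water adsorption vanishes. Because that balance is
affine in z₀, it is inverted exactly from the cumulative trapezoid
(z₀ = z_hi − M/c_w0 for liquid at high z, M the integrated water profile);
this is the same root a bisection would find, at machine precision.
No orientation is assumed anywhere: the liquid side is inferred from where
the water density is high, since slab (water–vapor) and surface
(solid–water) geometries naturally face opposite ways.

The surfactant bulk concentration is the mean over the flattest contiguous
plateau of its profile: among all maximal runs in which every point stays
within a 2% relative band of the running mean, the widest-qualifying run
with the highest mean density is taken (the high-density requirement rejects
the vapor-side plateau without an orientation flag). A profile with no
qualifying window at least 1 nm wide has no bulk and is rejected.

Γ is integrated by the trapezoidal rule on a grid resampled (linear
interpolation) to 0.1 nm subintervals; the step-function bulk term is
evaluated analytically, so the sharp interface introduces no quadrature
artifact. Integration endpoints must lie at least 1.5 nm beyond z₀ on both
sides ("well inside" either phase); the margin is configurable, as no
canonical value exists. For solid surfaces the solid boundary is located at
the half-height crossing of the head-group peak on the water side, linearly
interpolated; an ambiguous (re-crossing) flank is an error that lists all
candidates rather than a silent pick.

## Langmuir fitting

Γ(c₀) = Γ∞k_c·c/(1 + k_c·c) with c in nm⁻³. The default estimator is
orthogonal distance regression (scipy.odr) because simulation-derived
isotherm points carry comparable uncertainty in both coordinates; when no
uncertainties are supplied the fit falls back to ordinary least squares —
ODR with fabricated weights would merely launder an arbitrary choice into
the covariance. Parameters are fitted as (ln k_c, ln Γ∞) to enforce
positivity; initialization uses Γ∞ ← 1.2·max Γ and the Henry slope of the
two most dilute points. Fits target the dilute-to-moderate regime: after an
initial pass, points with k_c·c > 2 are dropped and the fit is run once
more, with the window recorded in the output. The Henry coefficient is
always the identity K = k_c·Γ∞, never an independent parameter.

## Kirkwood–Buff thermodynamics

G_ij = ∫4πr²(g_ij − 1)dr by trapezoid. Finite-range RDFs never formally
converge, so the default estimate averages the running integral over the
final 20% of the range ("plateau" mode); a fixed cutoff is also available.
The spread of the running integral over the averaging window is returned as
a convergence diagnostic, and a non-plateauing integrand produces a warning
plus the best estimate, not an exception.

With both KB integrals treated as concentration-independent (their dilute
behavior), the chemical potential is

    βμ(c₀) = const + ln c₀ − ln(1 + ΔG·c₀),   ΔG = G_mm − G_mw,

which is ideal when ΔG = 0 and breaks down (pole) at c₀ = −1/ΔG for
ΔG < 0; that breakdown is an error, not a clamp.

## The tension law and ξ

Feeding the Langmuir isotherm and the constant-KB chemical potential through
the Gibbs adsorption equation dγ = −Γdμ integrates in closed form. Partial
fractions give

    Δγ(c₀) = −k_BT·Γ∞·(1/ξ)·ln[(1 + k_c c₀)/(1 + ΔG c₀)],

and eliminating c₀ in favor of Γ collapses the two logarithms into one:

    Δγ(Γ) = (k_BT·Γ∞/ξ)·ln(1 − ξΓ/Γ∞),   ξ = 1 − ΔG/k_c = 1 − Γ∞ΔG/K.

The integration is exact — the package's tests verify the closed form
against direct quadrature of −Γdμ to machine precision — so the law's
expansion is Δγ = −k_BT·Γ − (k_BTξ/2Γ∞)Γ² + O(Γ³): the linear
(Henry-regime) law Δγ = −k_BT·Γ carries no ξ, the first non-ideality
appears at second order, and the linear form is valid for Γ ≪ ξ⁻¹Γ∞. For
the same reason the dilute slope of Δγ(c₀) is −k_BT·K exactly. ξ = 1
recovers the Szyszkowski equation, which diverges logarithmically at
saturation; for ξ < 1 the law saturates at the finite value
(k_BTΓ∞/ξ)ln(1 − ξ).

ξ is dimensionless and temperature-free (ΔG/k_c is a ratio of volumes); the
`correction_factor` operation accepts a temperature argument for interface
symmetry but does not use it. Values outside (0, 1] — strong non-ideality
overwhelming a weak adsorber — are flagged with a warning, not forbidden,
because they signal the model leaving its regime rather than a computation
error. ξ grows toward 1 as K grows: the numerator Γ∞ΔG scales roughly
linearly with molecular size while K grows exponentially with it, so the
correction matters for small surfactants (≈0.65 for a methanol-like
ΔG = +0.043 nm³, K = 0.8 nm) and is negligible for large ones.

## Wetting-coefficient scaling

The continuum adsorption free energy ΔG_s = A_c*(γ_sm − γ_sw) − A_c·γ_mw
uses two areas: the full molecule–surface contact area A_c and the bare
cross-section A_c* (the patch of surface head groups displaced; the surplus
A_c − A_c* faces chemically-alike hydrocarbon and contributes nothing).
Substituting the Young equation makes ΔG_s affine in cos θ, whence
K_s(cos θ) = K_s⁽⁰⁾exp(−βγA_c*cos θ): adsorption weakens exponentially with
surface hydrophilicity. The sphere idealization fixes A_c*/A_m = 1/4 and the
infinite cylinder 1/π ≈ 0.32; rodlike molecules fall in this narrow
interval, and the sphere is the default. A custom ratio outside
[0.25, 0.32] is allowed with a warning (weak adsorbers penetrate less and
can fall below 1/4; no quantitative penetration model is implemented).

Both reference coefficients scale as K_i = b_i·exp(βγ̃_i·A_m) with effective
molecular surface tensions γ̃; the module fits these by linear regression on
ln K, and eliminating A_m yields the interface-coupling relation
ln(K_s/b_s) = [(γ̃_s − γ·(A_c*/A_m)·cos θ)/γ̃_v]·ln(K_v/b_v), verified as an
algebraic identity against the composed route to 10⁻¹⁰. Reference constants
for the three archetype alcohols (K_v = 0.8/21/410 nm, Γ∞ = 6.52/5.06/4.80
nm⁻², ξ = 0.650/0.950/0.998, γ̃_s ≈ 25.6 and γ̃_v ≈ 32.7 mN/m) and the
head-group polarity ↔ contact-angle table ship as documented constants for
worked examples; they derive from simulation trajectories this package does
not reproduce and are never asserted by tests as computed results.

## Droplet predictions

The modified Young equation is solved for cos(θ + Δθ) =
(γcos θ − Δγ_s)/(γ + Δγ_v); as the right-hand side is explicit, the solve is
a direct inversion on the [−1, 1] bracket (equivalent to the nominal
bisection at tolerance 10⁻¹⁰). Out-of-bracket values return
`complete_wetting`/`dewetting` flags with Δθ = NaN — never clamped angles —
and a non-positive surfactant-laden tension raises a beyond-model error.
Solid–vapor adsorption is assumed absent (appropriate for well-soluble
short-chained surfactants); no hook is provided.

The linearization Δθ = −k_BT·c₀(K_s + K_v cos θ)/(γ sin θ) follows from the
ξ-free linear tension law, so no ξ enters it for either interface; this
resolves, in favor of the exact expansion, the apparent tension between the
linear law "following from Henry's law with ideal chemical potential" and
the ξ-bearing second-order term. It is refused within 1° of θ = 0/180. The
landscape over surface hydrophilicities reports the −cot θ diagnostic
(Δθ·tan θ, constant on the hydrophilic branch when K_s is negligible) and
the least-sensitive region, which sits near θ = 90° for alcohol-like
parameters.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) tanh-edged water slabs whose Gibbs dividing
surface is the sigmoid midpoint analytically, with the surfactant profile
being the bulk concentration modulated by the same sigmoid (zero own excess)
plus a Gaussian interfacial peak of analytically normalized area Γ_true;
(ii) RDF families with closed-form KB integrals (ideal → 0; hard sphere →
−(4/3)πσ³; exponential decay → 8πaλ³, truncation correction reported); and
(iii) Langmuir-distributed (c₀, Γ) series with independent relative Gaussian
noise in both coordinates. One seeded `default_rng` per call; identical
seeds give byte-identical arrays. Default conditions: 5 nm slab in a 10 nm
box, 0.25 nm tanh width, 0.3 nm peak width, bulk water 33 nm⁻³, Δz = 0.02 nm,
one interface per profile (a two-sided mode mirrors the slab about its
center, which must then fit inside the box). Demo RDF amplitudes are chosen
so that G_mm − G_mw ≈ +0.26 nm³, a propanol-like self-association strength.

Not emulated: molecular detail, near-surface density oscillations of
structured solids, interfacial clustering of longer alcohols (the
saturation-regime deviations it causes), and time correlation of sampled
profiles. Consequently, passing tests establish the correctness of the
estimators on smooth, uncorrelated, Langmuir-consistent data — not their
robustness to oscillatory solid-side profiles or to isotherms with
attraction-driven shape deviations, which is exactly the regime the
reference constants above flag as hardest.

## Problem sizes

Default analysis sizes — 8 concentrations per interface, 501-point profiles,
3500-point RDFs, 100-seed (fitting) and 200-seed (scaling) recovery studies
— were chosen so the entire chain, tests included, completes in seconds on a
single CPU while keeping quadrature errors an order of magnitude below every
stated tolerance.

## Known limitations

* The Langmuir + constant-KB closed form inherits both assumptions; for
  weak adsorbers in strongly non-ideal solutions (k_c < ΔG, i.e. ξ < 0) the
  tension law has no valid regime, and the package warns rather than
  extrapolates.
* Γ∞ from dilute-window fits has limited accuracy by construction (few
  saturated points); the fit window is recorded with every fit.
* No Frumkin/BET isotherms, no pressure-tensor route to γ, no curvature
  (Tolman) corrections to molecular surface tensions, no contact-line
  hysteresis or dynamics.
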