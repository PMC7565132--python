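# Methods

## Model and assumptions

The package treats a bio-gel as a swollen network of freely jointed chains
and a penetrating particle as a rigid sphere or prolate ellipsoid. The
standing assumptions are: the particle imposes a purely local kinematic
constraint (chains further than nearest neighbors are unaffected); the
penetration is quasi-static, i.e. a sequence of equilibrium states with no
viscoelastic or rate effects; the particle is undeformable; and particle
concentrations are dilute, so a single particle's neighborhood is
representative. Chemical and adhesive particle–gel interactions are not
modelled; the spontaneous criterion is purely geometric.

Chain tension uses the inverse Langevin law through the rational
approximant β(x) = x(3 − x²)/(1 − x²). The exact inversion of
L(β) = coth β − 1/β exists in the test suite only, as a numerical oracle;
on x ∈ [0, 0.9] the approximant tracks it within 5%, which is ample given
that every downstream quantity is reported dimensionless.

## Parameters

| symbol | meaning | units | default |
|---|---|---|---|
| n | repeat units per chain | – | per gel |
| l | repeat-unit length | nm | 18 for mucus (midpoint of the reported 16–20) |
| J | swelling ratio (swollen/dry volume) | – | from liquid content, J = 1/(1−c_l) |
| κ | extensibility scale J^(1/3)/√n | – | 0.1 in the reference sweeps |
| ρ, ξ | particle short semi-axis, aspect ratio | nm, – | ξ = 1 (sphere) |
| η | R/(ρ√(2(ξ²+1))) | – | set by geometry |
| f_rup, f_dis | critical chain / cross-link forces | f·l/(k_BT) | ∞ (damage off) |
| steps | quasi-static sweep states | – | 400 |

All forces are dimensionless (f·l/k_BT). An SI helper multiplies by
k_BT/l with k_B = 1.380649×10⁻²³ J/K and a default T = 310 K (body
temperature); at l = 18 nm the force unit is ≈ 0.24 pN.

Two parameterizations of the chain are interchangeable: (n, l, J) for
characterization work, or κ directly for forced-penetration sweeps
(`ChainSpec.from_kappa`, which realizes κ with J = 1). κ is exposed as a
single scalar so that either convention for quoting the extensibility of a
swollen chain can be reproduced by setting it explicitly.

## The characterization pipeline and its reporting conventions

`characterize` computes, per gel and per coordination m, the minimal mesh
size R = d_avg·tan(π/m) consistent with the average spontaneously
penetrating diameter, then the chain length n from R. Two conventions are
deliberate and load-bearing:

- **R is rounded to two significant figures first, and n is computed from
  the rounded R**, then rounded to the nearest integer. A brute-force
  comparison of the rounding-order alternatives shows this is the only
  pipeline consistent with the full set of published mucus estimates
  (e.g. cervicovaginal m = 3 yields n = 146 from R = 590, but 144 from the
  unrounded 588.9).
- **The boundary case is not penetration**: R must strictly exceed
  2ρ·tan(π/m). A 10⁻¹² relative tolerance absorbs floating-point error in
  tan(π/4).

When liquid content or repeat-unit length is published only as a range
(both biofilms), the midpoint is the default and either can be overridden
per run. Mesh sizes R for the biofilms are robust — they depend on the
diameters alone — but chain counts n are not reported as trustworthy: the
published biofilm chain counts imply an unstated point value near
J^(1/3)·l ≈ 1.2 nm that cannot be recovered from the quoted ranges, so the
bundled fixture documents this in a comment instead of asserting it. For
the same reason the Streptococcus mutans m = 3 mesh size (2.0·tan 60° =
3.46 nm, quoted as 4 elsewhere under an unclear rounding) is excluded from
the reproduced set.

A diameter so small that the implied R falls below one swollen repeat unit
(n < 1) floors n at 1 and emits a warning rather than failing.

## Forced-penetration mechanics

The sink–stretch relation y/ρ = 1 − √(1 − λ²η²) is the tangency condition
between the particle's cross-section at the network plane and the cell of
stretched chains: a square of side λR for the sphere, a rhombus of vertex
angle γ = 2·arctan(1/ξ) for the ellipsoid entering through its short axis
with the long axis along the cell diagonal. (The two other ellipsoid
orientations — long-axis entry, long axis parallel to the chains — behave
differently and are out of scope.) Both constructions are verified in the
tests by independent numerical tangency solves.

Pre-collapse (λ ≤ 3), only the four contact chains stretch; the twelve
nearest neighbors rotate at constant length in trapezoids with base angle
α = arccos((λ−1)/2) and contribute their reference tension β(κ). The
trapezoid adopted is the unique one with parallel sides λR and R and legs
R, which is what makes α's closed form and the collapse at λ = 3
mutually consistent. Post-collapse, the neighbors stretch at λ/3 — series
compatibility of the collapsed trapezoid (near side λR equals far side
plus two legs, all stretching equally) — which is continuous at λ = 3 and
produces the upward kink in the force–sink slope (stiffening).

The **average chain force** is taken over the fixed population of 16 local
chains in both regimes. Averaging over the stretched subset only would
produce a downward jump at collapse, contradicting the stiffening the
model is built to capture; with the fixed denominator the average is
continuous, its slope jumping up by (12/16)(κ/3)β′(κ) at λ = 3.

The **cross-link resultant** is the in-plane vector sum of the four chain
tensions at a vertex: two stretched cell sides (tension β(κλ)) separated
by the vertex angle, and the two adjacent trapezoid legs, each leaving at
the base angle α below its own side — components cos α along that side,
−sin α along the other. The sum factorizes to

    f_CL,1 = 2·cos(γ/2)·|f + f_leg(cos α − sin α)|,
    f_CL,2 = 2·sin(γ/2)·|…|,

so the acute vertex (on the ellipsoid's long axis) always carries ξ times
the load of the obtuse one, the two coincide for the sphere (γ = 90°), and
the reference state λ = 1 is exactly equilibrated (zero resultant) — the
consistency check that validates the construction. The vertical load path
to the particle is carried by the contact, not by the in-plane resultant.
Whether published force–sink curves include the legs' reference tension as
a baseline is not determinable from their axes, so `simulate` exposes a
`subtract_reference` flag instead of hard-coding either reading; the flag
applies to the average chain force, whose nonzero λ = 1 value is the only
baseline at issue (the cross-link resultant already starts at zero).

**Damage.** A chain ruptures when its tension exceeds f_rup; a cross-link
dissociates when the resultant on the critical site (cross-link 1) exceeds
f_dis. If both thresholds are crossed within one quasi-static step, the
larger relative exceedance decides; an exact tie defaults to cross-link
dissociation, the more probable mode in physically cross-linked gels such
as mucin, and the tie-break is configurable. The sweep terminates at the
first damage event.

**Sweep driver.** λ runs uniformly (400 steps by default) from 1 to
min(1/η, λ_lock(1 − 10⁻⁶)) with λ_lock = 1/κ; λκ > 1 − 10⁻⁹ is treated as
the finite-extensibility singularity. Uniform-in-λ spacing keeps the
near-vertical end of the force–sink curve resolved. Outcomes: η ≥ 1 short
circuits to `spontaneous` (empty trajectory, and note that for ξ > 1 this
η-criterion is the diagonal-cell condition, stricter than fitting the
mesh); reaching 1/η is `elastic_penetration`; hitting λ_lock first with no
damage is `jammed`. Everything is deterministic.

## Synthetic data

`generate_fixtures` emulates literature-style spontaneous-penetration
tables — per gel a diameter range and average (20–500 nm), liquid content
0.90–0.99, repeat-unit length 1–20 nm — and forced-penetration scenarios
covering the three regimes (η > 1 spontaneous, spheres only, where η > 1
and the mesh criterion coincide; 1/3 < η < 1 penetration before
stiffening; η < 1/3 stiffened), with κ capped at 0.9η so sweeps end by
penetration rather than locking. It does not emulate heterogeneity of real
bio-gels (spatially varying mesh size), adhesive interactions, or
measurement error in diameters, so passing tests demonstrate internal
consistency of the pipeline, not fidelity to any particular tissue. Files
are byte-identical for identical seeds.

## Numerical choices

- Two-significant-figure rounding is half-away-from-zero on the scaled
  mantissa; chain counts round half to even only through Python's
  `round` at the final integer step, where no published value sits on a
  half.
- Angles are degrees at every interface, radians internally.
- λ > 3 clamps the trapezoid angle to 0 (valid stiffened states) rather
  than erroring; λ < 1 (compression) raises, as does a sink shallower
  than the λ = 1 initial sink.
- Problem sizes are small everywhere (≤ a few hundred sweep states, ≤ 200
  property-test examples), so the whole suite runs in seconds.

## Known limitations

Triangular-lattice forced penetration, viscoelasticity, explicit bulk
resistance and contact-force constitutive laws (only the entropic chain
forces are computed), multi-particle interactions, and diffusion dynamics
of the spontaneous process are all out of scope. The initial sink is
defined as the λ = 1 state of the sink–stretch relation; a weight-balance
initial sink would need a bulk model the framework deliberately leaves
unspecified.
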