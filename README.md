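# biogel

Biological gels — mucus layers, biofilm matrices — are highly hydrated
polymer networks that act as selective barriers to particulate matter:
nanomedicines trying to get through, nano-pollutants we would rather keep
out. `biogel` implements a microscopically motivated, entropy-based model of
how rigid particles penetrate such networks. It is written for researchers
in nanomedicine, nanosafety and soft-matter biophysics who want to turn
particle-penetration observations into microstructural estimates, or to
predict the forces (and the damage) that forced penetration produces.

## The model in brief

The gel is idealized as a network of freely jointed chains: `n` rigid
repeat units of length `l` between cross-links, swollen by a volumetric
ratio `J` (liquid content `c_l = (J−1)/J`). The referential end-to-end
distance of a chain is

    R = J^(1/3) · √n · l

and the dimensionless entropic tension of a chain at stretch λ is the
inverse Langevin law with the Padé-type approximant

    f·l/(k_B·T) = β(λκ),   β(x) = x(3 − x²)/(1 − x²),   κ = J^(1/3)/√n.

**Spontaneous penetration.** A sphere of diameter `2ρ` surrounded locally by
`m` chains slips through the mesh without force iff

    R > 2ρ · tan(π/m).

Read inversely, the largest spontaneously penetrating particle pins down
the mesh size R and — with `c_l` and `l` — the chain length
`n = (R/(J^(1/3) l))²`. That inverse pipeline is `characterize`.

**Forced penetration.** A sphere (or an ellipsoid with semi-axes ρ, ρ, ξρ
entering through its short axis) pressed quasi-statically into a locally
quadrilateral lattice stretches the four contact chains; sink and stretch
are linked by

    y/ρ = 1 − √(1 − λ²η²),   η = R / (ρ·√(2(ξ²+1))),

with full penetration at λ = 1/η. Neighbor chains rotate in trapezoids of
base angle α = arccos((λ−1)/2) until the trapezoid collapses at λ = 3 and
twelve neighbors must stretch too — the network stiffens. The vector sum of
the four chain tensions at a cross-link gives the resultant that decides
cross-link dissociation; chain tension decides rupture. `simulate` sweeps λ
and reports the trajectory and the outcome (spontaneous, elastic
penetration, chain rupture, cross-link dissociation, or jammed).

## Worked example

Characterize the bundled literature observations (three mucus types, two
biofilms) with the mucus defaults, 95% liquid content and `l = 18 nm`:

```sh
biogel characterize --input src/biogel/data/table1.csv --cl 0.95 --l-nm 18
```

prints (abridged to the mucus rows):

```text
name,m,R_nm,R_reported_nm,n
Respiratory mucus,3,242.48711305964275,240.0,24
Respiratory mucus,4,140.0,140.0,8
Intestinal mucus,3,363.73066958946424,360.0,54
Intestinal mucus,4,210.0,210.0,18
Cervicovaginal mucus,3,588.8972745734183,590.0,146
Cervicovaginal mucus,4,340.0,340.0,48
```

Respiratory mucus, for instance, admits 140 nm particles on average, so its
mesh must open at least `R = 140·tan(60°) ≈ 240 nm` in a triangular local
arrangement — chains of about 24 repeat units — or 140 nm (8 repeat units)
in a quadrilateral one. Intestinal and cervicovaginal mucus have
progressively longer chains; the microstructures can be compared directly.

A forced-penetration sweep of a ξ = 3 ellipsoid into a mesh with η = 1/4
and loosely stretched chains (κ = 0.1):

```sh
biogel simulate --xi 3 --eta 0.25 --kappa 0.1 --out traj.csv
# outcome: elastic_penetration
```

`traj.csv` tabulates λ, y/ρ, the trapezoid angle, the regime, the average
chain force and both cross-link resultants; because η < 1/3 the trajectory
contains stiffened (post-collapse) states before the particle is through.
Add `--f-dis 0.5` and the outcome becomes `crosslink_dissociation`, with
the sweep stopping at the damage point.

One-off mesh verdicts and seeded synthetic datasets:

```sh
biogel spontaneous --diameter 100 --r 300 --m 3   # yes; minimal R 173.205 nm
biogel fixtures --seed 1 --outdir fixtures/
```

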