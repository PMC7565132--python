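"""Seeded synthetic fixtures: gel-observation tables and simulation configs.

The generator emulates the kind of spontaneous-penetration datasets compiled
from particle-tracking literature: per gel, a particle-diameter range and
average, a liquid content around the 90-99% typical of bio-gels, and a
repeat-unit length. Alongside the table it emits forced-penetration
scenarios spanning the interesting corners of parameter space: spontaneous
cases (eta >= 1), penetration-before-stiffening (1/3 < eta < 1), stiffened
cases (eta < 1/3), and chains near their extensibility limit.

Output is deterministic: the same seed yields byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .lattice import ParticleShape, eta as eta_of

__all__ = ["generate_fixtures"]

_GEL_HEADER = "name,d_min_nm,d_max_nm,d_avg_nm,cl,l_nm,m_values\n"


def _synthetic_observation_row(rng: np.random.Generator, index: int) -> str:
    d_avg = float(np.round(rng.uniform(20.0, 500.0), 1))
    d_min = float(np.round(d_avg * rng.uniform(0.2, 0.9), 1))
    d_max = float(np.round(d_avg * rng.uniform(1.1, 4.0), 1))
    cl = float(np.round(rng.uniform(0.90, 0.99), 3))
    l = float(np.round(rng.uniform(1.0, 20.0), 2))
    return f"synthetic_gel_{index:03d},{d_min},{d_max},{d_avg},{cl},{l},3;4\n"


def _simulation_case(rng: np.random.Generator, index: int, label: str) -> dict:
    """One forced-penetration scenario with a self-consistent eta label."""
    rho = float(np.round(rng.uniform(50.0, 200.0), 2))
    if label == "spontaneous":
        # spheres only: for them eta > 1 coincides with the mesh criterion
        xi = 1.0
        eta_target = rng.uniform(1.05, 2.0)
    elif label == "forced_elastic":
        xi = float(rng.choice([1.0, 1.0, 2.0, 3.0]))
        # penetration before stiffening: 1/3 < eta < 1
        eta_target = rng.uniform(0.4, 0.95)
    else:  # forced_stiffening
        xi = float(rng.choice([1.0, 1.0, 2.0, 3.0]))
        eta_target = rng.uniform(0.15, 0.3)
    R = float(
        np.round(eta_target * rho * math.sqrt(2.0 * (xi**2 + 1.0)), 3)
    )
    # keep the sweep inside the locking stretch: lam_max = 1/kappa > 1/eta
    eta_actual = eta_of(ParticleShape(rho=rho, xi=xi), R)
    kappa_cap = 0.9 * eta_actual if eta_actual < 1.0 else 0.5
    kappa = float(np.round(rng.uniform(0.3 * kappa_cap, kappa_cap), 4))
    return {
        "name": f"sim_{label}_{index:03d}",
        "label": label,
        "rho_nm": rho,
        "xi": xi,
        "R_nm": R,
        "eta": float(np.round(eta_actual, 6)),
        "kappa": kappa,
        "steps": 200,
    }


def generate_fixtures(seed: int, count: int, outdir) -> dict:
    """Write a synthetic gel table and simulation configs under ``outdir``.

    Parameters
    ----------
    seed : int
        Seed for the pseudo-random generator; identical seeds produce
        byte-identical files.
    count : int
        Number of synthetic gel rows and of simulation cases per label
        (>= 1).
    outdir : path-like
        Output directory (created if absent).

    Returns
    -------
    dict
        Paths of the two files written: ``{"gels": ..., "simulations": ...}``.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gel_path = outdir / "synthetic_gels.csv"
    with open(gel_path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(f"# synthetic gel observations (seed={seed})\n")
        handle.write(_GEL_HEADER)
        for i in range(count):
            handle.write(_synthetic_observation_row(rng, i))

    cases = []
    for label in ("spontaneous", "forced_elastic", "forced_stiffening"):
        for i in range(count):
            cases.append(_simulation_case(rng, i, label))
    sim_path = outdir / "synthetic_simulations.yaml"
    with open(sim_path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(f"# synthetic simulation configs (seed={seed})\n")
        yaml.safe_dump(cases, handle, sort_keys=True)

    return {"gels": gel_path, "simulations": sim_path}
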