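"""Independent numerical oracles used by the test suite.

Everything here is deliberately written against different numerical
machinery than the package (adaptive quadrature and root finding instead
of cached cumulative-trapezoid tables; explicit pairwise union-find
instead of image labelling) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

ME_KEV = 510.99895  # electron rest energy, keV


def oracle_stopping(z: int, mass_per_nucleon: float, e_u: float,
                    z_over_a: float, i_ev: float) -> float:
    """First-order Bethe-Bloch, MeV cm^2/g, written from scratch."""
    gamma = 1.0 + e_u / mass_per_nucleon
    beta2 = (gamma * gamma - 1.0) / (gamma * gamma)
    wmax_kev = 2.0 * ME_KEV * beta2 * gamma * gamma
    return 0.307075 * z_over_a * z * z / beta2 * (
        math.log(wmax_kev * 1e3 / i_ev) - beta2)


def oracle_range_cm(z, a, mass_per_nucleon, e_u, rho, z_over_a, i_ev,
                    e_min: float = 0.5) -> float:
    """CSDA range by adaptive quadrature of A/(S rho) in energy."""
    def integrand(e):
        return a / (oracle_stopping(z, mass_per_nucleon, e, z_over_a, i_ev)
                    * rho)
    val, _ = quad(integrand, e_min, e_u, limit=400)
    return val


def oracle_energy_after(z, a, mass_per_nucleon, e_u, rho, z_over_a, i_ev,
                        thickness_cm, e_min: float = 0.5) -> float:
    """Residual energy by root finding on the range difference."""
    r0 = oracle_range_cm(z, a, mass_per_nucleon, e_u, rho, z_over_a, i_ev,
                         e_min)
    target = r0 - thickness_cm
    if target <= 0:
        return 0.0

    def f(e):
        return oracle_range_cm(z, a, mass_per_nucleon, e, rho, z_over_a,
                               i_ev, e_min) - target
    return brentq(f, e_min, e_u, xtol=1e-6)


def oracle_exit_variance_mm2(z, a, mass_per_nucleon, e0_u, rho, z_over_a,
                             i_ev, x0_gcm2, length_cm,
                             log_corr: float, n_steps: int = 400) -> float:
    """Exit lateral-position variance after a thick slab.

    Fine-step composition: each depth step contributes an independent
    scattering angle theta_step (Highland with the supplied global log
    factor) acting over the remaining lever arm, plus the in-step
    displacement term; the energy is degraded step by step.
    """
    dx = length_cm / n_steps
    e = e0_u
    var = 0.0
    for k in range(n_steps):
        if e <= 0.5:
            break
        gamma = 1.0 + e / mass_per_nucleon
        beta2 = (gamma * gamma - 1.0) / (gamma * gamma)
        pc = a * mass_per_nucleon * gamma * math.sqrt(beta2)
        theta = 13.6 / (math.sqrt(beta2) * pc) * z * math.sqrt(
            dx * rho / x0_gcm2) * log_corr
        lever_cm = (n_steps - k - 1) * dx
        var += (theta * lever_cm) ** 2 + (theta * dx) ** 2 / 3.0
        e = oracle_energy_after(z, a, mass_per_nucleon, e, rho, z_over_a,
                                i_ev, dx)
    return var * 100.0  # cm^2 -> mm^2


def union_find_clusters(hits: list[tuple[int, int]],
                        chebyshev: int = 1) -> list[frozenset]:
    """Brute-force O(n^2) connected components over pixel hits."""
    parent = list(range(len(hits)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if max(abs(hits[i][0] - hits[j][0]),
                   abs(hits[i][1] - hits[j][1])) <= chebyshev:
                union(i, j)
    groups: dict[int, set] = {}
    for i in range(len(hits)):
        groups.setdefault(find(i), set()).add(hits[i])
    return [frozenset(g) for g in groups.values()]


def bhattacharyya_overlap(a: np.ndarray, b: np.ndarray, bins: int = 60) -> float:
    """Bhattacharyya coefficient of two samples on a shared histogram."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    ha, edges = np.histogram(a, bins=bins, range=(lo, hi), density=False)
    hb, _ = np.histogram(b, bins=edges, density=False)
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return float(np.sqrt(pa * pb).sum())
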