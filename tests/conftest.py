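"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately separate implementations from the
package code paths they validate: a scalar-loop transfer-matrix
reflectivity, a quaternion-based superposition, and small brute-force
scans.
"""

import cmath

import numpy as np
import pytest


def brute_force_reflectivity(stack, q_values):
    """Scalar 2x2 complex transfer-matrix reflectivity, one Q at a time.

    Independent of the vectorised kernel: plain Python loops, cmath,
    explicit matrix multiplication.
    """
    thick, sld, isld, rough = stack.slab_arrays()
    n = len(sld)
    out = []
    for q in np.atleast_1d(q_values):
        ks = [cmath.sqrt((q / 2.0) ** 2
                         - 4.0 * cmath.pi * ((sld[i] + 1j * isld[i]) - sld[0]))
              for i in range(n)]
        m = [[1.0 + 0j, 0.0 + 0j], [0.0 + 0j, 1.0 + 0j]]
        for i in range(n - 1):
            denom = ks[i] + ks[i + 1]
            r = 0.0 if denom == 0 else (ks[i] - ks[i + 1]) / denom
            r *= cmath.exp(-2.0 * ks[i] * ks[i + 1] * rough[i] ** 2)
            beta = 1j * ks[i] * thick[i]
            a = [[cmath.exp(beta), r * cmath.exp(beta)],
                 [r * cmath.exp(-beta), cmath.exp(-beta)]]
            m = [[m[0][0] * a[0][0] + m[0][1] * a[1][0],
                  m[0][0] * a[0][1] + m[0][1] * a[1][1]],
                 [m[1][0] * a[0][0] + m[1][1] * a[1][0],
                  m[1][0] * a[0][1] + m[1][1] * a[1][1]]]
        out.append(abs(m[1][0] / m[0][0]) ** 2)
    return np.array(out)


def quaternion_superpose_rmsd(a, b):
    """Optimal superposition RMSD via the quaternion eigenvalue method."""
    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    e0 = np.sum(a ** 2) + np.sum(b ** 2)
    msd = max((e0 - 2.0 * lam) / len(a), 0.0)
    return float(np.sqrt(msd))


def random_stack(rng, max_layers=10):
    from pqinr import Layer, LayerStack

    n = int(rng.integers(1, max_layers + 1))
    layers = [Layer(thickness=float(rng.uniform(0, 300)),
                    sld=float(rng.uniform(-0.5e-6, 7e-6)),
                    roughness=float(rng.uniform(0, 8)))
              for _ in range(n)]
    return LayerStack(fronting_sld=float(rng.uniform(0, 4e-6)),
                      layers=layers,
                      backing_sld=float(rng.uniform(-0.5e-6, 7e-6)),
                      backing_roughness=float(rng.uniform(0, 8)))


@pytest.fixture(scope="session")
def pqic_scenario():
    from pqinr import builtin_scenarios

    return builtin_scenarios()["bilayer_pqic"]


@pytest.fixture(scope="session")
def pqic_data(pqic_scenario):
    from pqinr import simulate_experiment

    return simulate_experiment(pqic_scenario)
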