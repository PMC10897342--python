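"""Specular neutron reflectivity of stratified interfaces.

The kernel is the exact optical-matrix (Abeles) solution for a stack of
uniform slabs between two semi-infinite media.  For each layer n the
normal wavevector is

    k_n = sqrt((Q/2)^2 - 4 pi (rho_n - rho_fronting)),

the interfacial Fresnel coefficients are damped by Nevot-Croce factors
exp(-2 k_n k_{n+1} sigma^2) for Gaussian roughness sigma, and the
reflectivity is |M_10 / M_00|^2 of the characteristic-matrix product.
Instrument resolution is applied as a Gaussian smearing in Q with a
constant fractional width dQ/Q (FWHM convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Layer", "LayerStack", "ReflectivityCurve", "reflectivity", "smear"]


@dataclass(frozen=True)
class Layer:
    """A uniform slab.

    ``roughness`` is the Gaussian width (Å) of this layer's interface to
    the preceding (substrate-side) medium.
    """

    thickness: float
    sld: float
    roughness: float = 0.0
    isld: float = 0.0  # imaginary SLD (absorption); zero for these systems

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("layer thickness must be >= 0")
        if self.roughness < 0:
            raise ValueError("layer roughness must be >= 0")


@dataclass(frozen=True)
class LayerStack:
    """Slab model bounded by semi-infinite fronting and backing media.

    Layers are ordered from the substrate (fronting) side towards the
    solution (backing) side.  ``backing_roughness`` is the width of the
    final interface between the last layer and the backing medium.
    """

    fronting_sld: float
    layers: tuple[Layer, ...]
    backing_sld: float
    backing_roughness: float = 0.0

    def __init__(self, fronting_sld, layers, backing_sld, backing_roughness=0.0):
        object.__setattr__(self, "fronting_sld", float(fronting_sld))
        object.__setattr__(self, "layers", tuple(layers))
        object.__setattr__(self, "backing_sld", float(backing_sld))
        object.__setattr__(self, "backing_roughness", float(backing_roughness))
        if self.backing_roughness < 0:
            raise ValueError("backing_roughness must be >= 0")

    def slab_arrays(self):
        """(thickness, sld, isld, roughness) arrays over fronting+layers+backing.

        Roughness[i] belongs to the interface *above* slab i (towards the
        backing), matching the matrix recursion order.
        """
        n = len(self.layers)
        thick = np.zeros(n + 2)
        sld = np.zeros(n + 2)
        isld = np.zeros(n + 2)
        rough = np.zeros(n + 1)
        sld[0] = self.fronting_sld
        sld[-1] = self.backing_sld
        for i, lay in enumerate(self.layers):
            thick[i + 1] = lay.thickness
            sld[i + 1] = lay.sld
            isld[i + 1] = lay.isld
            rough[i] = lay.roughness
        rough[-1] = self.backing_roughness
        return thick, sld, isld, rough


def reflectivity(stack: LayerStack, q) -> np.ndarray:
    """Specular reflectivity |r(Q)|^2 for a layer stack.

    Vectorised over Q; returns an array matching ``q``.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("Q values must be > 0")
    thick, sld, isld, rough = stack.slab_arrays()
    nmedia = len(sld)

    # normal wavevector in each medium, relative to the fronting
    k0sq = (q / 2.0) ** 2
    rho = (sld + 1j * isld) - sld[0]
    k = np.sqrt(k0sq[:, None] - 4.0 * np.pi * rho[None, :] + 0j)

    # characteristic matrix product, interface by interface
    m00 = np.ones(q.shape, dtype=complex)
    m01 = np.zeros(q.shape, dtype=complex)
    m10 = np.zeros(q.shape, dtype=complex)
    m11 = np.ones(q.shape, dtype=complex)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(nmedia - 1):
            ki, kj = k[:, i], k[:, i + 1]
            denom = ki + kj
            # 0/0 only at a contrast-free interface, which reflects nothing
            rf = np.where(denom != 0, (ki - kj) / np.where(denom == 0, 1, denom), 0.0)
            if rough[i] > 0:
                rf = rf * np.exp(-2.0 * ki * kj * rough[i] ** 2)
            if i > 0 and thick[i] > 0:
                ep = np.exp(1j * ki * thick[i])
                em = 1.0 / ep
                a01 = rf * ep
                a10 = rf * em
                m00, m01, m10, m11 = (
                    m00 * ep + m01 * a10,
                    m00 * a01 + m01 * em,
                    m10 * ep + m11 * a10,
                    m10 * a01 + m11 * em,
                )
            else:
                m00, m01, m10, m11 = (
                    m00 + m01 * rf,
                    m00 * rf + m01,
                    m10 + m11 * rf,
                    m10 * rf + m11,
                )
        r_amp = np.where(m00 != 0, m10 / np.where(m00 == 0, 1, m00), 0.0)
    refl = np.abs(r_amp) ** 2
    # total external reflection can numerically exceed 1 by rounding only
    return np.clip(refl.real, 0.0, 1.0)


@dataclass
class ReflectivityCurve:
    """Measured or simulated reflectivity on a Q grid.

    ``dq_over_q`` is the fractional instrument resolution (FWHM of the
    Gaussian Q-kernel divided by Q); a per-point ``dq`` array, when
    available from the data file, takes precedence in the likelihood.
    """

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray | None = None
    dq_over_q: float = 0.0
    dq: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.dr is not None:
            self.dr = np.asarray(self.dr, dtype=float)
            if np.any(self.dr < 0):
                raise ValueError("dr must be >= 0")
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        if self.q.ndim != 1 or np.any(np.diff(self.q) <= 0) or np.any(self.q <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if self.r.shape != self.q.shape:
            raise ValueError("r and q must have the same shape")
        if self.dq_over_q < 0:
            raise ValueError("dq_over_q must be >= 0")


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# 17-point Gauss-Hermite-like quadrature of the Gaussian resolution kernel,
# truncated at +/-3.5 sigma.  Evaluating the model on the shifted Q points
# of every datum oversamples the curve far beyond the data spacing, so
# fringes are not aliased.
_N_SMEAR = 17
_SMEAR_X = np.linspace(-3.5, 3.5, _N_SMEAR)
_SMEAR_W = np.exp(-0.5 * _SMEAR_X**2)
_SMEAR_W /= _SMEAR_W.sum()


def smeared_reflectivity(stack: LayerStack, q, dq_over_q: float,
                         dq=None) -> np.ndarray:
    """Model reflectivity convolved with the Gaussian Q-resolution.

    ``dq_over_q`` is interpreted as FWHM/Q; 0 returns the unsmeared
    model.  A per-point ``dq`` array (absolute FWHM in Q, e.g. from a
    data file's 4th column) takes precedence over the constant fraction.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq is None and dq_over_q == 0:
        return reflectivity(stack, q)
    if dq is not None:
        sigma = np.asarray(dq, dtype=float) * _FWHM_TO_SIGMA
    else:
        sigma = q * dq_over_q * _FWHM_TO_SIGMA
    q_eval = q[:, None] + sigma[:, None] * _SMEAR_X[None, :]
    q_eval = np.clip(q_eval, 1e-8, None)
    r_eval = reflectivity(stack, q_eval.ravel()).reshape(q_eval.shape)
    return r_eval @ _SMEAR_W


def smear(curve: ReflectivityCurve, dq_over_q: float) -> ReflectivityCurve:
    """Gaussian-smear a tabulated curve in Q (FWHM/Q = ``dq_over_q``).

    Values beyond the tabulated range are taken from an extrapolation of
    the end values; interior points are interpolated on the tabulated
    grid.  For model curves prefer :func:`smeared_reflectivity`, which
    re-evaluates the exact model at the quadrature points instead.
    """
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0:
        return ReflectivityCurve(curve.q.copy(), curve.r.copy(),
                                 None if curve.dr is None else curve.dr.copy(),
                                 dq_over_q=0.0)
    sigma = curve.q * dq_over_q * _FWHM_TO_SIGMA
    q_eval = curve.q[:, None] + sigma[:, None] * _SMEAR_X[None, :]
    r_interp = np.interp(q_eval, curve.q, curve.r)
    r_sm = r_interp @ _SMEAR_W
    return ReflectivityCurve(curve.q.copy(), r_sm,
                             None if curve.dr is None else curve.dr.copy(),
                             dq_over_q=dq_over_q)
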