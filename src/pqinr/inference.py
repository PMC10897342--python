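"""Simultaneous multi-contrast fitting of reflectivity data.

A :class:`FitProblem` bundles one parametric interfacial model with any
number of (curve, solvent) datasets measured on the same surface.  The
geometry parameters are shared across all contrasts; per-dataset
multiplicative scale and additive background enter as nuisance
parameters (free by default).  The data term is the Gaussian
half-chi-squared

    0.5 * sum_i ((R_model(Q_i) - R_i) / dR_i)^2

with the model smeared at each dataset's resolution.  Priors default to
uniform within bounds; optional normal priors add quadratic terms.
Posterior sampling uses an affine-invariant ensemble sampler (emcee),
initialised in a small ball around the best fit, and 65% credible bands
are central pointwise intervals over the retained draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
import emcee
from scipy import optimize

from .models import (
    PqiABCModelParams,
    PqiCModelParams,
    build_pqiabc_stack,
    build_pqic_stack,
)
from .reflectivity import ReflectivityCurve, smeared_reflectivity
from .sld import ProteinComposition, Solvent

__all__ = [
    "FitProblem",
    "FitResult",
    "PosteriorSamples",
    "SamplerConfig",
    "neg_log_likelihood",
    "fit",
    "sample_posterior",
    "credible_band",
]

_DEFAULT_SCALE_BOUNDS = (0.5, 2.0)
_DEFAULT_BACKGROUND_BOUNDS = (0.0, 1.0e-5)


@dataclass
class FitProblem:
    """A joint multi-contrast fit of one interfacial model.

    Parameters
    ----------
    base_params:
        Model parameter set; fixed parameters keep these values, free
        ones take their start value from here.
    free_names:
        Names of the model parameters to vary (fields of
        ``base_params``), each with finite ``bounds``.
    datasets:
        ``(ReflectivityCurve, Solvent)`` pairs fitted simultaneously.
    fit_nuisance:
        When true (default), append per-dataset ``scale_i`` and
        ``background_i`` free parameters.
    priors:
        Optional normal priors, name -> (mean, sigma); everything else
        is uniform within bounds.
    """

    base_params: PqiCModelParams
    free_names: Sequence[str]
    bounds: dict[str, tuple[float, float]]
    datasets: Sequence[tuple[ReflectivityCurve, Solvent]]
    lipid_variant: str = "deuterated"
    fit_nuisance: bool = True
    priors: dict[str, tuple[float, float]] = field(default_factory=dict)
    protein: ProteinComposition | None = None
    registry: dict | None = None  # component registry override
    scale_bounds: tuple[float, float] = _DEFAULT_SCALE_BOUNDS
    background_bounds: tuple[float, float] = _DEFAULT_BACKGROUND_BOUNDS

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        valid = {f.name for f in fields(self.base_params)}
        for name in self.free_names:
            if name not in valid:
                raise ValueError(f"unknown model parameter {name!r}")
            if name not in self.bounds:
                raise ValueError(f"no bounds given for free parameter {name!r}")
        names = list(self.parameter_names())
        if len(set(names)) != len(names):
            raise ValueError("free parameter names must be unique")
        for name in names:
            lo, hi = self._bound(name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite, lo < hi")

    # -- parameter vector layout -------------------------------------------
    def parameter_names(self) -> list[str]:
        names = list(self.free_names)
        if self.fit_nuisance:
            for i in range(len(self.datasets)):
                names += [f"scale_{i}", f"background_{i}"]
        return names

    def _bound(self, name: str) -> tuple[float, float]:
        if name.startswith("scale_"):
            return self.scale_bounds
        if name.startswith("background_"):
            return self.background_bounds
        return self.bounds[name]

    def bounds_array(self) -> np.ndarray:
        return np.array([self._bound(n) for n in self.parameter_names()])

    def start_vector(self) -> np.ndarray:
        x = [getattr(self.base_params, n) for n in self.free_names]
        if self.fit_nuisance:
            for _ in self.datasets:
                x += [1.0, 0.0]
        x = np.array(x, dtype=float)
        lo, hi = self.bounds_array().T
        return np.clip(x, lo, hi)

    def split_theta(self, theta):
        """(model params object, scales, backgrounds) for one vector."""
        theta = np.asarray(theta, dtype=float)
        nfree = len(self.free_names)
        updates = dict(zip(self.free_names, theta[:nfree]))
        params = replace(self.base_params, **updates)
        nds = len(self.datasets)
        if self.fit_nuisance:
            nuis = theta[nfree:].reshape(nds, 2)
            scales, backgrounds = nuis[:, 0], nuis[:, 1]
        else:
            scales, backgrounds = np.ones(nds), np.zeros(nds)
        return params, scales, backgrounds

    def build_stack(self, params, solvent: Solvent):
        if isinstance(params, PqiABCModelParams):
            return build_pqiabc_stack(params, solvent, protein=self.protein,
                                      registry=self.registry)
        return build_pqic_stack(params, solvent, self.lipid_variant,
                                protein=self.protein, registry=self.registry)

    def model_curves(self, theta) -> list[np.ndarray]:
        """Model reflectivity on each dataset's Q grid (smeared, scaled)."""
        params, scales, backgrounds = self.split_theta(theta)
        out = []
        for (curve, solvent), s, b in zip(self.datasets, scales, backgrounds):
            stack = self.build_stack(params, solvent)
            r = smeared_reflectivity(stack, curve.q, curve.dq_over_q,
                                     dq=curve.dq)
            out.append(s * r + b)
        return out

    def in_bounds(self, theta) -> bool:
        lo, hi = self.bounds_array().T
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= lo) and np.all(theta <= hi))


def neg_log_likelihood(problem: FitProblem, theta) -> float:
    """Negative log posterior up to a constant; +inf outside bounds."""
    if not problem.in_bounds(theta):
        return np.inf
    total = 0.0
    for model_r, (curve, _solvent) in zip(problem.model_curves(theta),
                                          problem.datasets):
        dr = curve.dr if curve.dr is not None else np.ones_like(curve.r)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(dr > 0, (model_r - curve.r) / np.where(dr > 0, dr, 1.0), 0.0)
        total += 0.5 * float(np.sum(z * z))
    names = problem.parameter_names()
    theta = np.asarray(theta, dtype=float)
    for name, (mu, sigma) in problem.priors.items():
        i = names.index(name)
        total += 0.5 * ((theta[i] - mu) / sigma) ** 2
    return total


@dataclass
class FitResult:
    """Best-fit summary of a bounded local optimisation."""

    theta: np.ndarray
    names: list[str]
    nll: float
    chi2_per_point: list[float]
    success: bool
    message: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.theta))


def fit(problem: FitProblem, start=None, seed: int | None = None) -> FitResult:
    """Bounded derivative-free local optimisation of the likelihood.

    Powell's method within the parameter bounds, started from the
    config/base values (or ``start``).  Deterministic given the start
    point; ``seed`` is accepted for interface symmetry and recorded use
    by multi-start callers.  Non-convergence returns the partial result
    with diagnostics rather than raising.
    """
    x0 = np.asarray(start, dtype=float) if start is not None else problem.start_vector()
    lo, hi = problem.bounds_array().T
    span = hi - lo

    # optimise in bounds-normalised space: parameter magnitudes differ by
    # many orders (e.g. thicknesses in tens of Å vs backgrounds ~1e-6)
    def unscale(u):
        return lo + u * span

    u0 = np.clip((x0 - lo) / span, 1e-3, 1.0 - 1e-3)
    # restart Powell from its own optimum until converged: a fresh
    # direction set escapes the correlated valleys between strongly
    # coupled thickness parameters
    best_fun = np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(4):
            res = optimize.minimize(
                lambda u: neg_log_likelihood(problem, unscale(u)),
                u0, method="Powell", bounds=[(0.0, 1.0)] * len(u0),
                options={"xtol": 1e-6, "ftol": 1e-8, "maxiter": 2000},
            )
            improvement = best_fun - res.fun
            best_fun = min(best_fun, res.fun)
            u0 = np.clip(res.x, 0.0, 1.0)
            if improvement < 0.5:
                break
    theta = unscale(np.clip(res.x, 0.0, 1.0))
    chi2 = []
    for model_r, (curve, _s) in zip(problem.model_curves(theta), problem.datasets):
        dr = curve.dr if curve.dr is not None else np.ones_like(curve.r)
        chi2.append(float(np.mean(((model_r - curve.r) / dr) ** 2)))
    return FitResult(theta=theta, names=problem.parameter_names(),
                     nll=float(res.fun), chi2_per_point=chi2,
                     success=bool(res.success), message=str(res.message))


@dataclass
class SamplerConfig:
    """Ensemble MCMC settings; all recorded in output metadata."""

    walkers: int = 64
    steps: int = 5000
    burn_in: int = 1000
    seed: int = 0
    init_ball: float = 1.0e-3  # relative width of the start ball

    def __post_init__(self) -> None:
        if self.steps <= self.burn_in:
            raise ValueError("steps must exceed burn_in")


@dataclass
class PosteriorSamples:
    """Flattened post-burn-in MCMC draws with sampler metadata."""

    draws: np.ndarray
    log_probs: np.ndarray
    names: list[str]
    metadata: dict

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]


def sample_posterior(problem: FitProblem, config: SamplerConfig,
                     start=None) -> PosteriorSamples:
    """Ensemble MCMC over the posterior.

    Walkers start in a small relative ball around ``start`` (default the
    problem's start vector — normally a prior best fit), jittered within
    bounds; the burn-in portion of every chain is discarded.  Identical
    seeds give identical draws.
    """
    ndim = len(problem.parameter_names())
    if config.walkers < 2 * ndim:
        raise ValueError(f"need >= {2 * ndim} walkers for {ndim} parameters")
    x0 = np.asarray(start, dtype=float) if start is not None else problem.start_vector()
    lo, hi = problem.bounds_array().T
    rng = np.random.RandomState(config.seed)
    span = hi - lo
    p0 = x0[None, :] + config.init_ball * span[None, :] * rng.randn(config.walkers, ndim)
    p0 = np.clip(p0, lo + 1e-12 * span, hi - 1e-12 * span)

    def log_prob(th):
        return -neg_log_likelihood(problem, th)

    sampler = emcee.EnsembleSampler(config.walkers, ndim, log_prob)
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(p0, config.steps, progress=False)
    chain = sampler.get_chain(discard=config.burn_in, flat=True)
    logp = sampler.get_log_prob(discard=config.burn_in, flat=True)
    acc = float(np.mean(sampler.acceptance_fraction))
    metadata = {
        "walkers": config.walkers,
        "steps": config.steps,
        "burn_in": config.burn_in,
        "seed": config.seed,
        "acceptance_fraction": acc,
    }
    if not 0.1 <= acc <= 0.9:
        metadata["warning"] = (
            f"mean acceptance fraction {acc:.3f} outside [0.1, 0.9]; "
            "chains may be poorly tuned")
    return PosteriorSamples(draws=chain, log_probs=logp,
                            names=problem.parameter_names(), metadata=metadata)


def credible_band(samples: PosteriorSamples,
                  functional: Callable[[np.ndarray], np.ndarray] | str,
                  level: float = 0.65):
    """Central pointwise credible interval of a functional over draws.

    ``functional`` maps one parameter vector to a scalar or array (a
    parameter name string selects that parameter directly).  Returns
    ``(lower, upper)`` at the central ``level`` mass.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if samples.draws.size == 0:
        raise ValueError("no posterior draws")
    if isinstance(functional, str):
        values = samples.parameter(functional)
    else:
        values = np.array([np.asarray(functional(th)) for th in samples.draws])
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(values, alpha, axis=0)
    upper = np.quantile(values, 1.0 - alpha, axis=0)
    return lower, upper
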