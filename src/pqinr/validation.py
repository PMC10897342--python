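"""Round-trip validation harnesses: simulate -> fit -> compare.

The simulate/fit round trip on the built-in scenarios is the pipeline's
principal self-check: data are generated from known ground truth under
the four solvent contrasts, jointly fitted from deliberately displaced
start values, and the recovered structural parameters compared with the
truth.  `credible_coverage` repeats the round trip over independent
noise realisations and counts how often the central credible interval
brackets the truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .inference import (FitProblem, FitResult, SamplerConfig, credible_band,
                        fit, sample_posterior)
from .models import PqiABCModelParams
from .synthetic import ExperimentScenario, builtin_scenarios, simulate_experiment

__all__ = ["DEFAULT_BOUNDS", "DEFAULT_START_OFFSETS", "recovery_problem",
           "recovery_fit", "credible_coverage"]

# Fit bounds for the structural parameters of the built-in scenarios.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "apm": (45.0, 80.0),
    "pqic_thickness": (20.0, 90.0),
    "pqic_volume_fraction": (0.0, 0.6),
    "bilayer_coverage": (0.5, 1.0),
    "head_hydration": (0.0, 0.8),
    "pqib_thickness": (150.0, 320.0),
    "pqib_volume_fraction": (0.0, 0.6),
    "distal_thickness": (10.0, 120.0),
    "hdmpc_mixing_fraction": (0.0, 0.6),
}

# Deliberate displacements of the fit start away from the truth (the
# optimiser must find its way back; starting at the truth would prove
# nothing).
DEFAULT_START_OFFSETS: dict[str, float] = {
    "apm": 3.0,
    "pqic_thickness": -8.0,
    "pqic_volume_fraction": -0.07,
    "bilayer_coverage": -0.05,
    "pqib_thickness": -15.0,
    "pqib_volume_fraction": -0.03,
}


def _default_free_names(scenario: ExperimentScenario) -> list[str]:
    names = ["apm", "pqic_thickness", "pqic_volume_fraction",
             "bilayer_coverage"]
    if isinstance(scenario.truth, PqiABCModelParams):
        names += ["pqib_thickness", "pqib_volume_fraction"]
    return names


def recovery_problem(scenario: ExperimentScenario,
                     data=None,
                     free_names=None,
                     fit_nuisance: bool = True) -> FitProblem:
    """Build the joint fit problem for a scenario's simulated data.

    The start values are the scenario truth displaced by
    :data:`DEFAULT_START_OFFSETS` (clipped to bounds).
    """
    if data is None:
        data = simulate_experiment(scenario)
    free = list(free_names) if free_names else _default_free_names(scenario)
    start_updates = {}
    for name in free:
        off = DEFAULT_START_OFFSETS.get(name, 0.0)
        lo, hi = DEFAULT_BOUNDS[name]
        start_updates[name] = float(np.clip(getattr(scenario.truth, name) + off,
                                            lo, hi))
    start_params = replace(scenario.truth, **start_updates)
    return FitProblem(
        base_params=start_params,
        free_names=free,
        bounds={n: DEFAULT_BOUNDS[n] for n in free},
        datasets=data,
        lipid_variant=scenario.lipid_variant,
        fit_nuisance=fit_nuisance,
    )


def recovery_fit(scenario: ExperimentScenario, free_names=None,
                 fit_nuisance: bool = True) -> tuple[FitProblem, FitResult, dict]:
    """Simulate, fit, and report recovered-vs-truth parameter errors."""
    problem = recovery_problem(scenario, free_names=free_names,
                               fit_nuisance=fit_nuisance)
    result = fit(problem)
    best = result.as_dict()
    errors = {n: best[n] - getattr(scenario.truth, n)
              for n in problem.free_names}
    return problem, result, errors


def credible_coverage(scenario_name: str = "bilayer_pqic",
                      parameter: str = "pqic_thickness",
                      n_replicates: int = 20,
                      level: float = 0.65,
                      n_points: int = 60,
                      free_names=("apm", "pqic_thickness",
                                  "pqic_volume_fraction"),
                      walkers: int = 16,
                      steps: int = 200,
                      burn_in: int = 70,
                      seed: int = 0) -> dict:
    """Fraction of replicates whose credible interval brackets the truth.

    Each replicate re-simulates the named built-in scenario with an
    independent noise seed, fits it, samples the posterior with short
    ensemble chains, and checks whether the central ``level`` interval
    of ``parameter`` contains the true value.
    """
    base = builtin_scenarios()[scenario_name]
    truth_value = getattr(base.truth, parameter)
    covered = 0
    intervals = []
    for rep in range(n_replicates):
        scenario = replace(base, seed=seed + 1000 + rep, n_points=n_points)
        problem = recovery_problem(scenario, free_names=free_names,
                                   fit_nuisance=False)
        best = fit(problem)
        config = SamplerConfig(walkers=walkers, steps=steps, burn_in=burn_in,
                               seed=seed + rep, init_ball=2e-3)
        samples = sample_posterior(problem, config, start=best.theta)
        lo, hi = credible_band(samples, parameter, level=level)
        intervals.append((float(lo), float(hi)))
        if lo <= truth_value <= hi:
            covered += 1
    return {
        "parameter": parameter,
        "truth": truth_value,
        "level": level,
        "n_replicates": n_replicates,
        "covered": covered,
        "coverage": covered / n_replicates,
        "intervals": intervals,
    }
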