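"""Ground-truth experiment generator for the reflectometry pipeline.

Emulates time-of-flight reflectometer measurements of the supported-
bilayer assembly stages: for a known layer model the exact reflectivity
is computed per solvent contrast, smeared at the instrument resolution
(dQ/Q = 3.5%), and perturbed with Gaussian noise whose relative width
has a floor and grows as the reflectivity approaches the instrument
background.  The stored ``dr`` column holds the true noise sigma, so
(data - model) / dr is standard normal by construction.

The built-in scenario catalogue mirrors the four assembly stages of the
measured system — bare substrate, protein-free bilayer, bilayer with
the PqiC lipoprotein layer (50 Å), and the full PqiABC trans-envelope
structure (230 Å spanning layer) — each at the four solvent contrasts
(D2O, 80% D2O, protein-matched water, H2O).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .models import (
    PqiABCModelParams,
    PqiCModelParams,
    build_pqiabc_stack,
    build_pqic_stack,
)
from .reflectivity import ReflectivityCurve, smeared_reflectivity
from .sld import Solvent

__all__ = ["ExperimentScenario", "simulate_experiment", "builtin_scenarios",
           "PAPER_CONTRASTS", "INSTRUMENT_BACKGROUND"]

#: The four solvent contrasts of the measured system (D2O fractions).
PAPER_CONTRASTS = (1.0, 0.8, 0.42, 0.0)

#: Reflectivity level at which counting noise dominates.
INSTRUMENT_BACKGROUND = 1.0e-7


@dataclass(frozen=True)
class ExperimentScenario:
    """One simulated contrast-variation experiment with known truth."""

    name: str
    truth: PqiCModelParams
    contrasts: Sequence[float] = PAPER_CONTRASTS
    q_min: float = 0.01
    q_max: float = 0.3
    n_points: int = 90
    dq_over_q: float = 0.035
    noise_floor: float = 0.01
    seed: int = 0
    lipid_variant: str = "deuterated"

    def __post_init__(self) -> None:
        if not (0.0 < self.q_min < self.q_max <= 1.0):
            raise ValueError("q range must satisfy 0 < q_min < q_max <= 1")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")

    def q_grid(self) -> np.ndarray:
        return np.geomspace(self.q_min, self.q_max, self.n_points)


def _noise_sigma(r_model: np.ndarray, noise_floor: float) -> np.ndarray:
    """Absolute 1-sigma noise: relative floor inflated near background."""
    rel = noise_floor * np.sqrt(1.0 + INSTRUMENT_BACKGROUND
                                / np.maximum(r_model, INSTRUMENT_BACKGROUND))
    return rel * np.maximum(r_model, INSTRUMENT_BACKGROUND)


def simulate_experiment(scenario: ExperimentScenario,
                        ) -> list[tuple[ReflectivityCurve, Solvent]]:
    """Simulate one curve per contrast from the scenario's ground truth.

    Returns ``(curve, solvent)`` pairs in the scenario's contrast order.
    With ``noise_floor = 0`` the curves equal the smeared model exactly;
    otherwise a Gaussian perturbation with the recorded sigma is drawn
    from the scenario seed (identical seeds give identical data).
    """
    rng = np.random.default_rng(scenario.seed)
    out = []
    for f_d2o in scenario.contrasts:
        solvent = Solvent(f_d2o)
        if isinstance(scenario.truth, PqiABCModelParams):
            stack = build_pqiabc_stack(scenario.truth, solvent)
        else:
            stack = build_pqic_stack(scenario.truth, solvent,
                                     scenario.lipid_variant)
        q = scenario.q_grid()
        r_model = smeared_reflectivity(stack, q, scenario.dq_over_q)
        sigma = _noise_sigma(r_model, scenario.noise_floor)
        r = r_model + sigma * rng.standard_normal(q.shape) \
            if scenario.noise_floor > 0 else r_model.copy()
        curve = ReflectivityCurve(q=q, r=r, dr=sigma,
                                  dq_over_q=scenario.dq_over_q)
        out.append((curve, solvent))
    return out


# Ground truth parameter sets for the built-in catalogue.  Values are
# typical of high-coverage DMPC bilayers on piranha-cleaned silicon with
# a thin native oxide; the protein layer thicknesses carry the measured
# system's geometry (50 Å lipoprotein slab, 230 Å spanning protein).
_BILAYER_TRUTH = PqiCModelParams(
    sio2_thickness=12.0, sio2_hydration=0.10,
    apm=60.0, head_hydration=0.35, tail_hydration=0.05,
    bilayer_coverage=0.95,
    pqic_thickness=50.0, pqic_volume_fraction=0.0,
)
_PQIC_TRUTH = replace(_BILAYER_TRUTH, pqic_volume_fraction=0.25)
_PQIABC_TRUTH = PqiABCModelParams(
    **{f: getattr(_PQIC_TRUTH, f) for f in (
        "sio2_thickness", "sio2_hydration", "apm", "head_hydration",
        "tail_hydration", "bilayer_coverage", "pqic_thickness",
        "pqic_volume_fraction")},
    pqib_thickness=230.0, pqib_volume_fraction=0.15,
    distal_thickness=45.0, distal_protein_fraction=0.20,
    distal_lipid_fraction=0.40, hdmpc_mixing_fraction=0.15,
)
# a bare substrate is the bilayer model with zero coverage and protein
_BARE_TRUTH = replace(_BILAYER_TRUTH, bilayer_coverage=0.0,
                      pqic_volume_fraction=0.0, head_hydration=1.0,
                      tail_hydration=1.0)


def builtin_scenarios() -> dict[str, ExperimentScenario]:
    """Catalogue of the four assembly-stage scenarios."""
    return {
        "bare_substrate": ExperimentScenario("bare_substrate", _BARE_TRUTH,
                                             seed=101),
        "bilayer": ExperimentScenario("bilayer", _BILAYER_TRUTH, seed=102),
        "bilayer_pqic": ExperimentScenario("bilayer_pqic", _PQIC_TRUTH,
                                           seed=103),
        "pqiabc": ExperimentScenario("pqiabc", _PQIABC_TRUTH, seed=104),
    }
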