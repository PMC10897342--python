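"""Parametric interfacial models of protein-decorated supported bilayers.

Two bespoke structures are provided:

* a five-layer model of a deuterated DMPC bilayer on silicon with a
  lipoprotein (PqiC) layer intercalated into the outer headgroups:
  SiO2 | inner heads | tails | tails | outer heads+PqiC overlap region,
  ordered substrate -> solution, and
* a seven-layer model extending it with a thick diffuse periplasmic-
  spanning protein (PqiB) layer and a distal mixed protein/lipid (PqiA +
  hydrogenous DMPC) layer, completing a trans-envelope double-membrane
  system.

The geometry is shared across solvent contrasts: for fixed parameters
only the SLDs change with the solvent, never thicknesses, roughnesses or
volume fractions.  Head and tail thicknesses are not free parameters:
they derive from the fitted area per lipid molecule via
thickness = component volume / APM, which pins the head:tail molar ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import erf

from .sld import (
    COMPONENT_REGISTRY,
    SLD_SILICON,
    SLD_SILICON_OXIDE,
    ProteinComposition,
    Solvent,
    component_sld,
    layer_thickness_from_apm,
    protein_sld,
)
from .reflectivity import Layer, LayerStack

__all__ = [
    "PqiCModelParams",
    "PqiABCModelParams",
    "VolumeFractionProfile",
    "build_pqic_stack",
    "build_pqiabc_stack",
    "volume_fraction_profile",
    "sld_profile_from_params",
    "intermembrane_distance",
]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class PqiCModelParams:
    """Parameters of the five-layer bilayer + lipoprotein model.

    Hydration fractions are the water volume fractions *within* the
    covered membrane area; ``bilayer_coverage`` scales the lipid
    occupancy of the whole plane (the residual area is solvent).  The
    protein layer is a single uniform slab of ``pqic_volume_fraction``
    protein in solvent.  Roughnesses name the substrate-side interface
    of each region; ``solvent_roughness`` is the final interface to bulk.
    """

    sio2_thickness: float = 12.0
    sio2_hydration: float = 0.10
    apm: float = 60.0
    head_hydration: float = 0.35
    tail_hydration: float = 0.05
    bilayer_coverage: float = 0.95
    pqic_thickness: float = 50.0
    pqic_volume_fraction: float = 0.25
    substrate_roughness: float = 3.0
    sio2_roughness: float = 3.0
    bilayer_roughness: float = 3.5
    pqic_roughness: float = 4.0
    solvent_roughness: float = 5.0

    def __post_init__(self) -> None:
        for name in ("sio2_hydration", "head_hydration", "tail_hydration",
                     "bilayer_coverage", "pqic_volume_fraction"):
            _check_fraction(name, getattr(self, name))
        if self.apm <= 0:
            raise ValueError("apm must be > 0")
        for name in ("sio2_thickness", "pqic_thickness", "substrate_roughness",
                     "sio2_roughness", "bilayer_roughness", "pqic_roughness",
                     "solvent_roughness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PqiABCModelParams(PqiCModelParams):
    """Seven-layer trans-envelope extension of :class:`PqiCModelParams`.

    Adds a diffuse periplasmic protein layer (PqiB), a distal mixed
    protein/lipid layer (PqiA + hydrogenous DMPC), and the fraction of
    hydrogenous DMPC mixed into the proximal deuterated bilayer.
    """

    pqib_thickness: float = 230.0
    pqib_volume_fraction: float = 0.15
    #: SLD of the spanning-protein material; None ties it to the shared
    #: protein composition (volume fraction stays free either way)
    pqib_sld: float | None = None
    distal_thickness: float = 45.0
    distal_protein_fraction: float = 0.20
    distal_lipid_fraction: float = 0.40
    hdmpc_mixing_fraction: float = 0.0
    pqib_roughness: float = 8.0
    distal_roughness: float = 8.0

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("pqib_volume_fraction", "distal_protein_fraction",
                     "distal_lipid_fraction", "hdmpc_mixing_fraction"):
            _check_fraction(name, getattr(self, name))
        if self.distal_protein_fraction + self.distal_lipid_fraction > 1.0 + 1e-9:
            raise ValueError("distal protein + lipid fractions exceed 1")
        for name in ("pqib_thickness", "distal_thickness",
                     "pqib_roughness", "distal_roughness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Default protein composition used for the PqiC/PqiB layer SLDs.  The
# PqiB layer SLD is tied to the same protein composition by default
# (free only through its volume fraction).
_DEFAULT_PROTEIN = ProteinComposition.average_protein()


def _mix(solvent_sld_value: float, component_sld_value: float,
         component_fraction: float) -> float:
    """Convex SLD mix of a component with solvent filling the rest."""
    return (component_fraction * component_sld_value
            + (1.0 - component_fraction) * solvent_sld_value)


def _bilayer_slds(params: PqiCModelParams, solvent: Solvent,
                  lipid_variant: str, hdmpc_mixing: float = 0.0,
                  registry: Mapping | None = None) -> tuple[float, float]:
    """(head layer SLD, tail layer SLD) after hydration/coverage mixing."""
    reg = registry or COMPONENT_REGISTRY
    deuterated = {"deuterated": True, "hydrogenous": False}[lipid_variant]
    head_sld = component_sld(reg["dmpc_head"], deuterated=False)
    tail_d = component_sld(reg["dmpc_tails"], deuterated=deuterated)
    tail_h = component_sld(reg["dmpc_tails"], deuterated=False)
    # hydrogenous lipid mixed into the (deuterated) proximal bilayer acts
    # on the tails only; headgroup b-sums are isotope-identical here
    tail_sld = (1.0 - hdmpc_mixing) * tail_d + hdmpc_mixing * tail_h
    head_frac = params.bilayer_coverage * (1.0 - params.head_hydration)
    tail_frac = params.bilayer_coverage * (1.0 - params.tail_hydration)
    return (_mix(solvent.sld, head_sld, head_frac),
            _mix(solvent.sld, tail_sld, tail_frac))


def _layer_geometry(params: PqiCModelParams,
                    registry: Mapping | None = None) -> tuple[float, float]:
    """(head thickness, per-leaflet tail thickness) from the shared APM."""
    reg = registry or COMPONENT_REGISTRY
    d_head = layer_thickness_from_apm(reg["dmpc_head"].molecular_volume, params.apm)
    d_tail = layer_thickness_from_apm(reg["dmpc_tails"].molecular_volume, params.apm)
    if d_tail <= 0:
        raise ValueError("derived tail thickness must be > 0")
    return d_head, d_tail


def build_pqic_stack(params: PqiCModelParams, solvent: Solvent,
                     lipid_variant: str = "deuterated",
                     protein: ProteinComposition | None = None,
                     registry: Mapping | None = None,
                     hdmpc_mixing: float = 0.0) -> LayerStack:
    """Render the five-layer model for one solvent contrast.

    Layers, substrate -> solution: SiO2, inner heads, tail leaflet,
    tail leaflet, outer heads, protein.  (The protein slab is the model's
    fifth *structural* region; the two tail leaflets share one region.)
    """
    comp = protein or _DEFAULT_PROTEIN
    d_head, d_tail = _layer_geometry(params, registry)
    head_sld, tail_sld = _bilayer_slds(params, solvent, lipid_variant,
                                       hdmpc_mixing, registry)
    sio2_sld = _mix(solvent.sld, SLD_SILICON_OXIDE, 1.0 - params.sio2_hydration)
    pqic_sld = _mix(solvent.sld, protein_sld(comp, solvent.f_d2o),
                    params.pqic_volume_fraction)
    layers = [
        Layer(params.sio2_thickness, sio2_sld, params.substrate_roughness),
        Layer(d_head, head_sld, params.sio2_roughness),
        Layer(d_tail, tail_sld, params.bilayer_roughness),
        Layer(d_tail, tail_sld, params.bilayer_roughness),
        Layer(d_head, head_sld, params.bilayer_roughness),
        Layer(params.pqic_thickness, pqic_sld, params.pqic_roughness),
    ]
    return LayerStack(SLD_SILICON, layers, solvent.sld, params.solvent_roughness)


def build_pqiabc_stack(params: PqiABCModelParams, solvent: Solvent,
                       protein: ProteinComposition | None = None,
                       registry: Mapping | None = None) -> LayerStack:
    """Render the seven-layer trans-envelope model for one contrast."""
    comp = protein or _DEFAULT_PROTEIN
    base = build_pqic_stack(params, solvent, "deuterated", comp, registry,
                            hdmpc_mixing=params.hdmpc_mixing_fraction)
    reg = registry or COMPONENT_REGISTRY
    prot_sld = protein_sld(comp, solvent.f_d2o)
    pqib_material = params.pqib_sld if params.pqib_sld is not None else prot_sld
    pqib_sld = _mix(solvent.sld, pqib_material, params.pqib_volume_fraction)
    # distal mixed layer: protein + hydrogenous lipid + solvent
    lip_vol = (reg["dmpc_head"].molecular_volume
               + reg["dmpc_tails"].molecular_volume)
    lip_sld = ((reg["dmpc_head"].sum_b() + reg["dmpc_tails"].sum_b()) / lip_vol)
    solv_frac = 1.0 - params.distal_protein_fraction - params.distal_lipid_fraction
    distal_sld = (params.distal_protein_fraction * prot_sld
                  + params.distal_lipid_fraction * lip_sld
                  + solv_frac * solvent.sld)
    layers = list(base.layers) + [
        Layer(params.pqib_thickness, pqib_sld, params.pqib_roughness),
        Layer(params.distal_thickness, distal_sld, params.distal_roughness),
    ]
    return LayerStack(SLD_SILICON, layers, solvent.sld, params.solvent_roughness)


# ---------------------------------------------------------------------------
# Volume fraction profiles
# ---------------------------------------------------------------------------

@dataclass
class VolumeFractionProfile:
    """Component occupancies vs distance from the substrate surface.

    Fractions sum to 1 at every z; ``components`` maps component name to
    its fraction array on ``z``.
    """

    z: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def solvent(self) -> np.ndarray:
        total = sum(self.components.values())
        return 1.0 - total


def _smeared_box(z: np.ndarray, z0: float, z1: float,
                 sigma0: float, sigma1: float) -> np.ndarray:
    """Error-function smeared boxcar occupying [z0, z1]."""
    lo = (0.5 * (1.0 + erf((z - z0) / (np.sqrt(2.0) * sigma0)))
          if sigma0 > 0 else (z >= z0).astype(float))
    hi = (0.5 * (1.0 + erf((z - z1) / (np.sqrt(2.0) * sigma1)))
          if sigma1 > 0 else (z >= z1).astype(float))
    return lo - hi


def _stack_regions(params: PqiCModelParams,
                   registry: Mapping | None = None):
    """(name, z0, z1, sigma0, sigma1, occupancies) per structural slab.

    ``occupancies`` maps component labels to the non-solvent volume
    fraction each contributes within the slab.
    """
    d_head, d_tail = _layer_geometry(params, registry)
    cov = params.bilayer_coverage
    head_occ = cov * (1.0 - params.head_hydration)
    tail_occ = cov * (1.0 - params.tail_hydration)
    z = 0.0
    specs = [
        ("oxide", params.sio2_thickness,
         {"oxide": 1.0 - params.sio2_hydration}),
        ("inner_heads", d_head, {"heads": head_occ}),
        ("tails", 2 * d_tail, {"tails": tail_occ}),
        ("outer_heads", d_head, {"heads": head_occ}),
        ("pqic", params.pqic_thickness,
         {"pqic": params.pqic_volume_fraction}),
    ]
    if isinstance(params, PqiABCModelParams):
        specs += [
            ("pqib", params.pqib_thickness,
             {"pqib": params.pqib_volume_fraction}),
            ("distal", params.distal_thickness,
             {"distal_protein": params.distal_protein_fraction,
              "distal_lipid": params.distal_lipid_fraction}),
        ]
    # each region carries its substrate-side interface roughness; the
    # solution-side width is the next region's (or the bulk-solvent one)
    regions = []
    subs_side = [params.substrate_roughness, params.sio2_roughness,
                 params.bilayer_roughness, params.bilayer_roughness,
                 params.pqic_roughness]
    if isinstance(params, PqiABCModelParams):
        subs_side += [params.pqib_roughness, params.distal_roughness]
    solution_side = subs_side[1:] + [params.solvent_roughness]
    for (name, thickness, occ), s0, s1 in zip(specs, subs_side, solution_side):
        z1 = z + thickness
        regions.append((name, z, z1, s0, s1, occ))
        z = z1
    return regions


def volume_fraction_profile(params: PqiCModelParams, z_grid,
                            registry: Mapping | None = None) -> VolumeFractionProfile:
    """Component volume fractions across the interface.

    Each slab's occupancy is rendered as an error-function smeared boxcar
    with the slab's interfacial roughnesses; the substrate occupies
    everything below z = 0 and solvent fills the residual volume.
    """
    z = np.asarray(z_grid, dtype=float)
    if z.ndim != 1 or np.any(np.diff(z) <= 0):
        raise ValueError("z grid must be one-dimensional and increasing")
    regions = _stack_regions(params, registry)
    comps: dict[str, np.ndarray] = {}

    sub_sigma = params.substrate_roughness
    substrate = (0.5 * (1.0 - erf(z / (np.sqrt(2.0) * sub_sigma)))
                 if sub_sigma > 0 else (z < 0).astype(float))
    comps["substrate"] = substrate
    for name, z0, z1, s0, s1, occ in regions:
        box = _smeared_box(z, z0, z1, s0, s1)
        for comp_name, frac in occ.items():
            comps[comp_name] = comps.get(comp_name, np.zeros_like(z)) + frac * box
    profile = VolumeFractionProfile(z=z, components=comps)
    return profile


def sld_profile_from_params(params: PqiCModelParams, solvent: Solvent, z_grid,
                            lipid_variant: str = "deuterated",
                            protein: ProteinComposition | None = None,
                            registry: Mapping | None = None) -> np.ndarray:
    """Real-space SLD profile implied by the volume fractions.

    Weighted sum of component SLDs over the profile; by construction this
    equals the erf-smeared slab SLD profile of the rendered stack.
    """
    comp = protein or _DEFAULT_PROTEIN
    reg = registry or COMPONENT_REGISTRY
    prof = volume_fraction_profile(params, z_grid, registry)
    deuterated = {"deuterated": True, "hydrogenous": False}[lipid_variant]
    mixing = getattr(params, "hdmpc_mixing_fraction", 0.0)
    tail_d = component_sld(reg["dmpc_tails"], deuterated=deuterated)
    tail_h = component_sld(reg["dmpc_tails"], deuterated=False)
    lip_vol = (reg["dmpc_head"].molecular_volume
               + reg["dmpc_tails"].molecular_volume)
    comp_slds = {
        "substrate": SLD_SILICON,
        "oxide": SLD_SILICON_OXIDE,
        "heads": component_sld(reg["dmpc_head"]),
        "tails": (1.0 - mixing) * tail_d + mixing * tail_h,
        "pqic": protein_sld(comp, solvent.f_d2o),
        "pqib": (getattr(params, "pqib_sld", None)
                 if getattr(params, "pqib_sld", None) is not None
                 else protein_sld(comp, solvent.f_d2o)),
        "distal_protein": protein_sld(comp, solvent.f_d2o),
        "distal_lipid": (reg["dmpc_head"].sum_b() + reg["dmpc_tails"].sum_b()) / lip_vol,
    }
    sld = prof.solvent() * solvent.sld
    for name, frac in prof.components.items():
        sld = sld + frac * comp_slds[name]
    return sld


def intermembrane_distance(params: PqiABCModelParams) -> float:
    """Separation between the two membrane regions, Å.

    Defined as the span from the solution-side boundary of the proximal
    bilayer's outer headgroups to the substrate-side boundary of the
    distal lipid layer: the PqiC slab plus the PqiB slab.  This endpoint
    convention is recorded in report metadata; hydration parameters do
    not enter.
    """
    return params.pqic_thickness + params.pqib_thickness
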