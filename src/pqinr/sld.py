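"""Scattering-length density (SLD) bookkeeping for membrane/protein interfaces.

Everything downstream of the reflectivity kernel is driven by coherent
neutron scattering lengths.  This module holds the small constant tables
(bound coherent scattering lengths, lipid component volumes, per-residue
protein data) and the conversions between molecular composition and SLD:

* solvent SLD as a linear isotopic H2O/D2O mixture,
* component SLD = sum(b) / molecular volume,
* protein SLD with labile-hydrogen exchange proportional to the solvent
  D2O fraction, and the resulting protein match point,
* layer thickness from area per molecule (thickness = V / APM).

Units: lengths in Å, volumes in Å^3, scattering lengths in Å
(1 fm = 1e-5 Å), SLD in Å^-2.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "B_COHERENT_FM",
    "FM_TO_ANG",
    "WATER_VOLUME",
    "SLD_SILICON",
    "SLD_SILICON_OXIDE",
    "ScatteringComponent",
    "Solvent",
    "ProteinComposition",
    "COMPONENT_REGISTRY",
    "formula_sum_b",
    "solvent_sld",
    "component_sld",
    "protein_sld",
    "match_point",
    "layer_thickness_from_apm",
]

# Bound coherent scattering lengths, fm (Sears compilation).
B_COHERENT_FM: Mapping[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
    "S": 2.847,
    "Si": 4.1491,
}

FM_TO_ANG = 1.0e-5

#: Molecular volume of one water molecule, Å^3 (shared by both isotopes).
WATER_VOLUME = 30.0

#: Semi-infinite substrate SLDs, Å^-2 (crystalline Si and its native oxide).
SLD_SILICON = 2.07e-6
SLD_SILICON_OXIDE = 3.47e-6

B_D_MINUS_B_H = (B_COHERENT_FM["D"] - B_COHERENT_FM["H"]) * FM_TO_ANG


def formula_sum_b(formula: Mapping[str, float]) -> float:
    """Total coherent scattering length of a formula, in Å.

    ``formula`` maps element symbols (``"D"`` allowed) to atom counts.
    """
    try:
        return sum(B_COHERENT_FM[el] * n for el, n in formula.items()) * FM_TO_ANG
    except KeyError as exc:  # pragma: no cover - guard
        raise KeyError(f"no scattering length tabulated for element {exc}") from exc


@dataclass(frozen=True)
class ScatteringComponent:
    """A molecular fragment with known volume and scattering lengths.

    Parameters
    ----------
    name:
        Label used in registries and reports.
    molecular_volume:
        Component molecular volume, Å^3. Must be positive.
    sum_b_h:
        Total coherent scattering length of the fully hydrogenous form, Å.
    n_labile_h:
        Solvent-exchangeable hydrogens (exchange with the D2O fraction).
    n_nonlabile_substitutable_h:
        Hydrogens replaced by deuterium in the chemically deuterated
        variant (e.g. the 54 acyl hydrogens of d54-DMPC tails).
    """

    name: str
    molecular_volume: float
    sum_b_h: float
    n_labile_h: int = 0
    n_nonlabile_substitutable_h: int = 0

    def __post_init__(self) -> None:
        if self.molecular_volume <= 0:
            raise ValueError(f"{self.name}: molecular_volume must be > 0")
        if self.n_labile_h < 0 or self.n_nonlabile_substitutable_h < 0:
            raise ValueError(f"{self.name}: hydrogen counts must be >= 0")

    def sum_b(self, deuterated: bool = False) -> float:
        """Σb in Å for the hydrogenous or deuterated variant."""
        if deuterated:
            return self.sum_b_h + self.n_nonlabile_substitutable_h * B_D_MINUS_B_H
        return self.sum_b_h


def _component_from_formula(
    name: str,
    formula: Mapping[str, float],
    volume: float,
    n_labile_h: int = 0,
    n_substitutable: int = 0,
) -> ScatteringComponent:
    return ScatteringComponent(
        name=name,
        molecular_volume=volume,
        sum_b_h=formula_sum_b(formula),
        n_labile_h=n_labile_h,
        n_nonlabile_substitutable_h=n_substitutable,
    )


# DMPC split into headgroup (phosphocholine + glycerol backbone + carbonyls,
# C10H18NO8P) and the pair of myristoyl tails (2 x C13H27).  Literature SLB
# volumes; overridable via config (cli module).  The d54 variant substitutes
# all 54 tail hydrogens.
COMPONENT_REGISTRY: dict[str, ScatteringComponent] = {
    "dmpc_head": _component_from_formula(
        "dmpc_head", {"C": 10, "H": 18, "N": 1, "O": 8, "P": 1}, 319.0
    ),
    "dmpc_tails": _component_from_formula(
        "dmpc_tails", {"C": 26, "H": 54}, 782.0, n_substitutable=54
    ),
    "water": _component_from_formula("water", {"H": 2, "O": 1}, WATER_VOLUME,
                                     n_labile_h=2),
}


def solvent_sld(f_d2o: float) -> float:
    """SLD of an H2O/D2O mixture, Å^-2, linear in the D2O volume fraction."""
    if not 0.0 <= f_d2o <= 1.0:
        raise ValueError(f"f_d2o must lie in [0, 1], got {f_d2o}")
    b_h2o = formula_sum_b({"H": 2, "O": 1})
    b_d2o = formula_sum_b({"D": 2, "O": 1})
    sld_h2o = b_h2o / WATER_VOLUME
    sld_d2o = b_d2o / WATER_VOLUME
    return (1.0 - f_d2o) * sld_h2o + f_d2o * sld_d2o


@dataclass(frozen=True)
class Solvent:
    """An isotopic water contrast, identified by its D2O volume fraction."""

    f_d2o: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_d2o <= 1.0:
            raise ValueError(f"f_d2o must lie in [0, 1], got {self.f_d2o}")

    @property
    def sld(self) -> float:
        return solvent_sld(self.f_d2o)


def component_sld(component: ScatteringComponent, deuterated: bool = False) -> float:
    """SLD of a component: Σb / molecular volume (Å^-2)."""
    return component.sum_b(deuterated) / component.molecular_volume


# ---------------------------------------------------------------------------
# Protein compositions
# ---------------------------------------------------------------------------

# Residue (amino acid minus water) chemical formulas.
RESIDUE_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
}

# Residue volumes in the folded protein, Å^3 (Zamyatnin-type consensus).
RESIDUE_VOLUMES: Mapping[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Labile (solvent-exchangeable) hydrogens per residue: the backbone amide
# plus side-chain OH/NH/SH protons (Pro has no amide H).
RESIDUE_LABILE_H: Mapping[str, int] = {
    "A": 1, "R": 6, "N": 3, "D": 1, "C": 2,
    "Q": 3, "E": 1, "G": 1, "H": 2, "I": 1,
    "L": 1, "K": 3, "M": 1, "F": 1, "P": 0,
    "S": 2, "T": 2, "W": 2, "Y": 2, "V": 1,
}

# Average residue frequencies of globular proteins (fraction per residue),
# used for the generic "average protein" match-point estimate.
AVERAGE_RESIDUE_FREQUENCIES: Mapping[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class ProteinComposition:
    """Amino-acid composition with derived scattering totals.

    ``sum_b_nonexchanged`` is the all-hydrogenous Σb (labile hydrogens
    counted as H); labile exchange is added on top by :func:`protein_sld`.
    Counts may be fractional (e.g. an average composition).
    """

    residue_counts: Mapping[str, float]
    total_volume: float = field(init=False)
    sum_b_nonexchanged: float = field(init=False)
    n_labile_h: float = field(init=False)

    def __post_init__(self) -> None:
        unknown = set(self.residue_counts) - set(RESIDUE_FORMULAS)
        if unknown:
            raise ValueError(f"unknown residues: {sorted(unknown)}")
        if not self.residue_counts or sum(self.residue_counts.values()) <= 0:
            raise ValueError("composition must contain at least one residue")
        vol = sum(RESIDUE_VOLUMES[r] * n for r, n in self.residue_counts.items())
        sb = sum(formula_sum_b(RESIDUE_FORMULAS[r]) * n
                 for r, n in self.residue_counts.items())
        nl = sum(RESIDUE_LABILE_H[r] * n for r, n in self.residue_counts.items())
        object.__setattr__(self, "total_volume", vol)
        object.__setattr__(self, "sum_b_nonexchanged", sb)
        object.__setattr__(self, "n_labile_h", nl)

    @classmethod
    def from_sequence(cls, sequence: str) -> "ProteinComposition":
        """Build from a one-letter amino-acid sequence (whitespace ignored)."""
        counts: dict[str, float] = {}
        for ch in sequence.upper():
            if ch.isspace():
                continue
            if ch not in RESIDUE_FORMULAS:
                raise ValueError(f"unknown residue code {ch!r}")
            counts[ch] = counts.get(ch, 0) + 1
        return cls(counts)

    @classmethod
    def from_fasta(cls, path_or_handle) -> "ProteinComposition":
        """Build from the first record of a FASTA file."""
        from Bio import SeqIO

        if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
            with open(path_or_handle) as handle:
                record = next(SeqIO.parse(handle, "fasta"))
        else:
            record = next(SeqIO.parse(path_or_handle, "fasta"))
        return cls.from_sequence(str(record.seq))

    @classmethod
    def average_protein(cls, n_residues: float = 100.0) -> "ProteinComposition":
        """The generic globular-protein composition (frequency weighted)."""
        return cls({r: f * n_residues for r, f in AVERAGE_RESIDUE_FREQUENCIES.items()})


def protein_sld(comp: ProteinComposition, f_d2o: float) -> float:
    """Protein SLD at a solvent D2O fraction, Å^-2.

    Labile hydrogens are assumed fully exchanged in proportion to the
    solvent D2O fraction (no kinetic retardation), so the SLD is affine
    in ``f_d2o`` with slope n_labile * (b_D - b_H) / V.
    """
    if not 0.0 <= f_d2o <= 1.0:
        raise ValueError(f"f_d2o must lie in [0, 1], got {f_d2o}")
    b = comp.sum_b_nonexchanged + comp.n_labile_h * f_d2o * B_D_MINUS_B_H
    return b / comp.total_volume


def match_point(comp: ProteinComposition) -> float:
    """Solvent D2O fraction at which the protein SLD equals the water SLD.

    Both SLDs are affine in f_d2o, so the match point is the intersection
    of two straight lines.  The root is returned even when it falls
    outside [0, 1] (with a warning) so the caller can see how far off a
    pathological composition lies; parallel lines raise ``ValueError``.
    """
    p0 = protein_sld(comp, 0.0)
    p1 = protein_sld(comp, 1.0)
    s0 = solvent_sld(0.0)
    s1 = solvent_sld(1.0)
    slope_diff = (p1 - p0) - (s1 - s0)
    if abs(slope_diff) < 1e-9 * max(abs(p1 - p0), abs(s1 - s0)):
        raise ValueError("protein and solvent SLD lines are parallel; "
                         "no unique match point")
    f = (p0 - s0) / -slope_diff
    if not 0.0 <= f <= 1.0:
        warnings.warn(f"match point {f:.3f} lies outside [0, 1]", stacklevel=2)
    return f


def layer_thickness_from_apm(molecular_volume: float, area_per_molecule: float) -> float:
    """Slab thickness of a molecular component: V / APM (Å)."""
    if molecular_volume <= 0:
        raise ValueError("molecular_volume must be > 0")
    if area_per_molecule <= 0:
        raise ValueError("area_per_molecule must be > 0")
    return molecular_volume / area_per_molecule
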