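"""Biomass equation construction from measured macromolecular composition.

Protein and RNA contents are measured per strain; DNA is fixed at 3.1 % of dry
weight, and the remaining dry weight is split among phospholipids (PLP),
lipopolysaccharide (LPS), peptidoglycan (PGL) and glycogen (GL) in the fixed
mass ratio 9.1 : 3.4 : 2.5 : 2.5.  Each macromolecule class is expanded into
precursor drains (mmol per gDW) through monomer composition tables; the flux
through the resulting biomass reaction equals the specific growth rate (1/h).

Also provides the small closed-form assay conversions used alongside the flux
analysis: RNA quantitation from hydrolysate UV absorbance, specific enzyme
activity, and OD595 -> dry weight conversion.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "BiomassComposition",
    "BiomassEquation",
    "GrowthParameters",
    "REMAINDER_RATIO",
    "rna_concentration",
    "specific_activity",
    "dw_from_od",
    "compose_biomass",
    "load_monomer_tables",
    "drains_from_composition",
]

#: mass ratio PLP : LPS : PGL : GL of the non-measured dry-weight remainder
REMAINDER_RATIO = {"plp": 9.1, "lps": 3.4, "pgl": 2.5, "gl": 2.5}

CARBON_MW = 12.011

#: carbon atoms per precursor pool (for the drain carbon audit)
POOL_CARBONS = {
    "G6P": 6, "F6P": 6, "R5P": 5, "E4P": 4, "DHAP": 3, "PG3": 3, "PEP": 3,
    "PYR": 3, "ACCOA": 2, "CO2": 1, "METHF": 1, "ALA": 3, "VAL": 5, "LEU": 6,
    "ILE": 6, "PHE": 9, "TYR": 9, "SER": 3, "GLY": 2, "THR": 4, "ASP": 4,
    "GLU": 5, "MET": 5, "OAA": 4, "AKG": 5,
}


@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecular mass fractions (g/gDW) plus the OD->DW coefficient."""

    prot: float
    rna: float
    dna: float
    plp: float
    lps: float
    pgl: float
    gl: float
    k_dw_od: float = 0.51

    def __post_init__(self):
        fracs = [self.prot, self.rna, self.dna, self.plp, self.lps, self.pgl, self.gl]
        if any(f < 0 for f in fracs):
            raise ValueError("mass fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {sum(fracs):.6f}")

    @property
    def remainder(self) -> float:
        return self.plp + self.lps + self.pgl + self.gl


@dataclass
class GrowthParameters:
    """Measured external rates: growth, glucose uptake, acetate secretion."""

    growth_rate: float  # 1/h
    glucose_uptake: float  # mmol/gDW/h
    acetate_efflux: float  # mmol/gDW/h
    growth_rate_sd: float = 0.0
    glucose_uptake_sd: float = 0.0
    acetate_efflux_sd: float = 0.0

    def __post_init__(self):
        if min(self.growth_rate, self.glucose_uptake, self.acetate_efflux) < 0:
            raise ValueError("growth parameters must be non-negative")


@dataclass
class BiomassEquation:
    """Precursor drain coefficients, mmol consumed per gram dry weight."""

    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(c < 0 for c in self.coefficients.values()):
            raise ValueError("drain coefficients must be non-negative")

    def carbon_per_gram(self) -> float:
        """Grams of carbon drained per gDW formed (mass audit)."""
        return sum(
            c * POOL_CARBONS[m] * CARBON_MW / 1000.0
            for m, c in self.coefficients.items()
        )


def rna_concentration(od270_minus_od290: float) -> float:
    """RNA concentration (g/L) from the alkaline-hydrolysate UV difference.

    C = (OD270 - OD290) * 10.3 / 0.19, where 0.19 is the absorbance difference
    of a hydrolysate at 1 mg/L nucleic acid phosphate and 10.3 converts the
    phosphate amount to ribonucleotides.
    """
    if od270_minus_od290 < 0:
        raise ValueError("absorbance difference must be non-negative")
    return od270_minus_od290 * 10.3 / 0.19


def specific_activity(
    pi_released: float, t: float, protein: float, blank: float = 0.0, input_in_mmol: bool = False
) -> float:
    """Specific activity (umol Pi / min / mg protein) of a Pi-releasing enzyme.

    ``pi_released`` is blank-corrected by ``blank``; pass ``input_in_mmol=True``
    to apply the mmol -> umol factor of 1000.
    """
    if t <= 0 or protein <= 0:
        raise ValueError("reaction time and protein amount must be positive")
    pi = (pi_released - blank) * (1000.0 if input_in_mmol else 1.0)
    return pi / (t * protein)


def dw_from_od(od595: float, k_dw_od: float) -> float:
    """Dry weight concentration (gDW/L) from OD595 and the K_DW/OD coefficient."""
    if od595 < 0 or k_dw_od < 0:
        raise ValueError("OD and K_DW/OD must be non-negative")
    return od595 * k_dw_od


def compose_biomass(
    prot: float, rna: float, dna: float = 0.031, k_dw_od: float = 0.51
) -> BiomassComposition:
    """Close the composition: remainder split 9.1:3.4:2.5:2.5 over PLP/LPS/PGL/GL."""
    if prot < 0 or rna < 0 or dna < 0:
        raise ValueError("mass fractions must be non-negative")
    rem = 1.0 - (prot + rna + dna)
    if rem < -1e-12:
        raise ValueError(f"prot + rna + dna = {prot + rna + dna:.4f} exceeds 1")
    rem = max(rem, 0.0)
    total = sum(REMAINDER_RATIO.values())
    parts = {k: rem * v / total for k, v in REMAINDER_RATIO.items()}
    # absorb float residue into protein-free closure
    return BiomassComposition(
        prot=prot, rna=rna, dna=dna,
        plp=parts["plp"], lps=parts["lps"], pgl=parts["pgl"], gl=parts["gl"],
        k_dw_od=k_dw_od,
    )


def default_tables_path() -> Path:
    return Path(str(importlib.resources.files("emuflux").joinpath("data/biomass_monomers.yaml")))


def load_monomer_tables(path: str | Path | None = None) -> dict:
    p = Path(path) if path is not None else default_tables_path()
    with open(p) as fh:
        tables = yaml.safe_load(fh)
    for key in ("protein", "rna", "dna", "plp", "lps", "pgl", "gl"):
        if key not in tables:
            raise KeyError(f"monomer tables missing section {key!r}")
    return tables


def _polymer_drains(mass_fraction: float, section: dict) -> dict[str, float]:
    """Drains for one polymer class with per-monomer fractions and recipes."""
    fracs = section["fractions"]
    mws = section["residue_mw"]
    total = sum(fracs.values())
    shares = {k: v / total for k, v in fracs.items()}
    mean_mw = sum(shares[k] * mws[k] for k in shares)
    total_mmol = mass_fraction * 1000.0 / mean_mw
    drains: dict[str, float] = {}
    for monomer, share in shares.items():
        if monomer not in section["recipes"]:
            raise KeyError(f"missing recipe for monomer {monomer!r}")
        for pool, n in section["recipes"][monomer].items():
            drains[pool] = drains.get(pool, 0.0) + total_mmol * share * n
    return drains


def drains_from_composition(
    comp: BiomassComposition, tables: dict | None = None
) -> BiomassEquation:
    """Expand a composition into precursor drain coefficients (mmol/gDW)."""
    tables = tables if tables is not None else load_monomer_tables()
    drains: dict[str, float] = {}

    def add(d: dict[str, float]):
        for k, v in d.items():
            drains[k] = drains.get(k, 0.0) + v

    add(_polymer_drains(comp.prot, tables["protein"]))
    add(_polymer_drains(comp.rna, tables["rna"]))
    add(_polymer_drains(comp.dna, tables["dna"]))
    for cls in ("plp", "lps", "pgl", "gl"):
        sec = tables[cls]
        mmol = getattr(comp, cls) * 1000.0 / sec["monomer_mw"]
        add({pool: mmol * n for pool, n in sec["recipe"].items()})
    return BiomassEquation({k: v for k, v in sorted(drains.items())})
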