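"""Mass-isotopomer distribution (MID) utilities.

An MID is a 1-D numpy vector of fractions ``m0..mN`` for a molecule or
fragment with N carbons: non-negative, summing to 1.  This module provides
substrate MIDs under a positional labeling specification, MID convolution
(the condensation step of EMU arithmetic), GC-MS fragment definitions, and
natural-abundance correction via the standard correction-matrix method.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NATURAL_13C",
    "ISOTOPE_ABUNDANCES",
    "LabelingSpec",
    "FragmentDef",
    "convolve",
    "is_valid_mid",
    "substrate_mid",
    "load_fragments",
    "default_fragments_path",
    "correction_matrix",
    "correct_natural_abundance",
    "apply_natural_abundance",
    "parse_formula",
]

#: natural abundance of 13C
NATURAL_13C = 0.0107

#: isotope mass-shift distributions per element (m+0, m+1, m+2, ...)
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Si": (0.92223, 0.04685, 0.03092),
    "P": (1.0,),
}

#: parent monomer -> metabolite pool of the packaged core network
MONOMER_TO_POOL = {
    "Ala": "ALA", "Gly": "GLY", "Val": "VAL", "Leu": "LEU", "Ile": "ILE",
    "Phe": "PHE", "Tyr": "TYR", "Ser": "SER", "Thr": "THR", "Met": "MET",
    "Asp": "ASP", "Glu": "GLU", "Rib": "R5P", "Glc": "G6P",
}


def is_valid_mid(x: np.ndarray, tol: float = 1e-9) -> bool:
    x = np.asarray(x, float)
    return bool(np.all(x >= -tol) and abs(x.sum() - 1.0) <= tol)


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """MID of a condensation product: discrete convolution, renormalized."""
    out = np.convolve(np.asarray(a, float), np.asarray(b, float))
    s = out.sum()
    return out / s if s > 0 else out


@dataclass(frozen=True)
class LabelingSpec:
    """Positional substrate labeling, e.g. 100% [1,2-13C]glucose.

    ``enriched`` maps 1-based carbon positions to their 13C fraction; other
    positions carry ``natural_abundance`` 13C (0.0107 by default, emulating
    real tracer preparations; set to ``None`` or 0 for idealized substrates).
    Unlisted substrate metabolites (e.g. environmental CO2) are unlabeled up
    to the same natural abundance.
    """

    metabolite: str = "GLC_ext"
    enriched: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 1.0})
    natural_abundance: float | None = NATURAL_13C

    def position_fraction(self, metabolite: str, position: int, carbon_count: int) -> float:
        na = self.natural_abundance or 0.0
        if metabolite != self.metabolite:
            return na
        if position < 1 or position > carbon_count:
            raise ValueError(f"position {position} outside 1..{carbon_count} of {metabolite}")
        return self.enriched.get(position, na)


def substrate_mid(
    spec: LabelingSpec, metabolite: str, positions: tuple[int, ...], carbon_count: int | None = None
) -> np.ndarray:
    """MID of a substrate EMU (product of per-position Bernoulli labels)."""
    n = carbon_count if carbon_count is not None else max(positions)
    bad = [p for p in spec.enriched if spec.metabolite == metabolite and not 1 <= p <= n]
    if bad:
        raise ValueError(f"labeling positions {bad} outside carbon range of {metabolite}")
    mid = np.array([1.0])
    for p in sorted(positions):
        f = spec.position_fraction(metabolite, p, n)
        mid = np.convolve(mid, [1.0 - f, f])
    return mid


# -- GC-MS fragments ---------------------------------------------------------


@dataclass(frozen=True)
class FragmentDef:
    """A measured GC-MS fragment of a derivatized monomer.

    ``carbons`` are the 1-based backbone positions of the parent monomer that
    the ion covers; ``formula`` is the elemental composition of the full ion
    (backbone carbons included) used for natural-abundance correction.
    """

    name: str
    monomer: str
    carbons: tuple[int, ...]
    formula: dict[str, int] = field(default_factory=dict)
    pool: str | None = None  # explicit metabolite pool (overrides monomer map)

    def __post_init__(self):
        if not self.carbons or min(self.carbons) < 1:
            raise ValueError(f"{self.name}: invalid carbon subset {self.carbons}")

    @property
    def metabolite(self) -> str:
        return self.pool if self.pool is not None else MONOMER_TO_POOL[self.monomer]

    @property
    def size(self) -> int:
        return len(self.carbons)


def parse_formula(text: str) -> dict[str, int]:
    import re

    out: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", text.strip()):
        if el:
            out[el] = out.get(el, 0) + (int(num) if num else 1)
    return out


def default_fragments_path() -> Path:
    return Path(str(importlib.resources.files("emuflux").joinpath("data/fragments_gcms.tsv")))


def load_fragments(path: str | Path | None = None) -> list[FragmentDef]:
    """Load the fragment fixture table (fragment, monomer, carbons, formula)."""
    p = Path(path) if path is not None else default_fragments_path()
    frags = []
    for line in p.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or line.startswith("fragment"):
            continue
        name, monomer, carbons, formula = line.split("\t")
        if "-" in carbons:
            lo, hi = carbons.split("-")
            pos = tuple(range(int(lo), int(hi) + 1))
        else:
            pos = (int(carbons),)
        frags.append(FragmentDef(name, monomer, pos, parse_formula(formula)))
    return frags


# -- natural-abundance correction -------------------------------------------


def _element_pattern(element: str, count: int) -> np.ndarray:
    base = np.asarray(ISOTOPE_ABUNDANCES[element], float)
    out = np.array([1.0])
    for _ in range(count):
        out = np.convolve(out, base)
    return out


def correction_matrix(
    formula: dict[str, int], n_backbone: int, abundances: dict[str, tuple[float, ...]] | None = None
) -> np.ndarray:
    """Correction matrix M with ``measured = M @ backbone_mid``.

    Columns are the isotope patterns contributed by all atoms except the
    ``n_backbone`` carbons of interest (derivatization carbons, H, N, O, S,
    Si...), truncated to the backbone channel count.  Setting all abundances
    to zero yields the identity.
    """
    table = ISOTOPE_ABUNDANCES if abundances is None else abundances
    n = n_backbone + 1
    pattern = np.array([1.0])
    for el, cnt in formula.items():
        if cnt < 0:
            raise ValueError(f"negative atom count for {el}")
        eff = cnt - n_backbone if el == "C" else cnt
        if eff < 0:
            raise ValueError(f"formula has fewer C than backbone carbons ({cnt} < {n_backbone})")
        dist = np.asarray(table.get(el, ISOTOPE_ABUNDANCES[el]), float)
        for _ in range(eff):
            pattern = np.convolve(pattern, dist)
    M = np.zeros((n, n))
    for j in range(n):
        take = min(len(pattern), n - j)
        M[j : j + take, j] = pattern[:take]
    return M


def apply_natural_abundance(mid: np.ndarray, frag: FragmentDef, **kw) -> np.ndarray:
    """Forward model: backbone MID -> raw measured MID (renormalized)."""
    M = correction_matrix(frag.formula, frag.size, **kw)
    raw = M @ np.asarray(mid, float)
    return raw / raw.sum()


def correct_natural_abundance(raw: np.ndarray, frag: FragmentDef, **kw) -> np.ndarray:
    """Deconvolve non-backbone isotope contributions from a raw MID.

    Solves the truncated correction system in the least-squares sense, clips
    negatives and renormalizes.  Raises on an ill-conditioned matrix.
    """
    raw = np.asarray(raw, float)
    M = correction_matrix(frag.formula, frag.size, **kw)
    if np.linalg.cond(M) > 1e8:
        raise np.linalg.LinAlgError("ill-conditioned natural-abundance correction matrix")
    x, *_ = np.linalg.lstsq(M, raw, rcond=None)
    x = np.clip(x, 0.0, None)
    s = x.sum()
    if s <= 0:
        raise ValueError("natural-abundance correction produced an empty MID")
    return x / s
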