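"""Stoichiometric/atom-transition network model for 13C metabolic flux analysis.

The model is a list of reactions over carbon-carrying metabolite pools.  Each
carbon-mapped reaction carries one or more *atom-map variants*: letter strings
that assign every reactant carbon (1-based) to a product carbon.  A reaction
with two equally weighted variants expresses molecular symmetry (succinate,
fumarate), which scrambles labeling without affecting mass balances.

Reversible reactions are represented by a forward/reverse flux pair
``F = max(net, 0) + exch``, ``R = max(-net, 0) + exch``; the net flux is
``F - R`` and the exchange flux ``exch = min(F, R)`` affects labeling only.

Model files are tab-separated with columns::

    reaction_id  equation  atom_map  reversible  kind  lower  upper

``equation`` uses ``1 A + 1 B -> 1 C``; carbon-mapped species are written with
unit coefficients, repeated if consumed/produced more than once, so that
equation terms align 1:1 with atom-map terms.  ``atom_map`` uses
``ab + c -> abc``; alternative equally weighted maps are separated by ``;``.
Metabolite ids ending in ``_ext`` (and the ``BIOMASS`` sink) are unbalanced
environment pools; unbalanced pools consumed by some reaction are substrates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "AtomMapVariant",
    "Reaction",
    "MetabolicModel",
    "FluxState",
    "FreeFluxBasis",
    "ModelError",
    "load_model",
    "default_model_path",
    "validate_atom_balance",
    "normalize_to_uptake",
    "denormalize_from_uptake",
]

REACTION_KINDS = {"internal", "uptake", "efflux", "biomass", "exchange_env"}

#: free fluxes preferred by the RREF pivoting order (chosen for interpretability:
#: pathway entry points, anaplerotic and slack fluxes). Columns for these
#: reactions are ordered last so they end up non-pivot (free) where possible.
PREFERRED_FREE = [
    "ace_out",
    "gcs",
    "gly_thr",
    "asp_fum",
    "ser_deam",
    "pox",
    "pps",
    "fbp",
    "icl",
    "mae",
    "pck",
    "ppc",
    "edd",
    "zwf",
    "cs",
    "biomass",
    "pts",
]


class ModelError(ValueError):
    """Raised for malformed or inconsistent model definitions."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    carbon_count: int
    is_balanced: bool = True
    is_substrate: bool = False

    def __post_init__(self):
        if self.carbon_count < 0:
            raise ModelError(f"negative carbon count for {self.id}")


@dataclass(frozen=True)
class AtomMapVariant:
    """One atom mapping: reactant and product letter strings, with a weight.

    Weights of all variants of a reaction sum to 1; two variants at 0.5 encode
    a symmetric molecule.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    weight: float = 1.0


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[tuple[float, str], ...]
    products: tuple[tuple[float, str], ...]
    atom_maps: tuple[AtomMapVariant, ...] = ()
    reversible: bool = False
    kind: str = "internal"
    lower: float = 0.0
    upper: float = np.inf

    @property
    def has_atom_map(self) -> bool:
        return len(self.atom_maps) > 0

    def stoich(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c, m in self.reactants:
            out[m] = out.get(m, 0.0) - c
        for c, m in self.products:
            out[m] = out.get(m, 0.0) + c
        return out


@dataclass(frozen=True)
class FreeFluxBasis:
    """Affine parameterization of the steady-state flux space.

    ``v_net = N @ theta`` where ``theta`` are the net fluxes of ``free_ids``
    (in order).  Any assignment of theta yields S @ v = 0.
    """

    free_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    N: np.ndarray  # (n_reactions, n_free)

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def full_net(self, theta: np.ndarray) -> np.ndarray:
        return self.N @ np.asarray(theta, dtype=float)


class MetabolicModel:
    """Validated reaction network with stoichiometric matrix and flux basis."""

    def __init__(self, metabolites: dict[str, Metabolite], reactions: list[Reaction]):
        self.metabolites = dict(metabolites)
        self.reactions = list(reactions)
        self.reaction_ids = [r.id for r in self.reactions]
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            dup = [r for r in self.reaction_ids if self.reaction_ids.count(r) > 1]
            raise ModelError(f"duplicate reaction id(s): {sorted(set(dup))}")
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self.balanced_ids = [m.id for m in self.metabolites.values() if m.is_balanced]
        self._validate()
        self._S = self._build_S()
        self._basis: FreeFluxBasis | None = None

    # -- construction -------------------------------------------------------

    def _validate(self) -> None:
        for r in self.reactions:
            if r.kind not in REACTION_KINDS:
                raise ModelError(f"{r.id}: unknown kind {r.kind!r}")
            for _, m in r.reactants + r.products:
                if m not in self.metabolites:
                    raise ModelError(f"{r.id}: unknown metabolite {m!r}")
            for v in r.atom_maps:
                terms_r = [m for _, m in r.reactants if self.metabolites[m].carbon_count > 0]
                terms_p = [m for _, m in r.products if self.metabolites[m].carbon_count > 0]
                if len(v.reactants) != len(terms_r) or len(v.products) != len(terms_p):
                    raise ModelError(f"{r.id}: atom map terms do not align with equation")
                for s, m in zip(v.reactants, terms_r):
                    if len(s) != self.metabolites[m].carbon_count:
                        raise ModelError(
                            f"{r.id}: atom string {s!r} does not match "
                            f"{m} carbon count {self.metabolites[m].carbon_count}"
                        )
                for s, m in zip(v.products, terms_p):
                    if len(s) != self.metabolites[m].carbon_count:
                        raise ModelError(
                            f"{r.id}: atom string {s!r} does not match "
                            f"{m} carbon count {self.metabolites[m].carbon_count}"
                        )
                for side in (v.reactants, v.products):
                    joined = "".join(side)
                    if len(set(joined)) != len(joined):
                        raise ModelError(
                            f"{r.id}: atom letters must be distinct within one side, got {side}"
                        )

    def _build_S(self) -> np.ndarray:
        S = np.zeros((len(self.balanced_ids), len(self.reactions)))
        row = {m: i for i, m in enumerate(self.balanced_ids)}
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich().items():
                if m in row:
                    S[row[m], j] += c
        return S

    # -- public surface ------------------------------------------------------

    @property
    def S(self) -> np.ndarray:
        """Stoichiometric matrix over balanced metabolites (rows) x reactions."""
        return self._S

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def reaction_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    def free_flux_basis(self, preferred_free: list[str] | None = None) -> FreeFluxBasis:
        """Nullspace basis of S with named free fluxes (via ordered RREF).

        The basis dimension equals ``n_reactions - rank(S)``.  Columns for
        reactions in ``preferred_free`` are eliminated last, so they are chosen
        as free parameters whenever linear independence allows.
        """
        if self._basis is not None and preferred_free is None:
            return self._basis
        pref = PREFERRED_FREE if preferred_free is None else preferred_free
        n_r = len(self.reactions)
        prio = {rid: k for k, rid in enumerate(pref)}
        # columns sorted: non-preferred first (stable), preferred last in listed order
        order = sorted(range(n_r), key=lambda j: (prio.get(self.reaction_ids[j], -1), j))
        A = self._S[:, order].copy()
        m, n = A.shape
        piv_cols: list[int] = []
        i = 0
        for j in range(n):
            if i >= m:
                break
            k = i + int(np.argmax(np.abs(A[i:, j])))
            if abs(A[k, j]) < 1e-10:
                continue
            A[[i, k]] = A[[k, i]]
            A[i] = A[i] / A[i, j]
            mask = np.ones(m, bool)
            mask[i] = False
            A[mask] -= np.outer(A[mask, j], A[i])
            piv_cols.append(j)
            i += 1
        rank = len(piv_cols)
        free_cols = [j for j in range(n) if j not in piv_cols]
        N_perm = np.zeros((n, len(free_cols)))
        for k, j in enumerate(free_cols):
            N_perm[j, k] = 1.0
            for row_i, pj in enumerate(piv_cols):
                N_perm[pj, k] = -A[row_i, j]
        # undo the column permutation
        N = np.zeros_like(N_perm)
        for pos, j_orig in enumerate(order):
            N[j_orig] = N_perm[pos]
        free_ids = tuple(self.reaction_ids[order[j]] for j in free_cols)
        basis = FreeFluxBasis(free_ids, tuple(self.reaction_ids), N)
        # sanity: any theta must satisfy steady state
        test = self._S @ N
        if np.max(np.abs(test)) > 1e-8:
            raise ModelError("free-flux basis inconsistent with S (rank deficiency)")
        if len(free_cols) != n - rank:
            raise ModelError("free set size inconsistent with rank")
        if preferred_free is None:
            self._basis = basis
        return basis

    def with_biomass(self, coefficients: dict[str, float], rid: str = "biomass") -> "MetabolicModel":
        """Return a copy whose biomass-drain stoichiometry is replaced.

        ``coefficients`` are mmol of each pool consumed per gDW; the reaction
        keeps its single unbalanced product (the biomass sink).
        """
        old = self.reaction(rid)
        reactants = tuple((float(c), m) for m, c in sorted(coefficients.items()) if c > 0)
        for _, m in reactants:
            if m not in self.metabolites:
                raise ModelError(f"biomass drain references unknown pool {m!r}")
        new = replace(old, reactants=reactants)
        rxns = [new if r.id == rid else r for r in self.reactions]
        return MetabolicModel(self.metabolites, rxns)

    def steady_state_residual(self, state: "FluxState") -> float:
        return float(np.max(np.abs(self._S @ state.net)))


@dataclass
class FluxState:
    """Net and exchange flux values aligned with a model's reaction order.

    Units are mmol / gDW / h; the biomass flux equals the specific growth rate
    in 1/h.  Exchange entries are zero for irreversible reactions.
    """

    model: MetabolicModel
    net: np.ndarray
    exch: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.net = np.asarray(self.net, dtype=float)
        if self.exch is None:
            self.exch = np.zeros_like(self.net)
        self.exch = np.asarray(self.exch, dtype=float)
        if self.net.shape != (len(self.model.reactions),):
            raise ModelError("net flux vector length does not match model")

    def __getitem__(self, rid: str) -> float:
        return float(self.net[self.model.reaction_index(rid)])

    def exchange(self, rid: str) -> float:
        return float(self.exch[self.model.reaction_index(rid)])

    def forward_reverse(self) -> tuple[np.ndarray, np.ndarray]:
        """F/R decomposition: F = net+ + exch, R = net- + exch."""
        pos = np.maximum(self.net, 0.0)
        neg = np.maximum(-self.net, 0.0)
        return pos + self.exch, neg + self.exch

    def copy(self) -> "FluxState":
        return FluxState(self.model, self.net.copy(), self.exch.copy())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.model.reaction_ids, map(float, self.net)))


def normalize_to_uptake(state: FluxState, uptake: float) -> FluxState:
    """Rescale so the glucose uptake maps to 100 (fluxes in % of uptake)."""
    if uptake <= 0:
        raise ValueError(f"uptake must be positive, got {uptake}")
    f = 100.0 / uptake
    return FluxState(state.model, state.net * f, state.exch * f)


def denormalize_from_uptake(state: FluxState, uptake: float) -> FluxState:
    if uptake <= 0:
        raise ValueError(f"uptake must be positive, got {uptake}")
    f = uptake / 100.0
    return FluxState(state.model, state.net * f, state.exch * f)


# -- parsing ----------------------------------------------------------------


def _parse_side(side: str) -> list[tuple[float, str]]:
    terms = []
    for t in side.split("+"):
        t = t.strip()
        if not t:
            continue
        parts = t.split()
        if len(parts) == 1:
            coeff, met = 1.0, parts[0]
        elif len(parts) == 2:
            coeff, met = float(parts[0]), parts[1]
        else:
            raise ModelError(f"malformed equation term {t!r}")
        terms.append((coeff, met))
    return terms


def _parse_atom_map(text: str) -> list[AtomMapVariant]:
    variants = []
    raw = [v.strip() for v in text.split(";") if v.strip()]
    for v in raw:
        if "->" not in v:
            raise ModelError(f"malformed atom map {v!r}")
        lhs, rhs = v.split("->")
        variants.append(
            AtomMapVariant(
                tuple(s.strip() for s in lhs.split("+") if s.strip()),
                tuple(s.strip() for s in rhs.split("+") if s.strip()),
                1.0 / len(raw),
            )
        )
    return variants


def default_model_path() -> Path:
    return Path(str(importlib.resources.files("emuflux").joinpath("data/ecoli_core_13c.tsv")))


def load_model(path: str | Path | None = None) -> MetabolicModel:
    """Load and validate a model table; default is the packaged E. coli core.

    The packaged fixture covers EMP, the pentose-phosphate pathway with
    ping-pong transketolase/transaldolase half reactions, Entner-Doudoroff,
    the TCA cycle and glyoxylate shunt, anaplerotic PEP carboxylase, malic
    enzyme and OAA decarboxylation, FBPase / PEP-synthetase futile partners,
    both acetate routes (reversible Pta-AckA, irreversible PoxB), serine and
    threonine routes to glycine with irreversible glycine cleavage, serine
    deaminase, explicit amino-acid / one-carbon / nucleotide carbon transfer,
    a biomass drain, and explicit CO2 exchange with the environment.
    """
    p = Path(path) if path is not None else default_model_path()
    rows = []
    for ln, line in enumerate(p.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        cols = line.split("\t")
        if cols[0] == "reaction_id":
            continue
        if len(cols) < 7:
            raise ModelError(f"{p}:{ln}: expected 7 tab-separated columns")
        rows.append(cols)

    carbon_counts: dict[str, int] = {}
    reactions = []
    for rid, eqn, amap, rev, kind, lo, hi in (c[:7] for c in rows):
        if "->" not in eqn:
            raise ModelError(f"{rid}: equation lacks '->'")
        lhs, rhs = eqn.split("->")
        reactants = tuple(_parse_side(lhs))
        products = tuple(_parse_side(rhs))
        maps = tuple(_parse_atom_map(amap)) if amap.strip() else ()
        if maps:
            # atom-map terms align 1:1 with equation terms; collect carbon counts
            for variant in maps:
                for side_mets, strings in (
                    ([m for _, m in reactants], variant.reactants),
                    ([m for _, m in products], variant.products),
                ):
                    if len(strings) != len(side_mets):
                        raise ModelError(f"{rid}: atom map terms do not align with equation")
                    for m, s in zip(side_mets, strings):
                        prev = carbon_counts.setdefault(m, len(s))
                        if prev != len(s):
                            raise ModelError(
                                f"{rid}: inconsistent carbon count for {m} "
                                f"({prev} vs {len(s)})"
                            )
        reactions.append(
            Reaction(
                id=rid,
                reactants=reactants,
                products=products,
                atom_maps=maps,
                reversible=rev.strip().lower() in {"1", "true", "yes", "r"},
                kind=kind.strip(),
                lower=float(lo) if lo.strip() else 0.0,
                upper=float(hi) if hi.strip() else np.inf,
            )
        )

    mets: dict[str, Metabolite] = {}
    all_ids = {m for r in reactions for _, m in r.reactants + r.products}
    consumed = {m for r in reactions for _, m in r.reactants}
    for m in sorted(all_ids):
        balanced = not (m.endswith("_ext") or m == "BIOMASS")
        mets[m] = Metabolite(
            id=m,
            carbon_count=carbon_counts.get(m, 0),
            is_balanced=balanced,
            is_substrate=(not balanced) and m in consumed,
        )
    return MetabolicModel(mets, reactions)


def validate_atom_balance(model: MetabolicModel) -> list[dict]:
    """Per-reaction carbon-balance report for every atom-mapped reaction.

    A mapping is balanced when the letter multiset on the reactant side equals
    the product side for each variant.  Report-only: never raises.
    """
    report = []
    for r in model.reactions:
        if not r.has_atom_map:
            continue
        ok = True
        detail = ""
        for v in r.atom_maps:
            left = sorted("".join(v.reactants))
            right = sorted("".join(v.products))
            if left != right:
                ok = False
                detail = f"reactant letters {''.join(left)} != product letters {''.join(right)}"
                break
        report.append({"reaction": r.id, "balanced": ok, "detail": detail})
    return report
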