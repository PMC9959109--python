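"""Shared fixtures: the packaged core model, presets, and small toy networks.

Toy networks are built programmatically; they are deliberately tiny so the
brute-force isotopomer oracle and bootstrap experiments stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from emuflux.biomass import GrowthParameters
from emuflux.fitting import FluxFitter, MeasurementSet
from emuflux.mid import FragmentDef, LabelingSpec
from emuflux.network import AtomMapVariant, FluxState, MetabolicModel, Metabolite, Reaction
from emuflux.synthetic import build_preset


def make_metabolite(mid: str, carbons: int, balanced=True, substrate=False) -> Metabolite:
    return Metabolite(mid, carbons, balanced, substrate)


def make_reaction(rid, reactants, products, amap=None, rev=False, kind="internal") -> Reaction:
    variants = ()
    if amap:
        parts = [v.strip() for v in amap.split(";")]
        variants = tuple(
            AtomMapVariant(
                tuple(s.strip() for s in p.split("->")[0].split("+")),
                tuple(s.strip() for s in p.split("->")[1].split("+")),
                1.0 / len(parts),
            )
            for p in parts
        )
    return Reaction(
        rid,
        tuple((1.0, m) for m in reactants),
        tuple((1.0, m) for m in products),
        variants,
        rev,
        kind,
    )


def build_toy(mets, rxns) -> MetabolicModel:
    return MetabolicModel({m.id: m for m in mets}, rxns)


# -- toy networks for the EMU-vs-oracle equivalence --------------------------


def linear_toy():
    """A_ext -> B -> C -> sink, 3 carbons straight through."""
    m = build_toy(
        [
            make_metabolite("A_ext", 3, balanced=False, substrate=True),
            make_metabolite("B", 3),
            make_metabolite("C", 3),
            make_metabolite("OUT", 0, balanced=False),
        ],
        [
            make_reaction("upt", ["A_ext"], ["B"], "abc -> abc", kind="uptake"),
            make_reaction("r1", ["B"], ["C"], "abc -> abc"),
            make_reaction("out", ["C"], ["OUT"], kind="efflux"),
        ],
    )
    state = FluxState(m, np.array([1.0, 1.0, 1.0]))
    return m, state


def cyclic_toy():
    """Reversible rotating cycle with cleavage (scrambles positions)."""
    m = build_toy(
        [
            make_metabolite("A_ext", 3, balanced=False, substrate=True),
            make_metabolite("B", 3),
            make_metabolite("C", 3),
            make_metabolite("D", 2),
            make_metabolite("E", 1),
            make_metabolite("OUT", 0, balanced=False),
        ],
        [
            make_reaction("upt", ["A_ext"], ["B"], "abc -> abc", kind="uptake"),
            make_reaction("rot", ["B"], ["C"], "abc -> bca", rev=True),
            make_reaction("clv", ["C"], ["D", "E"], "abc -> ab + c"),
            make_reaction("outD", ["D"], ["OUT"], kind="efflux"),
            make_reaction("outE", ["E"], ["OUT"], kind="efflux"),
        ],
    )
    state = FluxState(
        m,
        np.array([1.0, 1.0, 1.0, 1.0, 1.0]),
        np.array([0.0, 1.7, 0.0, 0.0, 0.0]),
    )
    return m, state


def branched_toy():
    """Cleavage then recombining condensation, with side drains."""
    m = build_toy(
        [
            make_metabolite("A_ext", 4, balanced=False, substrate=True),
            make_metabolite("A", 4),
            make_metabolite("B", 2),
            make_metabolite("C", 2),
            make_metabolite("D", 4),
            make_metabolite("OUT", 0, balanced=False),
        ],
        [
            make_reaction("upt", ["A_ext"], ["A"], "abcd -> abcd", kind="uptake"),
            make_reaction("clv", ["A"], ["B", "C"], "abcd -> ab + cd"),
            make_reaction("cnd", ["B", "C"], ["D"], "ab + cd -> cdab"),
            make_reaction("outB", ["B"], ["OUT"], kind="efflux"),
            make_reaction("outC", ["C"], ["OUT"], kind="efflux"),
            make_reaction("outD", ["D"], ["OUT"], kind="efflux"),
        ],
    )
    state = FluxState(m, np.array([1.0, 1.0, 0.4, 0.6, 0.6, 0.4]))
    return m, state


TOY_LABELING = LabelingSpec("A_ext", {1: 1.0}, natural_abundance=None)


# -- a small identifiable fitting problem ------------------------------------

SPLIT_TRUTH = {"upt": 10.0, "r1": 5.0, "r2": 3.0, "r3": 2.0}  # r2 = upt - r1 - r3


def split_toy_model() -> MetabolicModel:
    """Two parallel routes with different atom rearrangements plus a side sink.

    The r1/r2 split is identifiable only through the positional labeling of E;
    upt and r3 are anchored by the measured rates.
    """
    return build_toy(
        [
            make_metabolite("S_ext", 3, balanced=False, substrate=True),
            make_metabolite("A", 3),
            make_metabolite("E", 3),
            make_metabolite("F", 3),
            make_metabolite("OUT", 0, balanced=False),
        ],
        [
            make_reaction("upt", ["S_ext"], ["A"], "abc -> abc", kind="uptake"),
            make_reaction("r1", ["A"], ["E"], "abc -> abc"),
            make_reaction("r2", ["A"], ["E"], "abc -> cba"),
            make_reaction("r3", ["A"], ["F"], "abc -> abc"),
            make_reaction("outE", ["E"], ["OUT"], kind="efflux"),
            make_reaction("outF", ["F"], ["OUT"], kind="efflux"),
        ],
    )


SPLIT_FRAGMENTS = [
    FragmentDef("E12", "E", (1, 2), pool="E"),
    FragmentDef("E123", "E", (1, 2, 3), pool="E"),
]
SPLIT_EFFLUX_MAP = {"growth_rate": "outE", "glucose_uptake": "upt", "acetate_efflux": "outF"}
SPLIT_LABELING = LabelingSpec("S_ext", {1: 1.0}, natural_abundance=None)


def split_toy_state(model: MetabolicModel, truth=SPLIT_TRUTH) -> FluxState:
    upt, r1, r3 = truth["upt"], truth["r1"], truth["r3"]
    r2 = upt - r1 - r3
    net = {"upt": upt, "r1": r1, "r2": r2, "r3": r3, "outE": r1 + r2, "outF": r3}
    return FluxState(model, np.array([net[r.id] for r in model.reactions]))


def split_toy_measurements(
    model, state, rng=None, mid_sd=0.003, rate_sd=0.15
) -> MeasurementSet:
    from emuflux.emu import EMUSimulator, decompose

    sim = EMUSimulator(decompose(model, SPLIT_FRAGMENTS), SPLIT_LABELING)
    mids = sim.simulate(state)
    out_m, out_s = {}, {}
    for f in SPLIT_FRAGMENTS:
        clean = mids[(f.metabolite, tuple(sorted(f.carbons)))]
        noisy = clean if rng is None else np.clip(clean + rng.normal(0, mid_sd, len(clean)), 0, None)
        noisy = noisy / noisy.sum()
        out_m[f.name] = noisy
        out_s[f.name] = np.full(len(clean), mid_sd)

    def rate(rid):
        v = state[rid]
        return v if rng is None else max(0.0, v + rng.normal(0, rate_sd))

    growth = GrowthParameters(
        growth_rate=rate("outE"),
        glucose_uptake=rate("upt"),
        acetate_efflux=rate("outF"),
        growth_rate_sd=rate_sd,
        glucose_uptake_sd=rate_sd,
        acetate_efflux_sd=rate_sd,
    )
    return MeasurementSet(out_m, out_s, growth)


def split_toy_fitter(model, meas) -> FluxFitter:
    return FluxFitter(
        model, meas, labeling=SPLIT_LABELING, fragments=SPLIT_FRAGMENTS,
        anchors={}, efflux_map=SPLIT_EFFLUX_MAP,
    )


# -- session fixtures --------------------------------------------------------


@pytest.fixture(scope="session")
def core_model():
    from emuflux.network import load_model

    return load_model()


@pytest.fixture(scope="session")
def wt_preset():
    return build_preset("wild_type")


@pytest.fixture(scope="session")
def mutant_preset():
    return build_preset("hppa_dppa")


@pytest.fixture(scope="session")
def wt_noisefree_data(wt_preset):
    from emuflux.synthetic import generate_cle_dataset

    return generate_cle_dataset(wt_preset, seed=1, sd=0.0)
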