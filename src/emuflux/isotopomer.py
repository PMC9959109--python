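"""Brute-force positional-isotopomer balance solver (verification oracle).

Tracks the full 2^n isotopomer distribution of every balanced carbon-carrying
pool and solves the steady-state isotopomer balances by damped fixed-point
iteration.  Exponential in pool carbon count, so intended for small networks;
it is deliberately independent of the EMU machinery (no shared solve path)
and serves as the ground truth the EMU cascade is verified against.

Isotopomer state vectors are indexed by bitmask: bit ``k`` set means carbon
position ``k+1`` is 13C.
"""

from __future__ import annotations

import numpy as np

from .emu import EMU, _Directed
from .mid import LabelingSpec
from .network import FluxState, MetabolicModel, ModelError

__all__ = ["IsotopomerOracle", "brute_force_isotopomer_oracle"]

MAX_POOL_CARBONS = 20


class IsotopomerOracle:
    def __init__(self, model: MetabolicModel, labeling: LabelingSpec):
        self.model = model
        self.labeling = labeling
        self.directed = _Directed(model)
        self.pools = [
            m.id
            for m in model.metabolites.values()
            if m.is_balanced and m.carbon_count > 0
        ]
        for p in self.pools:
            if model.metabolites[p].carbon_count > MAX_POOL_CARBONS:
                raise ModelError(f"pool {p} too large for isotopomer enumeration")
        self._substrate_dist: dict[str, np.ndarray] = {}
        for m in model.metabolites.values():
            if not m.is_balanced and m.carbon_count > 0:
                self._substrate_dist[m.id] = self._substrate(m.id, m.carbon_count)

    def _substrate(self, met: str, n: int) -> np.ndarray:
        dist = np.ones(1)
        for p in range(1, n + 1):
            f = self.labeling.position_fraction(met, p, n)
            dist = np.concatenate([dist * (1 - f), dist * f])
        return dist

    def solve(
        self, state: FluxState, tol: float = 1e-14, max_iter: int = 20000, damping: float = 0.0
    ) -> dict[str, np.ndarray]:
        """Fixed-point solve of all pool isotopomer distributions."""
        v = self.directed.flux_vector(state)
        ncar = {p: self.model.metabolites[p].carbon_count for p in self.pools}
        dists = {p: self._unlabeled(n) for p, n in ncar.items()}

        # precompute, per pool, its production routes:
        # (flux_index, weight, [(source_met_or_None, source_dist_key, bit mapping)])
        routes: dict[str, list] = {p: [] for p in self.pools}
        for pm, entries in self.directed.producers.items():
            if pm not in routes:
                continue
            for fi, w, r_mets, r_strs, p_str in entries:
                # mapping: for each product bit position i (0-based), which
                # reactant term j and which bit within that term feeds it
                feeds = []
                for i, letter in enumerate(p_str):
                    for j, s in enumerate(r_strs):
                        k = s.find(letter)
                        if k >= 0:
                            feeds.append((j, k, i))
                            break
                    else:
                        raise ModelError(f"letter {letter!r} unmatched in reaction feeding {pm}")
                routes[pm].append((fi, w, tuple(r_mets), feeds))

        for it in range(max_iter):
            delta = 0.0
            for p in self.pools:
                influx = 0.0
                acc = np.zeros(2 ** ncar[p])
                for fi, w, r_mets, feeds in routes[p]:
                    f = v[fi] * w
                    if f <= 0:
                        continue
                    influx += f
                    acc += f * self._route_dist(r_mets, feeds, ncar[p], dists)
                if influx <= 0:
                    continue  # inert pool: no material flows through it
                new = acc / influx
                if damping > 0:
                    new = damping * dists[p] + (1 - damping) * new
                delta = max(delta, float(np.max(np.abs(new - dists[p]))))
                dists[p] = new
            if delta < tol:
                break
        else:
            raise RuntimeError("isotopomer fixed point did not converge")
        return dists

    def _route_dist(self, r_mets, feeds, n_prod, dists) -> np.ndarray:
        # joint distribution of the contributing reactant atoms (independent
        # molecules -> outer product), marginalized and permuted to product bits
        per_term: dict[int, list[tuple[int, int]]] = {}
        for j, k, i in feeds:
            per_term.setdefault(j, []).append((k, i))
        out = np.ones(1)
        placed: list[int] = []  # product bit of each accumulated bit, in order
        for j, pairs in sorted(per_term.items()):
            met = r_mets[j]
            dist = dists.get(met)
            if dist is None:
                dist = self._substrate_dist[met]
            marg = self._marginal(dist, [k for k, _ in pairs])
            out = np.multiply.outer(marg, out).ravel()  # new bits become high bits
            placed = placed + [i for _, i in pairs]
        # `out` is indexed with bit b corresponding to product bit placed[b]
        prod = np.zeros(2 ** n_prod)
        idx = np.arange(out.size)
        target = np.zeros(out.size, dtype=np.int64)
        for b, i in enumerate(placed):
            target |= (((idx >> b) & 1) << i).astype(np.int64)
        np.add.at(prod, target, out)
        return prod

    @staticmethod
    def _marginal(dist: np.ndarray, keep_bits: list[int]) -> np.ndarray:
        """Marginal over a subset of bit positions (order preserved)."""
        n = int(np.log2(dist.size))
        idx = np.arange(dist.size)
        out = np.zeros(2 ** len(keep_bits))
        target = np.zeros(dist.size, dtype=np.int64)
        for new_b, old_b in enumerate(keep_bits):
            target |= ((idx >> old_b) & 1) << new_b
        np.add.at(out, target, dist)
        return out

    @staticmethod
    def _unlabeled(n: int) -> np.ndarray:
        d = np.zeros(2 ** n)
        d[0] = 1.0
        return d

    def mid(self, dists: dict[str, np.ndarray], emu: EMU) -> np.ndarray:
        """Marginalize a pool's isotopomer distribution to an EMU's MID."""
        met = self.model.metabolites[emu.met]
        dist = dists[emu.met] if met.is_balanced else self._substrate_dist[emu.met]
        bits = [p - 1 for p in emu.positions]
        marg = self._marginal(dist, bits)
        out = np.zeros(len(bits) + 1)
        for mask, val in enumerate(marg):
            out[bin(mask).count("1")] += val
        return out


def brute_force_isotopomer_oracle(
    model: MetabolicModel,
    state: FluxState,
    labeling: LabelingSpec,
    targets,
    tol: float = 1e-14,
) -> dict[EMU, np.ndarray]:
    """Full isotopomer solve, marginalized to the target EMUs' MIDs."""
    from .emu import fragment_emu
    from .mid import FragmentDef

    oracle = IsotopomerOracle(model, labeling)
    dists = oracle.solve(state, tol=tol)
    out = {}
    for t in targets:
        e = fragment_emu(t) if isinstance(t, FragmentDef) else t
        out[e] = oracle.mid(dists, e)
    return out
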