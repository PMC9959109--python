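"""Parametric-bootstrap percentile confidence intervals for net fluxes.

Replicate datasets are drawn from the fitted model's predicted means plus
Gaussian noise at the measurement SDs and refit (warm-started from the
optimum, optionally with extra random restarts).  Replicates whose refit
fails the chi-square test are discarded ("discarding" Monte Carlo), and
percentile CIs are taken over the retained refits.  Batches are repeated
until every tracked CI border moves less than a tolerance between consecutive
batches, or the replicate budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitResult, FluxFitter, _local_fit, chi_square_test, sample_feasible_starts

__all__ = [
    "BootstrapSettings",
    "ConfidenceInterval",
    "percentile_ci",
    "parametric_bootstrap",
]

MIN_RETAINED = 20


@dataclass(frozen=True)
class BootstrapSettings:
    """Settings of the confidence-interval estimation procedure.

    ``border_tol`` is in percentage points of normalized flux (uptake = 100).
    """

    level: float = 0.95
    batch: int = 100
    max_replicates: int = 1000
    border_tol: float = 0.5
    seed: int = 0
    alpha: float = 0.05
    extra_starts: int = 0
    refit_tol: float = 1e-8
    refit_max_nfev: int | None = 100
    noise_scale: float = 1.0  # multiplier on measurement SDs for replicates

    def __post_init__(self):
        if not (0.0 <= self.level < 1.0):
            raise ValueError("confidence level must be in [0, 1)")
        if self.batch < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class ConfidenceInterval:
    flux_id: str
    lower: float
    upper: float
    replicates: int
    converged: bool

    def __post_init__(self):
        if self.lower > self.upper + 1e-12:
            raise ValueError(f"{self.flux_id}: lower CI bound exceeds upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def overlaps(self, other: "ConfidenceInterval") -> bool:
        return not (self.upper < other.lower or other.upper < self.lower)


def percentile_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    """Percentile interval with linear interpolation between order statistics.

    For a sample of size n the q-quantile sits at rank h = (n-1) q and is
    interpolated linearly between the floor(h)-th and ceil(h)-th order
    statistics.  ``level=0`` degenerates to [median, median].
    """
    x = np.sort(np.asarray(values, float))
    if x.size == 0:
        raise ValueError("empty sample")

    def q(p: float) -> float:
        h = (x.size - 1) * p
        lo = int(np.floor(h))
        hi = int(np.ceil(h))
        return float(x[lo] + (h - lo) * (x[hi] - x[lo]))

    a = (1.0 - level) / 2.0
    return q(a), q(1.0 - a)


def parametric_bootstrap(
    fitter: FluxFitter,
    fit: FitResult,
    settings: BootstrapSettings | None = None,
    track: list[str] | None = None,
) -> dict[str, ConfidenceInterval]:
    """Percentile PB-CIs of the normalized net fluxes, with discarding.

    ``track`` limits the convergence rule to fluxes of interest (default:
    all reactions).  Returns one ConfidenceInterval per reaction id, on the
    normalized (% of uptake) scale.
    """
    st = settings if settings is not None else BootstrapSettings()
    rng = np.random.default_rng(st.seed)
    model = fitter.model
    track = list(track) if track is not None else list(model.reaction_ids)

    # predicted means at the optimum
    mids_hat = fitter.sim.simulate(fit.state)
    mean_vec = {e: mids_hat[e] for e in fitter._target_emus}
    g = fitter.meas.growth

    retained: list[np.ndarray] = []  # normalized net vectors
    n_drawn = 0
    prev_borders: dict[str, tuple[float, float]] | None = None
    converged = False

    while n_drawn < st.max_replicates and not converged:
        for _ in range(min(st.batch, st.max_replicates - n_drawn)):
            n_drawn += 1
            rep = _replicate_measurements(fitter, fit, mean_vec, rng, st.noise_scale)
            rep_fitter = fitter.with_measurements(rep)
            p0s = [fit.params]
            if st.extra_starts:
                p0s += list(
                    sample_feasible_starts(
                        rep_fitter, st.extra_starts, seed=int(rng.integers(2**31))
                    )
                )
            best = None
            for p0 in p0s:
                try:
                    res = _local_fit(rep_fitter, p0, st.refit_max_nfev, st.refit_tol)
                except np.linalg.LinAlgError:
                    continue
                ssr = rep_fitter.ssr(res.x)
                if best is None or ssr < best[0]:
                    best = (ssr, res.x)
            if best is None:
                continue
            ssr, p_opt = best
            passed, _ = chi_square_test(ssr, rep_fitter.n_meas, rep_fitter.n_params, st.alpha)
            if not passed:
                continue  # the discarding step
            state = rep_fitter.state_from_params(p_opt)
            retained.append(state.net * 100.0 / state[fitter.uptake_id])
        if len(retained) < max(2, MIN_RETAINED // 2):
            continue
        borders = {}
        sample = np.array(retained)
        for rid in track:
            j = model.reaction_index(rid)
            borders[rid] = percentile_ci(sample[:, j], st.level)
        if prev_borders is not None:
            moves = [
                max(abs(borders[r][0] - prev_borders[r][0]),
                    abs(borders[r][1] - prev_borders[r][1]))
                for r in track
            ]
            converged = max(moves) < st.border_tol
        prev_borders = borders

    ok = len(retained) >= MIN_RETAINED and converged
    sample = np.array(retained) if retained else np.zeros((0, len(model.reaction_ids)))
    out = {}
    for rid in model.reaction_ids:
        j = model.reaction_index(rid)
        if sample.shape[0]:
            lo, hi = percentile_ci(sample[:, j], st.level)
        else:
            lo = hi = float("nan")
        out[rid] = ConfidenceInterval(rid, lo, hi, sample.shape[0], ok)
    return out


def _replicate_measurements(fitter: FluxFitter, fit: FitResult, mean_vec, rng, scale=1.0):
    """One synthetic replicate: predicted means + Gaussian measurement noise."""
    from .biomass import GrowthParameters
    from .fitting import MeasurementSet

    g = fitter.meas.growth
    mids, sds = {}, {}
    for frag, emu in zip(fitter.fragments, fitter._target_emus):
        sd = fitter.meas.mid_sds[frag.name]
        noisy = mean_vec[emu] + rng.normal(0.0, sd * scale)
        s = noisy.sum()
        mids[frag.name] = noisy / s if s > 0 else np.full_like(noisy, 1.0 / len(noisy))
        sds[frag.name] = sd.copy()
    emap = fitter.efflux_map
    sim_g = GrowthParameters(
        growth_rate=max(0.0, fit.state[emap["growth_rate"]] + rng.normal(0.0, g.growth_rate_sd * scale)),
        glucose_uptake=max(0.0, fit.state[emap["glucose_uptake"]] + rng.normal(0.0, g.glucose_uptake_sd * scale)),
        acetate_efflux=max(0.0, fit.state[emap["acetate_efflux"]] + rng.normal(0.0, g.acetate_efflux_sd * scale)),
        growth_rate_sd=g.growth_rate_sd,
        glucose_uptake_sd=g.glucose_uptake_sd,
        acetate_efflux_sd=g.acetate_efflux_sd,
    )
    return MeasurementSet(mids, sds, sim_g)
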