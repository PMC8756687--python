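"""Incremental-mixture ABC calibration with warm-start recalibration.

The engine is likelihood-free: a parameter draw is *accepted* when
every simulated target statistic falls inside that target's current
tolerance interval, and accepted draws carry importance weights
``prior(theta) / q(theta)`` where ``q`` is a defensive mixture of the
prior and multivariate-normal components added incrementally around
the highest-weight accepted draws (adaptive importance sampling in the
Population Monte Carlo style).  Tolerance intervals start wide and
shrink geometrically toward the targets' final bands; the run stops
once the effective sample size ``ESS = (sum w)^2 / sum w^2`` over
draws satisfying every final band reaches the configured target.

Sequential recalibration ("warm start") exploits the Bayesian
factorization p(theta | y, z) ∝ p(theta | y) p(z | theta, y): a
converged state for targets ``y`` is re-scored against new targets
``z`` (re-simulating each stored draw under its stored seed, so the
``y`` statistics are reproduced bit-for-bit), ``z`` starts at its
initial intervals, the stored mixture components are retained, and the
same iteration loop resumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .priors import PriorSpec
from .targets import Target, ToleranceInterval

logger = logging.getLogger("crccal.imabc")

#: A simulator maps (theta vector, integer seed) to target-name -> value.
Simulator = Callable[[np.ndarray, int], Mapping[str, float]]
MapFn = Callable[..., Iterable]


def draw_seed(master_seed: int, draw_id: int) -> int:
    """Per-draw simulator seed; independent of batch order/partition."""
    return int(np.random.SeedSequence([master_seed, draw_id]).generate_state(1)[0])


@dataclass
class Draw:
    """One simulated parameter draw and its bookkeeping."""

    draw_id: int
    theta: np.ndarray
    simulated: dict[str, float]
    log_prior: float
    log_proposal: float
    weight: float
    seed: int


@dataclass
class TargetBand:
    """A target's tolerance intervals during calibration."""

    name: str
    initial: ToleranceInterval
    final: ToleranceInterval
    current: ToleranceInterval

    def at_final(self) -> bool:
        return (
            abs(self.current.lower - self.final.lower) < 1e-12
            and abs(self.current.upper - self.final.upper) < 1e-12
        )


@dataclass
class MixtureComponent:
    center: np.ndarray
    cov: np.ndarray
    chol: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.chol is None:
            self.chol = np.linalg.cholesky(self.cov)


@dataclass
class CalibrationState:
    """Resumable engine state."""

    param_names: tuple[str, ...]
    prior: PriorSpec
    bands: dict[str, TargetBand]
    draws: list[Draw]
    components: list[MixtureComponent]
    config: RunConfig
    master_seed: int
    iteration: int = 0
    next_draw_id: int = 0
    n_sim_calls: int = 0
    converged: bool = False
    used_center_ids: set[int] = field(default_factory=set)
    #: (draws sampled, components existing at the time) per sampling stage;
    #: the importance weights divide by the stage-size-weighted mixture of
    #: all proposals that actually generated draws (balance heuristic), not
    #: merely the latest one.
    stages: list[tuple[int, int]] = field(default_factory=list)

    # -- weights & ESS -----------------------------------------------------

    def _component_log_densities(self, thetas: np.ndarray) -> np.ndarray:
        """(n_components, n_draws) Gaussian log-densities."""
        k = thetas.shape[1]
        out = np.empty((len(self.components), len(thetas)))
        for m, c in enumerate(self.components):
            diff = thetas - c.center
            sol = np.linalg.solve(c.chol, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(c.chol)))
            out[m] = -0.5 * (maha + logdet + k * np.log(2.0 * np.pi))
        return out

    def _stage_log_proposal(
        self, log_prior: np.ndarray, comp_log: np.ndarray, n_components: int
    ) -> np.ndarray:
        """Log density of the defensive mixture with the first
        ``n_components`` Gaussian components."""
        if n_components == 0:
            return log_prior
        w_def = self.config.defensive_weight
        log_mix = (
            np.logaddexp.reduce(comp_log[:n_components], axis=0)
            - np.log(n_components)
        )
        return np.logaddexp(np.log(w_def) + log_prior, np.log(1 - w_def) + log_mix)

    def _log_mixture(self, thetas: np.ndarray) -> np.ndarray:
        """Log of the *effective* sampling density at rows of thetas.

        Each sampling stage drew from the defensive mixture current at
        that time; the density that actually generated the pooled draws
        is the stage-size-weighted average of those mixtures.
        """
        thetas = np.atleast_2d(thetas)
        log_prior = self.prior.logpdf(thetas)
        stages = self.stages or [(1, len(self.components))]
        if all(m == 0 for _, m in stages) or not self.components:
            return log_prior
        comp_log = self._component_log_densities(thetas)
        total = sum(n for n, _ in stages)
        parts = [
            np.log(n / total) + self._stage_log_proposal(log_prior, comp_log, m)
            for n, m in stages
            if n > 0
        ]
        return np.logaddexp.reduce(np.vstack(parts), axis=0)

    def _log_current_mixture(self, thetas: np.ndarray) -> np.ndarray:
        """Log density of the latest proposal (used for sampling only)."""
        thetas = np.atleast_2d(thetas)
        log_prior = self.prior.logpdf(thetas)
        if not self.components:
            return log_prior
        comp_log = self._component_log_densities(thetas)
        return self._stage_log_proposal(log_prior, comp_log, len(self.components))

    def in_intervals(self, draw: Draw, which: str = "current") -> bool:
        for band in self.bands.values():
            iv = getattr(band, which)
            if not iv.contains(draw.simulated[band.name]):
                return False
        return True

    def refresh_weights(self) -> None:
        """Recompute proposal densities and importance weights in place.

        Weights are prior/q for draws inside every current interval and
        exactly 0 otherwise, normalized to sum to 1.
        """
        if not self.draws:
            return
        thetas = np.array([d.theta for d in self.draws])
        log_q = self._log_mixture(thetas)
        raw = np.zeros(len(self.draws))
        for i, d in enumerate(self.draws):
            d.log_proposal = float(log_q[i])
            if self.in_intervals(d):
                raw[i] = np.exp(d.log_prior - d.log_proposal)
        total = raw.sum()
        if total <= 0:
            raise RuntimeError("all importance weights are zero")
        for d, w in zip(self.draws, raw / total):
            d.weight = float(w)

    def ess(self, which: str = "current") -> float:
        """(sum w)^2 / sum w^2 over draws inside the given intervals."""
        w = np.array(
            [d.weight for d in self.draws if self.in_intervals(d, which)]
        )
        s2 = float((w**2).sum())
        return float(w.sum()) ** 2 / s2 if s2 > 0 else 0.0

    def weights_array(self) -> np.ndarray:
        return np.array([d.weight for d in self.draws])

    def thetas_array(self) -> np.ndarray:
        return np.array([d.theta for d in self.draws])


# ---------------------------------------------------------------------------
# engine operations
# ---------------------------------------------------------------------------

def _simulate_batch(
    thetas: np.ndarray,
    draw_ids: Sequence[int],
    state: CalibrationState,
    simulator: Simulator,
    map_fn: MapFn,
    which: str = "current",
) -> list[Draw]:
    """Score a batch of proposals and keep those inside every ``which``
    interval; results are independent of map order because each draw
    carries its own seed.

    If the simulator exposes ``stages`` — a list of (fn, target-names)
    pairs — stages are evaluated in order and a draw is abandoned as
    soon as one of its already-computed statistics falls outside its
    accept band, so cheap statistics can veto before expensive ones
    are simulated.  Accepted draws always carry the full statistic set.
    """
    seeds = [draw_seed(state.master_seed, i) for i in draw_ids]
    stages = getattr(simulator, "stages", None)
    bands = [state.bands[n] for n in state.bands]

    def evaluate(theta, seed):
        if stages is None:
            return dict(simulator(theta, seed))
        sim: dict[str, float] = {}
        for fn, names in stages:
            sim.update(fn(theta, seed))
            for b in bands:
                if b.name in sim and not getattr(b, which).contains(sim[b.name]):
                    return sim  # doomed: later stages not needed
        return sim

    results = list(map_fn(evaluate, list(thetas), seeds))
    state.n_sim_calls += len(thetas)
    log_p = state.prior.logpdf(thetas)
    draws = [
        Draw(
            draw_id=i,
            theta=np.asarray(t, dtype=float),
            simulated=dict(r),
            log_prior=float(lp),
            log_proposal=float(lp),  # refreshed later
            weight=0.0,
            seed=s,
        )
        for i, t, r, s, lp in zip(draw_ids, thetas, results, seeds, log_p)
    ]
    return [
        d
        for d in draws
        if all(n in d.simulated for n in state.bands) and state.in_intervals(d, which)
    ]


def init_from_prior(
    prior: PriorSpec,
    targets: Sequence[Target],
    n_init: int,
    simulator: Simulator,
    seed: int,
    config: RunConfig | None = None,
    map_fn: MapFn = map,
) -> CalibrationState:
    """Draw ``n_init`` prior samples, keep those inside every initial
    interval, and start with uniform weights among the kept draws."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    config = config or RunConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    bands = {
        t.name: TargetBand(t.name, t.initial_interval, t.final_interval, t.initial_interval)
        for t in targets
    }
    state = CalibrationState(
        param_names=prior.names,
        prior=prior,
        bands=bands,
        draws=[],
        components=[],
        config=config,
        master_seed=seed,
    )
    thetas = prior.sample(n_init, rng)
    state.stages.append((n_init, 0))
    ids = list(range(state.next_draw_id, state.next_draw_id + n_init))
    state.next_draw_id += n_init
    state.draws = _simulate_batch(thetas, ids, state, simulator, map_fn, "initial")
    if not state.draws:
        raise RuntimeError(
            "no prior draw satisfies the initial tolerance intervals; "
            "the prior is inconsistent with the targets"
        )
    state.refresh_weights()
    logger.info(
        "iter=0 stage=init n_sim=%d accepted=%d ess=%.1f",
        n_init, len(state.draws), state.ess(),
    )
    return state


def add_mixture_components(
    state: CalibrationState, n_centers: int, rng: np.random.Generator | None = None
) -> CalibrationState:
    """Add Gaussian proposal components at the highest-weight draws.

    Centers are chosen by stable sort (weight descending, draw id
    ascending), skipping draws already used as centers so successive
    iterations explore new high-weight regions; each covariance is the
    sample covariance of the nearest accepted draws (in
    coordinate-standardized distance), regularized by adding
    ``cov_reg * trace`` to the diagonal.
    """
    if len(state.draws) < n_centers:
        raise ValueError("fewer accepted draws than requested centers")
    # rank draws inside the final bands ahead of the merely-accepted, so
    # new components concentrate where the run must ultimately sit
    order = sorted(
        state.draws,
        key=lambda d: (not state.in_intervals(d, "final"), -d.weight, d.draw_id),
    )
    fresh = [d for d in order if d.draw_id not in state.used_center_ids]
    centers = fresh[:n_centers]
    if len(centers) < n_centers:  # every draw already used: allow reuse
        centers += order[: n_centers - len(centers)]
    state.used_center_ids.update(d.draw_id for d in centers)
    thetas = state.thetas_array()
    k = thetas.shape[1]
    scale = thetas.std(axis=0)
    scale[scale == 0] = 1.0
    n_local = min(len(state.draws), max(2 * k + 2, 20))
    prior_span = state.prior.bounds[:, 1] - state.prior.bounds[:, 0]
    for c in centers:
        dist = np.sum(((thetas - c.theta) / scale) ** 2, axis=1)
        local = thetas[np.argsort(dist)[:n_local]]
        cov = np.cov(local, rowvar=False).reshape(k, k) if len(local) > 1 else None
        if cov is None or not np.all(np.isfinite(cov)) or np.trace(cov) <= 0:
            # degenerate neighbourhood: fall back to a diagonal proposal
            # spanning a tenth of the prior range
            cov = np.diag((0.1 * prior_span) ** 2)
        cov = cov + state.config.cov_reg * max(np.trace(cov), 1e-300) * np.eye(k)
        try:
            comp = MixtureComponent(center=c.theta.copy(), cov=cov)
        except np.linalg.LinAlgError:
            cov = cov + 1e-6 * np.eye(k) * max(np.trace(cov), 1.0)
            try:
                comp = MixtureComponent(center=c.theta.copy(), cov=cov)
            except np.linalg.LinAlgError as err:
                raise RuntimeError("singular proposal covariance") from err
        state.components.append(comp)
    state.refresh_weights()
    return state


def importance_weights(state: CalibrationState) -> np.ndarray:
    """Refresh and return normalized importance weights."""
    state.refresh_weights()
    return state.weights_array()


def sample_mixture(
    state: CalibrationState, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw proposals from the defensive mixture (prior + components)."""
    if not state.components:
        return state.prior.sample(n, rng)
    w_def = state.config.defensive_weight
    n_def = rng.binomial(n, w_def)
    out = [state.prior.sample(n_def, rng)] if n_def else []
    rest = n - n_def
    if rest:
        comp_idx = rng.integers(len(state.components), size=rest)
        k = len(state.param_names)
        z = rng.standard_normal((rest, k))
        pts = np.empty((rest, k))
        for i, (ci, zi) in enumerate(zip(comp_idx, z)):
            c = state.components[ci]
            pts[i] = c.center + c.chol @ zi
        out.append(pts)
    return np.vstack(out)


def shrink_intervals(state: CalibrationState) -> CalibrationState:
    """Move each target's current interval one step toward its final band.

    Endpoints are interpolated by the configured step factor (1.0 jumps
    straight to the final band); a target's step is skipped — and
    logged — if it would leave fewer than ``min_draws_retained`` draws
    inside all current intervals.  Draws falling outside the updated
    bands are dropped and weights renormalized.
    """
    if not state.draws:
        raise RuntimeError("cannot shrink intervals with no accepted draws")
    step = state.config.shrink_factor
    for band in state.bands.values():
        if band.at_final():
            continue
        cur, fin = band.current, band.final
        new_lo = cur.lower + step * (fin.lower - cur.lower)
        new_hi = cur.upper + step * (fin.upper - cur.upper)
        span = max(abs(fin.lower), abs(fin.upper), 1.0)
        if abs(new_lo - fin.lower) < 1e-12 * span and abs(new_hi - fin.upper) < 1e-12 * span:
            new_lo, new_hi = fin.lower, fin.upper
        tentative = ToleranceInterval(new_lo, new_hi)
        survivors = sum(
            1
            for d in state.draws
            if tentative.contains(d.simulated[band.name])
            and all(
                b.current.contains(d.simulated[b.name])
                for b in state.bands.values()
                if b.name != band.name
            )
        )
        if survivors < state.config.min_draws_retained:
            logger.info(
                "iter=%d stage=shrink target=%s skipped survivors=%d",
                state.iteration, band.name, survivors,
            )
            continue
        band.current = tentative
    state.draws = [d for d in state.draws if state.in_intervals(d)]
    state.refresh_weights()
    return state


def _maybe_converge(state: CalibrationState) -> bool:
    """Stop when draws inside every *final* band already carry enough ESS;
    snap bands to final and drop the rest."""
    ess_final = state.ess("final")
    if ess_final >= state.config.target_ess:
        for band in state.bands.values():
            band.current = band.final
        state.draws = [d for d in state.draws if state.in_intervals(d)]
        state.refresh_weights()
        state.converged = True
        return True
    return False


def run_calibration(
    prior: PriorSpec,
    targets: Sequence[Target],
    simulator: Simulator,
    config: RunConfig,
    seed: int,
    map_fn: MapFn = map,
) -> CalibrationState:
    """Full IMABC loop: initialize from the prior, then iterate
    add-components / sample / simulate / accept / shrink / reweight
    until the ESS target is met at the final intervals."""
    state = init_from_prior(prior, targets, config.n_init, simulator, seed, config, map_fn)
    return _iterate(state, simulator, map_fn)


def _iterate(
    state: CalibrationState, simulator: Simulator, map_fn: MapFn
) -> CalibrationState:
    config = state.config
    if _maybe_converge(state):
        logger.info("iter=%d stage=done ess=%.1f (prior draws sufficed)", state.iteration, state.ess())
        return state
    while state.iteration < config.max_iterations:
        state.iteration += 1
        rng = np.random.default_rng(
            np.random.SeedSequence([state.master_seed, 1, state.iteration])
        )
        n_centers = min(config.n_centers, len(state.draws))
        add_mixture_components(state, n_centers, rng)
        n_batch = n_centers * config.batch_per_component
        thetas = sample_mixture(state, n_batch, rng)
        state.stages.append((n_batch, len(state.components)))
        inside = state.prior.in_support(thetas)
        thetas = thetas[inside]  # outside-support proposals have zero weight
        ids = list(range(state.next_draw_id, state.next_draw_id + len(thetas)))
        state.next_draw_id += n_batch  # reserve ids for the full batch
        state.draws.extend(_simulate_batch(thetas, ids, state, simulator, map_fn))
        shrink_intervals(state)
        logger.info(
            "iter=%d stage=loop n_sim=%d accepted=%d ess=%.1f ess_final=%.1f bands_final=%d/%d",
            state.iteration, state.n_sim_calls, len(state.draws),
            state.ess(), state.ess("final"),
            sum(b.at_final() for b in state.bands.values()), len(state.bands),
        )
        if _maybe_converge(state):
            logger.info("iter=%d stage=done ess=%.1f", state.iteration, state.ess())
            return state
    state.converged = False
    logger.warning("iter=%d stage=unconverged ess_final=%.1f", state.iteration, state.ess("final"))
    return state


def warm_start_recalibration(
    saved_state: CalibrationState,
    new_targets: Sequence[Target],
    simulator: Simulator,
    config: RunConfig | None = None,
    map_fn: MapFn = map,
) -> CalibrationState:
    """Resume a converged calibration with additional targets.

    Every stored draw is re-simulated under its stored seed — which
    reproduces the original targets' statistics exactly and scores the
    new ones — then acceptance is re-applied with the new targets at
    their initial intervals, the stored mixture is retained, and the
    usual loop resumes.  The simulator must now report the combined
    target set.
    """
    if not saved_state.converged:
        raise ValueError("warm start requires a converged saved state")
    dup = set(b for b in saved_state.bands) & set(t.name for t in new_targets)
    if dup:
        raise ValueError(f"new targets duplicate existing names: {sorted(dup)}")
    state = saved_state
    if config is not None:
        state.config = config
    for t in new_targets:
        state.bands[t.name] = TargetBand(
            t.name, t.initial_interval, t.final_interval, t.initial_interval
        )
    thetas = state.thetas_array()
    seeds = [d.seed for d in state.draws]
    results = list(map_fn(simulator, list(thetas), seeds))
    state.n_sim_calls += len(seeds)
    for d, r in zip(state.draws, results):
        d.simulated = dict(r)
    state.draws = [d for d in state.draws if state.in_intervals(d)]
    if not state.draws:
        raise RuntimeError(
            "no stored draw satisfies the new targets' initial intervals; "
            "widen them or start from scratch"
        )
    state.refresh_weights()
    logger.info(
        "iter=%d stage=warm_start accepted=%d ess=%.1f",
        state.iteration, len(state.draws), state.ess(),
    )
    state.converged = False
    return _iterate(state, simulator, map_fn)


# ---------------------------------------------------------------------------
# state serialization (JSON + companion draws CSV)
# ---------------------------------------------------------------------------

def save_state(state: CalibrationState, path: str | Path) -> None:
    """Write the state to ``path`` (JSON) and draws to ``<path>.draws.csv``."""
    path = Path(path)
    doc = {
        "param_names": list(state.param_names),
        "prior": {
            name: {
                "family": m.family, "lower": m.lower, "upper": m.upper,
                **({"mu": m.mu, "sd": m.sd} if m.family == "truncnorm" else {}),
            }
            for name, m in state.prior.margins
        },
        "bands": {
            name: {
                "initial": [b.initial.lower, b.initial.upper],
                "final": [b.final.lower, b.final.upper],
                "current": [b.current.lower, b.current.upper],
            }
            for name, b in state.bands.items()
        },
        "components": [
            {"center": c.center.tolist(), "cov": c.cov.tolist()}
            for c in state.components
        ],
        "config": state.config.to_dict(),
        "master_seed": state.master_seed,
        "stages": [list(st) for st in state.stages],
        "iteration": state.iteration,
        "next_draw_id": state.next_draw_id,
        "n_sim_calls": state.n_sim_calls,
        "converged": state.converged,
        "ess": state.ess(),
        "draws_csv": path.name + ".draws.csv",
    }
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    tmp.replace(path)

    target_names = list(state.bands)
    rows = []
    for d in state.draws:
        row = {"draw_id": d.draw_id, "seed": d.seed, "weight": d.weight,
               "log_prior": d.log_prior, "log_proposal": d.log_proposal}
        row.update({n: v for n, v in zip(state.param_names, d.theta)})
        row.update({f"sim:{t}": d.simulated[t] for t in target_names})
        rows.append(row)
    csv_path = path.parent / doc["draws_csv"]
    tmp_csv = csv_path.with_suffix(csv_path.suffix + ".tmp")
    pd.DataFrame(rows).to_csv(tmp_csv, index=False, float_format="%.17g")
    tmp_csv.replace(csv_path)


def load_state(path: str | Path) -> CalibrationState:
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    prior = PriorSpec.from_dict(doc["prior"])
    bands = {
        name: TargetBand(
            name,
            ToleranceInterval(*b["initial"]),
            ToleranceInterval(*b["final"]),
            ToleranceInterval(*b["current"]),
        )
        for name, b in doc["bands"].items()
    }
    components = [
        MixtureComponent(np.array(c["center"]), np.array(c["cov"]))
        for c in doc["components"]
    ]
    df = pd.read_csv(path.parent / doc["draws_csv"], float_precision="round_trip")
    names = doc["param_names"]
    target_names = list(bands)
    draws = [
        Draw(
            draw_id=int(r["draw_id"]),
            theta=np.array([r[n] for n in names]),
            simulated={t: float(r[f"sim:{t}"]) for t in target_names},
            log_prior=float(r["log_prior"]),
            log_proposal=float(r["log_proposal"]),
            weight=float(r["weight"]),
            seed=int(r["seed"]),
        )
        for _, r in df.iterrows()
    ]
    return CalibrationState(
        param_names=tuple(names),
        prior=prior,
        bands=bands,
        draws=draws,
        components=components,
        config=RunConfig.from_dict(doc["config"]),
        master_seed=int(doc["master_seed"]),
        stages=[tuple(st) for st in doc.get("stages", [])],
        iteration=int(doc["iteration"]),
        next_draw_id=int(doc["next_draw_id"]),
        n_sim_calls=int(doc["n_sim_calls"]),
        converged=bool(doc["converged"]),
    )
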