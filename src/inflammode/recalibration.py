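"""Sparse ensemble re-calibration of the inflammation model.

Given the young baseline parameterization and a middle-aged time-course
dataset, the search looks for a *minimal* set of parameter changes — at
most ``n_max`` — that lets the model reproduce the observed analyte
trajectories. The procedure escalates the change budget N = 1, 2, ...:
at each level it draws random N-subsets of the candidate parameters,
optimizes multiplicative fold changes for each subset by seeded,
restarted coordinate descent in log10-fold space, and stops escalating
once at least one fit beats the acceptance threshold. All accepted,
deduplicated fits form an ensemble of near-equivalent models, reported
as fold changes relative to the young baseline rather than as a single
elected optimum.

The fit error is the mean (over observed analytes) of the mean squared
difference between log10(model + 1) and log10(observed group mean + 1)
at the observed times, so each analyte contributes on its own
concentration scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SimulationError
from .model import DoseProtocol, resting_state, simulate
from .params import PARAM_DEFS, PARAM_ORDER, ModelParameters
from .synthetic import ANALYTE_STATES, TimeCourseDataset

LOG_EPS = 1.0  # concentration unit added before taking log10

#: parameters eligible for change by default: everything appearing in the
#: measured-analyte equations (TNF, IL-6, IL-10, NO) plus the unmeasured
#: activated-macrophage, activated-neutrophil and iNOS equations.
CANDIDATE_PARAMS = (
    # MA equation
    "kmpe", "xmpe", "kmd", "xmd", "km6", "xm6", "kma", "Mmax",
    # NA equation
    "knpe", "xnpe", "kn", "Nmax",
    # shared IL-10 brake
    "hn10", "x10l",
    # iNOS / NO equations
    "kinosm", "kinosn", "kdinos", "knono", "kno",
    # TNF equation
    "kcpm", "kcp", "xcp6", "hcp6", "xcp10", "hcp10",
    # IL-6 equation
    "s6", "k6m", "k6n", "k6cp", "x6cp", "h6cp", "k6no", "x6no", "kd6",
    # IL-10 equation
    "s10", "k10m0", "k10cp", "x10cp", "h10cp", "k10",
)

#: Hill coefficients may not drop below 1, which caps their fold-down range.
_HILL_FLOOR = {"hn10", "hcp6", "hcp10", "h6cp", "h10cp"}


@dataclass(frozen=True)
class FitConfig:
    """Settings for the sparse re-calibration search."""

    candidate_params: Sequence[str] = CANDIDATE_PARAMS
    n_max: int = 8
    fold_bounds: tuple = (10 ** -2.5, 10 ** 2.5)
    restarts_per_n: int = 1
    subset_draws_per_n: int = 6
    greedy_draws_per_n: int = 3  # of the draws, how many extend incumbent fits
    beam_width: int = 2  # distinct incumbents kept as bases for extensions
    swap_draws: int = 2  # per level, swap moves tried when still above threshold
    harvest_draws: int = 8  # extra fits per harvest round at the stop level
    target_members: int = 5  # harvest until this many distinct members (or budget)
    max_harvest_rounds: int = 5
    error_threshold: float | None = None  # None: must be set before searching
    seed: int = 0
    step_schedule: tuple = (2.0, 1.01)  # initial and minimum multiplicative step
    dedup_radius: float = 0.3  # log10-fold Euclidean distance

    def __post_init__(self):
        unknown = sorted(set(self.candidate_params) - set(PARAM_ORDER))
        if unknown:
            raise InvalidInputError(f"unknown candidate parameter(s): {unknown}")
        if not 1 <= self.n_max <= len(self.candidate_params):
            raise InvalidInputError("need 1 <= n_max <= |candidate_params|")
        lo, hi = self.fold_bounds
        if not (0 < lo < 1 < hi):
            raise InvalidInputError("fold_bounds must straddle 1")
        if self.restarts_per_n < 1 or self.subset_draws_per_n < 1:
            raise InvalidInputError("counts must be >= 1")
        s0, smin = self.step_schedule
        if not (s0 > smin > 1.0):
            raise InvalidInputError("step_schedule must satisfy start > floor > 1")


@dataclass
class FitResult:
    """Outcome of one subset optimization."""

    changed: Dict[str, float]  # parameter -> fold (value / young value), != 1
    error: float
    n_changed: int
    trace: List[float] = field(default_factory=list)
    seed_used: int = 0
    subset: tuple = ()

    def apply_to(self, young: ModelParameters, label: str = "refit") -> ModelParameters:
        updates = {k: young[k] * f for k, f in self.changed.items()}
        return young.replace(label=label, **updates)

    def log_folds(self, names: Sequence[str]) -> np.ndarray:
        return np.array([math.log10(self.changed.get(k, 1.0)) for k in names])


@dataclass
class Ensemble:
    """Accepted, deduplicated near-equivalent fits for one dataset."""

    members: List[FitResult]
    error_threshold: float
    dedup_radius: float
    provenance: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @property
    def best(self) -> FitResult | None:
        return self.members[0] if self.members else None


def _prepare_observations(data: TimeCourseDataset):
    """Collapse replicates to per-analyte group-mean curves."""
    means = data.group_means()
    obs = {}
    for analyte, grp in means.groupby("analyte"):
        if analyte not in ANALYTE_STATES:
            continue
        grp = grp.sort_values("time_min")
        obs[analyte] = (
            grp["time_min"].to_numpy(dtype=float),
            grp["value"].to_numpy(dtype=float),
        )
    if not obs or not any(len(t) >= 2 for t, _ in obs.values()):
        raise InvalidInputError(
            "dataset must observe at least one modelled analyte at >= 2 times"
        )
    return obs


def objective(
    params: ModelParameters,
    data: TimeCourseDataset,
    protocol: DoseProtocol = DoseProtocol(dose=1.0),
    _obs=None,
    _fast: bool = False,
) -> float:
    """Log-scale mean-squared mismatch between model and group means.

    ``mean over analytes of mean over times of
    (log10(model + 1) - log10(group mean + 1))^2``. The +1 pg/ml (or uM)
    offset keeps floored zero observations finite. Simulation failures
    propagate with the offending parameter set attached.
    """
    obs = _obs if _obs is not None else _prepare_observations(data)
    all_times = sorted(set(float(t) for times, _ in obs.values() for t in times))
    try:
        rest = resting_state(params, fast=_fast)
        res = simulate(params, protocol, init=rest, obs_times=all_times,
                       mxstep=3000 if _fast else 20000)
    except SimulationError as exc:
        exc.diagnostics["params"] = params.to_dict()
        raise
    except Exception as exc:
        raise SimulationError(
            f"objective evaluation failed: {exc}",
            diagnostics={"params": params.to_dict()},
        ) from exc
    total = 0.0
    for analyte, (times, values) in obs.items():
        model = res.get(ANALYTE_STATES[analyte])
        idx = np.searchsorted(res.times, times)
        r = np.log10(model[idx] + LOG_EPS) - np.log10(values + LOG_EPS)
        total += float(np.mean(r * r))
    return total / len(obs)


class _Evaluator:
    """Caches observation prep and counts model evaluations.

    Candidate parameter sets for which the model cannot be evaluated
    (no stable resting state, solver breakdown) score ``inf`` so the
    descent simply rejects the move instead of aborting the search.
    """

    def __init__(self, young, data, protocol):
        self.young = young
        self.obs = _prepare_observations(data)
        self.protocol = protocol
        self.n_eval = 0
        self.n_failed = 0

    def __call__(self, subset, logf):
        updates = {
            name: self.young[name] * (10.0 ** lf)
            for name, lf in zip(subset, logf)
        }
        params = self.young.replace(label="candidate", **updates)
        self.n_eval += 1
        try:
            return objective(params, None, self.protocol, _obs=self.obs, _fast=True)
        except SimulationError:
            self.n_failed += 1
            return math.inf


def _fold_bounds_for(name, young, config):
    """Per-parameter log10-fold bounds (Hill floors tighten the lower end)."""
    lo, hi = config.fold_bounds
    llo, lhi = math.log10(lo), math.log10(hi)
    if name in _HILL_FLOOR:
        llo = max(llo, math.log10(1.0 / young[name]))
    return llo, lhi


def optimize_subset(
    subset: Sequence[str],
    young: ModelParameters,
    data: TimeCourseDataset | None,
    config: FitConfig,
    protocol: DoseProtocol = DoseProtocol(dose=1.0),
    rng: np.random.Generator | None = None,
    _evaluator: "_Evaluator | None" = None,
    warm_start: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit fold changes for one fixed parameter subset.

    Multiplicative coordinate descent in log10-fold space: sweeps over the
    subset trying up/down moves of the current step factor, shrinking the
    step geometrically (square root) from ``step_schedule[0]`` down to
    ``step_schedule[1]`` whenever a sweep yields no improvement. The first
    restart starts from the unchanged baseline (fold 1, or ``warm_start``);
    later restarts start log-uniformly within ``fold_bounds``. The best
    restart wins. Only subset members may end with fold != 1.
    """
    subset = tuple(subset)
    bad = sorted(set(subset) - set(config.candidate_params))
    if bad:
        raise InvalidInputError(f"subset not within candidate_params: {bad}")
    if len(subset) > config.n_max:
        raise InvalidInputError("subset larger than n_max")
    ev = _evaluator or _Evaluator(young, data, protocol)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seed_used = int(rng.integers(2 ** 31 - 1))
    local = np.random.default_rng(seed_used)

    if not subset:
        err = ev((), np.array([]))
        return FitResult(changed={}, error=err, n_changed=0, trace=[err],
                         seed_used=seed_used, subset=())

    bounds = [_fold_bounds_for(name, young, config) for name in subset]
    step0, step_min = config.step_schedule
    best_logf, best_err, best_trace = None, math.inf, []

    for restart in range(config.restarts_per_n):
        if restart == 0:
            if warm_start:
                logf = np.array([
                    math.log10(warm_start.get(name, 1.0)) for name in subset
                ])
            else:
                logf = np.zeros(len(subset))
        else:
            logf = np.array([
                local.uniform(lo, hi) for lo, hi in bounds
            ])
        logf = np.clip(logf, [b[0] for b in bounds], [b[1] for b in bounds])
        err = ev(subset, logf)
        trace = [err]
        # coarse-to-fine descent cycles: shrink the step geometrically,
        # and once the floor is reached re-coarsen while that still helps
        # (ridges between correlated rates need repeated passes)
        while True:
            err_at_cycle_start = err
            step = step0
            lstep = math.log10(step)
            while True:
                improved = False
                for i in range(len(subset)):
                    for delta in (lstep, -lstep):
                        cand = logf[i] + delta
                        lo, hi = bounds[i]
                        if cand < lo - 1e-12 or cand > hi + 1e-12:
                            continue
                        trial = logf.copy()
                        trial[i] = min(max(cand, lo), hi)
                        e = ev(subset, trial)
                        if e < err - 1e-14:
                            logf, err = trial, e
                            trace.append(e)
                            improved = True
                            break
                if not improved:
                    if step <= step_min:
                        break
                    step = max(math.sqrt(step), step_min)
                    lstep = math.log10(step)
            if err >= err_at_cycle_start * (1.0 - 1e-3):
                break
        if err < best_err:
            best_logf, best_err, best_trace = logf, err, trace

    changed = {
        name: 10.0 ** lf
        for name, lf in zip(subset, best_logf)
        if lf != 0.0
    }
    return FitResult(
        changed=changed,
        error=best_err,
        n_changed=len(changed),
        trace=best_trace,
        seed_used=seed_used,
        subset=subset,
    )


def _score_extension(ev, base_fit: FitResult, q: str, young, config) -> tuple:
    """Cheap 1-D descent on parameter ``q`` with the base folds frozen.

    Returns (best error, best fold for q); used to rank candidate
    extensions of an incumbent subset before committing to a full
    optimization.
    """
    subset = tuple(sorted(set(base_fit.subset) | {q}))
    base_logf = {name: math.log10(base_fit.changed.get(name, 1.0))
                 for name in subset}
    lo, hi = _fold_bounds_for(q, young, config)
    lq = 0.0

    def eval_at(lq_val):
        logf = np.array([base_logf[name] if name != q else lq_val
                         for name in subset])
        return ev(subset, logf)

    err = eval_at(lq)
    step = math.log10(config.step_schedule[0])
    while step >= math.log10(1.05):
        moved = False
        for delta in (step, -step):
            cand = lq + delta
            if cand < lo or cand > hi:
                continue
            e = eval_at(cand)
            if e < err - 1e-14:
                lq, err = cand, e
                moved = True
                break
        if not moved:
            step /= 2.0
    return err, 10.0 ** lq


def _member_distance(a: FitResult, b: FitResult, names: Sequence[str]) -> float:
    return float(np.linalg.norm(a.log_folds(names) - b.log_folds(names)))


def _member_sort_key(m: FitResult):
    # lower error first; ties: fewer changes, then lexicographic subset
    return (m.error, m.n_changed, tuple(sorted(m.changed)))


def dedup_members(members: List[FitResult], names, radius: float) -> List[FitResult]:
    """Merge fits closer than ``radius`` in log10-fold space (best kept)."""
    kept: List[FitResult] = []
    for m in sorted(members, key=_member_sort_key):
        if all(_member_distance(m, k, names) > radius for k in kept):
            kept.append(m)
    return kept


def sparse_search(
    young: ModelParameters,
    data: TimeCourseDataset,
    config: FitConfig,
    protocol: DoseProtocol = DoseProtocol(dose=1.0),
) -> Ensemble:
    """Escalating sparse search for an ensemble of acceptable re-fits.

    For N = 1..n_max: optimize ``subset_draws_per_n`` N-subsets of the
    candidate parameters with ``restarts_per_n`` restarts each; after
    finishing a level, stop escalating if any fit so far beats
    ``error_threshold``. The first ``greedy_draws_per_n`` draws of each
    level are stochastic forward steps — they extend the incumbent best
    subset by randomly drawn extra parameters and warm-start from its fold
    values (which also keeps the best error non-increasing in N); the
    remaining draws are fully random N-subsets. The unchanged baseline
    (N = 0) is always evaluated first and accepted if it already meets the
    threshold. If nothing is accepted by N = n_max, an empty ensemble with
    a structured "insufficient fit quality" report is returned (not an
    exception).
    """
    if config.error_threshold is None:
        raise InvalidInputError("config.error_threshold must be set")
    rng = np.random.default_rng(config.seed)
    ev = _Evaluator(young, data, protocol)
    names = list(config.candidate_params)
    threshold = config.error_threshold

    all_results: List[FitResult] = []
    best_per_level: List[FitResult] = []

    identity = optimize_subset((), young, None, config, protocol, rng=rng,
                               _evaluator=ev)
    all_results.append(identity)
    if identity.error <= threshold:
        members = [identity]
        return Ensemble(
            members=members, error_threshold=threshold,
            dedup_radius=config.dedup_radius,
            provenance={"seed": config.seed, "n_evaluations": ev.n_eval},
            report={"status": "accepted", "stopped_at_n": 0,
                    "n_accepted": 1},
        )

    beam: List[FitResult] = [identity]
    stopped_at = None
    for n in range(1, config.n_max + 1):
        n_greedy = min(config.greedy_draws_per_n, config.subset_draws_per_n)
        level_results: List[FitResult] = []
        # score every single-parameter extension of each incumbent with a
        # cheap one-dimensional descent, then fully optimize the best few
        extensions = []
        for base_fit in beam:
            if len(base_fit.subset) >= n:
                continue
            base = set(base_fit.subset)
            for q in names:
                if q in base:
                    continue
                score, q_fold = _score_extension(
                    ev, base_fit, q, young, config)
                extensions.append((score, q, base_fit, q_fold))
        extensions.sort(key=lambda e: e[0])
        for score, q, base_fit, q_fold in extensions[:n_greedy]:
            subset = tuple(sorted(set(base_fit.subset) | {q}))
            warm = dict(base_fit.changed)
            warm[q] = q_fold
            fit = optimize_subset(subset, young, None, config, protocol,
                                  rng=rng, _evaluator=ev, warm_start=warm)
            level_results.append(fit)
        n_random = config.subset_draws_per_n - len(level_results)
        for _ in range(max(n_random, 0)):
            idx = rng.choice(len(names), size=n, replace=False)
            subset = tuple(sorted(names[i] for i in idx))
            fit = optimize_subset(subset, young, None, config, protocol,
                                  rng=rng, _evaluator=ev, warm_start=None)
            level_results.append(fit)
        # plateau swaps: early greedy choices can trap the chain in the
        # wrong basin, so when the level is still above threshold try
        # replacing the incumbent's weakest parameters with the
        # best-scoring fresh candidates
        level_incumbent = min(level_results + beam, key=_member_sort_key)
        if (level_incumbent.error > threshold and config.swap_draws > 0
                and len(level_incumbent.subset) >= 2):
            weakest = sorted(
                level_incumbent.subset,
                key=lambda k: abs(math.log10(
                    level_incumbent.changed.get(k, 1.0))))
            fresh = [q for _s, q, _b, _f in extensions
                     if q not in level_incumbent.subset]
            for p_out, q_in in zip(weakest[:config.swap_draws],
                                   fresh[:config.swap_draws]):
                subset = tuple(sorted(
                    (set(level_incumbent.subset) - {p_out}) | {q_in}))
                warm = {k: v for k, v in level_incumbent.changed.items()
                        if k != p_out}
                fit = optimize_subset(subset, young, None, config, protocol,
                                      rng=rng, _evaluator=ev, warm_start=warm)
                level_results.append(fit)
        all_results.extend(level_results)
        # next beam: best distinct-subset fits from this level (incumbents
        # carry over so the best error never increases with N)
        pool_fits = sorted(level_results + beam, key=_member_sort_key)
        beam, seen = [], set()
        for f in pool_fits:
            if f.subset not in seen:
                beam.append(f)
                seen.add(f.subset)
            if len(beam) >= config.beam_width:
                break
        best_per_level.append(beam[0])
        if any(r.error <= threshold for r in all_results):
            stopped_at = n
            # harvest: keep fitting at this level — next-ranked extensions
            # plus fresh random subsets — so the ensemble reflects the
            # spread of near-equivalent fits, not just the first one past
            # the bar
            next_ext = n_greedy
            # candidate harvest moves: first the next-ranked extensions,
            # then swaps that replace one fitted parameter with a fresh
            # candidate — swaps change the subset's identity, which is what
            # makes harvested members genuinely distinct
            best_acc = min((r for r in all_results if r.error <= threshold),
                           key=_member_sort_key)
            swap_moves = []
            by_weakness = sorted(best_acc.subset,
                                 key=lambda k: abs(math.log10(
                                     best_acc.changed.get(k, 1.0))))
            fresh = [q for _s, q, _b, _f in extensions
                     if q not in best_acc.subset]
            for p_out in by_weakness[:6]:
                for q_in in fresh[:6]:
                    swap_moves.append((p_out, q_in))
            for _round in range(config.max_harvest_rounds):
                accepted_now = dedup_members(
                    [r for r in all_results if r.error <= threshold],
                    names, config.dedup_radius)
                if len(accepted_now) >= config.target_members:
                    break
                burst = []
                ext_burst = extensions[next_ext:next_ext + config.harvest_draws // 2]
                next_ext += len(ext_burst)
                for score, q, base_fit, q_fold in ext_burst:
                    subset = tuple(sorted(set(base_fit.subset) | {q}))
                    warm = dict(base_fit.changed)
                    warm[q] = q_fold
                    burst.append((subset, warm))
                n_swaps = config.harvest_draws - len(ext_burst)
                while n_swaps > 0 and swap_moves:
                    p_out, q_in = swap_moves.pop(0)
                    subset = tuple(sorted(
                        (set(best_acc.subset) - {p_out}) | {q_in}))
                    warm = {k: v for k, v in best_acc.changed.items()
                            if k != p_out}
                    burst.append((subset, warm))
                    n_swaps -= 1
                for subset, warm in burst:
                    fit = optimize_subset(subset, young, None, config,
                                          protocol, rng=rng, _evaluator=ev,
                                          warm_start=warm)
                    all_results.append(fit)
                if not burst:
                    break
            break

    accepted = [r for r in all_results if r.error <= threshold]
    members = dedup_members(accepted, names, config.dedup_radius)
    report = {
        "status": "accepted" if members else "insufficient fit quality",
        "stopped_at_n": stopped_at,
        "n_accepted": len(members),
        "best_error": min(r.error for r in all_results),
        "error_threshold": threshold,
        "best_error_per_level": [r.error for r in best_per_level],
    }
    return Ensemble(
        members=members,
        error_threshold=threshold,
        dedup_radius=config.dedup_radius,
        provenance={"seed": config.seed, "n_evaluations": ev.n_eval,
                    "young_label": young.label},
        report=report,
    )


def render_fold(fold: float) -> str:
    """Render a fold factor as 'k-fold higher/lower' (nearest integer)."""
    if fold == 1.0:
        return "unchanged"
    if fold > 1.0:
        return f"{round(fold)}-fold higher"
    return f"{round(1.0 / fold)}-fold lower"


def fold_change_report(ensemble: Ensemble, young: ModelParameters) -> pd.DataFrame:
    """Tabulate each member's changed parameters as fold changes.

    Columns: member, parameter, definition, fold (exact, machine-readable),
    change (rendered 'k-fold higher/lower'), error. Re-applying the exact
    folds to the young baseline reproduces each member's parameter set.
    """
    if not ensemble.members:
        raise InvalidInputError("cannot report an empty ensemble")
    rows = []
    for i, m in enumerate(ensemble.members):
        for name in sorted(m.changed):
            fold = m.changed[name]
            rows.append(
                (i, name, PARAM_DEFS[name], fold, render_fold(fold), m.error)
            )
        if not m.changed:
            rows.append((i, "", "(baseline unchanged)", 1.0, "unchanged", m.error))
    return pd.DataFrame(
        rows, columns=["member", "parameter", "definition", "fold", "change", "error"]
    )


def truth_referenced_threshold(
    truth_params: ModelParameters,
    data: TimeCourseDataset,
    protocol: DoseProtocol = DoseProtocol(dose=1.0),
    factor: float = 1.2,
) -> float:
    """Acceptance threshold pinned to the generating parameters' own error.

    For synthetic data the fit-quality bar is ``factor`` times the
    objective of the known truth on the same noisy dataset, replacing a
    judgement-based 'sufficient fit quality' call with an oracle-relative
    bound.
    """
    return factor * objective(truth_params, data, protocol)
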