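"""Ensemble orchestration: parallel trials, steering barriers, convergence.

An ensemble is N independent phase-retrieval trials advanced in logical
lock-step.  The *ordinary* ensemble never communicates.  The *steered*
ensemble runs the adaptive shrink-wrap rule in every trial; once every
trial's blur width has latched at its floor, trials are paused after 100
further cycles and then every ``mod_period`` cycles: all current maps are
scored pairwise, the minimal-score pair donates a reference, a consensus
map is built from the low-score maps and blended into every trial with
the stage's weight w.  Modification stops after ``mod_stop_cycle``; from
then on only HIO cycles run (no further shrink-wrap).

Lock-step is a logical contract, not a threading one: trials are advanced
sequentially between barrier points, so results are bit-reproducible for
a given (pattern, config, seeds) regardless of any execution concurrency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .datatypes import DiffractionPattern, PhasingConfig, SteeringConfig
from .phasing import Trial, TrialHistory, run_trial
from .steering import (
    PairScores,
    apply_transform,
    build_steering_map,
    invert_transform,
    modify_map,
    pairwise_scores,
    select_reference,
    w_schedule,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleRecord",
    "run_ordinary_ensemble",
    "run_steered_ensemble",
    "first_modification_trigger",
    "score_histogram",
    "convergence_check",
    "should_terminate",
]

HIST_BIN_WIDTH = 0.02


@dataclass
class EnsembleRecord:
    """Everything a run of N trials produced.

    ``histograms`` maps a modification stage index to the (counts, edges)
    similarity-score histogram of that stage's pairwise scores;
    ``modification_log`` records (cycle, w, reference index, number of
    qualifying maps, min pairwise score) per stage.
    """

    mode: str
    trials: List[TrialHistory]
    seeds: List[int]
    histograms: Dict[int, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    modification_log: List[dict] = field(default_factory=list)
    converged: bool = False
    terminated_early: bool = False
    trigger_cycle: Optional[int] = None

    @property
    def final_maps(self) -> List[np.ndarray]:
        return [t.final_map for t in self.trials if not t.failed]


def run_ordinary_ensemble(
    pattern: DiffractionPattern,
    config: PhasingConfig,
    n_trials: int,
    seeds: Optional[Sequence[int]] = None,
    snapshot_cycles: Sequence[int] = (),
) -> EnsembleRecord:
    """N independent trials with the ordinary shrink-wrap schedule."""
    seeds = _check_seeds(seeds, n_trials)
    trials = [
        run_trial(pattern, config, "ordinary", seed, snapshot_cycles)
        for seed in seeds
    ]
    record = EnsembleRecord(mode="ordinary", trials=trials, seeds=list(seeds))
    finals = record.final_maps
    if len(finals) >= 2:
        T = pairwise_scores(finals).T
        scores = T[np.triu_indices(len(finals), k=1)]
        record.histograms[0] = score_histogram(scores)
        record.converged = convergence_check(*record.histograms[0])
    return record


def _check_seeds(seeds: Optional[Sequence[int]], n_trials: int) -> List[int]:
    if n_trials < 2:
        raise ValueError("an ensemble needs at least two trials")
    if seeds is None:
        seeds = list(range(n_trials))
    seeds = [int(s) for s in seeds]
    if len(seeds) != n_trials or len(set(seeds)) != n_trials:
        raise ValueError("need one distinct seed per trial")
    return seeds


def first_modification_trigger(
    latch_cycles: Sequence[Optional[int]],
    sw_period: int = 100,
    post_trigger_cycles: int = 100,
) -> Optional[int]:
    """Cycle of the first consensus modification.

    ``latch_cycles`` holds, per trial, the cycle at which the adaptive
    blur width latched at its floor (None if it never did).  The trigger
    is the first cycle at which *every* trial is latched, rounded up to a
    shrink-wrap boundary, plus ``post_trigger_cycles``.  Returns None (no
    steering) if any trial never latches.
    """
    if any(c is None for c in latch_cycles):
        return None
    last = max(latch_cycles)
    boundary = int(np.ceil(last / sw_period)) * sw_period
    return boundary + post_trigger_cycles


def run_steered_ensemble(
    pattern: DiffractionPattern,
    config: PhasingConfig,
    steering: SteeringConfig,
    n_trials: int,
    seeds: Optional[Sequence[int]] = None,
    snapshot_cycles: Sequence[int] = (),
) -> EnsembleRecord:
    """N lock-step trials with adaptive shrink-wrap and consensus steering.

    Steering only ever touches the real-space maps; the measured
    amplitudes and their validity mask are never altered.
    """
    seeds = _check_seeds(seeds, n_trials)
    trials = [Trial(pattern, config, "steered_local", seed) for seed in seeds]
    wanted = sorted(set(int(c) for c in snapshot_cycles))
    snapshots: List[Dict[int, np.ndarray]] = [{} for _ in trials]
    latch_cycle: List[Optional[int]] = [None] * n_trials
    record = EnsembleRecord(mode="steered", trials=[], seeds=list(seeds))

    def _advance_to(target: int, skip_last_sw: bool = False) -> None:
        """Advance every trial to `target`, running SW at each shrink-wrap
        boundary up to mod_stop_cycle and collecting snapshots along the
        way.  ``skip_last_sw`` suppresses the SW event at `target` itself
        (modification cycles get a consensus update instead, keeping
        exactly four SW updates between consecutive modifications)."""
        while trials[0].cycle < target:
            stop = min(
                (trials[0].cycle // config.sw_period + 1) * config.sw_period,
                target,
            )
            do_sw = (
                stop % config.sw_period == 0
                and stop <= steering.mod_stop_cycle
                and not (skip_last_sw and stop == target)
            )
            for idx, tr in enumerate(trials):
                for c in [c for c in wanted if tr.cycle < c <= stop]:
                    tr.run_cycles(c - tr.cycle)
                    snapshots[idx][c] = tr.output_map()
                tr.run_cycles(stop - tr.cycle)
                if do_sw:
                    tr.sw_update()
                    if tr.zeta_latched and latch_cycle[idx] is None:
                        latch_cycle[idx] = tr.cycle
            _assert_barrier(trials)

    def _all_live_latched() -> bool:
        live = [i for i, tr in enumerate(trials) if not tr.failed]
        return bool(live) and all(latch_cycle[i] is not None for i in live)

    # Phase 1: run until every live trial has latched (checked at SW
    # boundaries).
    trigger = None
    while trials[0].cycle < config.n_cycles:
        boundary = min(trials[0].cycle + config.sw_period, config.n_cycles)
        _advance_to(boundary)
        if _all_live_latched():
            live_latch = [
                latch_cycle[i] for i, tr in enumerate(trials) if not tr.failed
            ]
            trigger = first_modification_trigger(
                live_latch, config.sw_period, steering.post_trigger_cycles
            )
            break
    if trigger is None or trigger > min(config.n_cycles, steering.mod_stop_cycle):
        logger.warning(
            "adaptive shrink-wrap never settled in all trials; "
            "running without steering"
        )
        _advance_to(config.n_cycles)
        return _finalize(record, trials, snapshots, None)

    record.trigger_cycle = trigger
    logger.info("first modification at cycle %d", trigger)

    # Phase 2: modification barriers at trigger, trigger + mod_period, ...
    stage = 0
    mod_cycle = trigger
    while mod_cycle <= min(steering.mod_stop_cycle, config.n_cycles):
        _advance_to(mod_cycle, skip_last_sw=True)
        stage += 1
        w = w_schedule(stage, steering.w0, steering.dw, steering.w_max)
        alive = [i for i, tr in enumerate(trials) if not tr.failed]
        if len(alive) < 2:
            logger.warning("fewer than two live trials; steering stops")
            break
        maps = [trials[i].output_map() for i in alive]
        scores = select_reference(
            pairwise_scores(maps), maps, steering.search_radius
        )
        rho_bar = build_steering_map(maps, scores, steering.t_threshold)
        for k, i in enumerate(alive):
            # blend the raw HIO state (not the clipped output map) so the
            # out-of-support feedback memory survives, scaled by 1 - w
            aligned = apply_transform(trials[i].rho, scores.transforms[k])
            mixed = modify_map(aligned, rho_bar, w)
            trials[i].rho = invert_transform(mixed, scores.transforms[k])
        iu = np.triu_indices(len(maps), k=1)
        pair_vals = scores.T[iu]
        record.histograms[stage] = score_histogram(pair_vals)
        n_qual = int(
            (scores.scores_vs_reference < steering.t_threshold).sum()
        )
        record.modification_log.append(
            {
                "cycle": mod_cycle,
                "stage": stage,
                "w": w,
                "reference": alive[scores.reference_index],
                "n_qualifying": n_qual,
                "min_T": float(pair_vals.min()),
            }
        )
        logger.info(
            "stage %d at cycle %d: w=%.2f reference=%d qualifying=%d min_T=%.3f",
            stage, mod_cycle, w, alive[scores.reference_index], n_qual,
            float(pair_vals.min()),
        )
        if steering.terminate_early and should_terminate(
            [e["min_T"] for e in record.modification_log],
            steering.t_threshold,
            steering.terminate_patience,
        ):
            record.terminated_early = True
            logger.warning("no low-score pairs for %d stages; terminating",
                           steering.terminate_patience)
            return _finalize(record, trials, snapshots, trigger)
        mod_cycle += steering.mod_period

    # Phase 3: pure HIO tail (no shrink-wrap past mod_stop_cycle).
    _advance_to(config.n_cycles)
    return _finalize(record, trials, snapshots, trigger)


def _assert_barrier(trials: Sequence[Trial]) -> None:
    cycles = {tr.cycle for tr in trials}
    if len(cycles) != 1:
        raise RuntimeError(f"lock-step violated: cycle counters {cycles}")


def _finalize(
    record: EnsembleRecord,
    trials: Sequence[Trial],
    snapshots: Sequence[Dict[int, np.ndarray]],
    trigger: Optional[int],
) -> EnsembleRecord:
    record.trials = [
        TrialHistory(
            final_map=tr.output_map(),
            final_support=tr.support.copy(),
            snapshots=snapshots[i],
            cycle=tr.cycle,
            zeta=tr.zeta,
            zeta_latched=tr.zeta_latched,
            failed=tr.failed,
            seed=tr.seed,
        )
        for i, tr in enumerate(trials)
    ]
    record.trigger_cycle = trigger
    finals = record.final_maps
    if len(finals) >= 2:
        T = pairwise_scores(finals).T
        vals = T[np.triu_indices(len(finals), k=1)]
        final_stage = max(record.histograms) + 1 if record.histograms else 0
        record.histograms[final_stage] = score_histogram(vals)
        record.converged = convergence_check(*record.histograms[final_stage])
    return record


def score_histogram(
    values: Sequence[float], bin_width: float = HIST_BIN_WIDTH
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of similarity scores over [0, 1] with fixed-width bins."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one score")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, edges = np.histogram(np.clip(values, 0.0, 1.0), bins=edges)
    return counts, edges


def _smooth(counts: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(float), kernel, mode="same")


def convergence_check(counts: np.ndarray, edges: np.ndarray) -> bool:
    """Has the score distribution collapsed to one narrow realistic peak?

    True iff the (3-bin moving-average smoothed) histogram has exactly one
    local maximum, its center lies in (0.05, 0.2), and its full width at
    half maximum is below 0.1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return False
    sm = _smooth(counts)
    centers = (np.asarray(edges)[:-1] + np.asarray(edges)[1:]) / 2.0
    # pad so boundary maxima count as peaks; find_peaks handles flat tops
    padded = np.concatenate([[-1.0], sm, [-1.0]])
    peaks, props = signal.find_peaks(padded, plateau_size=1)
    peaks = peaks - 1
    if len(peaks) != 1:
        return False
    # center of a flat top: middle of the plateau
    p = int((props["left_edges"][0] + props["right_edges"][0]) / 2) - 1
    if not 0.05 < centers[p] < 0.2:
        return False
    return _fwhm(sm, centers, p) < 0.1


def _fwhm(sm: np.ndarray, centers: np.ndarray, peak: int) -> float:
    """Full width at half maximum by linear interpolation of the crossings."""
    half = sm[peak] / 2.0
    left = centers[0]
    for i in range(peak, 0, -1):
        if sm[i - 1] < half <= sm[i]:
            frac = (half - sm[i - 1]) / (sm[i] - sm[i - 1])
            left = centers[i - 1] + frac * (centers[i] - centers[i - 1])
            break
    right = centers[-1]
    for i in range(peak, len(sm) - 1):
        if sm[i + 1] < half <= sm[i]:
            frac = (sm[i] - half) / (sm[i] - sm[i + 1])
            right = centers[i] + frac * (centers[i + 1] - centers[i])
            break
    return right - left


def should_terminate(
    stage_min_scores: Sequence[float],
    t_threshold: float = 0.2,
    patience: int = 3,
) -> bool:
    """Stop steering when no pair has scored below the threshold for
    ``patience`` consecutive completed stages."""
    if len(stage_min_scores) < patience:
        return False
    recent = stage_min_scores[-patience:]
    return all(s >= t_threshold for s in recent)
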