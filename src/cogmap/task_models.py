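"""Task models that emit module demand traces.

Two schedule-level task simulations are provided: a pyramid-algebra task
(repeated-addition arithmetic, ``base $ height = value``) and a threaded
multitasking battery (visual tracking, 2-back letters, tone counting, and
their pairwise combinations).  Both emit :class:`DemandTrace` objects — per
module lists of half-open activity intervals in seconds — which downstream
modules convolve with a hemodynamic response function to predict BOLD.

Modules are the six independent serial resources of the cognitive
architecture: visual, aural, left/right manual, declarative memory, and the
problem state (working memory).  A module can serve one request at a time;
concurrent tasks queue first-come-first-served.  These are schedule-level
approximations: there is no production-rule engine and no subsymbolic
activation — only interval timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MODULES",
    "DemandTrace",
    "TrialSpec",
    "AlgebraParams",
    "MultitaskParams",
    "PyramidSolution",
    "MULTITASK_CONDITIONS",
    "pyramid_value",
    "pyramid_solve",
    "count_carries",
    "generate_algebra_trace",
    "generate_multitask_trace",
    "generate_algebra_session",
    "generate_multitask_session",
    "merge_traces",
]

#: Canonical module labels, in fixed order (also the design-matrix order).
MODULES: tuple[str, ...] = (
    "visual",
    "aural",
    "manual_left",
    "manual_right",
    "declarative",
    "problem_state",
)

_MODULE_SET = frozenset(MODULES)


def _check_module(label: str) -> str:
    if label not in _MODULE_SET:
        raise ValueError(
            f"unknown module label {label!r}; expected one of {sorted(_MODULE_SET)}"
        )
    return label


@dataclass
class DemandTrace:
    """Per-module sorted, pairwise-disjoint activity intervals for one run.

    ``intervals`` maps a module label to a list of ``(onset, offset)`` pairs
    in seconds, half-open ``[onset, offset)``.  Seriality of each module is
    an invariant: intervals within a module never overlap.
    """

    run_id: str
    intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for module, ivs in self.intervals.items():
            _check_module(module)
            self.intervals[module] = sorted((float(a), float(b)) for a, b in ivs)
            self._validate_module(module)

    def _validate_module(self, module: str) -> None:
        prev_off = -np.inf
        for onset, offset in self.intervals[module]:
            if not (0.0 <= onset < offset):
                raise ValueError(
                    f"invalid interval ({onset}, {offset}) for module {module!r}: "
                    "need 0 <= onset < offset"
                )
            if onset < prev_off:
                raise ValueError(
                    f"overlapping intervals in module {module!r} near t={onset:.3f}"
                )
            prev_off = offset

    def module_intervals(self, module: str) -> list[tuple[float, float]]:
        return self.intervals.get(_check_module(module), [])

    def total_duration(self, module: str) -> float:
        return float(sum(b - a for a, b in self.module_intervals(module)))

    def n_events(self, module: str) -> int:
        return len(self.module_intervals(module))

    @property
    def end_time(self) -> float:
        offs = [b for ivs in self.intervals.values() for _, b in ivs]
        return max(offs) if offs else 0.0

    def active_modules(self) -> list[str]:
        return [m for m in MODULES if self.intervals.get(m)]


def merge_traces(run_id: str, traces: Iterable[DemandTrace]) -> DemandTrace:
    """Concatenate per-trial traces into one run-level trace.

    Intervals must already be expressed in absolute run time and must not
    overlap within a module across trials.
    """
    merged: dict[str, list[tuple[float, float]]] = {}
    for tr in traces:
        for m, ivs in tr.intervals.items():
            merged.setdefault(m, []).extend(ivs)
    return DemandTrace(run_id=run_id, intervals=merged)


@dataclass(frozen=True)
class TrialSpec:
    """One trial: condition label, onset/duration in run time, task payload."""

    condition: str
    onset: float
    duration: float
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        if self.onset < 0:
            raise ValueError("trial onset must be non-negative")


@dataclass(frozen=True)
class AlgebraParams:
    """Timing parameters of the pyramid-algebra model.

    ``retrieval_mean`` is the mean declarative retrieval latency (483 ms
    for this task, as estimated from behavior).  Retrieval
    durations are drawn from a gamma distribution with that mean and shape
    ``retrieval_shape``; set ``retrieval_shape=None`` for a fixed constant.
    """

    retrieval_mean: float = 0.483
    retrieval_shape: float | None = 2.0
    encode_step: float = 0.3
    motor_step: float = 0.5
    ps_step: float = 0.2
    carry_extra: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("retrieval_mean", "encode_step", "motor_step", "ps_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.carry_extra < 0:
            raise ValueError("carry_extra must be non-negative")


@dataclass(frozen=True)
class MultitaskParams:
    """Timing parameters of the multitask battery.

    Defaults encode the experimental design: 20 tones over a 30 s trial with
    10–17 high tones to count, a 12-letter 2-back stream at 1000 ms on +
    1500 ms blank, and a 10 s response window appended to counting trials.
    """

    n_tones: int = 20
    trial_len: float = 30.0
    response_window: float = 10.0
    high_tone_range: tuple[int, int] = (10, 17)
    letter_on: float = 1.0
    letter_blank: float = 1.5
    n_letters: int = 12
    swap_store_dur: float = 0.3
    swap_retrieve_dur: float = 0.3
    tracking_sample_dur: float = 0.2
    tracking_press_dur: float = 0.15
    tone_encode_dur: float = 0.3
    letter_encode_dur: float = 0.185
    retrieval_dur: float = 0.3
    ps_update_dur: float = 0.2
    press_dur: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tones <= 0 or self.n_letters <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.high_tone_range
        if not (0 <= lo <= hi <= self.n_tones):
            raise ValueError("high_tone_range must lie within [0, n_tones]")
        for name in (
            "trial_len", "response_window", "letter_on", "letter_blank",
            "swap_store_dur", "swap_retrieve_dur", "tracking_sample_dur",
            "tracking_press_dur", "tone_encode_dur", "letter_encode_dur",
            "retrieval_dur", "ps_update_dur", "press_dur",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


MULTITASK_CONDITIONS: tuple[str, ...] = (
    "track", "nback", "count", "track+nback", "track+count", "nback+count",
)


# ---------------------------------------------------------------------------
# Pyramid arithmetic
# ---------------------------------------------------------------------------

def pyramid_value(base: int, height: int) -> int:
    """Value of the pyramid ``base $ height``: sum of ``height`` terms
    starting at ``base`` and decreasing by one (4 $ 3 = 4 + 3 + 2 = 9)."""
    base, height = int(base), int(height)
    if base < 1 or height < 1:
        raise ValueError("base and height must be positive integers")
    if height > base:
        raise ValueError(f"invalid pyramid: height {height} exceeds base {base}")
    return sum(base - i for i in range(height))


def _addition_chain(base: int, height: int) -> list[tuple[int, int, int]]:
    """Ordered chain of the ``height - 1`` additions solving base $ height.

    Each element is ``(accumulator, addend, sum)``; e.g. 4 $ 3 yields
    ``[(4, 3, 7), (7, 2, 9)]``.
    """
    chain = []
    acc = base
    for i in range(1, height):
        term = base - i
        chain.append((acc, term, acc + term))
        acc += term
    return chain


def count_carries(chain: Sequence[tuple[int, int, int] | tuple[int, int]]) -> int:
    """Number of additions in the chain requiring a column-addition carry,
    i.e. whose units digits sum to 10 or more (9 + 8 and 17 + 7 both carry)."""
    n = 0
    for step in chain:
        a, b = int(step[0]), int(step[1])
        if a < 0 or b < 0:
            raise ValueError("chain operands must be non-negative")
        if a % 10 + b % 10 >= 10:
            n += 1
    return n


@dataclass(frozen=True)
class PyramidSolution:
    """Result of solving a pyramid problem for its single unknown."""

    base: int
    height: int
    value: int
    unknown: str
    answer: int
    chain: list[tuple[int, int, int]]
    exact: bool  # False when the guess-and-check answer misses the true base

    @property
    def n_carries(self) -> int:
        return count_carries(self.chain)


_BASE_RANGE = (4, 9)  # experimental base range; also bounds guess-and-check


def pyramid_solve(
    base: int | None = None,
    height: int | None = None,
    value: int | None = None,
    *,
    base_range: tuple[int, int] = _BASE_RANGE,
) -> PyramidSolution:
    """Solve a pyramid problem with exactly one unknown, as the model does.

    Unknown value: iterate the addition chain.  Unknown height: run the same
    chain until the accumulator matches ``value`` (smallest height).  Unknown
    base: guess-and-check — evaluate one guessed base (the upper midpoint of
    ``base_range``) and report guess, guess+1 (result too small) or guess−1
    (too big); ``exact`` is False when that report misses the true base.
    """
    unknowns = [n for n, v in (("base", base), ("height", height), ("value", value))
                if v is None]
    if len(unknowns) != 1:
        raise ValueError("exactly one of base/height/value must be unknown")
    unknown = unknowns[0]

    if unknown == "value":
        v = pyramid_value(base, height)
        return PyramidSolution(base, height, v, "value", v,
                               _addition_chain(base, height), True)

    if unknown == "height":
        if value == base:
            return PyramidSolution(base, 1, value, "height", 1, [], True)
        acc = base
        chain = []
        for i in range(1, base):
            term = base - i
            chain.append((acc, term, acc + term))
            acc += term
            if acc == value:
                return PyramidSolution(base, i + 1, value, "height", i + 1,
                                       chain, True)
            if acc > value:
                break
        return PyramidSolution(base, -1, value, "height", -1, chain, False)

    # unknown base: single guess-and-check step
    lo, hi = base_range
    guess = (lo + hi + 1) // 2
    try:
        got = pyramid_value(guess, height)
    except ValueError:
        return PyramidSolution(-1, height, value, "base", -1, [], False)
    chain = _addition_chain(guess, height)
    if got == value:
        answer = guess
    elif got < value:
        answer = guess + 1
    else:
        answer = guess - 1
    exact = (
        1 <= height <= answer and pyramid_value(answer, height) == value
    )
    return PyramidSolution(answer, height, value, "base", answer, chain, exact)


# ---------------------------------------------------------------------------
# Algebra trace generation
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates intervals; seriality is the caller's responsibility."""

    def __init__(self) -> None:
        self.intervals: dict[str, list[tuple[float, float]]] = {}

    def add(self, module: str, onset: float, duration: float) -> float:
        self.intervals.setdefault(module, []).append((onset, onset + duration))
        return onset + duration

    def trace(self, run_id: str) -> DemandTrace:
        return DemandTrace(run_id=run_id, intervals=self.intervals)


def _retrieval_duration(params: AlgebraParams, rng: np.random.Generator) -> float:
    if params.retrieval_shape is None:
        return params.retrieval_mean
    shape = params.retrieval_shape
    return float(rng.gamma(shape, params.retrieval_mean / shape))


def generate_algebra_trace(
    trial: TrialSpec,
    params: AlgebraParams,
    rng: np.random.Generator,
) -> tuple[DemandTrace, float]:
    """Demand trace and simulated RT for one pyramid trial.

    The model encodes the three problem slots visually, runs the addition
    chain (one declarative retrieval plus one problem-state update per step,
    an extra problem-state interval per carry), then clicks the answer's
    digits and the submit button with the right hand.  All steps are strictly
    sequential, so the RT is the offset of the last manual interval relative
    to trial onset.

    ``trial.payload`` must contain ``base``/``height``/``value`` with exactly
    one of them ``None`` (the unknown).
    """
    p = trial.payload
    sol = pyramid_solve(p.get("base"), p.get("height"), p.get("value"))
    b = _Builder()
    t = trial.onset
    for _ in range(3):  # attend base, height, value slots in turn
        t = b.add("visual", t, params.encode_step)
    for step in sol.chain:
        t = b.add("declarative", t, _retrieval_duration(params, rng))
        t = b.add("problem_state", t, params.ps_step)
        if step[0] % 10 + step[1] % 10 >= 10 and params.carry_extra > 0:
            t = b.add("problem_state", t, params.carry_extra)
    answer = sol.answer if sol.answer >= 0 else 0
    n_digits = len(str(answer))
    for _ in range(n_digits + 1):  # digit clicks + submit
        t = b.add("manual_right", t, params.motor_step)
    rt = t - trial.onset
    return b.trace(run_id=f"trial-{trial.condition}"), rt


def _algebra_condition(base: int, height: int) -> str:
    return ("large" if base >= 7 else "small") + "_" + ("large" if height >= 4 else "small")


def generate_algebra_session(
    params: AlgebraParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    n_per_condition: int = 18,
    trial_slot: float = 51.0,
    problem_duration: float = 30.0,
) -> tuple[DemandTrace, list[TrialSpec], "np.ndarray"]:
    """Full scanner session of the algebra task.

    Generates ``4 × n_per_condition`` trials (conditions cross small/large
    base 4–6/7–9 with small/large height 2–3/4–5), shuffled, one per
    ``trial_slot`` seconds (30 s problem + feedback, repetition detection and
    fixation).  The unknown slot rotates over value/height/base.  Returns the
    merged run trace, the trial specs, and the per-trial simulated RTs.
    """
    params = params or AlgebraParams()
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    cells = [(bs, hs) for bs in ("small", "large") for hs in ("small", "large")]
    problems: list[tuple[int, int]] = []
    for bs, hs in cells:
        bases = (4, 5, 6) if bs == "small" else (7, 8, 9)
        heights = (2, 3) if hs == "small" else (4, 5)
        for k in range(n_per_condition):
            base = int(rng.choice(bases))
            height = int(rng.choice([h for h in heights if h <= base]))
            problems.append((base, height))
    order = rng.permutation(len(problems))
    unknown_cycle = ("value", "height", "base")
    trials: list[TrialSpec] = []
    traces: list[DemandTrace] = []
    rts = np.empty(len(problems))
    for i, j in enumerate(order):
        base, height = problems[j]
        value = pyramid_value(base, height)
        payload = {"base": base, "height": height, "value": value}
        payload[unknown_cycle[i % 3]] = None
        trial = TrialSpec(
            condition=_algebra_condition(base, height),
            onset=i * trial_slot,
            duration=problem_duration,
            payload=payload,
        )
        trace, rt = generate_algebra_trace(trial, params, rng)
        trials.append(trial)
        traces.append(trace)
        rts[i] = rt
    return merge_traces("algebra-session", traces), trials, rts


# ---------------------------------------------------------------------------
# Threaded multitask trace generation
# ---------------------------------------------------------------------------

@dataclass
class _Step:
    module: str
    duration: float
    anchor: float | None = None  # earliest start, trial-relative; None = ASAP
    is_ps: bool = False          # problem-state ownership handover tracking
    swap_inserted: bool = False  # swap already scheduled for this handover


_TASK_ORDER = {"track": 0, "nback": 1, "count": 2}


def _tracking_steps(params: MultitaskParams) -> list[_Step]:
    steps: list[_Step] = []
    cycle = params.tracking_sample_dur + params.tracking_press_dur
    t = 0.0
    while t < params.trial_len:
        steps.append(_Step("visual", params.tracking_sample_dur, anchor=t))
        steps.append(_Step("manual_right", params.tracking_press_dur))
        t += cycle
    return steps


def _nback_steps(params: MultitaskParams, hand: str) -> list[_Step]:
    soa = params.letter_on + params.letter_blank
    steps: list[_Step] = []
    for k in range(params.n_letters):
        onset = k * soa
        steps.append(_Step("visual", params.letter_encode_dur, anchor=onset))
        if k >= 2:  # two-back comparison requires a declarative retrieval
            steps.append(_Step("declarative", params.retrieval_dur))
        steps.append(_Step("problem_state", params.ps_update_dur, is_ps=True))
        steps.append(_Step(hand, params.press_dur))
    return steps


def _count_steps(
    params: MultitaskParams, rng: np.random.Generator, hand: str
) -> tuple[list[_Step], int]:
    lo, hi = params.high_tone_range
    n_high = int(rng.integers(lo, hi + 1))
    high = np.zeros(params.n_tones, bool)
    high[rng.choice(params.n_tones, size=n_high, replace=False)] = True
    sep = params.trial_len / params.n_tones
    steps: list[_Step] = []
    for k in range(params.n_tones):
        steps.append(_Step("aural", params.tone_encode_dur, anchor=k * sep))
        if high[k]:
            steps.append(_Step("problem_state", params.ps_update_dur, is_ps=True))
    # response phase: increment the on-screen counter once per counted tone
    for r in range(n_high):
        anchor = params.trial_len if r == 0 else None
        steps.append(_Step(hand, params.press_dur, anchor=anchor))
    return steps, n_high


def generate_multitask_trace(
    condition: str,
    params: MultitaskParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    onset: float = 0.0,
) -> DemandTrace:
    """Demand trace for one multitask trial under a greedy threaded scheduler.

    Each task is a thread of ordered resource requests; modules serve one
    request at a time and queue competing threads first-come-first-served
    (ties: earlier previous completion, then fixed task order track < nback <
    count).  Whenever the problem state changes hands between threads, a
    declarative store and retrieve (the swap) are inserted first — this only
    ever fires in the ``nback+count`` condition, whose two threads both hold
    state there.
    """
    params = params or MultitaskParams()
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    if condition not in MULTITASK_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {MULTITASK_CONDITIONS}"
        )
    tasks = condition.split("+")
    threads: dict[str, list[_Step]] = {}
    for task in tasks:
        if task == "track":
            threads["track"] = _tracking_steps(params)
        elif task == "nback":
            threads["nback"] = _nback_steps(params, hand="manual_left")
        elif task == "count":
            # right hand alone or with n-back; left hand when paired with tracking
            hand = "manual_left" if "track" in tasks else "manual_right"
            threads["count"], _ = _count_steps(params, rng, hand=hand)

    builder = _Builder()
    idx = {task: 0 for task in threads}
    ready = {task: 0.0 for task in threads}
    module_free: dict[str, float] = {}
    ps_owner: str | None = None

    while any(idx[t] < len(threads[t]) for t in threads):
        best: tuple[float, float, int] | None = None
        best_task = None
        for task in threads:
            i = idx[task]
            if i >= len(threads[task]):
                continue
            step = threads[task][i]
            est = max(ready[task], module_free.get(step.module, 0.0))
            if step.anchor is not None:
                est = max(est, step.anchor)
            key = (est, ready[task], _TASK_ORDER[task])
            if best is None or key < best:
                best, best_task = key, task
        assert best_task is not None
        step = threads[best_task][idx[best_task]]
        if step.is_ps and not step.swap_inserted and ps_owner not in (None, best_task):
            # swap the displaced thread's problem state out via declarative memory
            step.swap_inserted = True
            threads[best_task][idx[best_task]:idx[best_task]] = [
                _Step("declarative", params.swap_store_dur),
                _Step("declarative", params.swap_retrieve_dur),
            ]
            continue
        start = best[0]
        end = builder.add(step.module, onset + start, step.duration)
        module_free[step.module] = end - onset
        ready[best_task] = end - onset
        if step.is_ps:
            ps_owner = best_task
        idx[best_task] += 1

    return builder.trace(run_id=f"trial-{condition}")


def generate_multitask_session(
    params: MultitaskParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    n_per_condition: int = 12,
    trial_slot: float = 40.0,
) -> tuple[DemandTrace, list[TrialSpec]]:
    """Full session of the multitask battery: ``6 × n_per_condition`` trials
    in shuffled order, one per ``trial_slot`` seconds (30 s trial + response
    window / rest)."""
    params = params or MultitaskParams()
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    conditions = list(MULTITASK_CONDITIONS) * n_per_condition
    order = rng.permutation(len(conditions))
    trials: list[TrialSpec] = []
    traces: list[DemandTrace] = []
    for i, j in enumerate(order):
        cond = conditions[j]
        onset = i * trial_slot
        trials.append(TrialSpec(condition=cond, onset=onset, duration=params.trial_len))
        traces.append(generate_multitask_trace(cond, params, rng, onset=onset))
    return merge_traces("multitask-session", traces), trials
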