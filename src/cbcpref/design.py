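"""Randomized choice-task design: generation, diagnostics, sample size.

Each respondent receives a personal block of random tasks plus fixed holdout
tasks shared by everyone.  Random tasks are built greedily, one attribute at
a time, by a minimal-overlap / level-balance rule: within a task the
alternatives take distinct levels whenever the attribute has at least as
many levels as alternatives, and across a respondent's random tasks every
level of every attribute appears a floor-or-ceil-balanced number of times.
Ties are broken uniformly at random, which keeps pairwise attribute-level
joint frequencies close to independence (near-orthogonality) without an
explicit search.

Sample-size guidance comes two ways: Johnson's rule of thumb
``n >= 500 c / (t a)`` (c = max levels on any attribute, t = tasks,
a = alternatives), and a simulation that fits an aggregate logit to
uniform-random dummy choices on freshly generated designs and finds the
smallest n whose expected maximum coded-parameter standard error meets a
target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import (
    ConfigurationError,
    CorruptDesignError,
    InfeasibleDesignError,
    NoValidHoldoutError,
    TargetNotMetError,
)
from .schema import AttributeSchema

RANDOM, HOLDOUT = "random", "holdout"


@dataclass(frozen=True)
class ChoiceTask:
    """One choice question: ``a`` full-profile alternatives, pick one.

    ``alternatives`` holds 0-based level indices, one per attribute.
    """

    task_id: str
    position: int
    task_type: str
    alternatives: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "alternatives", tuple(tuple(int(v) for v in alt) for alt in self.alternatives)
        )
        if self.task_type not in (RANDOM, HOLDOUT):
            raise ConfigurationError(f"unknown task_type {self.task_type!r}")
        if self.position < 1:
            raise ConfigurationError("task position is 1-based")
        if len(set(self.alternatives)) != len(self.alternatives):
            raise InfeasibleDesignError(
                f"task {self.task_id!r}: alternatives must be pairwise distinct"
            )

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)


@dataclass(frozen=True)
class RespondentDesign:
    """The ordered task sequence one respondent answers."""

    respondent_id: str
    tasks: tuple[ChoiceTask, ...]

    def __post_init__(self):
        object.__setattr__(self, "tasks", tuple(self.tasks))

    @property
    def random_tasks(self) -> tuple[ChoiceTask, ...]:
        return tuple(t for t in self.tasks if t.task_type == RANDOM)

    @property
    def holdout_tasks(self) -> tuple[ChoiceTask, ...]:
        return tuple(t for t in self.tasks if t.task_type == HOLDOUT)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to Johnson's rule: c = max levels per attribute, t = task
    repetitions, a = alternatives per task, and the SE target used by the
    simulation-based check."""

    c: int
    t: int
    a: int
    se_target: float = 0.05

    def __post_init__(self):
        if min(self.c, self.t, self.a) < 1:
            raise ConfigurationError("c, t and a must be positive integers")
        if self.se_target <= 0:
            raise ConfigurationError("se_target must be positive")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_task_levels(schema: AttributeSchema, t: int, a: int, rng) -> np.ndarray:
    """Level indices for t random tasks, shape (t, a, n_attributes).

    Greedy per attribute: each task takes the ``a`` least-used levels so far
    (random tie-break), guaranteeing within-task distinctness when the
    attribute has >= a levels and floor/ceil balance of level counts over
    the t*a concept slots.
    """
    n_attr = schema.n_attributes
    out = np.empty((t, a, n_attr), dtype=np.int64)
    for j, m in enumerate(schema.level_counts):
        counts = np.zeros(m)
        for task in range(t):
            order = np.argsort(counts + rng.random(m), kind="stable")
            sel = order[np.arange(a) % m]      # repeats only if a > m
            out[task, :, j] = rng.permutation(sel)
            counts[sel] += 1
    return out


def generate_respondent_design(
    schema: AttributeSchema,
    t: int,
    a: int,
    holdouts: tuple[ChoiceTask, ...] = (),
    holdout_positions: tuple[int, ...] = (),
    seed=None,
    respondent_id: str = "r1",
    rng=None,
) -> RespondentDesign:
    """Generate one respondent's block of t random tasks plus holdouts.

    Holdouts are inserted at the given 1-based positions within the final
    sequence of ``t + len(holdouts)`` tasks; the random tasks fill the
    remaining positions in generation order.  Deterministic given ``seed``.
    """
    if a < 2:
        raise ConfigurationError("need at least 2 alternatives per task")
    if t < 1:
        raise ConfigurationError("need at least 1 random task")
    n_profiles = math.prod(schema.level_counts)
    if a > n_profiles:
        raise InfeasibleDesignError(
            f"{a} alternatives but only {n_profiles} distinct profiles exist"
        )
    if len(holdouts) != len(holdout_positions):
        raise ConfigurationError("one position per holdout task required")
    total = t + len(holdouts)
    if holdout_positions and (
        len(set(holdout_positions)) != len(holdout_positions)
        or min(holdout_positions) < 1
        or max(holdout_positions) > total
    ):
        raise ConfigurationError(
            f"holdout positions must be distinct and within 1..{total}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    levels = _random_task_levels(schema, t, a, rng)
    if a > min(schema.level_counts):
        # overlap is unavoidable on some attribute; enforce distinct profiles
        for task in range(t):
            tries = 0
            while len({tuple(row) for row in levels[task]}) < a:
                j = int(np.argmax(schema.level_counts))
                levels[task, :, j] = rng.permutation(levels[task, :, j])
                tries += 1
                if tries > 100:
                    raise InfeasibleDesignError(
                        "could not construct pairwise-distinct alternatives"
                    )

    holdout_by_pos = dict(zip(holdout_positions, holdouts))
    tasks, next_random = [], 0
    for pos in range(1, total + 1):
        if pos in holdout_by_pos:
            tasks.append(replace(holdout_by_pos[pos], position=pos))
        else:
            tasks.append(
                ChoiceTask(
                    task_id=f"R{next_random + 1}",
                    position=pos,
                    task_type=RANDOM,
                    alternatives=tuple(map(tuple, levels[next_random])),
                )
            )
            next_random += 1
    return RespondentDesign(respondent_id=str(respondent_id), tasks=tuple(tasks))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DesignDiagnostics:
    """Balance / overlap / orthogonality summary of a set of designs.

    ``level_frequencies`` aggregates level appearances over all tasks and
    respondents; ``max_balance_deviation`` is the worst per-respondent,
    per-attribute spread (max count - min count) over random tasks;
    ``within_task_overlap_count`` totals repeated levels inside tasks; and
    ``pairwise_joint_frequency_deviation`` is the mean absolute deviation of
    attribute-pair joint level proportions from the independence expectation
    (0 for a perfectly orthogonal design).
    """

    level_frequencies: dict[str, np.ndarray]
    max_balance_deviation: int
    within_task_overlap_count: int
    pairwise_joint_frequency_deviation: float


def check_design(
    designs: list[RespondentDesign], schema: AttributeSchema
) -> DesignDiagnostics:
    if not designs:
        raise ConfigurationError("no designs to check")
    n_attr = schema.n_attributes
    freqs = {name: np.zeros(m, dtype=np.int64)
             for name, m in zip(schema.names, schema.level_counts)}
    overlap = 0
    max_dev = 0
    random_rows = []
    for d in designs:
        per_resp = [np.zeros(m, dtype=np.int64) for m in schema.level_counts]
        for task in d.tasks:
            arr = np.asarray(task.alternatives)
            if arr.shape[1] != n_attr:
                raise CorruptDesignError(
                    f"task {task.task_id!r} has {arr.shape[1]} attributes"
                )
            for j, (name, m) in enumerate(zip(schema.names, schema.level_counts)):
                col = arr[:, j]
                if col.min() < 0 or col.max() >= m:
                    raise CorruptDesignError(
                        f"task {task.task_id!r}: level index out of range "
                        f"for attribute {name!r}"
                    )
                binc = np.bincount(col, minlength=m)
                freqs[name] += binc
                overlap += len(col) - np.count_nonzero(binc)
                if task.task_type == RANDOM:
                    per_resp[j] += binc
            if task.task_type == RANDOM:
                random_rows.append(arr)
        for c in per_resp:
            if c.sum():
                max_dev = max(max_dev, int(c.max() - c.min()))

    pooled = np.concatenate(random_rows) if random_rows else np.empty((0, n_attr), int)
    devs = []
    if len(pooled):
        N = len(pooled)
        for j1, j2 in combinations(range(n_attr), 2):
            m1, m2 = schema.level_counts[j1], schema.level_counts[j2]
            joint = np.zeros((m1, m2))
            np.add.at(joint, (pooled[:, j1], pooled[:, j2]), 1.0)
            joint /= N
            expected = np.outer(joint.sum(axis=1), joint.sum(axis=0))
            devs.append(np.abs(joint - expected).mean())
    return DesignDiagnostics(
        level_frequencies=freqs,
        max_balance_deviation=max_dev,
        within_task_overlap_count=int(overlap),
        pairwise_joint_frequency_deviation=float(np.mean(devs)) if devs else 0.0,
    )


# ---------------------------------------------------------------------------
# holdouts
# ---------------------------------------------------------------------------

def construct_holdout(
    schema: AttributeSchema,
    reference_utilities,
    share_range: tuple[float, float] = (0.60, 0.80),
    seed=None,
    rng=None,
    task_id: str = "H1",
    scale: float = 1.0,
    max_tries: int = 5000,
) -> ChoiceTask:
    """Search for a two-alternative task with a clear but not dominant winner.

    Random minimal-overlap profile pairs are drawn until the preferred
    alternative's logit share under ``reference_utilities`` falls strictly
    inside ``share_range`` (default 0.60-0.80, between chance and dominance).
    """
    lo, hi = share_range
    if not (0.5 <= lo < hi <= 1.0):
        raise ConfigurationError("share_range must lie within (0.5, 1.0)")
    if rng is None:
        rng = np.random.default_rng(seed)
    beta = np.asarray(reference_utilities, dtype=float)
    for _ in range(max_tries):
        pair = np.stack(
            [rng.choice(m, size=2, replace=False) for m in schema.level_counts],
            axis=1,
        )
        u = schema.code_profiles(pair) @ beta * scale
        share = float(expit(abs(u[0] - u[1])))
        if lo < share < hi:
            return ChoiceTask(
                task_id=task_id,
                position=1,
                task_type=HOLDOUT,
                alternatives=tuple(map(tuple, pair)),
            )
    raise NoValidHoldoutError(
        f"no profile pair reached a preferred share in ({lo}, {hi}) "
        f"after {max_tries} draws"
    )


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def johnson_rule(spec_or_c, t: int | None = None, a: int | None = None) -> int:
    """Johnson's rule-of-thumb minimum respondent count, ceil(500 c / (t a)).

    Accepts a :class:`SampleSizeSpec` or the three integers directly.
    Monotone nondecreasing in c, nonincreasing in t and a.
    """
    if isinstance(spec_or_c, SampleSizeSpec):
        c, t, a = spec_or_c.c, spec_or_c.t, spec_or_c.a
    else:
        c = spec_or_c
        if t is None or a is None:
            raise ConfigurationError("johnson_rule needs c, t and a")
        SampleSizeSpec(c=c, t=t, a=a)  # validation
    return math.ceil(500 * c / (t * a))


@dataclass
class SampleSizeResult:
    """Outcome of the dummy-respondent design simulation."""

    n_required: int
    se_target: float
    table: pd.DataFrame  # columns: n, mean_max_se, sd_max_se, replicates


def simulate_sample_size(
    schema: AttributeSchema,
    t: int,
    a: int,
    se_target: float,
    n_grid,
    replicates: int = 20,
    seed=None,
) -> SampleSizeResult:
    """Find the smallest sample size meeting an expected-SE criterion.

    For each candidate n, ``replicates`` panels of n dummy respondents are
    simulated: each receives a freshly generated t-task design and chooses
    uniformly at random.  An aggregate effects-coded logit is fit per panel
    and the maximum standard error over coded parameters recorded; the
    criterion is the replicate mean of that maximum.  ``t`` counts every
    task the dummy-data fit uses (at the design stage holdouts look exactly
    like any other task, so the full questionnaire length belongs here).

    Raises :class:`TargetNotMetError` (carrying the SE table) if no grid
    value meets the target.
    """
    from .models import fit_mnl_arrays  # deferred: avoids an import cycle

    n_grid = [int(n) for n in n_grid]
    if not n_grid or any(
        n2 <= n1 for n1, n2 in zip(n_grid, n_grid[1:])
    ) or n_grid[0] < 2:
        raise ConfigurationError("n_grid must be ascending positive integers")
    if replicates < 1:
        raise ConfigurationError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    p = schema.n_params
    rows = []
    for n in n_grid:
        max_ses = np.empty(replicates)
        for r in range(replicates):
            levels = np.concatenate(
                [_random_task_levels(schema, t, a, rng) for _ in range(n)]
            )
            X = schema.code_profiles(levels).reshape(-1, a, p)
            chosen = rng.integers(a, size=n * t)
            _, cov, _, _ = fit_mnl_arrays(X, chosen)
            max_ses[r] = np.sqrt(np.diag(cov)).max()
        rows.append(
            {
                "n": n,
                "mean_max_se": float(max_ses.mean()),
                "sd_max_se": float(max_ses.std(ddof=1)) if replicates > 1 else 0.0,
                "replicates": replicates,
            }
        )
    table = pd.DataFrame(rows)
    ok = table.loc[table["mean_max_se"] <= se_target, "n"]
    if ok.empty:
        raise TargetNotMetError(
            f"no n in {n_grid} met SE target {se_target} "
            f"(best {table['mean_max_se'].min():.4f})",
            table=table,
        )
    return SampleSizeResult(
        n_required=int(ok.iloc[0]), se_target=se_target, table=table
    )


# ---------------------------------------------------------------------------
# design <-> frame
# ---------------------------------------------------------------------------

def designs_to_frame(
    designs: list[RespondentDesign],
    schema: AttributeSchema,
    wave: int = 1,
    group: str = "all",
) -> pd.DataFrame:
    """One row per alternative, attribute columns as 1-based level indices."""
    rows = []
    for d in designs:
        for task in d.tasks:
            for alt_i, alt in enumerate(task.alternatives, start=1):
                row = {
                    "respondent_id": d.respondent_id,
                    "group": group,
                    "wave": wave,
                    "task_id": task.task_id,
                    "position": task.position,
                    "task_type": task.task_type,
                    "alternative_id": alt_i,
                }
                row.update(
                    {name: lv + 1 for name, lv in zip(schema.names, alt)}
                )
                rows.append(row)
    return pd.DataFrame(rows)


def frame_to_designs(
    df: pd.DataFrame, schema: AttributeSchema
) -> dict[tuple[str, int], RespondentDesign]:
    """Rebuild RespondentDesign objects from a long-format frame, keyed by
    (respondent_id, wave)."""
    out = {}
    for (rid, wave), g in df.groupby(["respondent_id", "wave"], sort=False):
        tasks = []
        for (task_id, pos, ttype), tg in g.groupby(
            ["task_id", "position", "task_type"], sort=False
        ):
            tg = tg.sort_values("alternative_id")
            alts = tuple(
                tuple(int(v) - 1 for v in row)
                for row in tg[schema.names].to_numpy()
            )
            tasks.append(
                ChoiceTask(
                    task_id=str(task_id),
                    position=int(pos),
                    task_type=str(ttype),
                    alternatives=alts,
                )
            )
        tasks.sort(key=lambda tk: tk.position)
        out[(str(rid), int(wave))] = RespondentDesign(str(rid), tuple(tasks))
    return out
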