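"""Synthetic respondent panels with known preference structure.

The study population this module emulates: cancer outpatients choosing
between analgesic-treatment profiles, observed in two survey waves three
months apart.  Respondents belong to segments, each a Normal cloud of
effects-coded part-worth vectors around a segment mean.  Two kinds of
segment appear in the default panel:

* *traders*, who weigh all attributes (heterogeneous logit choosers), and
* a *lexicographic* minority, whose part-worths concentrate at least 80% of
  the total utility range on a single dominant attribute, so their choices
  are driven almost entirely by that attribute.

Wave-to-wave preference drift is Normal noise on the part-worths, and
dropout between waves is independent Bernoulli.  Every draw flows from one
seeded generator, so panels are reproducible end to end.

:func:`make_paper_like_dataset` builds the default two-group panel: 241
respondents (139 + 102), two waves with 17% dropout, group W dominated by
expected pain relief and group A trading side-effect type against pain
relief, with a 29% lexicographic subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    ChoiceTask,
    RespondentDesign,
    construct_holdout,
    generate_respondent_design,
)
from .exceptions import AlignmentError, ConfigurationError
from .schema import AttributeSchema, pain_treatment_schema

LEX_MIN_SHARE = 0.80  # a lexicographic segment's dominant share of total range


def _ranges(schema: AttributeSchema, beta: np.ndarray) -> np.ndarray:
    return np.array(
        [blk.max() - blk.min() for blk in schema.expand_partworths(beta)]
    )


@dataclass(frozen=True)
class SegmentSpec:
    """One homogeneous subpopulation of choosers.

    ``mean_partworths`` is on the effects-coded scale (length p);
    ``heterogeneity_sd`` is the per-parameter SD of the Normal cloud around
    it (scalar or length p); ``response_scale`` multiplies utilities inside
    the logit (larger = more deterministic choices).  A segment declaring a
    ``lexicographic_attribute`` must give that attribute at least 80% of
    the total utility range.
    """

    name: str
    proportion: float
    mean_partworths: tuple
    heterogeneity_sd: float | tuple = 0.0
    response_scale: float = 1.0
    lexicographic_attribute: str | None = None
    group: str | None = None

    def validate(self, schema: AttributeSchema) -> None:
        beta = np.asarray(self.mean_partworths, dtype=float)
        if beta.shape != (schema.n_params,):
            raise ConfigurationError(
                f"segment {self.name!r}: mean_partworths must have length "
                f"{schema.n_params}"
            )
        if not 0 <= self.proportion <= 1:
            raise ConfigurationError(f"segment {self.name!r}: bad proportion")
        if self.response_scale <= 0:
            raise ConfigurationError(f"segment {self.name!r}: bad response_scale")
        sd = np.broadcast_to(
            np.asarray(self.heterogeneity_sd, dtype=float), (schema.n_params,)
        )
        if (sd < 0).any():
            raise ConfigurationError(
                f"segment {self.name!r}: heterogeneity_sd must be nonnegative"
            )
        if self.lexicographic_attribute is not None:
            j = schema.attribute_index(self.lexicographic_attribute)
            r = _ranges(schema, beta)
            share = r[j] / r.sum()
            if share < LEX_MIN_SHARE - 1e-9:
                raise ConfigurationError(
                    f"lexicographic segment {self.name!r} puts only "
                    f"{share:.0%} of the utility range on "
                    f"{self.lexicographic_attribute!r} (needs >= 80%)"
                )

    @property
    def group_label(self) -> str:
        return self.group if self.group is not None else self.name


@dataclass(frozen=True)
class PanelSpec:
    """Panel dimensions: respondent count, waves, between-wave part-worth
    drift SD, and independent per-wave dropout probability."""

    n_respondents: int
    waves: int = 2
    drift_sd: float = 0.0
    dropout_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_respondents < 1 or self.waves < 1:
            raise ConfigurationError("need n_respondents >= 1 and waves >= 1")
        if self.drift_sd < 0:
            raise ConfigurationError("drift_sd must be nonnegative")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")


@dataclass
class SimulatedRespondent:
    """Ground truth for one synthetic respondent: the effects-coded
    part-worth vector per wave and which waves were completed."""

    respondent_id: str
    group: str
    segment: str
    true_partworths: np.ndarray  # (waves, p)
    completed_waves: tuple[int, ...]
    response_scale: float = 1.0
    lexicographic_attribute: str | None = None


def sample_population(
    segments: list[SegmentSpec],
    panel: PanelSpec,
    schema: AttributeSchema | None = None,
    rng=None,
    exact_counts: bool = False,
) -> list[SimulatedRespondent]:
    """Draw a panel of respondents with wave-specific true part-worths.

    Segment assignment is multinomial with the stated proportions (or
    largest-remainder exact allocation with ``exact_counts``); wave w+1
    part-worths are wave w plus Normal(0, drift_sd) noise; dropout after
    wave 1 is independent Bernoulli per wave.
    """
    if not segments:
        raise ConfigurationError("need at least one segment")
    schema = schema or pain_treatment_schema()
    for s in segments:
        s.validate(schema)
    props = np.array([s.proportion for s in segments], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ConfigurationError(f"segment proportions sum to {props.sum():.4f}")
    if rng is None:
        rng = np.random.default_rng(panel.seed)

    n = panel.n_respondents
    if exact_counts:
        base = np.floor(props * n).astype(int)
        rem = props * n - base
        for j in np.argsort(-rem)[: n - base.sum()]:
            base[j] += 1
        assignment = np.repeat(np.arange(len(segments)), base)
        rng.shuffle(assignment)
    else:
        assignment = rng.choice(len(segments), size=n, p=props)

    p = schema.n_params
    width = len(str(n))
    out = []
    for i, seg_idx in enumerate(assignment):
        seg = segments[seg_idx]
        mean = np.asarray(seg.mean_partworths, dtype=float)
        sd = np.broadcast_to(np.asarray(seg.heterogeneity_sd, dtype=float), (p,))
        betas = np.empty((panel.waves, p))
        betas[0] = mean + sd * rng.standard_normal(p)
        for w in range(1, panel.waves):
            betas[w] = betas[w - 1] + panel.drift_sd * rng.standard_normal(p)
        completed = [1]
        for w in range(2, panel.waves + 1):
            if rng.random() >= panel.dropout_rate:
                completed.append(w)
            else:
                break
        out.append(
            SimulatedRespondent(
                respondent_id=f"r{i + 1:0{width}d}",
                group=seg.group_label,
                segment=seg.name,
                true_partworths=betas,
                completed_waves=tuple(completed),
                response_scale=seg.response_scale,
                lexicographic_attribute=seg.lexicographic_attribute,
            )
        )
    return out


def simulate_choices(
    respondents: list[SimulatedRespondent],
    designs: dict[tuple[str, int], RespondentDesign],
    schema: AttributeSchema,
    rng=None,
    seed=None,
) -> pd.DataFrame:
    """Simulate logit choices: exactly one chosen alternative per task,
    drawn with probability proportional to exp(scale * X beta).

    ``designs`` maps (respondent_id, wave) to that wave's task block; a
    missing key raises :class:`AlignmentError`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for r in respondents:
        for wave in r.completed_waves:
            design = designs.get((r.respondent_id, wave))
            if design is None:
                raise AlignmentError(
                    f"no design for respondent {r.respondent_id!r} wave {wave}"
                )
            beta = r.true_partworths[wave - 1]
            for task in design.tasks:
                X = schema.code_profiles(np.asarray(task.alternatives))
                u = r.response_scale * (X @ beta)
                u -= u.max()
                prob = np.exp(u)
                prob /= prob.sum()
                choice = rng.choice(len(prob), p=prob)
                for alt_i, alt in enumerate(task.alternatives):
                    row = {
                        "respondent_id": r.respondent_id,
                        "group": r.group,
                        "wave": wave,
                        "task_id": task.task_id,
                        "position": task.position,
                        "task_type": task.task_type,
                        "alternative_id": alt_i + 1,
                        "chosen": int(alt_i == choice),
                    }
                    row.update(
                        {nm: lv + 1 for nm, lv in zip(schema.names, alt)}
                    )
                    rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the default two-group panel
# ---------------------------------------------------------------------------

# Per-level mean utilities of the trading (non-lexicographic) segments, on
# the logit scale, zero-centered within attribute.  Group W trades mainly on
# expected pain relief; group A trades side-effect type against pain relief.
_TRADER_MEANS = {
    "W": {
        "pain_relief": [-1.435, -0.2198, 0.5194, 1.1354],
        "side_effect_type": [-0.642, 0.420, 0.266, 0.378, -0.422],
        "side_effect_severity": [0.660, 0.534, -1.194],
        "analgesic_type": [0.398, -0.398],
        "cost": [0.500, 0.440, -0.002, -0.246, -0.692],
    },
    "A": {
        "pain_relief": [-1.476, -0.1824, 0.452, 1.206],
        "side_effect_type": [-1.729, 1.0488, 0.5472, 0.5396, -0.4066],
        "side_effect_severity": [0.636, 0.412, -1.046],
        "analgesic_type": [0.380, -0.380],
        "cost": [0.476, 0.382, -0.0046, -0.230, -0.622],
    },
}
_LEX_ATTRIBUTE = {"W": "pain_relief", "A": "side_effect_type"}
_GROUP_SIZES = {"W": 139, "A": 102}


def _levels_to_coded(schema: AttributeSchema, by_attr: dict) -> np.ndarray:
    """Coded vector from per-level values (re-centered exactly to zero)."""
    parts = []
    for attr in schema.attributes:
        vals = np.asarray(by_attr[attr.name], dtype=float)
        if len(vals) != attr.n_levels:
            raise ConfigurationError(f"wrong level count for {attr.name!r}")
        vals = vals - vals.mean()
        parts.append(vals[:-1])
    return np.concatenate(parts)


def make_lexicographic(
    schema: AttributeSchema,
    beta: np.ndarray,
    attribute: str,
    dominant_share: float = LEX_MIN_SHARE,
    shrink: float = 0.2,
) -> np.ndarray:
    """Rescale a part-worth vector into a lexicographic profile.

    Non-dominant blocks are multiplied by ``shrink`` and the dominant block
    by whatever factor gives it ``dominant_share`` of the total utility
    range, preserving within-attribute orderings.  Dominance is achieved
    mostly by muting the other attributes rather than amplifying the
    dominant one, so a mixed trader/lexicographic population keeps its mean
    well away from the lexicographic region.
    """
    j = schema.attribute_index(attribute)
    r = _ranges(schema, beta)
    if r[j] <= 0:
        raise ConfigurationError(
            f"attribute {attribute!r} has zero range; cannot dominate"
        )
    others = shrink * (r.sum() - r[j])
    lam = dominant_share * others / ((1.0 - dominant_share) * r[j])
    out = np.asarray(beta, dtype=float).copy()
    for i, (start, stop) in enumerate(schema.blocks()):
        out[start:stop] *= lam if i == j else shrink
    return out


def paper_like_segments(
    schema: AttributeSchema | None = None,
    lexicographic_fraction: float = 0.29,
    heterogeneity_sd: float = 0.25,
    lex_heterogeneity_sd: float = 0.15,
    trader_response_scale: float = 1.0,
    lex_response_scale: float = 1.5,
    lex_shrink: float = 0.3,
) -> list[SegmentSpec]:
    """The default four segments: trader + lexicographic within each group."""
    schema = schema or pain_treatment_schema()
    total = sum(_GROUP_SIZES.values())
    segments = []
    for grp, size in _GROUP_SIZES.items():
        mean = _levels_to_coded(schema, _TRADER_MEANS[grp])
        gprop = size / total
        segments.append(
            SegmentSpec(
                name=f"{grp}_trader",
                proportion=gprop * (1.0 - lexicographic_fraction),
                mean_partworths=tuple(mean),
                heterogeneity_sd=heterogeneity_sd,
                response_scale=trader_response_scale,
                group=grp,
            )
        )
        if lexicographic_fraction > 0:
            segments.append(
                SegmentSpec(
                    name=f"{grp}_lex",
                    proportion=gprop * lexicographic_fraction,
                    mean_partworths=tuple(
                        make_lexicographic(
                            schema, mean, _LEX_ATTRIBUTE[grp], shrink=lex_shrink
                        )
                    ),
                    heterogeneity_sd=lex_heterogeneity_sd,
                    response_scale=lex_response_scale,
                    lexicographic_attribute=_LEX_ATTRIBUTE[grp],
                    group=grp,
                )
            )
    return segments


def reference_population_mean(schema: AttributeSchema | None = None) -> np.ndarray:
    """Proportion-weighted mean part-worths of the default trader segments;
    used as reference utilities when constructing holdout tasks."""
    schema = schema or pain_treatment_schema()
    total = sum(_GROUP_SIZES.values())
    return sum(
        (size / total) * _levels_to_coded(schema, _TRADER_MEANS[g])
        for g, size in _GROUP_SIZES.items()
    )


@dataclass
class SyntheticPanel:
    """A simulated panel plus everything needed to score it."""

    data: pd.DataFrame
    truth: pd.DataFrame
    respondents: list[SimulatedRespondent]
    designs: dict[tuple[str, int], RespondentDesign]
    holdouts: tuple[ChoiceTask, ...]
    schema: AttributeSchema
    segments: list[SegmentSpec] = field(default_factory=list)


def _truth_frame(respondents, schema):
    rows = []
    names = schema.param_names()
    for r in respondents:
        for wave in r.completed_waves:
            row = {
                "respondent_id": r.respondent_id,
                "group": r.group,
                "segment": r.segment,
                "lexicographic": r.lexicographic_attribute is not None,
                "wave": wave,
            }
            row.update(dict(zip(names, r.true_partworths[wave - 1])))
            rows.append(row)
    return pd.DataFrame(rows)


def make_panel(
    segments: list[SegmentSpec],
    panel: PanelSpec,
    schema: AttributeSchema,
    t: int = 12,
    a: int = 2,
    holdout_positions: tuple[int, ...] = (5, 10),
    reference_utilities=None,
    holdout_share_range: tuple[float, float] = (0.60, 0.80),
    seed=None,
    exact_counts: bool = False,
) -> SyntheticPanel:
    """Assemble a full synthetic panel: population, designs, choices.

    Holdout tasks are constructed once from ``reference_utilities`` and are
    identical for every respondent and every wave; each respondent's random
    tasks are regenerated fresh at each wave (respondents do not see the
    same random questions twice).
    """
    rng = np.random.default_rng(seed if seed is not None else panel.seed)
    if reference_utilities is None:
        reference_utilities = reference_population_mean(schema)
    holdouts = tuple(
        construct_holdout(
            schema,
            reference_utilities,
            share_range=holdout_share_range,
            rng=rng,
            task_id=f"H{i + 1}",
        )
        for i in range(len(holdout_positions))
    )
    respondents = sample_population(
        segments, panel, schema=schema, rng=rng, exact_counts=exact_counts
    )
    designs = {}
    for r in respondents:
        for wave in r.completed_waves:
            designs[(r.respondent_id, wave)] = generate_respondent_design(
                schema,
                t=t,
                a=a,
                holdouts=holdouts,
                holdout_positions=holdout_positions,
                rng=rng,
                respondent_id=r.respondent_id,
            )
    data = simulate_choices(respondents, designs, schema, rng=rng)
    return SyntheticPanel(
        data=data,
        truth=_truth_frame(respondents, schema),
        respondents=respondents,
        designs=designs,
        holdouts=holdouts,
        schema=schema,
        segments=list(segments),
    )


def make_paper_like_dataset(
    seed=None,
    n_respondents: int = 241,
    waves: int = 2,
    lexicographic_fraction: float = 0.29,
    heterogeneity_sd: float = 0.25,
    drift_sd: float = 0.25,
    dropout_rate: float = 0.17,
    t: int = 12,
    a: int = 2,
    holdout_positions: tuple[int, ...] = (5, 10),
    trader_response_scale: float = 1.0,
    lex_response_scale: float = 1.5,
    lex_shrink: float = 0.3,
) -> SyntheticPanel:
    """The default study-like panel: 241 respondents in groups W (139) and
    A (102), 12 random + 2 holdout tasks (positions 5 and 10), two waves
    with 17% dropout, and a 29% lexicographic subpopulation (dominant
    attribute: pain relief in group W, side-effect type in group A).

    Group and segment counts use exact largest-remainder allocation so the
    planted structure matches the configured fractions as closely as integer
    counts allow; all other randomness (part-worth draws, drift, dropout,
    designs, choices) is governed by ``seed``.
    """
    schema = pain_treatment_schema()
    segments = paper_like_segments(
        schema,
        lexicographic_fraction=lexicographic_fraction,
        heterogeneity_sd=heterogeneity_sd,
        trader_response_scale=trader_response_scale,
        lex_response_scale=lex_response_scale,
        lex_shrink=lex_shrink,
    )
    panel = PanelSpec(
        n_respondents=n_respondents,
        waves=waves,
        drift_sd=drift_sd,
        dropout_rate=dropout_rate,
        seed=seed,
    )
    return make_panel(
        segments,
        panel,
        schema,
        t=t,
        a=a,
        holdout_positions=holdout_positions,
        seed=seed,
        exact_counts=True,
    )
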