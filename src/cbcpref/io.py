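"""Long-format choice data on disk.

The on-disk dialect is one CSV row per alternative:

    respondent_id, group, wave, task_id, position, task_type,
    alternative_id, chosen, <one column per attribute>

Attribute columns hold 1-based level indices (level 1 is the first level in
the schema); ``chosen`` is 0/1 with exactly one 1 per respondent-wave-task.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import ChoiceDataError
from .schema import AttributeSchema

ID_COLUMNS = [
    "respondent_id",
    "group",
    "wave",
    "task_id",
    "position",
    "task_type",
    "alternative_id",
]
CHOSEN_COLUMN = "chosen"
TASK_TYPES = {"random", "holdout"}
TASK_KEY = ["respondent_id", "wave", "task_id"]


def required_columns(schema: AttributeSchema, with_chosen: bool = True) -> list[str]:
    cols = list(ID_COLUMNS)
    if with_chosen:
        cols.append(CHOSEN_COLUMN)
    return cols + schema.names


def validate_choice_data(
    df: pd.DataFrame, schema: AttributeSchema, with_chosen: bool = True
) -> pd.DataFrame:
    """Validate a long-format frame in place and return it.

    Checks columns, task types, level ranges, and (if ``with_chosen``) the
    one-chosen-per-task contract.  Error messages name the offending rows or
    tasks so malformed files can be fixed by hand.
    """
    missing = [c for c in required_columns(schema, with_chosen) if c not in df.columns]
    if missing:
        raise ChoiceDataError(f"missing required column(s): {missing}")

    bad_type = df.loc[~df["task_type"].isin(TASK_TYPES)]
    if len(bad_type):
        raise ChoiceDataError(
            f"unknown task_type at rows {bad_type.index.tolist()[:5]} "
            f"(expected one of {sorted(TASK_TYPES)})"
        )

    for attr, m in zip(schema.names, schema.level_counts):
        col = pd.to_numeric(df[attr], errors="coerce")
        bad = df.loc[col.isna() | (col < 1) | (col > m) | (col != col.round())]
        if len(bad):
            raise ChoiceDataError(
                f"attribute {attr!r}: level index out of range 1..{m} "
                f"at rows {bad.index.tolist()[:5]}"
            )

    if with_chosen:
        chosen = pd.to_numeric(df[CHOSEN_COLUMN], errors="coerce")
        if chosen.isna().any() or not chosen.isin([0, 1]).all():
            raise ChoiceDataError("'chosen' must be 0 or 1 in every row")
        per_task = df.groupby(TASK_KEY, sort=False)[CHOSEN_COLUMN].sum()
        bad = per_task[per_task != 1]
        if len(bad):
            key, n = bad.index[0], bad.iloc[0]
            raise ChoiceDataError(
                f"{len(bad)} task(s) without exactly one chosen alternative; "
                f"first offender respondent={key[0]!r} wave={key[1]} "
                f"task={key[2]!r} has {int(n)} chosen rows"
            )
    return df


def read_choice_data(path, schema: AttributeSchema) -> pd.DataFrame:
    """Read and validate a long-format choice CSV."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "task_id": str, "group": str})
    return validate_choice_data(df, schema)


def write_choice_data(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_utilities(
    betas, respondent_ids, schema: AttributeSchema, path, wave=None, group=None
) -> None:
    """Write individual part-worths: coded columns plus the expanded
    per-level zero-centered utilities (``u(attr=level)``)."""
    import numpy as np

    betas = np.asarray(betas, dtype=float)
    out = pd.DataFrame({"respondent_id": list(respondent_ids)})
    if wave is not None:
        out["wave"] = wave
    if group is not None:
        out["group"] = group
    for j, name in enumerate(schema.param_names()):
        out[name] = betas[:, j]
    expanded = schema.expand_partworths(betas)
    for attr, block in zip(schema.attributes, expanded):
        for j, lv in enumerate(attr.levels):
            out[f"u({attr.name}={lv})"] = block[:, j]
    out.to_csv(path, index=False)
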