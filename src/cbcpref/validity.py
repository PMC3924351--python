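"""Internal and external validity of fitted part-worths.

Internal fit is the Root Likelihood (RLH): the geometric mean of the
predicted probabilities of the choices a respondent actually made.  With k
alternatives per task, utilities carrying no information give RLH = 1/k;
a perfect fit gives 1.

External validity compares model-predicted aggregate shares on the holdout
tasks (excluded from estimation) with the shares respondents actually
chose, as a Mean Absolute Error in share percentage points.  Before
computing the MAE the logit exponent (scale factor) is tuned on a grid per
group: the scale governs how deterministic predicted choices are, and
groups may answer with different response consistency even when their
part-worths agree.

Lexicographic (single-attribute-dominant) behavior is flagged when a
respondent's RLH exceeds 1.5x chance *and* one attribute carries more than
half of their total importance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import log_softmax

from .exceptions import AlignmentError, UndefinedImportanceError
from .models import task_arrays
from .schema import AttributeSchema

DEFAULT_SCALE_GRID = tuple(np.geomspace(0.1, 10.0, 25))


# ---------------------------------------------------------------------------
# RLH
# ---------------------------------------------------------------------------

def rlh(beta, tasks, choices, schema: AttributeSchema, scale: float = 1.0) -> float:
    """Root Likelihood: geometric mean of predicted chosen-alternative
    probabilities over ``tasks``; computed in log space."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise FloatingPointError("non-finite utilities")
    choices = np.asarray(choices, dtype=int)
    if len(choices) != len(tasks) or len(tasks) == 0:
        raise AlignmentError("need one chosen index per task, at least one task")
    log_probs = []
    for task, c in zip(tasks, choices):
        alts = getattr(task, "alternatives", task)
        X = schema.code_profiles(np.asarray(alts))
        log_probs.append(log_softmax(scale * (X @ beta))[c])
    return float(np.exp(np.mean(log_probs)))


def respondent_rlh(
    betas,
    respondent_ids,
    data,
    schema: AttributeSchema,
    scale: float = 1.0,
    include_holdouts: bool = False,
) -> pd.Series:
    """Per-respondent RLH over their estimation tasks, vectorized.

    By default holdouts are excluded, keeping fit (RLH) and validation
    (MAE) on disjoint tasks.
    """
    X, chosen, keys = task_arrays(data, schema, include_holdouts)
    betas = np.asarray(betas, dtype=float)
    lookup = {rid: i for i, rid in enumerate(respondent_ids)}
    rows = keys["respondent_id"].map(lookup)
    if rows.isna().any():
        missing = keys.loc[rows.isna(), "respondent_id"].unique()[:5]
        raise AlignmentError(f"no utilities for respondent(s) {list(missing)}")
    B = betas[rows.to_numpy(dtype=int)]
    U = scale * np.einsum("nkp,np->nk", X, B)
    ll = np.take_along_axis(
        U - np.logaddexp.reduce(U, axis=1, keepdims=True),
        chosen[:, None],
        axis=1,
    )[:, 0]
    out = (
        pd.DataFrame({"respondent_id": keys["respondent_id"], "ll": ll})
        .groupby("respondent_id", sort=False)["ll"]
        .mean()
    )
    return np.exp(out).rename("rlh")


# ---------------------------------------------------------------------------
# relative importance
# ---------------------------------------------------------------------------

def relative_importance(beta, schema: AttributeSchema) -> np.ndarray:
    """Attribute importances: 100 * range(per-level utilities) / sum of
    ranges.  Rows sum to 100.  Accepts (p,) or (n, p)."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    ranges = np.stack(
        [blk.max(axis=-1) - blk.min(axis=-1) for blk in schema.expand_partworths(beta)],
        axis=-1,
    )
    totals = ranges.sum(axis=-1)
    if np.any(totals <= 0):
        raise UndefinedImportanceError(
            "all attribute utility ranges are zero for at least one respondent"
        )
    out = 100.0 * ranges / totals[..., None]
    return out[0] if np.asarray(beta).ndim == 1 or out.shape[0] == 1 else out


def importance_table(
    betas, respondent_ids, schema: AttributeSchema
) -> pd.DataFrame:
    """Per-respondent importance rows as a DataFrame."""
    imp = np.atleast_2d(relative_importance(np.atleast_2d(betas), schema))
    out = pd.DataFrame(imp, columns=schema.names)
    out.insert(0, "respondent_id", list(respondent_ids))
    return out


# ---------------------------------------------------------------------------
# lexicographic behavior
# ---------------------------------------------------------------------------

def lexicographic_rlh_threshold(n_alternatives: int = 2) -> float:
    """1.5x the chance RLH of 1/k."""
    return 1.5 / n_alternatives


def flag_lexicographic(
    rlh_value: float,
    importances,
    rlh_threshold: float | None = None,
    importance_threshold: float = 50.0,
    n_alternatives: int = 2,
) -> bool:
    """True iff RLH strictly exceeds the threshold (default 1.5/k, i.e.
    0.750 for paired tasks) AND the largest attribute importance strictly
    exceeds ``importance_threshold`` percent."""
    if rlh_threshold is None:
        rlh_threshold = lexicographic_rlh_threshold(n_alternatives)
    return bool(
        rlh_value > rlh_threshold and np.max(importances) > importance_threshold
    )


# ---------------------------------------------------------------------------
# holdout prediction and MAE
# ---------------------------------------------------------------------------

def predict_holdout_shares(
    betas, holdout, schema: AttributeSchema, scale: float = 1.0
) -> np.ndarray:
    """Aggregate predicted shares for one holdout task: each respondent's
    logit probabilities at their posterior-mean part-worths (exponent
    ``scale``), averaged across respondents.  Accepts an HBPosterior or a
    (n, p) array."""
    betas = np.atleast_2d(np.asarray(getattr(betas, "individual_means", betas), float))
    if betas.shape[0] == 0:
        raise AlignmentError("no respondents to average over")
    alts = getattr(holdout, "alternatives", holdout)
    X = schema.code_profiles(np.asarray(alts))
    U = scale * (betas @ X.T)                      # (n, k)
    P = np.exp(U - np.logaddexp.reduce(U, axis=1, keepdims=True))
    return P.mean(axis=0)


def observed_holdout_shares(
    data, schema: AttributeSchema, holdout_ids=None
) -> dict[str, np.ndarray]:
    """Observed aggregate choice frequencies per holdout task."""
    df = pd.DataFrame(data)
    df = df.loc[df["task_type"] == "holdout"]
    if holdout_ids is not None:
        df = df.loc[df["task_id"].isin(list(holdout_ids))]
    if df.empty:
        raise AlignmentError("no holdout rows in the data")
    out = {}
    for task_id, g in df.groupby("task_id", sort=False):
        shares = (
            g.groupby("alternative_id", sort=True)["chosen"].mean().to_numpy(float)
        )
        out[str(task_id)] = shares
    return out


def mae(predicted: dict, observed: dict) -> float:
    """Mean absolute difference between predicted and observed holdout
    shares, in percentage points (0 = perfect agreement)."""
    if set(predicted) != set(observed):
        raise AlignmentError(
            f"holdout tasks differ: {sorted(predicted)} vs {sorted(observed)}"
        )
    diffs = []
    for key in sorted(predicted):
        p, o = np.asarray(predicted[key], float), np.asarray(observed[key], float)
        if p.shape != o.shape:
            raise AlignmentError(f"holdout {key!r}: alternative counts differ")
        diffs.append(np.abs(p - o))
    return float(100.0 * np.concatenate(diffs).mean())


def tune_scale(
    betas,
    holdouts,
    observed: dict,
    schema: AttributeSchema,
    grid=DEFAULT_SCALE_GRID,
) -> tuple[float, float]:
    """Grid-search the logit exponent minimizing holdout MAE.

    Returns (best scale, MAE at best scale); ties resolve to the smallest
    scale.  ``holdouts`` maps task ids to tasks, or is an iterable of tasks
    with ``task_id`` attributes.
    """
    grid = sorted(float(s) for s in grid)
    if not grid:
        raise AlignmentError("scale grid is empty")
    if not isinstance(holdouts, dict):
        holdouts = {h.task_id: h for h in holdouts}
    best_scale, best_mae = None, np.inf
    for s in grid:
        predicted = {
            tid: predict_holdout_shares(betas, task, schema, scale=s)
            for tid, task in holdouts.items()
        }
        m = mae(predicted, observed)
        if m < best_mae - 1e-12:
            best_scale, best_mae = s, m
    return best_scale, best_mae


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def validity_report(
    posteriors: dict,
    data,
    schema: AttributeSchema,
    holdouts,
    scale_grid=DEFAULT_SCALE_GRID,
    importance_threshold: float = 50.0,
) -> dict:
    """Assemble the per-group, per-wave validity table.

    ``posteriors`` maps (group, wave) to a fitted posterior (anything with
    ``individual_means`` and ``respondent_ids``); ``holdouts`` maps task ids
    to tasks.  Reports mean RLH with a normal-approximation 95% CI, MAE at
    the tuned scale (and at scale 1), the tuned scale factor, and the
    lexicographic count/rate, per group-wave and pooled per wave.
    """
    if not isinstance(holdouts, dict):
        holdouts = {h.task_id: h for h in holdouts}
    df = pd.DataFrame(data)
    report: dict = {"groups": {}, "waves": {}}
    wave_totals: dict = {}
    for (group, wave), post in sorted(posteriors.items(), key=lambda kv: str(kv[0])):
        betas = np.asarray(post.individual_means, float)
        ids = list(post.respondent_ids)
        sub = df.loc[(df["group"] == group) & (df["wave"] == wave)]
        r = respondent_rlh(betas, ids, sub, schema)
        n = len(r)
        half = 1.96 * r.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        k = int(sub.groupby(["respondent_id", "task_id"]).size().iloc[0])
        imp = relative_importance(betas, schema)
        flags = [
            flag_lexicographic(
                r[rid], imp[i], importance_threshold=importance_threshold,
                n_alternatives=k,
            )
            for i, rid in enumerate(ids)
        ]
        observed = observed_holdout_shares(sub, schema, holdout_ids=holdouts)
        predicted_1 = {
            tid: predict_holdout_shares(betas, t, schema, 1.0)
            for tid, t in holdouts.items()
        }
        scale, mae_tuned = tune_scale(betas, holdouts, observed, schema, scale_grid)
        entry = {
            "n": n,
            "mean_rlh": float(r.mean()),
            "rlh_ci": [float(r.mean() - half), float(r.mean() + half)],
            "mae_scale1": mae(predicted_1, observed),
            "scale_factor": float(scale),
            "mae": float(mae_tuned),
            "lexicographic_count": int(sum(flags)),
            "lexicographic_rate": float(np.mean(flags)),
        }
        report["groups"][f"{group}@T{wave}"] = entry
        tot = wave_totals.setdefault(wave, {"n": 0, "lex": 0})
        tot["n"] += n
        tot["lex"] += int(sum(flags))
    for wave, tot in sorted(wave_totals.items()):
        report["waves"][f"T{wave}"] = {
            "n": tot["n"],
            "lexicographic_count": tot["lex"],
            "lexicographic_rate": tot["lex"] / tot["n"] if tot["n"] else float("nan"),
        }
    return report
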