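"""Test-retest (inter-temporal) stability of preference structure.

Each respondent's attribute importances at the two waves are converted to
ranks (1 = most important, ties broken by schema order).  Agreement across
waves is summarized three ways:

* Cohen's kappa on the pooled respondent-by-attribute rank pairs (and per
  attribute), with the conventional magnitude labels (slight / fair /
  moderate / substantial / almost perfect) and a large-sample 95% CI;
* the Spearman correlation of the pooled rank pairs;
* persistence of *strong* preferences: an attribute with baseline
  importance of 50% or more counts as stable when it ranks first or second
  at the second wave.

Change scores (actual T2 - T1 and absolute differences of importances) are
also produced; actual changes sum to zero per respondent because
importances sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .exceptions import AlignmentError, DegenerateTableError
from .schema import AttributeSchema

STRONG_THRESHOLD = 50.0  # percent importance: "strong preference"
TOP_RANKS = (1, 2)       # counts as stable at the second wave

_KAPPA_BANDS = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


# ---------------------------------------------------------------------------
# ranks
# ---------------------------------------------------------------------------

def rank_attributes(importances) -> np.ndarray:
    """Descending ranks (1 = highest importance); ties go to the attribute
    earlier in the schema.  Accepts (m,) or (n, m)."""
    imp = np.asarray(importances, dtype=float)
    one = imp.ndim == 1
    imp = np.atleast_2d(imp)
    order = np.argsort(-imp, axis=1, kind="stable")  # stable = schema-order ties
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, imp.shape[1] + 1)[None, :], axis=1)
    return ranks[0] if one else ranks


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

@dataclass
class KappaResult:
    kappa: float
    ci: tuple[float, float]
    se: float
    n: int
    p_observed: float
    p_expected: float

    @property
    def label(self) -> str:
        return kappa_label(self.kappa)


def cohen_kappa(pairs) -> KappaResult:
    """Cohen's kappa for paired categorical ratings, with 95% CI.

    kappa = (p_o - p_e) / (1 - p_e), where p_e comes from the marginal
    products.  The CI uses the Fleiss-Cohen-Everitt large-sample standard
    error.  Raises :class:`DegenerateTableError` when every pair falls in
    one category (p_e = 1).
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise AlignmentError("need at least 2 rating pairs")
    cats = sorted({c for pair in pairs for c in pair}, key=str)
    index = {c: i for i, c in enumerate(cats)}
    m = len(cats)
    table = np.zeros((m, m))
    for c1, c2 in pairs:
        table[index[c1], index[c2]] += 1
    n = table.sum()
    P = table / n
    row, col = P.sum(axis=1), P.sum(axis=0)
    p_o = float(np.trace(P))
    p_e = float(row @ col)
    if 1.0 - p_e < 1e-12:
        raise DegenerateTableError(
            "all ratings fall in a single category; kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss, Cohen & Everitt large-sample variance
    diag = np.diag(P)
    term1 = float(
        np.sum(diag * ((1 - p_e) - (row + col) * (1 - p_o)) ** 2)
    )
    off = P * (col[None, :] + row[:, None]) ** 2
    np.fill_diagonal(off, 0.0)
    term2 = (1 - p_o) ** 2 * float(off.sum())
    term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (term1 + term2 - term3) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(
        kappa=float(kappa),
        ci=(float(kappa - 1.96 * se), float(min(kappa + 1.96 * se, 1.0))),
        se=se,
        n=int(n),
        p_observed=p_o,
        p_expected=p_e,
    )


def kappa_label(kappa: float) -> str:
    """Magnitude guideline band for a kappa value (upper edges inclusive)."""
    if kappa > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0:
        return "no agreement"
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "almost perfect"


# ---------------------------------------------------------------------------
# strong preferences
# ---------------------------------------------------------------------------

def strong_preference_flags(
    importances, threshold: float = STRONG_THRESHOLD
) -> np.ndarray:
    """0/1 per attribute: 1 iff importance >= threshold (inclusive)."""
    return (np.asarray(importances, dtype=float) >= threshold).astype(int)


def classify_stability(strong_attribute, ranks_t2, attributes=None) -> bool:
    """Stable iff the baseline strong attribute ranks 1st or 2nd at T2.

    ``strong_attribute`` is an attribute index, or a name when the ordered
    ``attributes`` list is given.
    """
    if isinstance(strong_attribute, str):
        if attributes is None:
            raise AlignmentError("attribute names require the attributes list")
        strong_attribute = list(attributes).index(strong_attribute)
    ranks_t2 = np.asarray(ranks_t2, dtype=int)
    return bool(ranks_t2[int(strong_attribute)] in TOP_RANKS)


def change_scores(
    importances_t1: pd.DataFrame,
    importances_t2: pd.DataFrame,
    attributes: list[str],
) -> pd.DataFrame:
    """Actual (T2 - T1) and absolute importance changes per respondent.

    Frames need ``respondent_id`` plus one column per attribute; only
    respondents present in both waves are returned.
    """
    t1 = importances_t1.set_index("respondent_id")[attributes]
    t2 = importances_t2.set_index("respondent_id")[attributes]
    common = t1.index.intersection(t2.index)
    if len(common) == 0:
        raise AlignmentError("no respondents present at both waves")
    delta = t2.loc[common] - t1.loc[common]
    out = pd.DataFrame({"respondent_id": common})
    for a in attributes:
        out[f"actual_{a}"] = delta[a].to_numpy()
        out[f"absolute_{a}"] = delta[a].abs().to_numpy()
    return out


def spearman_rank_agreement(ranks_t1, ranks_t2) -> float:
    """Spearman correlation over pooled respondent-attribute rank pairs."""
    r1 = np.asarray(ranks_t1, dtype=float).ravel()
    r2 = np.asarray(ranks_t2, dtype=float).ravel()
    if r1.shape != r2.shape or len(r1) < 2:
        raise AlignmentError("need equal-length paired ranks (>= 2 pairs)")
    if np.all(r1 == r1[0]) or np.all(r2 == r2[0]):
        raise DegenerateTableError("constant ranks; correlation undefined")
    rho = spearmanr(r1, r2).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _kappa_entry(result: KappaResult) -> dict:
    return {
        "kappa": result.kappa,
        "ci": list(result.ci),
        "label": result.label,
        "n_pairs": result.n,
    }


def _group_stability(t1: pd.DataFrame, t2: pd.DataFrame, attrs: list[str]) -> dict:
    common = t1.index.intersection(t2.index)
    imp1 = t1.loc[common, attrs].to_numpy(float)
    imp2 = t2.loc[common, attrs].to_numpy(float)
    ranks1, ranks2 = rank_attributes(imp1), rank_attributes(imp2)
    pooled_pairs = list(zip(ranks1.ravel(), ranks2.ravel()))
    entry: dict = {"n_respondents": int(len(common))}
    try:
        entry["overall"] = _kappa_entry(cohen_kappa(pooled_pairs))
    except DegenerateTableError:
        entry["overall"] = None
    entry["spearman"] = spearman_rank_agreement(ranks1, ranks2)

    strong1 = strong_preference_flags(imp1)
    top2 = np.isin(ranks2, TOP_RANKS)
    per_attr = {}
    stable_n = stable_total = 0
    for j, a in enumerate(attrs):
        d: dict = {}
        try:
            d["rank_kappa"] = _kappa_entry(
                cohen_kappa(list(zip(ranks1[:, j], ranks2[:, j])))
            )
        except DegenerateTableError:
            d["rank_kappa"] = None
        s, t = strong1[:, j].astype(bool), top2[:, j]
        d["n_strong_t1"] = int(s.sum())
        d["sensitivity"] = float(t[s].mean()) if s.any() else None
        d["specificity"] = float((~t[~s]).mean()) if (~s).any() else None
        stable_n += int(t[s].sum())
        stable_total += int(s.sum())
        per_attr[a] = d
    entry["attributes"] = per_attr
    entry["strong_preferences"] = {
        "n": stable_total,
        "stable": stable_n,
        "stable_fraction": stable_n / stable_total if stable_total else None,
    }
    deltas = imp2 - imp1
    entry["change_scores"] = {
        a: {
            "mean_actual": float(deltas[:, j].mean()),
            "mean_absolute": float(np.abs(deltas[:, j]).mean()),
        }
        for j, a in enumerate(attrs)
    }
    return entry


def stability_report(
    importances_t1: pd.DataFrame,
    importances_t2: pd.DataFrame,
    schema: AttributeSchema,
    group_col: str = "group",
) -> dict:
    """Stability summary overall and per group.

    Input frames carry ``respondent_id``, optionally ``group``, and one
    importance column per attribute.  Respondents lost to follow-up are
    excluded pairwise.
    """
    attrs = schema.names
    t1 = importances_t1.set_index("respondent_id")
    t2 = importances_t2.set_index("respondent_id")
    report = {"overall": _group_stability(t1, t2, attrs), "groups": {}}
    if group_col in importances_t1.columns:
        for grp, g1 in t1.groupby(group_col, sort=True):
            report["groups"][str(grp)] = _group_stability(g1, t2, attrs)
    return report
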