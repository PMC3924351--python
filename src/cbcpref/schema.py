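"""Attribute/level schemas and effects coding.

A conjoint profile is one level per attribute.  Estimation uses sum-to-zero
(effects) coding: an attribute with ``m`` levels occupies ``m - 1`` design
columns; level ``j < m-1`` is the ``j``-th unit vector, and the last level
codes ``-1`` in every column of the block.  The implied per-level utilities
therefore sum to zero within each attribute, which is the zero-centered
convention conjoint software reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CorruptDesignError, InvalidSchemaError

MAX_LEVELS = 6


@dataclass(frozen=True)
class Attribute:
    """One choice attribute with its ordered, discrete levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of attributes defining the coded parameter space.

    Invariants (checked on construction): at least two attributes, unique
    names, and 2..6 levels per attribute.
    """

    attributes: tuple[Attribute, ...] = field(default_factory=tuple)

    def __post_init__(self):
        attrs = tuple(
            a if isinstance(a, Attribute) else Attribute(*a) for a in self.attributes
        )
        object.__setattr__(self, "attributes", attrs)
        if len(attrs) < 2:
            raise InvalidSchemaError("a schema needs at least 2 attributes")
        names = [a.name for a in attrs]
        if len(set(names)) != len(names):
            raise InvalidSchemaError(f"attribute names not unique: {names}")
        for a in attrs:
            if not 2 <= a.n_levels <= MAX_LEVELS:
                raise InvalidSchemaError(
                    f"attribute {a.name!r} has {a.n_levels} level(s); "
                    f"must have 2..{MAX_LEVELS}"
                )

    # -- basic shape ------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def level_counts(self) -> list[int]:
        return [a.n_levels for a in self.attributes]

    @property
    def n_params(self) -> int:
        """Length of the effects-coded parameter vector, sum of (m - 1)."""
        return sum(m - 1 for m in self.level_counts)

    @property
    def max_levels(self) -> int:
        return max(self.level_counts)

    def blocks(self) -> list[tuple[int, int]]:
        """(start, stop) column slice of each attribute in the coded vector."""
        out, start = [], 0
        for m in self.level_counts:
            out.append((start, start + m - 1))
            start += m - 1
        return out

    def param_names(self) -> list[str]:
        """One name per coded column: ``attr[level]`` for all but the last level."""
        out = []
        for a in self.attributes:
            out.extend(f"{a.name}[{lv}]" for lv in a.levels[:-1])
        return out

    def attribute_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidSchemaError(f"unknown attribute {name!r}") from None

    # -- effects coding ---------------------------------------------------

    def coding_matrix(self, attr_index: int) -> np.ndarray:
        """(m, m-1) effects-coding matrix for one attribute."""
        m = self.level_counts[attr_index]
        return np.vstack([np.eye(m - 1), -np.ones(m - 1)])

    def code_profiles(self, profiles: np.ndarray) -> np.ndarray:
        """Effects-code an integer array of profiles.

        Parameters
        ----------
        profiles : array of shape (..., n_attributes)
            0-based level indices.

        Returns
        -------
        array of shape (..., n_params)
        """
        profiles = np.asarray(profiles)
        if profiles.shape[-1] != self.n_attributes:
            raise CorruptDesignError(
                f"profiles have {profiles.shape[-1]} attributes, "
                f"schema has {self.n_attributes}"
            )
        cols = []
        for j, m in enumerate(self.level_counts):
            idx = profiles[..., j]
            if idx.size and (idx.min() < 0 or idx.max() >= m):
                raise CorruptDesignError(
                    f"level index out of range for attribute "
                    f"{self.names[j]!r} (valid 0..{m - 1})"
                )
            cols.append(self.coding_matrix(j)[idx])
        return np.concatenate(cols, axis=-1)

    def expand_partworths(self, beta: np.ndarray) -> list[np.ndarray]:
        """Per-level zero-centered utilities from a coded vector.

        The omitted last level of each attribute gets minus the sum of the
        block, so each returned array sums to zero.
        Accepts a trailing parameter axis of length ``n_params``.
        """
        beta = np.asarray(beta, dtype=float)
        if beta.shape[-1] != self.n_params:
            raise CorruptDesignError(
                f"beta has length {beta.shape[-1]}, expected {self.n_params}"
            )
        out = []
        for start, stop in self.blocks():
            block = beta[..., start:stop]
            last = -block.sum(axis=-1, keepdims=True)
            out.append(np.concatenate([block, last], axis=-1))
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {"name": a.name, "levels": list(a.levels)} for a in self.attributes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeSchema":
        try:
            attrs = tuple(
                Attribute(a["name"], tuple(a["levels"])) for a in d["attributes"]
            )
        except (KeyError, TypeError) as exc:
            raise InvalidSchemaError(f"malformed schema mapping: {exc}") from exc
        return cls(attrs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AttributeSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def pain_treatment_schema() -> AttributeSchema:
    """The analgesic-treatment schema: five attributes of a cancer-pain
    analgesic (expected pain relief, side-effect type and severity, analgesic
    class, monthly out-of-pocket cost) with 4/5/3/2/5 levels, giving a
    14-parameter effects-coded space."""
    return AttributeSchema(
        (
            Attribute(
                "pain_relief",
                ("<50%", "60-70%", "80-90%", "100%"),
            ),
            Attribute(
                "side_effect_type",
                (
                    "confusion",
                    "drowsiness/dizziness",
                    "heartburn/sour stomach",
                    "constipation",
                    "nausea/vomiting",
                ),
            ),
            Attribute("side_effect_severity", ("mild", "moderate", "severe")),
            Attribute("analgesic_type", ("opioid-like", "nsaid-like")),
            Attribute(
                "cost",
                ("$10-$20", "$30-$40", "$50-$60", "$70-$90", "$100+"),
            ),
        )
    )
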