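"""Subgroup collections for marginal and intersectional debiasing.

A debiasing scenario determines the collection ``C`` of patient subgroups the
fairness machinery audits or repairs: a single protected attribute's levels
(``single:<attr>``), all attributes' levels taken marginally (``marginal``),
every observed cell of the attribute product (``intersectional``), or no
groups at all (``base``).  A prevalence cutoff gamma drops groups too small
to estimate reliably — the same cutoff the calibration audit applies to
(group x bin) cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ConfigError

__all__ = ["GroupSpec", "GroupCollection", "build_collection", "prevalence_filter"]

SCENARIOS = ("base", "marginal", "intersectional")  # plus "single:<attr>"


def canonical_label(constraints: dict) -> str:
    return "; ".join(f"{a}={v}" for a, v in sorted(constraints.items()))


@dataclass(frozen=True)
class GroupSpec:
    """A subgroup defined by equality constraints on protected attributes."""

    constraints: dict
    label: str = ""

    def __post_init__(self):
        if not self.constraints:
            raise ConfigError("a group needs at least one constraint")
        if not self.label:
            object.__setattr__(self, "label", canonical_label(self.constraints))

    def mask(self, frame: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(frame), dtype=bool)
        for attr, lvl in self.constraints.items():
            m &= frame[attr].to_numpy() == lvl
        return m


@dataclass
class GroupCollection:
    """The set C of subgroups, with membership over a fixed record table."""

    scenario: str
    groups: list
    membership: dict = field(default_factory=dict)  # label -> bool vector
    n_records: int = 0

    @property
    def prevalence(self) -> dict:
        n = max(self.n_records, 1)
        return {g.label: self.membership[g.label].sum() / n for g in self.groups}

    @property
    def labels(self) -> list:
        return [g.label for g in self.groups]

    def rebind(self, frame: pd.DataFrame) -> "GroupCollection":
        """Same group list, membership recomputed on a new record table
        (e.g. a held-out test split)."""
        memb = {g.label: g.mask(frame) for g in self.groups}
        return GroupCollection(self.scenario, list(self.groups), memb, len(frame))

    def to_json(self) -> str:
        prev = self.prevalence
        return json.dumps({
            "scenario": self.scenario,
            "n_records": int(self.n_records),
            "groups": [{"label": g.label, "constraints": g.constraints,
                        "prevalence": prev[g.label]} for g in self.groups],
        }, indent=2)


def _single(frame, attr):
    levels = pd.unique(frame[attr].dropna())
    try:
        levels = sorted(levels)
    except TypeError:
        levels = list(levels)
    return [GroupSpec({attr: lvl}) for lvl in levels]


def build_collection(data: pd.DataFrame, protected: list, scenario: str
                     ) -> GroupCollection:
    """Construct the group collection for one debiasing scenario.

    Intersectional cells with zero observed members are omitted: they can
    never pass the prevalence cutoff and would break rate denominators.
    Groups are ordered by canonical label so every downstream sweep is
    deterministic.
    """
    for attr in protected:
        if attr not in data.columns:
            raise ConfigError(f"protected attribute {attr!r} not in data")

    if scenario == "base":
        specs = []
    elif scenario == "marginal":
        specs = [g for a in protected for g in _single(data, a)]
    elif scenario == "intersectional":
        observed = data[list(protected)].drop_duplicates()
        specs = [GroupSpec(dict(zip(protected, row)))
                 for row in observed.itertuples(index=False)]
    elif scenario.startswith("single:"):
        attr = scenario.split(":", 1)[1]
        if attr not in protected:
            raise ConfigError(f"scenario {scenario!r}: {attr!r} is not a "
                              "declared protected attribute")
        specs = _single(data, attr)
    else:
        raise ConfigError(f"unknown scenario {scenario!r}")

    specs = sorted(specs, key=lambda g: g.label)
    memb = {g.label: g.mask(data) for g in specs}
    return GroupCollection(scenario, specs, memb, len(data))


def prevalence_filter(collection: GroupCollection, gamma: float) -> GroupCollection:
    """Retain exactly the groups with prevalence >= gamma."""
    if not 0.0 <= gamma <= 1.0:
        raise ConfigError("gamma must be in [0, 1]")
    prev = collection.prevalence
    kept = [g for g in collection.groups if prev[g.label] >= gamma]
    memb = {g.label: collection.membership[g.label] for g in kept}
    return GroupCollection(collection.scenario, kept, memb, collection.n_records)
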