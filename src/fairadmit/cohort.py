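"""Seeded synthetic emergency-department visit cohorts.

Real admission-prediction cohorts are credentialed or private, so this module
generates visit-level tables whose statistical structure makes every
downstream stage of the pipeline testable: categorical protected attributes
with highly imbalanced joint prevalences, admission rates that differ by
intersectional group, and a logistic outcome model with explicit
interaction-cell log-odds offsets.  Because the outcome is drawn from a known
logistic model, the generator also emits the true conditional risk, which
serves as a calibration oracle in tests and as the substrate for planting
known per-group miscalibration (:func:`perturb_scores`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureSpec",
    "OutcomeModel",
    "CohortConfig",
    "generate_cohort",
    "perturb_scores",
    "write_cohort",
    "read_cohort",
    "load_config",
]

_FAMILIES = ("normal", "lognormal", "ordinal")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: ``family`` is 'normal' (loc, scale), 'lognormal'
    (mean, sigma of log), or 'ordinal' (levels, probs)."""

    name: str
    family: str
    params: dict

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}; "
                              f"choose one of {_FAMILIES}")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for P(admit | x, attributes) on the log-odds scale.

    ``main_effects`` maps ``attr -> {level: offset}``; ``interactions`` maps a
    tuple of levels, ordered as in the config's attribute order, to an extra
    offset.  Feature coefficients may carry an optional ``center`` as
    ``(coef, center)``.
    """

    intercept: float
    coefficients: dict = field(default_factory=dict)
    main_effects: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CohortConfig:
    n_visits: int
    attribute_levels: dict
    attribute_joint_probs: np.ndarray
    feature_spec: tuple
    outcome_model: OutcomeModel
    seed: int = 0

    def __post_init__(self):
        if self.n_visits < 0:
            raise ConfigError("n_visits must be nonnegative")
        p = np.asarray(self.attribute_joint_probs, dtype=float).ravel()
        cells = list(itertools.product(*self.attribute_levels.values()))
        if p.size != len(cells):
            raise ConfigError(
                f"joint probability vector has {p.size} entries but the "
                f"attribute product has {len(cells)} cells")
        if (p < 0).any():
            raise ConfigError("joint probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"joint probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "attribute_joint_probs", p)
        cellset = set(cells)
        for cell in self.outcome_model.interactions:
            if tuple(cell) not in cellset:
                raise ConfigError(f"interaction offset for unknown cell {cell!r}")
        for attr, offs in self.outcome_model.main_effects.items():
            if attr not in self.attribute_levels:
                raise ConfigError(f"main effect for unknown attribute {attr!r}")
            for lvl in offs:
                if lvl not in self.attribute_levels[attr]:
                    raise ConfigError(f"main effect for unknown level {attr}={lvl!r}")

    @property
    def cells(self) -> list:
        return list(itertools.product(*self.attribute_levels.values()))

    @property
    def protected(self) -> list:
        return list(self.attribute_levels)


class ConfigError(ValueError):
    """Invalid cohort or pipeline configuration."""


def _coef_center(spec) -> tuple:
    if isinstance(spec, (tuple, list)):
        return float(spec[0]), float(spec[1])
    return float(spec), 0.0


def _draw_feature(fs: FeatureSpec, n: int, rng: np.random.Generator):
    p = fs.params
    if fs.family == "normal":
        return rng.normal(p["loc"], p["scale"], size=n)
    if fs.family == "lognormal":
        return rng.lognormal(p["mean"], p["sigma"], size=n)
    # ordinal: integer-coded categorical levels with given probabilities
    levels = np.asarray(p["levels"])
    probs = np.asarray(p["probs"], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ConfigError(f"ordinal probs for {fs.name!r} are not a distribution")
    return levels[rng.choice(len(levels), size=n, p=probs)]


def true_risk(config: CohortConfig, frame: pd.DataFrame) -> np.ndarray:
    """Conditional admission probability under the config's outcome model."""
    m = config.outcome_model
    eta = np.full(len(frame), m.intercept, dtype=float)
    for name, spec in m.coefficients.items():
        coef, center = _coef_center(spec)
        eta += coef * (frame[name].to_numpy(dtype=float) - center)
    for attr, offsets in m.main_effects.items():
        col = frame[attr].to_numpy()
        for lvl, off in offsets.items():
            eta[col == lvl] += off
    if m.interactions:
        attrs = config.protected
        key = list(zip(*(frame[a].to_numpy() for a in attrs)))
        offs = np.array([m.interactions.get(k, 0.0) for k in key])
        eta += offs
    return 1.0 / (1.0 + np.exp(-eta))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a seeded visit table.

    Columns: one per feature, one per protected attribute, ``admitted``
    (binary outcome) and ``true_risk`` (the generative probability).  One
    integer seed governs attributes, features and outcomes through
    independent substreams, so the same ``(config, seed)`` is byte-identical
    and changing ``n_visits`` does not reshuffle earlier draws of the other
    streams.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_attr, rng_feat, rng_out = (np.random.default_rng(s) for s in ss.spawn(3))
    n = config.n_visits

    cells = config.cells
    idx = rng_attr.choice(len(cells), size=n, p=config.attribute_joint_probs)
    data = {}
    for j, attr in enumerate(config.protected):
        lv = np.array([c[j] for c in cells])
        data[attr] = pd.Categorical(lv[idx], categories=config.attribute_levels[attr])

    for fs in config.feature_spec:
        data[fs.name] = _draw_feature(fs, n, rng_feat)

    frame = pd.DataFrame(data)
    risk = true_risk(config, frame)
    frame["admitted"] = (rng_out.random(n) < risk).astype(np.int64)
    frame["true_risk"] = risk
    return frame


def perturb_scores(scores, collection, cell_shifts: dict, seed: int = 0):
    """Shift scores of each listed group's members by a constant, clip to [0,1].

    Used to plant known per-group miscalibration so that the repair performed
    by the multicalibration postprocessor can be verified against a planted
    truth.  ``cell_shifts`` maps group labels in ``collection`` to offsets.
    ``seed`` is accepted for interface symmetry; the perturbation itself is
    deterministic.
    """
    out = np.asarray(scores, dtype=float).copy()
    labels = {g.label for g in collection.groups}
    for label, shift in cell_shifts.items():
        if label not in labels:
            raise ConfigError(f"cell {label!r} not in collection")
        mask = collection.membership[label]
        out[mask] = np.clip(out[mask] + shift, 0.0, 1.0)
    if out.size and np.all(out == out.flat[0]):
        import warnings

        warnings.warn("perturbation produced degenerate all-identical scores")
    return out


# ---------------------------------------------------------------------------
# I/O


def write_cohort(frame: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".parquet"):
        frame.to_parquet(path)
    else:
        frame.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def load_config(path) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML file.

    Expected keys: n_visits, seed, protected (attribute -> levels),
    joint_probs (flat list over the level product, row-major), features
    (list of {name, family, params}), outcome (intercept, coefficients,
    main_effects, interactions with ';'-joined cell keys).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = doc.get("outcome", {})
    inter = {tuple(k.split(";")): float(v)
             for k, v in out.get("interactions", {}).items()}
    model = OutcomeModel(
        intercept=float(out.get("intercept", 0.0)),
        coefficients=out.get("coefficients", {}),
        main_effects=out.get("main_effects", {}),
        interactions=inter,
    )
    feats = tuple(FeatureSpec(f["name"], f["family"], f["params"])
                  for f in doc.get("features", []))
    return CohortConfig(
        n_visits=int(doc["n_visits"]),
        attribute_levels=dict(doc["protected"]),
        attribute_joint_probs=np.asarray(doc["joint_probs"], dtype=float),
        feature_spec=feats,
        outcome_model=model,
        seed=int(doc.get("seed", 0)),
    )
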