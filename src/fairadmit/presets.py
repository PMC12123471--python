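"""Preset cohort configurations and published cohort summary counts.

``PUBLISHED_COUNTS`` holds publicly reported visit counts for two reference
ED cohorts (an adult ED drawn from MIMIC-IV, and a pediatric ED); they fix
the preset generator's marginal attribute prevalences and let the overall
admission rates be recomputed from first principles.

``biased_cohort_config`` is the package's reference synthetic cohort:
MIMIC-like ethnoracial x gender marginals (independent joint, smallest cell
~0.11% of visits — American Indian or Alaska Native men, the smallest group
such analyses retain), admission rates that differ by group,
and interaction log-odds offsets planted on intersectional cells.  The
interaction signs are mixed on purpose — opposite within an ethnoracial
group's two genders (and, for the two largest groups, opposite within each
gender as well), so neither a main-effects-only risk model nor a debiaser
that only sees marginal groups can absorb them: marginal debiasing is
insufficient by construction, while intersectional debiasing has the
needed resolution.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, FeatureSpec, OutcomeModel

__all__ = ["PUBLISHED_COUNTS", "admission_rates_from_counts", "mimic_marginals",
           "biased_cohort_config", "preset_learner", "preset_specs"]

# Publicly reported visit counts of the reference cohorts (overall / admitted).
PUBLISHED_COUNTS = {
    "mimic": {
        "visits": 160_016,
        "admitted": 47_283,
        "ethnoracial": {
            "American Indian or Alaska Native": 427,
            "Asian": 5_979,
            "Black or African American": 41_944,
            "Hispanic or Latino": 16_057,
            "White": 95_609,
        },
        "gender": {"Women": 91_774, "Men": 68_242},
        "acuity": {1: 8_720, 2: 47_570, 3: 90_948, 4: 9_922, 5: 382},
    },
    "bch": {"visits": 22_222, "admitted": 3_617},
}


def admission_rates_from_counts() -> dict:
    """Overall admission percentage of each cohort, from the printed counts."""
    return {site: 100.0 * d["admitted"] / d["visits"]
            for site, d in PUBLISHED_COUNTS.items()}


def mimic_marginals() -> dict:
    """Exact marginal prevalences implied by the printed visit counts."""
    t = PUBLISHED_COUNTS["mimic"]
    n = t["visits"]
    return {
        "ethnoracial": {k: v / n for k, v in t["ethnoracial"].items()},
        "gender": {k: v / n for k, v in t["gender"].items()},
    }


# Planted intersectional log-odds offsets.  The White/Black offsets form an
# XOR pattern across gender (opposite signs within each ethnoracial group
# and within each gender), so no additive main-effects model can absorb
# them at any sample size; the Asian pair cancels within its marginal
# group; the small-group offsets add small-prevalence realism.
_INTERACTIONS = {
    ("American Indian or Alaska Native", "Men"): 1.2,
    ("Asian", "Men"): 0.9,
    ("Asian", "Women"): -0.9,
    ("Hispanic or Latino", "Women"): -0.8,
    ("Black or African American", "Men"): -0.5,
    ("Black or African American", "Women"): 0.5,
    ("White", "Men"): 0.5,
    ("White", "Women"): -0.5,
}

# Group main effects on the log-odds scale, set so group admission rates
# bracket the cohort's spread (admitted shares range from ~14% to ~39%).
_MAIN_EFFECTS = {
    "ethnoracial": {
        "American Indian or Alaska Native": 0.28,
        "Asian": 0.24,
        "Black or African American": -0.97,
        "Hispanic or Latino": -0.95,
        "White": 0.41,
    },
    "gender": {"Women": -0.20, "Men": 0.25},
}

# Intercept calibrated once so the preset's expected admission rate is
# ~29.5%, the adult cohort's overall rate.
_INTERCEPT = -1.57

FEATURE_COLUMNS = ("acuity", "age", "prior_visits", "severity_index")


def biased_cohort_config(n_visits: int = 20_000, seed: int = 0) -> CohortConfig:
    """The reference synthetic cohort with interaction-driven subgroup bias."""
    marg = mimic_marginals()
    eth = list(marg["ethnoracial"])
    gen = list(marg["gender"])
    p_eth = np.array([marg["ethnoracial"][k] for k in eth])
    p_gen = np.array([marg["gender"][k] for k in gen])
    joint = np.outer(p_eth, p_gen).ravel()  # independent attributes

    ac = PUBLISHED_COUNTS["mimic"]["acuity"]
    ac_levels = sorted(ac)
    ac_probs = np.array([ac[k] for k in ac_levels], dtype=float)
    ac_probs /= ac_probs.sum()

    features = (
        FeatureSpec("acuity", "ordinal",
                    {"levels": ac_levels, "probs": ac_probs.tolist()}),
        FeatureSpec("age", "normal", {"loc": 53.0, "scale": 19.3}),
        FeatureSpec("prior_visits", "lognormal", {"mean": 0.0, "sigma": 0.8}),
        FeatureSpec("severity_index", "normal", {"loc": 0.0, "scale": 1.0}),
    )
    model = OutcomeModel(
        intercept=_INTERCEPT,
        coefficients={
            "acuity": (-1.2, 3.0),     # lower acuity number = more acute
            "age": (0.030, 53.0),
            "prior_visits": (0.3, 1.0),
            "severity_index": (0.6, 0.0),
        },
        main_effects=_MAIN_EFFECTS,
        interactions=dict(_INTERACTIONS),
    )
    return CohortConfig(
        n_visits=n_visits,
        attribute_levels={"ethnoracial": eth, "gender": gen},
        attribute_joint_probs=joint,
        feature_spec=features,
        outcome_model=model,
        seed=seed,
    )


def preset_learner(model: str = "logistic"):
    """The reference learner: numeric features plus protected main effects."""
    from .learners import LearnerSpec

    return LearnerSpec(model, FEATURE_COLUMNS, ("ethnoracial", "gender"))


def preset_specs(task: str, scenarios=("base", "marginal", "intersectional"),
                 n_trials: int = 20, base_seed: int = 0, model: str = "logistic",
                 fomo=None, threshold: float = 0.3) -> list:
    """Scenario specs for the reference comparison on the preset cohort.

    The classification threshold defaults to 0.3 — close to the cohort's
    admission prevalence, the operating point where sensitivity and
    specificity are of comparable size — rather than the generic 0.5, which
    on a 30%-prevalence outcome leaves most true positives below threshold
    and saturates small-group FNRs at 1.
    """
    from .harness import ScenarioSpec

    learner = preset_learner(model)
    return [ScenarioSpec(sc, task, learner, n_trials=n_trials,
                         base_seed=base_seed, threshold=threshold, fomo=fomo)
            for sc in scenarios]
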