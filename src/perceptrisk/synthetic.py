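"""Synthetic survey generator with the structure the analysis assumes.

The generator simulates a population whose risk perception is driven by a
latent trait theta with a two-component (low/high) mixture, modest
gender and age shifts, graded ("logistic item response") answers on a
40-item / 166-dummy codebook spanning the three risk dimensions, and
emotion/media flags whose prevalence is monotone in the trait.  Low-trait
respondents additionally follow one of a small number of response
*archetypes* — fixed answer patterns on disjoint item subsets — which makes
the low-risk population heterogeneous (several distinct clusters) while the
high-risk population stays homogeneous (one big cluster).  Ground truth
(theta, component, archetype) is returned for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codebook import Codebook, ItemCoding
from .responses import (AGE_BAND_LABELS, EMOTIONS, MEDIA, ResponseTable,
                        from_dataframe)

#: age-band sampling weights shaped like a university community
#: (heavily young, thin upper tail)
AGE_BAND_WEIGHTS = (0.43, 0.21, 0.13, 0.11, 0.08, 0.034, 0.0045, 0.0015)

_AGE_RANGES = ((15, 24), (25, 34), (35, 44), (45, 54), (55, 64),
               (65, 74), (75, 84), (85, 94))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


#: per-flag (slope on theta, population prevalence, female shift, age-band slope)
EMOTION_PARAMS = {
    "alertness":  (0.60, 0.647,  0.05,  0.08),
    "worry":      (0.45, 0.618,  0.10,  0.00),
    "isolation":  (0.20, 0.513,  0.15, -0.12),
    "anxiety":    (0.25, 0.467,  0.30, -0.18),
    "alarm":      (0.35, 0.358,  0.20, -0.05),
    "boredom":    (-0.15, 0.334,  0.00, -0.20),
    "confusion":  (-0.05, 0.307,  0.05, -0.18),
    "fear":       (0.30, 0.294,  0.20, -0.05),
    "depression": (-0.05, 0.247,  0.05, -0.20),
}

MEDIA_PARAMS = {
    "social_media":           (0.20, 0.650,  0.10, -0.18),
    "ministry_announcements": (0.50, 0.601,  0.20,  0.00),
    "television":             (0.15, 0.546,  0.00,  0.05),
    "websites":               (0.25, 0.546, -0.15,  0.00),
    "official_websites":      (0.30, 0.444,  0.00,  0.02),
    "newspapers":             (0.30, 0.413, -0.08,  0.15),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    The defaults mirror the structure of the modelled survey at a
    desk-friendly size: 40 single-choice items yielding 166 signed dummy
    columns, a clearly bimodal latent trait, a mostly-female population with
    older and female respondents shifted toward higher perceived risk, and
    three low-risk archetypes of equal prevalence.
    """

    n: int = 2000
    seed: int = 0

    # latent trait mixture (low, high)
    mixture_weights: tuple = (0.5, 0.5)
    component_means: tuple = (-1.6, 1.6)
    component_sds: tuple = (0.6, 0.6)
    female_effect: float = 0.25       # additive shift of theta for women
    age_effect: float = 0.10          # additive shift per age band above the first
    p_female: float = 0.62
    age_band_weights: tuple = AGE_BAND_WEIGHTS

    # items: (count, n_categories) blocks; totals 40 items / 166 dummies
    item_blocks: tuple = ((6, 5), (34, 4))
    discrimination_range: tuple = (2.5, 4.0)
    difficulty_range: tuple = (-2.0, 2.0)
    p_negative_given_not_plus: float = 0.85

    # low-risk archetypes
    n_archetypes: int = 3
    archetype_items: int = 13         # disjoint items overridden per archetype
    archetype_strength: float = 0.95  # probability an archetype item is overridden

    def __post_init__(self):
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.component_sds):
            raise ValueError("component sds must be > 0")
        if self.n_archetypes < 1:
            raise ValueError("need at least one archetype")
        n_items = sum(c for c, _ in self.item_blocks)
        if self.n_archetypes * self.archetype_items > n_items:
            raise ValueError(
                f"{self.n_archetypes} archetypes x {self.archetype_items} items"
                f" exceed the {n_items} available items (subsets are disjoint)"
            )
        if not 0 <= self.archetype_strength <= 1:
            raise ValueError("archetype_strength must be in [0, 1]")

    @property
    def n_items(self) -> int:
        return sum(c for c, _ in self.item_blocks)

    @property
    def n_dummies(self) -> int:
        return sum(c * k for c, k in self.item_blocks)


@dataclass
class SyntheticSurvey:
    """Generated survey bundle: responses, codebook and ground truth."""

    responses: ResponseTable
    codebook: Codebook
    truth: pd.DataFrame         # respondent_id, theta, component, archetype
    config: GeneratorConfig

    def write(self, outdir) -> dict:
        """Write responses.csv, codebook.yml, truth.csv and a config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "responses": outdir / "responses.csv",
            "codebook": outdir / "codebook.yml",
            "truth": outdir / "truth.csv",
            "config": outdir / "generator_config.yml",
        }
        self.responses.data.to_csv(paths["responses"], index=False)
        self.codebook.save(paths["codebook"])
        self.truth.to_csv(paths["truth"], index=False)
        with open(paths["config"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(_jsonable(asdict(self.config)), fh, sort_keys=False)
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def default_codebook(config: GeneratorConfig | None = None) -> Codebook:
    """Reference synthetic codebook: 40 items / 166 signed dummy columns.

    Items are spread over the three risk dimensions; each item has exactly
    one risk-consistent (+1) and one risk-inconsistent (-1) category, the
    rest are neutral.
    """
    config = config or GeneratorConfig()
    dims = ("knowledge", "perception_severity", "preventive_practice")
    items = []
    idx = 0
    for count, k in config.item_blocks:
        for _ in range(count):
            dim = dims[idx % 3]
            item_id = f"{dim[:4].upper()}{idx + 1:02d}"
            categories = tuple(f"c{c + 1}" for c in range(k))
            # first category risk-consistent, last risk-inconsistent
            signs = {c: 0 for c in categories}
            signs[categories[0]] = 1
            signs[categories[-1]] = -1
            items.append(ItemCoding(item_id, dim, categories, signs))
            idx += 1
    return Codebook(items=items)


def generate(config: GeneratorConfig | None = None) -> SyntheticSurvey:
    """Draw a full synthetic survey; fully reproducible from the seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n
    codebook = default_codebook(config)
    items = codebook.items
    n_items = len(items)

    # --- demographics and latent trait -------------------------------
    female = rng.uniform(size=n) < config.p_female
    gender = np.where(female, "female", "male")
    weights = np.asarray(config.age_band_weights, dtype=float)
    weights = weights / weights.sum()
    band_idx = rng.choice(len(weights), size=n, p=weights)
    ages = np.array([rng.integers(_AGE_RANGES[b][0], _AGE_RANGES[b][1] + 1)
                     for b in band_idx])

    component = rng.uniform(size=n) < config.mixture_weights[1]  # True = high
    means = np.where(component, config.component_means[1], config.component_means[0])
    sds = np.where(component, config.component_sds[1], config.component_sds[0])
    theta = (rng.standard_normal(n) * sds + means
             + config.female_effect * female
             + config.age_effect * band_idx)

    # --- archetypes for the low-trait component ----------------------
    archetype = np.full(n, -1)
    low = ~component
    archetype[low] = rng.integers(0, config.n_archetypes, size=int(low.sum()))
    item_order = rng.permutation(n_items)
    arch_items = {
        a: set(item_order[a * config.archetype_items:(a + 1) * config.archetype_items])
        for a in range(config.n_archetypes)
    }
    # fixed archetype answer per (archetype, item): a non-(+1) category
    arch_answer = {}
    for a, subset in arch_items.items():
        for j in subset:
            cats = items[j].categories
            arch_answer[(a, j)] = cats[int(rng.integers(1, len(cats)))]

    # --- item responses ----------------------------------------------
    discr = rng.uniform(*config.discrimination_range, size=n_items)
    diff = rng.uniform(*config.difficulty_range, size=n_items)

    data = {
        "respondent_id": [f"R{i:06d}" for i in range(n)],
        "age": ages,
        "gender": gender,
        "civil_status": rng.choice(["partner", "no_partner"], size=n),
        "education": rng.choice(["secondary", "undergraduate", "postgraduate"],
                                size=n, p=[0.2, 0.55, 0.25]),
        "position": rng.choice(["student", "academic", "administrative"],
                               size=n, p=[0.7, 0.18, 0.12]),
    }

    for j, item in enumerate(items):
        cats = item.categories
        plus = cats[0]
        minus = cats[-1]
        zeros = list(cats[1:-1])
        p_plus = _logistic(discr[j] * (theta - diff[j]))
        u = rng.uniform(size=n)
        answers = np.empty(n, dtype=object)
        take_plus = u < p_plus
        answers[take_plus] = plus
        rest = ~take_plus
        n_rest = int(rest.sum())
        if n_rest:
            v = rng.uniform(size=n_rest)
            neg = v < config.p_negative_given_not_plus
            sub = np.empty(n_rest, dtype=object)
            sub[neg] = minus
            n_zero = int((~neg).sum())
            if zeros:
                sub[~neg] = np.asarray(zeros, dtype=object)[
                    rng.integers(0, len(zeros), size=n_zero)]
            else:
                sub[~neg] = minus
            answers[rest] = sub
        # archetype override for low-component respondents
        override_u = rng.uniform(size=n)  # drawn for all: keeps streams aligned
        for a in range(config.n_archetypes):
            if j in arch_items[a]:
                mask = low & (archetype == a) & (override_u < config.archetype_strength)
                answers[mask] = arch_answer[(a, j)]
        data[item.item_id] = answers

    # --- emotion and media flags -------------------------------------
    centred_band = band_idx - band_idx.mean()
    for name, (slope, prev, fem, age_sl) in {**EMOTION_PARAMS, **MEDIA_PARAMS}.items():
        lin = (_logit(prev) + slope * theta + fem * (female - config.p_female)
               + age_sl * centred_band)
        data[name] = (rng.uniform(size=n) < _logistic(lin)).astype(int)

    df = pd.DataFrame(data)
    responses = from_dataframe(df, codebook)
    truth = pd.DataFrame({
        "respondent_id": data["respondent_id"],
        "theta": theta,
        "component": np.where(component, "high", "low"),
        "archetype": archetype,
    })
    return SyntheticSurvey(responses=responses, codebook=codebook,
                           truth=truth, config=config)


def recovery_report(truth: pd.DataFrame, scores, quartiles,
                    assignment=None) -> dict:
    """Compare pipeline outputs with the generator's ground truth.

    Reports the Pearson correlation between the latent trait and the risk
    score, the fraction of high-component respondents landing in QR3-QR4,
    and — when a cluster assignment is given — the QR1 vs QR4 entropy
    comparison and the adjusted Rand agreement between archetypes and
    clusters among low-trait respondents.
    """
    scores = np.asarray(scores)
    quartiles = np.asarray(quartiles)
    if len(truth) != len(scores) or len(truth) != len(quartiles):
        raise ValueError("truth and pipeline outputs are misaligned")
    theta = truth["theta"].to_numpy()
    report = {
        "theta_score_correlation": float(np.corrcoef(theta, scores)[0, 1]),
        "high_component_in_upper_quartiles": float(
            np.isin(quartiles[(truth["component"] == "high").to_numpy()], (3, 4)).mean()
        ),
    }
    if assignment is not None:
        from sklearn.metrics import adjusted_rand_score

        from .clustering import NOISE, heterogeneity_summary

        assignment = np.asarray(assignment)
        het = heterogeneity_summary(assignment, quartiles)
        het = het.set_index("quartile")
        report["qr1_normalized_entropy"] = float(het.loc[1, "normalized_entropy"])
        report["qr4_normalized_entropy"] = float(het.loc[4, "normalized_entropy"])
        report["qr1_major_clusters"] = int(het.loc[1, "n_major_clusters"])
        report["qr4_largest_cluster_share"] = float(het.loc[4, "largest_cluster_share"])
        low = (truth["component"] == "low").to_numpy()
        clustered_low = low & (assignment != NOISE)
        if clustered_low.sum() > 1:
            report["archetype_cluster_ari"] = float(adjusted_rand_score(
                truth.loc[clustered_low, "archetype"], assignment[clustered_low]))
    return report
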