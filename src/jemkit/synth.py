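"""Seeded synthetic surveys, crosswalks, matrices and cohorts.

Every other module is testable without any external data: the generators
plant known ground truth (occupation-level exposure prevalences, survey
sampling, cohort outcome odds ratios) so recovery can be asserted exactly.

The occupational structure is a coarse two-component mixture — low-exposure
"white-collar" occupations against high-exposure "manual" ones — chosen so
that all five prevalence bands are populated. It makes no attempt to mimic
real national occupational structures beyond that mixture.

Within-occupation heterogeneity ``h`` interpolates between two exposure
models for an individual in an occupation with planted prevalence ``p``:

    P(exposed) = (1 - h) * E + h * p,      E = 1{occupation dichotomizes exposed}

``h = 1`` (the default) is the plain Bernoulli(p) survey model; ``h = 0`` is
the degenerate case where every worker shares the occupation's dichotomized
status, so group-level assignment incurs no misclassification. Intermediate
values produce Berkson-type error and hence attenuation of group-level odds
ratios.

All generators are pure functions of (config, seed): a single master seed
deterministically derives independent per-stream sub-seeds (profiles /
survey / cohort / crosswalk), so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .crosswalk import Crosswalk, CrosswalkEntry
from .model import (
    DEFAULT_SCHEME,
    GENDERS,
    CategoryScheme,
    ExposureDefinition,
    OccupationCode,
    categorize,
    load_registry,
)

_STREAMS = {"profiles": 0, "survey": 1, "cohort": 2, "crosswalk": 3,
            "corrupt": 4}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent generator for one pipeline stage."""
    if stream not in _STREAMS:
        raise ConfigError(f"unknown stream {stream!r}")
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _STREAMS[stream]))
    )


@dataclass(frozen=True)
class OccupationProfile:
    """Ground truth for one (occupation, gender): planted prevalences."""

    occupation: OccupationCode
    gender: str
    true_prevalence: dict  # exposure_id -> probability
    workforce_share: float
    major_group: str


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study scenario.

    Defaults describe a mid-sized national survey feeding a validation
    cohort: 50 occupations per gender, 200 survey respondents per
    occupation-gender cell, a 20 000-person cohort aged 25-60, a planted
    heavy-lifting/low-back-pain odds ratio of 1.6 (inside the range
    typically reported for physical workload and musculoskeletal pain),
    a 20% baseline outcome prevalence, and a mild positive age effect.
    """

    seed: int
    n_occupations: int = 50
    survey_n_per_cell: int = 200
    cohort_n: int = 20_000
    planted_or: dict = field(
        default_factory=lambda: {("heavy_lifting", "low_back_pain"): 1.6})
    baseline_outcome_prev: float = 0.20
    age_beta: float = 0.02  # log-odds per year, centred at age 40
    heterogeneity: float = 1.0
    white_collar_share: float = 0.5
    symptom_base_prev: float = 0.15
    symptom_exposure_logodds: float = 0.5
    age_range: tuple[float, float] = (25.0, 60.0)
    merge_fraction: float = 0.2
    split_fraction: float = 0.1

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        for name in ("n_occupations", "survey_n_per_cell", "cohort_n"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ConfigError("heterogeneity must lie in [0, 1]")
        # normalize planted_or keys loaded from YAML ("exposure:outcome")
        fixed = {}
        for key, v in self.planted_or.items():
            if isinstance(key, str):
                exposure_id, outcome_id = key.split(":")
                fixed[(exposure_id, outcome_id)] = float(v)
            else:
                fixed[tuple(key)] = float(v)
        self.planted_or = fixed

    @property
    def outcome_ids(self) -> list[str]:
        return sorted({o for _, o in self.planted_or})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad scenario config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_or"] = {f"{e}:{o}": v for (e, o), v in self.planted_or.items()}
        d["age_range"] = list(self.age_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), "utf-8")


def _codes(n: int) -> list[str]:
    # 4-digit codes; the first uses major group "0" to exercise leading zeros
    return [f"{(i % 10)}{i // 10:03d}" for i in range(n)]


def generate_profiles(
    config: ScenarioConfig,
    registry: Sequence[ExposureDefinition] | None = None,
    coding_system: str = "SYNTH-A",
) -> list[OccupationProfile]:
    """Draw planted occupation profiles for both genders.

    White-collar occupations draw prevalences from Uniform(0, 0.12), manual
    ones from Uniform(0.03, 0.98); with the default 50 occupations this
    populates all five bands. Workforce shares are Dirichlet(1) per gender.
    Deterministic under a fixed seed.
    """
    registry = list(registry) if registry is not None else load_registry()
    rng = stream_rng(config.seed, "profiles")
    codes = _codes(config.n_occupations)
    is_manual = rng.random(config.n_occupations) >= config.white_collar_share
    profiles: list[OccupationProfile] = []
    for gender in GENDERS:
        shares = rng.dirichlet(np.ones(config.n_occupations))
        for i, code in enumerate(codes):
            prevalence = {}
            for d in registry:
                if is_manual[i]:
                    prevalence[d.exposure_id] = float(rng.uniform(0.03, 0.98))
                else:
                    prevalence[d.exposure_id] = float(rng.uniform(0.0, 0.12))
            profiles.append(OccupationProfile(
                occupation=OccupationCode(code, coding_system),
                gender=gender,
                true_prevalence=prevalence,
                workforce_share=float(shares[i]),
                major_group=code[0],
            ))
    return profiles


def _exposure_prob(p: float, h: float,
                   scheme: CategoryScheme = DEFAULT_SCHEME) -> float:
    """Individual exposure probability under heterogeneity h."""
    exposed_occ = categorize(100.0 * p, scheme) >= scheme.exposed_cut
    return (1.0 - h) * float(exposed_occ) + h * p


def generate_survey(profiles: Sequence[OccupationProfile],
                    config: ScenarioConfig) -> pd.DataFrame:
    """Simulate survey microdata from planted profiles.

    Each (occupation, gender) cell gets ``survey_n_per_cell`` respondents
    with exposure indicators drawn at the heterogeneity-adjusted
    probability. A symptomatic flag is drawn with log-odds increasing in the
    number of reported exposures, to exercise the asymptomatic-only filter.
    """
    rng = stream_rng(config.seed, "survey")
    exposure_ids = sorted(profiles[0].true_prevalence)
    rows = []
    rid = 0
    for prof in profiles:
        n = config.survey_n_per_cell
        block = {
            "respondent_id": [f"r{rid + j:07d}" for j in range(n)],
            "occupation_code": [prof.occupation.code] * n,
            "gender": [prof.gender] * n,
        }
        rid += n
        total_exposed = np.zeros(n)
        for e in exposure_ids:
            q = _exposure_prob(prof.true_prevalence[e], config.heterogeneity)
            draws = (rng.random(n) < q).astype(int)
            block[e] = draws
            total_exposed += draws
        base_logit = np.log(config.symptom_base_prev
                            / (1 - config.symptom_base_prev))
        logit = base_logit + config.symptom_exposure_logodds * (total_exposed > 0)
        p_sym = 1.0 / (1.0 + np.exp(-logit))
        block["symptomatic"] = (rng.random(n) < p_sym).astype(int)
        rows.append(pd.DataFrame(block))
    df = pd.concat(rows, ignore_index=True)
    cols = ["respondent_id", "occupation_code", "gender", "symptomatic"]
    return df[cols + exposure_ids]


def generate_cohort(profiles: Sequence[OccupationProfile],
                    config: ScenarioConfig) -> pd.DataFrame:
    """Simulate a validation cohort with planted outcome odds ratios.

    Occupation is sampled by workforce share within gender, age uniform on
    the working-age window, individual exposure Bernoulli at the
    heterogeneity-adjusted probability, and each outcome Bernoulli with

        logit P = b0 + sum_e log(OR_eo) * X_e + b_age * (age - 40)

    where b0 reproduces ``baseline_outcome_prev`` for an unexposed
    40-year-old. True individual exposures are returned in ``true_<id>``
    columns (ground truth for oracles); file writers drop them.
    """
    rng = stream_rng(config.seed, "cohort")
    exposure_ids = sorted(profiles[0].true_prevalence)
    by_gender: dict[str, list[OccupationProfile]] = {g: [] for g in GENDERS}
    for p in profiles:
        by_gender[p.gender].append(p)
    lo, hi = config.age_range
    b0 = np.log(config.baseline_outcome_prev / (1 - config.baseline_outcome_prev))

    half = config.cohort_n // 2
    counts = {"M": half, "F": config.cohort_n - half}
    frames = []
    pid = 0
    for gender in GENDERS:
        profs = by_gender[gender]
        shares = np.array([p.workforce_share for p in profs])
        shares = shares / shares.sum()
        n = counts[gender]
        occ_idx = rng.choice(len(profs), size=n, p=shares)
        age = rng.uniform(lo, hi, size=n)
        block = {
            "person_id": [f"p{pid + j:07d}" for j in range(n)],
            "occupation_code": [profs[i].occupation.code for i in occ_idx],
            "gender": [gender] * n,
            "age": np.round(age, 1),
        }
        pid += n
        true_x = {}
        for e in exposure_ids:
            q = np.array([
                _exposure_prob(profs[i].true_prevalence[e], config.heterogeneity)
                for i in occ_idx])
            true_x[e] = (rng.random(n) < q).astype(int)
            block[f"true_{e}"] = true_x[e]
        for outcome_id in config.outcome_ids:
            logit = b0 + config.age_beta * (block["age"] - 40.0)
            for (e, o), oratio in config.planted_or.items():
                if o == outcome_id:
                    logit = logit + np.log(oratio) * true_x[e]
            prob = 1.0 / (1.0 + np.exp(-logit))
            block[outcome_id] = (rng.random(n) < prob).astype(int)
        frames.append(pd.DataFrame(block))
    df = pd.concat(frames, ignore_index=True)
    cols = (["person_id", "occupation_code", "gender", "age"]
            + config.outcome_ids + [f"true_{e}" for e in exposure_ids])
    return df[cols]


@dataclass
class CrosswalkGroundTruth:
    """The planted merge/split structure of a generated crosswalk."""

    merges: dict[str, list[str]]  # target -> merged source codes
    splits: dict[str, list[str]]  # source -> split target codes
    identity: list[str]


def generate_crosswalk_pair(
    profiles: Sequence[OccupationProfile],
    config: ScenarioConfig,
    target_system: str = "SYNTH-B",
) -> tuple[Crosswalk, CrosswalkGroundTruth]:
    """Construct a second coding system by merging and splitting codes.

    A ``merge_fraction`` of codes is merged pairwise into single target
    codes and a ``split_fraction`` split into two targets (uniform half
    weights); the remainder map one-to-one. The planted structure is
    returned for assertions. With both fractions 0 the result is an
    identity-style crosswalk onto the target system.
    """
    rng = stream_rng(config.seed, "crosswalk")
    codes = sorted({p.occupation.code for p in profiles})
    source_system = profiles[0].occupation.coding_system
    order = rng.permutation(len(codes))
    n_merge_pairs = int(config.merge_fraction * len(codes) / 2)
    n_split = int(config.split_fraction * len(codes))

    entries: list[CrosswalkEntry] = []
    merges: dict[str, list[str]] = {}
    splits: dict[str, list[str]] = {}
    identity: list[str] = []
    pos = 0
    for _ in range(n_merge_pairs):
        a, b = codes[order[pos]], codes[order[pos + 1]]
        pos += 2
        target = f"M{len(merges):03d}"
        merges[target] = sorted([a, b])
        entries.append(CrosswalkEntry(a, target))
        entries.append(CrosswalkEntry(b, target))
    for _ in range(n_split):
        s = codes[order[pos]]
        pos += 1
        t1, t2 = f"S{len(splits):03d}a", f"S{len(splits):03d}b"
        splits[s] = [t1, t2]
        entries.append(CrosswalkEntry(s, t1, 0.5))
        entries.append(CrosswalkEntry(s, t2, 0.5))
    for i in order[pos:]:
        c = codes[i]
        identity.append(c)
        entries.append(CrosswalkEntry(c, c, 1.0))
    xwalk = Crosswalk(source_system, target_system, entries)
    return xwalk, CrosswalkGroundTruth(merges, splits, sorted(identity))


# ---------------------------------------------------------------------------
# corrupt fixtures: exercise the error paths deliberately
# ---------------------------------------------------------------------------


def corrupt_survey(df: pd.DataFrame, kind: str, seed: int = 0) -> pd.DataFrame:
    """Return a deliberately broken copy of a survey frame.

    kinds: ``missing_gender`` blanks one gender value; ``duplicate_id``
    duplicates one respondent row; ``nonbinary_exposure`` plants a 2 in an
    exposure column.
    """
    rng = stream_rng(seed, "corrupt")
    out = df.copy()
    i = int(rng.integers(len(out)))
    if kind == "missing_gender":
        out.loc[out.index[i], "gender"] = ""
    elif kind == "duplicate_id":
        out = pd.concat([out, out.iloc[[i]]], ignore_index=True)
    elif kind == "nonbinary_exposure":
        exposure_cols = [c for c in out.columns if c not in
                         ("respondent_id", "occupation_code", "gender",
                          "symptomatic")]
        out.loc[out.index[i], exposure_cols[0]] = 2
    else:
        raise ConfigError(f"unknown corruption kind {kind!r}")
    return out
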