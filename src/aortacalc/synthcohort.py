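"""Synthetic cohorts of subjects with per-segment thoracic-aorta calcium.

Two generation modes:

* ``stochastic`` — covariates and per-segment calcium positivity are drawn
  independently per subject from the configured prevalences (with an optional
  logistic age dependence), with positive scores from a log-normal
  distribution.  Used for sampling-property and power checks.

* ``exact-marginal`` — a deterministic construction whose marginal counts
  (extended/standard TAC positivity, CAC positivity, joint counts, per-segment
  positivity, age-tertile positivity, and per-group risk-factor counts) hit
  the requested integers exactly, then gets shuffled with the seed.  The
  default counts are those of the study population this package models
  (n = 970), so population-level summaries can be reproduced by integer
  arithmetic.

Scores are Agatston units; cholesterol in mmol/l; pressures in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExactCounts", "CohortSpec", "CohortConsistencyError", "generate_cohort",
           "SEGMENT_COLUMNS"]

SEGMENT_COLUMNS = ["tac_s1", "tac_s2", "tac_s3", "tac_s4", "tac_s5"]


class CohortConsistencyError(ValueError):
    """Requested exact-marginal counts are mutually inconsistent."""


@dataclass
class ExactCounts:
    """Integer marginal counts the exact-marginal construction must reproduce."""

    n: int = 970
    extended_pos: int = 618          # extended TAC > 0
    standard_pos: int = 296          # standard TAC (segments 1+5) > 0
    cac_pos: int = 598               # CAC > 0
    cac_and_extended: int = 457      # CAC > 0 and extended TAC > 0
    neither: int = 211               # CAC = 0 and extended TAC = 0
    only_standard_segments: int = 19  # TAC in 1/5 but none of 2-4
    group_sizes: tuple[int, int, int] = (211, 648, 111)
    segment_pos: tuple[int, ...] = (39, 116, 407, 533, 296)
    tertile_pos: tuple[int, int, int] = (123, 209, 286)  # extended-positive per age tertile
    group_male: tuple[int, int, int] = (167, 527, 60)
    group_hypertension: tuple[int, int, int] = (80, 354, 42)
    group_hypercholesterolemia: tuple[int, int, int] = (146, 561, 89)
    group_smoker: tuple[int, int, int] = (104, 371, 49)
    group_diabetes: tuple[int, int, int] = (19, 54, 10)

    def validate(self) -> None:
        checks = [
            ("standard_pos <= extended_pos", self.standard_pos <= self.extended_pos),
            ("cac_and_extended <= cac_pos", self.cac_and_extended <= self.cac_pos),
            ("cac_and_extended <= extended_pos", self.cac_and_extended <= self.extended_pos),
            (
                "neither == n - (cac_pos + extended_pos - cac_and_extended)",
                self.neither == self.n - (self.cac_pos + self.extended_pos - self.cac_and_extended),
            ),
            ("only_standard_segments <= standard_pos",
             self.only_standard_segments <= self.standard_pos),
            ("sum(group_sizes) == n", sum(self.group_sizes) == self.n),
            ("group_sizes[0] == neither", self.group_sizes[0] == self.neither),
            ("segment_pos[0] + segment_pos[4] >= standard_pos",
             self.segment_pos[0] + self.segment_pos[4] >= self.standard_pos),
            ("segment_pos[0] <= standard_pos", self.segment_pos[0] <= self.standard_pos),
            ("segment_pos[4] <= standard_pos", self.segment_pos[4] <= self.standard_pos),
            ("sum(tertile_pos) == extended_pos", sum(self.tertile_pos) == self.extended_pos),
        ]
        n_234 = self.extended_pos - self.only_standard_segments
        checks.append(
            ("segment_pos[1]+[2]+[3] >= extended_pos - only_standard_segments",
             sum(self.segment_pos[1:4]) >= n_234)
        )
        checks.append(
            ("max(segment_pos[1:4]) <= extended_pos - only_standard_segments",
             max(self.segment_pos[1:4]) <= n_234)
        )
        s_and_c = self.standard_pos + self.cac_pos - self.group_sizes[1]
        checks.append(("0 <= standard∩CAC <= min(standard_pos, cac_pos)",
                       0 <= s_and_c <= min(self.standard_pos, self.cac_pos)))
        checks.append(("standard∩CAC <= cac_and_extended", s_and_c <= self.cac_and_extended))
        for name, counts in (
            ("group_male", self.group_male),
            ("group_hypertension", self.group_hypertension),
            ("group_hypercholesterolemia", self.group_hypercholesterolemia),
            ("group_smoker", self.group_smoker),
            ("group_diabetes", self.group_diabetes),
        ):
            checks.append(
                (f"{name} <= group sizes",
                 all(c <= g for c, g in zip(counts, self.group_sizes))),
            )
        for desc, ok in checks:
            if not ok:
                raise CohortConsistencyError(f"inconsistent exact-marginal counts: {desc}")


@dataclass
class CohortSpec:
    """Conditions of the simulated screening population."""

    n: int = 970
    mode: str = "exact-marginal"  # "exact-marginal" | "stochastic"
    male_fraction: float = 754 / 970
    age_mean: float = 57.0
    age_sd: float = 9.0
    prev_hypertension: float = 476 / 970
    prev_hypercholesterolemia: float = 796 / 970
    prev_smoker: float = 524 / 970
    prev_diabetes: float = 83 / 970
    segment_prevalence: tuple[float, ...] = (0.04, 0.12, 0.42, 0.55, 0.31)
    cac_prevalence: float = 598 / 970
    age_slope_per_decade: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    score_mu: float = 3.0       # log-normal parameters of positive segment scores
    score_sigma: float = 1.6
    cac_mu: float = 3.2
    cac_sigma: float = 1.8
    counts: ExactCounts = field(default_factory=ExactCounts)
    seed: int = 0

    def validate(self) -> None:
        probs = [self.male_fraction, self.prev_hypertension, self.prev_hypercholesterolemia,
                 self.prev_smoker, self.prev_diabetes, self.cac_prevalence,
                 *self.segment_prevalence]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all prevalences must lie in [0, 1]")
        if self.mode not in ("exact-marginal", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "exact-marginal":
            if self.counts.n != self.n:
                raise CohortConsistencyError("counts.n differs from spec.n")
            self.counts.validate()


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the subject table (one row per subject)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "stochastic":
        return _stochastic(spec, rng)
    return _exact_marginal(spec, rng)


# -- stochastic mode -------------------------------------------------------


def _covariates(spec: CohortSpec, rng: np.random.Generator, male, htn, hchol) -> dict:
    n = len(male)
    sbp = np.where(htn, rng.normal(150, 14, n), rng.normal(124, 10, n)).clip(92, 220)
    dbp = (0.55 * sbp + rng.normal(8, 4, n)).clip(50, 130)
    tc = np.where(hchol, rng.normal(6.4, 0.8, n), rng.normal(4.9, 0.6, n)).clip(2.5, 12)
    hdl = np.where(male, rng.normal(1.15, 0.28, n), rng.normal(1.45, 0.33, n)).clip(0.55, 3.5)
    ldl = (tc - hdl - 0.5).clip(0.3, None)
    return {"sbp_mmhg": sbp, "dbp_mmhg": dbp, "total_chol_mmol": tc,
            "hdl_mmol": hdl, "ldl_mmol": ldl}


def _scores(rng: np.random.Generator, positive: np.ndarray, mu: float, sigma: float):
    out = np.zeros(positive.shape)
    k = int(positive.sum())
    if k:
        out[positive] = np.maximum(rng.lognormal(mu, sigma, k), 1.0)
    return out


def _stochastic(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n
    age = rng.normal(spec.age_mean, spec.age_sd, n).clip(30, 85)
    male = rng.random(n) < spec.male_fraction
    htn = rng.random(n) < spec.prev_hypertension
    hchol = rng.random(n) < spec.prev_hypercholesterolemia
    smoker = rng.random(n) < spec.prev_smoker
    diabetes = rng.random(n) < spec.prev_diabetes
    df = pd.DataFrame({"id": np.arange(n), "male": male, "age": age,
                       "hypertension": htn, "hypercholesterolemia": hchol,
                       "smoker": smoker, "diabetes": diabetes})
    for k, v in _covariates(spec, rng, male, htn, hchol).items():
        df[k] = v
    for i, col in enumerate(SEGMENT_COLUMNS):
        p = spec.segment_prevalence[i]
        slope = spec.age_slope_per_decade[i]
        if p in (0.0, 1.0) or slope == 0.0:
            prob = np.full(n, p)
        else:
            logit = np.log(p / (1 - p)) + slope * (age - spec.age_mean) / 10.0
            prob = 1.0 / (1.0 + np.exp(-logit))
        pos = rng.random(n) < prob
        df[col] = _scores(rng, pos, spec.score_mu, spec.score_sigma)
    cac_pos = rng.random(n) < spec.cac_prevalence
    df["cac"] = _scores(rng, cac_pos, spec.cac_mu, spec.cac_sigma)
    return df


# -- exact-marginal mode ---------------------------------------------------


def _exact_marginal(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic construction (by construction index), shuffled with the seed.

    Construction order: [both standard & arch-positive] [only segments 1/5]
    [only segments 2-4] [CAC-only] [calcium-free].  Every requested marginal
    count is hit with equality; within-class assignments (which subjects of a
    class carry CAC, a given segment, a risk factor, or fall in an age
    tertile) are randomized with the seed.
    """
    c = spec.counts
    n = c.n
    both = c.standard_pos - c.only_standard_segments
    only15 = c.only_standard_segments
    only234 = c.extended_pos - c.standard_pos
    cac_only = c.cac_pos - c.cac_and_extended
    free = c.neither
    assert both + only15 + only234 + cac_only + free == n

    seg = np.zeros((n, 5), dtype=bool)
    std_idx = np.arange(0, both + only15)              # subjects with TAC in 1/5
    idx234 = np.concatenate([np.arange(0, both),
                             np.arange(both + only15, c.extended_pos)])  # need >=1 of s2-4

    # segments 1 and 5 cover all standard-positive subjects
    s1, s2, s3, s4, s5 = c.segment_pos
    seg[std_idx[:s5], 4] = True
    if s1:
        seg[std_idx[len(std_idx) - s1:], 0] = True
    uncovered = std_idx[~(seg[std_idx, 0] | seg[std_idx, 4])]
    if uncovered.size:
        raise CohortConsistencyError(
            "segment_pos[0] + segment_pos[4] cannot cover every standard-positive subject"
        )
    # segments 2-4 cover all arch/ascending-positive subjects: s4 from the
    # front, s3 from the back, s2 plugs any remaining gap
    m = len(idx234)
    seg[idx234[:s4], 3] = True
    seg[idx234[m - s3:], 2] = True
    gap = idx234[~(seg[idx234, 2] | seg[idx234, 3])]
    if gap.size > s2:
        raise CohortConsistencyError(
            "segment_pos[1:4] cannot cover every subject needing calcium in segments 2-4"
        )
    seg[gap, 1] = True
    remaining = s2 - gap.size
    pool = idx234[~seg[idx234, 1]]
    seg[pool[:remaining], 1] = True

    # CAC: 246-style split among standard-positive, part of only-234, all CAC-only
    s_and_c = c.standard_pos + c.cac_pos - c.group_sizes[1]
    cac = np.zeros(n, dtype=bool)
    cac[:s_and_c] = True                                   # standard & CAC
    only234_idx = np.arange(both + only15, c.extended_pos)
    cac[only234_idx[: c.cac_and_extended - s_and_c]] = True
    cac[c.extended_pos: c.extended_pos + cac_only] = True

    ext_pos = np.zeros(n, dtype=bool)
    ext_pos[: c.extended_pos] = True
    std_pos = seg[:, 0] | seg[:, 4]
    group = np.where(~cac & ~ext_pos, 1, np.where(cac | std_pos, 2, 3))

    # ages: exact extended-positive counts per age tertile
    ages = np.sort(rng.normal(spec.age_mean, spec.age_sd, n).clip(30, 85))
    sizes = [len(a) for a in np.array_split(np.arange(n), 3)]
    offsets = np.cumsum([0] + sizes[:-1])
    pos_ranks, neg_ranks = [], []
    for size, off, k in zip(sizes, offsets, c.tertile_pos):
        if k > size:
            raise CohortConsistencyError("tertile_pos exceeds tertile size")
        chosen = off + rng.choice(size, size=k, replace=False)
        pos_ranks.append(chosen)
        neg_ranks.append(np.setdiff1d(off + np.arange(size), chosen))
    pos_ranks = rng.permutation(np.concatenate(pos_ranks))
    neg_ranks = rng.permutation(np.concatenate(neg_ranks))
    rank = np.empty(n, dtype=int)
    rank[ext_pos] = pos_ranks
    rank[~ext_pos] = neg_ranks
    age = ages[rank]

    # per-group categorical attributes, randomized within each group
    def assign(counts: tuple[int, int, int]) -> np.ndarray:
        flag = np.zeros(n, dtype=bool)
        for g, k in zip((1, 2, 3), counts):
            members = np.nonzero(group == g)[0]
            flag[rng.choice(members, size=k, replace=False)] = True
        return flag

    male = assign(c.group_male)
    htn = assign(c.group_hypertension)
    hchol = assign(c.group_hypercholesterolemia)
    smoker = assign(c.group_smoker)
    diabetes = assign(c.group_diabetes)

    df = pd.DataFrame({"id": np.arange(n), "male": male, "age": age,
                       "hypertension": htn, "hypercholesterolemia": hchol,
                       "smoker": smoker, "diabetes": diabetes})
    for k, v in _covariates(spec, rng, male, htn, hchol).items():
        df[k] = v
    for i, col in enumerate(SEGMENT_COLUMNS):
        df[col] = _scores(rng, seg[:, i], spec.score_mu, spec.score_sigma)
    df["cac"] = _scores(rng, cac, spec.cac_mu, spec.cac_sigma)

    order = rng.permutation(n)
    df = df.iloc[order].reset_index(drop=True)
    df["id"] = np.arange(n)
    return df
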