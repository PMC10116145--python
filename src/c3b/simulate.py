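"""Synthetic cohorts for exercising and validating the whole pipeline.

No raw subject-level data are distributed with the battery's norms, so
every downstream stage is validated against simulated inputs whose
generating truth is known:

* normative cohorts with the published stratification (3 age bands x 3
  education bands x 2 sexes, 428 subjects, ~17.1% African-American) whose
  raw scores come from the published regression models plus Gaussian
  noise with SD equal to the printed RMSE;
* MCI / healthy-control case-control samples with the published group
  means and SDs;
* retest pairs from a bivariate Gaussian with a specified true
  reliability;
* per-trial VMT response simulations with a controlled placement
  accuracy, for end-to-end scoring checks.

All generators are deterministic per seed and emit plain DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import battery
from .battery import VMTStimulus, VMTTrialResponse
from .norms import Demographics, NormativeModel, builtin_models, predicted_score

__all__ = [
    "AGE_BANDS",
    "EDU_BANDS",
    "TABLE_STRATA",
    "SyntheticCohortSpec",
    "CaseControlSpec",
    "RetestSpec",
    "generate_normative_cohort",
    "generate_case_control",
    "generate_retest",
    "generate_vmt_responses",
    "expected_vmt_trial_score",
]

AGE_BANDS: dict[str, tuple[int, int]] = {
    "18-39": (18, 39),
    "40-59": (40, 59),
    "60-89": (60, 89),
}
EDU_BANDS: dict[str, tuple[int, int]] = {
    "9-12": (9, 12),
    "13-15": (13, 15),
    "16-20": (16, 20),
}

#: Published normative stratification: (sex, age band, education band) -> n.
#: sex is the male indicator (female=0, male=1); total 428.
TABLE_STRATA: dict[tuple[int, str, str], int] = {
    (0, "18-39", "9-12"): 22, (0, "18-39", "13-15"): 28, (0, "18-39", "16-20"): 24,
    (0, "40-59", "9-12"): 17, (0, "40-59", "13-15"): 25, (0, "40-59", "16-20"): 24,
    (0, "60-89", "9-12"): 27, (0, "60-89", "13-15"): 33, (0, "60-89", "16-20"): 29,
    (1, "18-39", "9-12"): 22, (1, "18-39", "13-15"): 24, (1, "18-39", "16-20"): 23,
    (1, "40-59", "9-12"): 17, (1, "40-59", "13-15"): 21, (1, "40-59", "16-20"): 26,
    (1, "60-89", "9-12"): 11, (1, "60-89", "13-15"): 21, (1, "60-89", "16-20"): 34,
}

VMT_RANGE = (0, 70)
PST_MIN = 0  # items are unlimited within the window, so no upper clip


def _scale_strata(
    strata: Mapping[tuple[int, str, str], int], total_n: int
) -> dict[tuple[int, str, str], int]:
    """Scale stratum counts to a new total by largest-remainder rounding."""
    base = sum(strata.values())
    raw = {k: v * total_n / base for k, v in strata.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total_n - sum(out.values())
    for k in sorted(raw, key=lambda k: raw[k] - out[k], reverse=True)[:short]:
        out[k] += 1
    return out


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating conditions for a normative cohort.

    Defaults reproduce the normative study's conditions: the published
    stratification (total 428), AA fraction 0.171, raw scores from the
    published models with Gaussian noise at the printed RMSEs.
    """

    strata: Mapping[tuple[int, str, str], int] = field(
        default_factory=lambda: dict(TABLE_STRATA)
    )
    aa_fraction: float = 0.171
    models: Mapping[str, NormativeModel] | None = None  # None -> builtin sets
    noise_sd: Mapping[str, float] | None = None  # None -> each model's RMSE
    round_scores: bool = True  # integer raw scores, as recorded by the tests
    seed: int = 0

    def scaled(self, total_n: int) -> "SyntheticCohortSpec":
        """Same conditions with strata counts scaled to ``total_n``."""
        return replace(self, strata=_scale_strata(self.strata, total_n))

    @property
    def total_n(self) -> int:
        return sum(self.strata.values())


def generate_normative_cohort(spec: SyntheticCohortSpec | None = None) -> pd.DataFrame:
    """Draw a stratified normative cohort and its raw test scores.

    Ages are uniform within each band, education uniform on integer years
    within its band, race Bernoulli(aa_fraction) independent of stratum.
    Raw scores are the model's linear predictor plus Gaussian(0, noise SD),
    rounded to integers and clipped to attainable ranges (VMT 0-70,
    PST >= 0).
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed)
    models = dict(spec.models) if spec.models is not None else builtin_models()
    noise = dict(spec.noise_sd) if spec.noise_sd is not None else {
        tid: m.rmse for tid, m in models.items()
    }
    rows: list[dict] = []
    for (sex, age_band, edu_band), count in spec.strata.items():
        alo, ahi = AGE_BANDS[age_band]
        elo, ehi = EDU_BANDS[edu_band]
        for _ in range(count):
            rows.append(
                {
                    "age": float(rng.uniform(alo, ahi)),
                    "education": int(rng.integers(elo, ehi + 1)),
                    "sex": sex,
                    "race": int(rng.random() < spec.aa_fraction),
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"norm{i:05d}" for i in range(len(df))])
    for tid, model in models.items():
        demo = [
            Demographics(age=a, education=e, sex=s, race=r)
            for a, e, s, r in zip(df["age"], df["education"], df["sex"], df["race"])
        ]
        pred = np.array([predicted_score(model, d) for d in demo])
        raw = pred + rng.normal(0.0, noise[tid], size=len(df)) if noise[tid] > 0 else pred
        if spec.round_scores:
            raw = np.rint(raw)
            if tid.upper() == "VMT":
                raw = np.clip(raw, *VMT_RANGE)
            else:
                raw = np.maximum(raw, PST_MIN)
            raw = raw.astype(int)
        df[f"{tid.lower()}_raw"] = raw
    return df


@dataclass(frozen=True)
class CaseControlSpec:
    """Generating conditions for an MCI vs healthy-control sample.

    Score defaults are the published group summaries (PST 28.61/11.27 vs
    44.27/8.48; VMT 26.57/14.97 vs 51.63/14.18, n = 30 per group); the
    demographics mimic the validation sample's elderly profile (age about
    74 +/- 6 years, education about 15.7 +/- 3 years).
    """

    n_per_group: int = 30
    score_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "PST": {"MCI": (28.61, 11.27), "HC": (44.27, 8.48)},
            "VMT": {"MCI": (26.57, 14.97), "HC": (51.63, 14.18)},
        }
    )
    age_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"MCI": (75.07, 7.23), "HC": (73.53, 5.25)}
    )
    edu_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"MCI": (15.77, 2.90), "HC": (15.70, 3.06)}
    )
    male_fraction: float = 0.58
    aa_fraction: float = 0.18
    #: within-subject correlation between the two test scores; processing
    #: speed and episodic memory correlate moderately in elderly samples
    cross_test_correlation: float = 0.5
    seed: int = 0


def generate_case_control(spec: CaseControlSpec | None = None) -> pd.DataFrame:
    """Draw labelled MCI/HC records with demographics and raw scores.

    The two test scores are drawn jointly per subject from a bivariate
    Gaussian with the group's (mean, SD) pairs and the spec's cross-test
    correlation, then clipped to attainable ranges; ages are clipped to
    the 60-89 normative band, education to 2-20 integer years.
    """
    spec = spec or CaseControlSpec()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group in ("MCI", "HC"):
        amu, asd = spec.age_params[group]
        emu, esd = spec.edu_params[group]
        for i in range(spec.n_per_group):
            rows.append(
                {
                    "id": f"{group.lower()}{i:04d}",
                    "group": group,
                    "age": float(np.clip(rng.normal(amu, asd), 60, 89)),
                    "education": int(np.clip(np.rint(rng.normal(emu, esd)), 2, 20)),
                    "sex": int(rng.random() < spec.male_fraction),
                    "race": int(rng.random() < spec.aa_fraction),
                }
            )
    df = pd.DataFrame(rows)
    tests = list(spec.score_params)
    cols = {tid: np.empty(len(df)) for tid in tests}
    for group in ("MCI", "HC"):
        mask = (df["group"] == group).to_numpy()
        mus = np.array([spec.score_params[tid][group][0] for tid in tests])
        sds = np.array([spec.score_params[tid][group][1] for tid in tests])
        cov = np.outer(sds, sds) * (
            np.eye(len(tests)) * (1 - spec.cross_test_correlation)
            + spec.cross_test_correlation
        )
        draws = rng.multivariate_normal(mus, cov, size=int(mask.sum()))
        for j, tid in enumerate(tests):
            d = np.rint(draws[:, j])
            if tid.upper() == "VMT":
                d = np.clip(d, *VMT_RANGE)
            else:
                d = np.maximum(d, PST_MIN)
            cols[tid][mask] = d
    for tid in tests:
        df[f"{tid.lower()}_raw"] = cols[tid].astype(int)
    return df


@dataclass(frozen=True)
class RetestSpec:
    """Bivariate-Gaussian retest pairs with a known true reliability.

    Defaults match the retest study's scale: 30 healthy elders, equal
    occasion means/SDs, true correlation 0.8.
    """

    n: int = 30
    mean1: float = 44.4
    mean2: float = 44.4
    sd1: float = 8.6
    sd2: float = 8.6
    correlation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")


def generate_retest(spec: RetestSpec | None = None) -> pd.DataFrame:
    """Draw (t1, t2) pairs from the specified bivariate Gaussian."""
    spec = spec or RetestSpec()
    rng = np.random.default_rng(spec.seed)
    cov = spec.correlation * spec.sd1 * spec.sd2
    draws = rng.multivariate_normal(
        [spec.mean1, spec.mean2],
        [[spec.sd1**2, cov], [cov, spec.sd2**2]],
        size=spec.n,
    )
    return pd.DataFrame(
        {
            "id": [f"retest{i:04d}" for i in range(spec.n)],
            "t1": draws[:, 0],
            "t2": draws[:, 1],
        }
    )


def generate_vmt_responses(
    stimulus: VMTStimulus,
    accuracy: float | list[float],
    seed: int = 0,
    n_trials: int = battery.N_TRIALS,
    miss_strategy: str = "uniform",
) -> list[VMTTrialResponse]:
    """Simulate trial responses with a controlled placement accuracy.

    Each symbol is placed on its correct cell with probability
    ``accuracy``; the missed symbols are then placed by a uniformly random
    injection into the remaining free cells.  Under the default
    ``"uniform"`` strategy a missed symbol may land on its own cell by
    chance (which admits a closed-form expected trial score, see
    :func:`expected_vmt_trial_score`); ``"off_pattern"`` forces missed
    symbols onto non-target cells.
    """
    if miss_strategy not in ("uniform", "off_pattern"):
        raise ValueError("miss_strategy must be 'uniform' or 'off_pattern'")
    acc = [accuracy] * n_trials if np.isscalar(accuracy) else list(accuracy)
    if len(acc) != n_trials or any(not 0 <= p <= 1 for p in acc):
        raise ValueError("accuracy must be a probability (or one per trial)")
    rng = np.random.default_rng(seed)
    all_cells = [
        (r, c)
        for r in range(1, battery.BOARD_ROWS + 1)
        for c in range(1, battery.BOARD_COLS + 1)
    ]
    responses = []
    for p in acc:
        placements: dict[tuple[int, int], battery.SymbolID] = {}
        missed: list[battery.SymbolID] = []
        for cell, sym in sorted(stimulus.assignment.items()):
            if rng.random() < p:
                placements[cell] = sym
            else:
                missed.append(sym)
        if missed:
            free = [c for c in all_cells if c not in placements]
            if miss_strategy == "off_pattern":
                free = [c for c in free if c not in stimulus.cells]
            chosen = rng.choice(len(free), size=len(missed), replace=False)
            for sym, ci in zip(missed, chosen):
                placements[free[ci]] = sym
        responses.append(VMTTrialResponse(placements=placements))
    return responses


def expected_vmt_trial_score(accuracy: float) -> float:
    """Exact expected trial score under the ``"uniform"`` placement rule.

    Conditional on k of the 7 symbols being placed correctly, the
    remaining m = 7 - k symbols occupy a uniformly random injection into
    the 24 - k free cells; each of the m free target cells is then
    occupied by its own symbol with probability 1/(24-k) (2 points) or by
    some other missed symbol with probability (m-1)/(24-k) (1 point), so

        E[score | k] = 2k + m (m + 1) / (24 - k).

    The unconditional expectation sums this against Binomial(7, accuracy).
    """
    from scipy.stats import binom

    total = 0.0
    n_cells = battery.BOARD_ROWS * battery.BOARD_COLS
    for k in range(8):
        m = 7 - k
        cond = 2 * k + (m * (m + 1)) / (n_cells - k)
        total += binom.pmf(k, 7, accuracy) * cond
    return total
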