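"""Synthetic cohort generator emulating the published five-group structure.

No subject-level data accompany the study, so the pipeline is exercised on
simulated cohorts that reproduce the published group-level statistics: five
diagnostic groups (healthy controls, non-metabolic myalgia, complete
myoadenylate-deaminase deficiency, McArdle disease, respiratory-chain
deficiency) with their published sample sizes, sex ratios, age
distributions and percent-predicted MVC / maximal-power means and SDs.

Percent-predicted performances are drawn directly from a truncated
bivariate normal per group (the published report gives distributions only
at the %Pred level); raw forces and powers are then back-computed through
the normative equations, so the percent-predicted layer inverts the
generation exactly — every simulated subject is a round-trip test of the
normative module.  The inter-performance correlation rho is not published;
it defaults to 0 and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import Group, Sex, SubjectRecord
from .normative import predict_mvc, predict_mp

__all__ = ["GroupSpec", "CohortSpec", "default_spec", "generate_cohort"]

# Sex-conditional anthropometric sampling constants (mean, SD): adult
# European reference values; heights in meters, forearm circumference in cm.
HEIGHT_BY_SEX = {Sex.MALE: (1.77, 0.07), Sex.FEMALE: (1.63, 0.06)}
FOREARM_BY_SEX = {Sex.MALE: (27.0, 2.0), Sex.FEMALE: (24.0, 2.0)}

#: Relative spread of the two sub-maximal grip trials below the best trial.
_TRIAL_SHORTFALL_SD = 0.05

AGE_BOUNDS = (18.0, 85.0)
PCT_BOUNDS = (5.0, 250.0)


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one diagnostic group."""

    group: Group
    n: int
    p_female: float
    age_mean: float
    age_sd: float
    pct_mvc_mean: float
    pct_mvc_sd: float
    pct_mp_mean: float
    pct_mp_sd: float
    rho: float = 0.0  # correlation between %Pred MVC and %Pred MP
    vo2_mean: float | None = None  # raw peak V'O2, mL·min⁻¹·kg⁻¹
    vo2_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be ≥ 1")
        if not 0 <= self.p_female <= 1:
            raise ValueError("p_female must be a fraction")
        if min(self.age_sd, self.pct_mvc_sd, self.pct_mp_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if not -1 <= self.rho <= 1:
            raise ValueError("|rho| must be ≤ 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe: group specs, seed and truncation bounds."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    age_bounds: tuple[float, float] = AGE_BOUNDS
    pct_bounds: tuple[float, float] = PCT_BOUNDS

    def __post_init__(self) -> None:
        names = [g.group for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group labels must be unique")
        for lo, hi in (self.age_bounds, self.pct_bounds):
            if not lo < hi:
                raise ValueError("truncation bounds must be ordered")

    def scaled(self, factor: int) -> "CohortSpec":
        """Multiply every group's n (for large-sample simulation studies)."""
        if factor < 1:
            raise ValueError("scale factor must be ≥ 1")
        return replace(
            self, groups=tuple(replace(g, n=g.n * factor) for g in self.groups)
        )

    def with_n(self, n: int) -> "CohortSpec":
        """Set every group's n to the same value."""
        return replace(self, groups=tuple(replace(g, n=n) for g in self.groups))


def default_spec(seed: int = 0, rho: float = 0.0) -> CohortSpec:
    """The published cohort structure: n, sex ratio, age and %Pred moments.

    Group sizes 35/60/10/9/4 (total 118), female/male ratios 17/18, 20/40,
    4/6, 5/4 and 1/3, with the published mean ± SD for age, %Pred MVC,
    %Pred maximal power, and raw peak V'O2.
    """
    g = GroupSpec
    groups = (
        g(Group.CONTROL, 35, 17 / 35, 40.1, 12.9, 97.1, 12.4, 107.3, 20.9, rho, 34.3, 8.2),
        g(Group.NON_METABOLIC_MYALGIA, 60, 20 / 60, 42.5, 13.6, 87.6, 18.9, 98.2, 21.9, rho, 32.6, 9.2),
        g(Group.MAD_ABSENT, 10, 4 / 10, 39.9, 15.6, 87.9, 19.9, 71.7, 17.1, rho, 28.7, 12.9),
        g(Group.MCARDLE, 9, 5 / 9, 43.3, 25.9, 78.5, 9.3, 43.8, 14.6, rho, 21.2, 7.0),
        g(Group.RESPIRATORY_CHAIN, 4, 1 / 4, 40.5, 16.4, 76.1, 30.2, 67.5, 30.7, rho, 27.3, 11.4),
    )
    return CohortSpec(groups=groups, seed=seed)


def _check_satisfiable(mean: float, sd: float, lo: float, hi: float, what: str) -> None:
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError(f"{what}: constant {mean} outside bounds [{lo}, {hi}]")
        return
    if mean < lo - 4 * sd or mean > hi + 4 * sd:
        raise ValueError(
            f"{what}: mean {mean} lies > 4 SD outside bounds [{lo}, {hi}]; "
            "truncated sampling is unsatisfiable"
        )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated normal draws by rejection (bounds are wide; fast in practice)."""
    if sd == 0:
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _trunc_bvn(rng: np.random.Generator, spec: GroupSpec,
               lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated bivariate normal (%Pred MVC, %Pred MP) by rejection."""
    mean = [spec.pct_mvc_mean, spec.pct_mp_mean]
    cov = [
        [spec.pct_mvc_sd**2, spec.rho * spec.pct_mvc_sd * spec.pct_mp_sd],
        [spec.rho * spec.pct_mvc_sd * spec.pct_mp_sd, spec.pct_mp_sd**2],
    ]
    out = np.empty((size, 2))
    filled = 0
    while filled < size:
        draw = rng.multivariate_normal(mean, cov, size=2 * (size - filled) + 16)
        ok = ((draw >= lo) & (draw <= hi)).all(axis=1)
        keep = draw[ok]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw one synthetic cohort; deterministic under ``spec.seed``.

    Per subject: sex ~ Bernoulli(p_female); age ~ truncated normal; height
    and forearm circumference from sex-conditional normals; (%Pred MVC,
    %Pred MP) ~ truncated bivariate normal; raw MVC and MP back-computed
    through the normative predictions.  Three grip trials are emitted whose
    maximum equals the recorded MVC.  Each group uses its own deterministic
    substream of the master seed.
    """
    age_lo, age_hi = spec.age_bounds
    pct_lo, pct_hi = spec.pct_bounds
    for g in spec.groups:
        _check_satisfiable(g.age_mean, g.age_sd, age_lo, age_hi, f"{g.group.value} age")
        _check_satisfiable(g.pct_mvc_mean, g.pct_mvc_sd, pct_lo, pct_hi, f"{g.group.value} pct_mvc")
        _check_satisfiable(g.pct_mp_mean, g.pct_mp_sd, pct_lo, pct_hi, f"{g.group.value} pct_mp")

    children = np.random.SeedSequence(spec.seed).spawn(len(spec.groups))
    records: list[SubjectRecord] = []
    for g, child in zip(spec.groups, children):
        rng = np.random.default_rng(child)
        sexes = [Sex.FEMALE if u < g.p_female else Sex.MALE for u in rng.random(g.n)]
        ages = _trunc_normal(rng, g.age_mean, g.age_sd, age_lo, age_hi, g.n)
        pct = _trunc_bvn(rng, g, pct_lo, pct_hi, g.n)
        for i in range(g.n):
            sex = Sex(sexes[i])
            h_mu, h_sd = HEIGHT_BY_SEX[sex]
            f_mu, f_sd = FOREARM_BY_SEX[sex]
            height = float(_trunc_normal(rng, h_mu, h_sd, 1.0, 2.3, 1)[0])
            # keep circumference in a range where the MVC prediction stays positive
            circ = float(_trunc_normal(rng, f_mu, f_sd, 18.0, 40.0, 1)[0])
            pct_mvc, pct_mp = float(pct[i, 0]), float(pct[i, 1])
            mvc = pct_mvc / 100.0 * predict_mvc(sex, float(ages[i]), circ)
            mp = pct_mp / 100.0 * predict_mp(sex, float(ages[i]), height)
            shortfall = np.abs(rng.normal(0.0, _TRIAL_SHORTFALL_SD, size=2))
            trials = [mvc * (1 - shortfall[0]), mvc * (1 - shortfall[1]), mvc]
            rng.shuffle(trials)
            vo2 = None
            if g.vo2_mean is not None and g.vo2_sd is not None:
                vo2 = float(_trunc_normal(rng, g.vo2_mean, g.vo2_sd, 2.0, 90.0, 1)[0])
            records.append(
                SubjectRecord(
                    subject_id=f"{g.group.value}_{i + 1:04d}",
                    group=g.group,
                    sex=sex,
                    age=float(ages[i]),
                    height=height,
                    forearm_circumference=circ,
                    mvc=mvc,
                    mp=mp,
                    mvc_trials=tuple(trials),
                    peak_vo2=vo2,
                )
            )
    return records
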