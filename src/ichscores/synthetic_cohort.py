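"""Synthetic admission cohorts with the statistical structure the
prognostic analysis assumes.

Two generator modes:

``score_level``
    Draws (score, outcome) pairs directly from a joint probability table —
    by default the observed 107-patient joint distribution of each score
    and 30-day vital status.  One outcome is drawn per patient; each
    system's score is then drawn from its outcome-conditional distribution,
    independently across systems given the outcome.  This mode reproduces
    the score-outcome joint exactly in expectation and is what evaluation
    tests run on.

``component_level``
    Draws raw admission covariates (age, GCS, MRS, temperature, pulse
    pressure, volume, IVH/SAH/location flags) from outcome-conditional
    truncated normals and Bernoullis, calibrated to the cohort's published
    per-outcome means and SDs, and leaves scoring to
    :mod:`ichscores.score_models`.  Covariates are conditionally
    independent given the outcome; no cross-covariate correlation is
    modelled.

The observed count tables themselves ship as a packaged, checksummed CSV
fixture, exposed by :func:`table_fixtures`.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Dict, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .roc_eval import ScoreOutcomeTable

__all__ = [
    "CohortConfig",
    "CovariateSpec",
    "GroupNormal",
    "SystemJoint",
    "table_fixtures",
    "generate_cohort",
    "recover_parameters",
    "FIXTURE_SHA256",
]

FIXTURE_RESOURCE = "score_outcome_counts.csv"
FIXTURE_SHA256 = "d2391598ad10052da5758301c5f3ad6557bd7bec8108566ac51862b4edcb59f1"

# Observed cohort size behind the default joint table.
_COHORT_N = 107


def table_fixtures() -> tuple[ScoreOutcomeTable, ScoreOutcomeTable]:
    """The packaged observed count tables (ICH, Modified New ICH).

    Counts: 61 deceased and 46 survivors tabulated over score values 0-6
    for each system.  The packaged CSV is verified against a frozen SHA-256
    before parsing.
    """
    data = (
        resources.files("ichscores").joinpath("data", FIXTURE_RESOURCE).read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != FIXTURE_SHA256:
        raise RuntimeError(
            f"packaged fixture checksum mismatch: {digest} != {FIXTURE_SHA256}"
        )
    df = pd.read_csv(pd.io.common.BytesIO(data))
    tables = {}
    for system, grp in df.groupby("system"):
        grp = grp.sort_values("score")
        tables[system] = ScoreOutcomeTable(
            score_values=tuple(int(s) for s in grp["score"]),
            dead_counts=tuple(int(c) for c in grp["dead"]),
            alive_counts=tuple(int(c) for c in grp["alive"]),
        )
    return tables["ich"], tables["modified_new_ich"]


class GroupNormal(BaseModel):
    """Mean/SD of one covariate within one outcome group."""

    mean: float
    sd: float = Field(ge=0)


class CovariateSpec(BaseModel):
    """Outcome-conditional truncated-normal model of one covariate.

    ``lo``/``hi`` are the physiologic truncation bounds; ``integer`` marks
    discrete clinical scales whose draws are rounded to integers.
    """

    dead: GroupNormal
    alive: GroupNormal
    lo: float
    hi: float
    integer: bool = False

    @model_validator(mode="after")
    def _check_bounds(self) -> "CovariateSpec":
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got [{self.lo}, {self.hi}]")
        return self


class GroupRate(BaseModel):
    """Bernoulli rate of a binary covariate per outcome group."""

    dead: float = Field(ge=0, le=1)
    alive: float = Field(ge=0, le=1)


class SystemJoint(BaseModel):
    """Joint probability of (score, outcome) for one scoring system."""

    scores: list[int]
    dead: list[float]
    alive: list[float]

    @model_validator(mode="after")
    def _check(self) -> "SystemJoint":
        if not (len(self.scores) == len(self.dead) == len(self.alive)):
            raise ValueError("scores, dead, alive must have equal length")
        if any(p < 0 for p in self.dead + self.alive):
            raise ValueError("joint probabilities must be non-negative")
        total = sum(self.dead) + sum(self.alive)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"joint probabilities must sum to 1, got {total}")
        return self

    @property
    def prevalence(self) -> float:
        return sum(self.dead)

    def conditional(self, dead: bool) -> tuple[list[int], np.ndarray]:
        probs = np.asarray(self.dead if dead else self.alive, dtype=float)
        return self.scores, probs / probs.sum()


def _joint_from_table(table: ScoreOutcomeTable) -> SystemJoint:
    n = table.n_total
    return SystemJoint(
        scores=list(table.score_values),
        dead=[c / n for c in table.dead_counts],
        alive=[c / n for c in table.alive_counts],
    )


def _default_joint_probs() -> Dict[str, SystemJoint]:
    ich, mod = table_fixtures()
    return {
        "ich_score": _joint_from_table(ich),
        "modified_new_ich_score": _joint_from_table(mod),
    }


def _default_covariate_params() -> Dict[str, CovariateSpec]:
    # Per-outcome means/SDs of the observed 107-patient cohort; truncation
    # bounds are physiologic ranges, needed because only mean +/- SD is
    # published.  dbp is not published per outcome; a typical hypertensive
    # admission distribution is assumed so pulse pressure can be split into
    # sbp/dbp.
    return {
        "age": CovariateSpec(
            dead=GroupNormal(mean=70.75, sd=16.82),
            alive=GroupNormal(mean=61.63, sd=13.82),
            lo=18, hi=110, integer=True,
        ),
        "gcs": CovariateSpec(
            dead=GroupNormal(mean=7, sd=4),
            alive=GroupNormal(mean=12, sd=3),
            lo=3, hi=15, integer=True,
        ),
        "mrs": CovariateSpec(
            dead=GroupNormal(mean=5, sd=1),
            alive=GroupNormal(mean=3, sd=1),
            lo=0, hi=5, integer=True,
        ),
        "temperature": CovariateSpec(
            dead=GroupNormal(mean=36.97, sd=0.47),
            alive=GroupNormal(mean=36.99, sd=0.36),
            lo=30, hi=43,
        ),
        "pulse_pressure": CovariateSpec(
            dead=GroupNormal(mean=76.46, sd=26.10),
            alive=GroupNormal(mean=70.02, sd=19.57),
            lo=10, hi=150,
        ),
        "volume_cm3": CovariateSpec(
            dead=GroupNormal(mean=31.65, sd=18.93),
            alive=GroupNormal(mean=18.67, sd=10.99),
            lo=0.5, hi=150,
        ),
        "dbp": CovariateSpec(
            dead=GroupNormal(mean=85, sd=12),
            alive=GroupNormal(mean=85, sd=12),
            lo=40, hi=130,
        ),
    }


class CohortConfig(BaseModel):
    """Generator parameters.

    Defaults reproduce the observed cohort: 107 patients, 57% 30-day
    mortality, the published score-outcome joint distribution, per-outcome
    covariate means/SDs, and per-outcome IVH/SAH/infratentorial rates.
    A single integer seed drives one numpy Generator stream.
    """

    model_config = ConfigDict(validate_default=True)

    n: int = Field(default=_COHORT_N, ge=0)
    seed: int = 0
    mode: Literal["score_level", "component_level"] = "score_level"
    joint_probs: Dict[str, SystemJoint] = Field(default_factory=_default_joint_probs)
    covariate_params: Dict[str, CovariateSpec] = Field(
        default_factory=_default_covariate_params
    )
    ivh_probs: GroupRate = GroupRate(dead=40 / 61, alive=16 / 46)
    sah_probs: GroupRate = GroupRate(dead=13 / 61, alive=4 / 46)
    infratentorial_probs: GroupRate = GroupRate(dead=10 / 61, alive=6 / 46)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.mode == "score_level" and not self.joint_probs:
            raise ValueError("score_level mode requires joint_probs")
        prevs = [j.prevalence for j in self.joint_probs.values()]
        if prevs and max(prevs) - min(prevs) > 1e-9:
            raise ValueError(
                "joint_probs of all systems must imply the same outcome prevalence"
            )
        if self.mode == "component_level":
            required = {
                "age", "gcs", "mrs", "temperature", "pulse_pressure",
                "volume_cm3", "dbp",
            }
            missing = required - set(self.covariate_params)
            if missing:
                raise ValueError(
                    f"component_level mode missing covariate_params: {sorted(missing)}"
                )
        return self

    @property
    def prevalence(self) -> float:
        if self.joint_probs:
            return next(iter(self.joint_probs.values())).prevalence
        return 61 / 107


def _truncnorm_draw(
    rng: np.random.Generator, spec: GroupNormal, lo: float, hi: float, size: int
) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if spec.sd == 0:
        return np.full(size, np.clip(spec.mean, lo, hi))
    a = (lo - spec.mean) / spec.sd
    b = (hi - spec.mean) / spec.sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.mean, scale=spec.sd, size=size, random_state=rng
    )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate an admission cohort; deterministic given ``config.seed``.

    Returns a DataFrame with one row per patient.  In ``score_level`` mode
    the columns are the configured score systems plus ``dead_30d``; in
    ``component_level`` mode they are the cohort CSV covariate columns plus
    ``dead_30d``, with scores left to the scoring pipeline.
    """
    config = CohortConfig.model_validate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    dead = rng.random(n) < config.prevalence

    if config.mode == "score_level":
        out = pd.DataFrame({"dead_30d": dead.astype(int)})
        for name, joint in config.joint_probs.items():
            col = np.zeros(n, dtype=int)
            for flag in (True, False):
                mask = dead == flag
                scores, probs = joint.conditional(flag)
                col[mask] = rng.choice(scores, size=int(mask.sum()), p=probs)
            out[name] = col
        return out[[*config.joint_probs, "dead_30d"]]

    # component_level
    cols: dict[str, np.ndarray] = {}
    for field, spec in config.covariate_params.items():
        vals = np.zeros(n, dtype=float)
        for flag, grp in ((True, spec.dead), (False, spec.alive)):
            mask = dead == flag
            vals[mask] = _truncnorm_draw(rng, grp, spec.lo, spec.hi, int(mask.sum()))
        if spec.integer:
            vals = np.clip(np.rint(vals), spec.lo, spec.hi)
        cols[field] = vals

    def bern(rate: GroupRate) -> np.ndarray:
        r = np.where(dead, rate.dead, rate.alive)
        return (rng.random(n) < r).astype(int)

    df = pd.DataFrame(
        {
            "age": cols["age"].astype(int),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "gcs": cols["gcs"].astype(int),
            "mrs": cols["mrs"].astype(int),
            "temperature": np.round(cols["temperature"], 1),
            "sbp": np.round(cols["dbp"] + cols["pulse_pressure"], 1),
            "dbp": np.round(cols["dbp"], 1),
            "location": np.where(
                bern(config.infratentorial_probs) == 1, "infra", "supra"
            ),
            "ivh": bern(config.ivh_probs),
            "sah": bern(config.sah_probs),
            "volume_cm3": np.round(cols["volume_cm3"], 2),
            "dead_30d": dead.astype(int),
        }
    )
    return df


def recover_parameters(cohort: pd.DataFrame, outcome: str = "dead_30d") -> dict:
    """Empirical estimates of the generator parameters from a cohort.

    Returns per-outcome means/SDs for every numeric covariate present,
    per-outcome rates for the binary flags, and — when score columns are
    present — the empirical joint (score, outcome) cell frequencies.
    Requires at least two patients per outcome group.
    """
    if outcome not in cohort.columns:
        raise KeyError(f"outcome column {outcome!r} not in cohort")
    dead = cohort[outcome].astype(bool)
    n_dead, n_alive = int(dead.sum()), int((~dead).sum())
    if n_dead < 2 or n_alive < 2:
        raise ValueError(
            f"need >= 2 patients per outcome group, got {n_dead} dead / "
            f"{n_alive} alive"
        )

    result: dict = {
        "n": len(cohort),
        "prevalence": n_dead / len(cohort),
        "covariates": {},
        "rates": {},
        "joint_freqs": {},
    }
    if "sbp" in cohort.columns and "dbp" in cohort.columns:
        cohort = cohort.assign(pulse_pressure=cohort["sbp"] - cohort["dbp"])
    score_cols = [c for c in cohort.columns if c.endswith("_score")]
    flag_cols = [c for c in ("ivh", "sah") if c in cohort.columns]
    numeric = cohort.select_dtypes("number").columns
    for col in numeric:
        if col in (outcome, *score_cols, *flag_cols):
            continue
        result["covariates"][col] = {
            grp: {
                "mean": float(cohort.loc[m, col].mean()),
                "sd": float(cohort.loc[m, col].std(ddof=1)),
            }
            for grp, m in (("dead", dead), ("alive", ~dead))
        }
    for col in flag_cols:
        result["rates"][col] = {
            "dead": float(cohort.loc[dead, col].mean()),
            "alive": float(cohort.loc[~dead, col].mean()),
        }
    if "location" in cohort.columns:
        infra = cohort["location"].isin(["infra", "infratentorial"])
        result["rates"]["infratentorial"] = {
            "dead": float(infra[dead].mean()),
            "alive": float(infra[~dead].mean()),
        }
    for col in score_cols:
        cells: dict[str, dict[str, float]] = {"dead": {}, "alive": {}}
        for s in sorted(cohort[col].unique()):
            sel = cohort[col] == s
            cells["dead"][str(int(s))] = float((sel & dead).sum() / len(cohort))
            cells["alive"][str(int(s))] = float((sel & ~dead).sum() / len(cohort))
        result["joint_freqs"][col] = cells
    return result
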