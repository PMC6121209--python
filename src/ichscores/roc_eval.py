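"""Diagnostic evaluation of an ordinal score against a binary outcome.

The central object is a :class:`ScoreOutcomeTable`: per-score counts of
patients who died and survived within 30 days.  From it this module derives
stratified mortality, the empirical ROC curve, the AUC, and cutoff metrics
(sensitivity, specificity, predictive values, likelihood ratios, Youden J)
with a Youden-optimal cutoff search.

Positivity convention: a test is positive — death predicted — when the
score is **greater than or equal to** the cutoff.

All proportions are computed with exact rational arithmetic
(:class:`fractions.Fraction`); rounding happens only at presentation, half
away from zero.  The AUC uses the Mann-Whitney pairwise estimator with
half-credit for ties, and is asserted, exactly, against the trapezoidal
area under the empirical ROC polygon on every call — the two are the same
number by construction, and the identity is cheap insurance against count
bookkeeping errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Literal, Optional, Sequence, Union

__all__ = [
    "DegenerateTableError",
    "ScoreOutcomeTable",
    "DiagnosticMetrics",
    "RocPoint",
    "metrics_at_cutoff",
    "roc_points",
    "auc",
    "trapezoid_auc",
    "youden_optimal_cutoff",
    "stratum_mortality",
    "group_mean_score",
    "evaluate_scores",
    "round_half_up",
]

ROUNDING_RULE = "half away from zero"


class DegenerateTableError(ValueError):
    """Raised when an operation needs at least one patient in each outcome
    group and the table has none."""


def round_half_up(x: Union[float, Fraction], ndigits: int = 0) -> float:
    """Round half away from zero (the convention clinical tables use,
    unlike banker's rounding)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoreOutcomeTable:
    """Per-score-value counts of deceased and surviving patients."""

    score_values: tuple[int, ...]
    dead_counts: tuple[int, ...]
    alive_counts: tuple[int, ...]

    def __post_init__(self):
        if not (
            len(self.score_values) == len(self.dead_counts) == len(self.alive_counts)
        ):
            raise ValueError("score_values, dead_counts, alive_counts must align")
        if len(self.score_values) == 0:
            raise ValueError("table must have at least one score value")
        if any(b <= a for a, b in zip(self.score_values, self.score_values[1:])):
            raise ValueError("score_values must be strictly increasing")
        if any(c < 0 for c in self.dead_counts) or any(
            c < 0 for c in self.alive_counts
        ):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_outcomes(
        cls, scores: Iterable[int], dead: Iterable[bool]
    ) -> "ScoreOutcomeTable":
        """Tabulate individual (score, died) observations."""
        tally: dict[int, list[int]] = {}
        for s, d in zip(scores, dead):
            cell = tally.setdefault(int(s), [0, 0])
            cell[0 if d else 1] += 1
        values = tuple(sorted(tally))
        return cls(
            score_values=values,
            dead_counts=tuple(tally[v][0] for v in values),
            alive_counts=tuple(tally[v][1] for v in values),
        )

    @property
    def n_dead(self) -> int:
        return sum(self.dead_counts)

    @property
    def n_alive(self) -> int:
        return sum(self.alive_counts)

    @property
    def n_total(self) -> int:
        return self.n_dead + self.n_alive

    def require_both_outcomes(self) -> None:
        if self.n_dead == 0 or self.n_alive == 0:
            raise DegenerateTableError(
                f"need >= 1 patient in each outcome group, got "
                f"{self.n_dead} dead / {self.n_alive} alive"
            )

    def materialize(self) -> list[tuple[int, bool]]:
        """Expand counts back into individual (score, died) patients."""
        out: list[tuple[int, bool]] = []
        for s, nd, na in zip(self.score_values, self.dead_counts, self.alive_counts):
            out.extend([(s, True)] * nd)
            out.extend([(s, False)] * na)
        return out

    def swapped(self) -> "ScoreOutcomeTable":
        """Table with the outcome labels exchanged."""
        return ScoreOutcomeTable(
            self.score_values, self.alive_counts, self.dead_counts
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Test characteristics at one cutoff (positive ⇔ score >= cutoff).

    Proportions are exact fractions; likelihood ratios may be ``math.inf``
    when the corresponding denominator proportion is zero, and predictive
    values are ``None`` when no patient falls in the predicted class.
    """

    cutoff: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Fraction
    specificity: Fraction
    ppv: Optional[Fraction]
    npv: Optional[Fraction]
    lr_pos: Union[Fraction, float]
    lr_neg: Union[Fraction, float]
    youden_j: Fraction

    def as_dict(self, percent_digits: int = 0, ratio_digits: int = 2) -> dict:
        """Presentation form: exact fractions plus rounded display values."""

        def frac(x):
            return None if x is None else f"{x.numerator}/{x.denominator}"

        def ratio(x):
            if x is None:
                return None
            if isinstance(x, float) and math.isinf(x):
                return "inf"
            return round_half_up(x, ratio_digits)

        return {
            "cutoff": self.cutoff,
            "counts": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "exact": {
                "sensitivity": frac(self.sensitivity),
                "specificity": frac(self.specificity),
                "ppv": frac(self.ppv),
                "npv": frac(self.npv),
            },
            "sensitivity_pct": round_half_up(self.sensitivity * 100, percent_digits),
            "specificity_pct": round_half_up(self.specificity * 100, percent_digits),
            "ppv": ratio(self.ppv),
            "npv": ratio(self.npv),
            "lr_pos": ratio(self.lr_pos),
            "lr_neg": ratio(self.lr_neg),
            "youden_j": round_half_up(self.youden_j, ratio_digits),
            "rounding": ROUNDING_RULE,
        }


@dataclass(frozen=True)
class RocPoint:
    fpr: Fraction
    tpr: Fraction
    cutoff: Optional[int]  # None on the forced (1,1) endpoint


def metrics_at_cutoff(table: ScoreOutcomeTable, cutoff: int) -> DiagnosticMetrics:
    """Exact test characteristics when death is predicted at score >= cutoff."""
    table.require_both_outcomes()
    tp = sum(
        d for s, d in zip(table.score_values, table.dead_counts) if s >= cutoff
    )
    fp = sum(
        a for s, a in zip(table.score_values, table.alive_counts) if s >= cutoff
    )
    fn = table.n_dead - tp
    tn = table.n_alive - fp
    sens = Fraction(tp, table.n_dead)
    spec = Fraction(tn, table.n_alive)
    ppv = Fraction(tp, tp + fp) if tp + fp > 0 else None
    npv = Fraction(tn, tn + fn) if tn + fn > 0 else None
    lr_pos = sens / (1 - spec) if spec < 1 else math.inf
    lr_neg = (1 - sens) / spec if spec > 0 else math.inf
    return DiagnosticMetrics(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        youden_j=sens + spec - 1,
    )


def roc_points(table: ScoreOutcomeTable) -> list[RocPoint]:
    """Empirical ROC polygon vertices, from (0,0) to (1,1).

    One point per candidate cutoff, sweeping the cutoff downward from just
    above the maximum score (everyone negative) to the minimum score
    (everyone positive); both endpoints are always present.
    """
    table.require_both_outcomes()
    points: list[RocPoint] = []
    cutoffs = [table.score_values[-1] + 1] + list(reversed(table.score_values))
    for c in cutoffs:
        m = metrics_at_cutoff(table, c)
        points.append(RocPoint(fpr=1 - m.specificity, tpr=m.sensitivity, cutoff=c))
    if points[-1].fpr != 1 or points[-1].tpr != 1:  # unreachable; defensive
        points.append(RocPoint(fpr=Fraction(1), tpr=Fraction(1), cutoff=None))
    return points


def trapezoid_auc(table: ScoreOutcomeTable) -> Fraction:
    """Exact trapezoidal area under the empirical ROC polygon."""
    pts = roc_points(table)
    area = Fraction(0)
    for p, q in zip(pts, pts[1:]):
        area += (q.fpr - p.fpr) * (p.tpr + q.tpr) / 2
    return area


def auc(table: ScoreOutcomeTable) -> Fraction:
    """Exact AUC: P(score_dead > score_alive) + ½·P(tie) over all
    n_dead × n_alive patient pairs (Mann-Whitney estimator).

    Equality with the trapezoidal area is asserted on every call.
    """
    table.require_both_outcomes()
    wins = Fraction(0)
    for sd, nd in zip(table.score_values, table.dead_counts):
        if nd == 0:
            continue
        for sa, na in zip(table.score_values, table.alive_counts):
            if na == 0:
                continue
            if sd > sa:
                wins += nd * na
            elif sd == sa:
                wins += Fraction(nd * na, 2)
    result = wins / (table.n_dead * table.n_alive)
    assert result == trapezoid_auc(table), "pairwise and trapezoid AUC disagree"
    return result


def youden_optimal_cutoff(table: ScoreOutcomeTable) -> tuple[int, Fraction]:
    """Cutoff maximizing Youden J = sensitivity + specificity − 1.

    Candidates are every observed score plus one above the maximum; ties
    are broken toward the lower cutoff, favoring sensitivity.
    """
    table.require_both_outcomes()
    best: Optional[tuple[int, Fraction]] = None
    for c in list(table.score_values) + [table.score_values[-1] + 1]:
        j = metrics_at_cutoff(table, c).youden_j
        if best is None or j > best[1]:
            best = (c, j)
    return best


def stratum_mortality(table: ScoreOutcomeTable) -> dict[int, Optional[Fraction]]:
    """Observed mortality dead/(dead+alive) per score stratum.

    Strata with no patients map to ``None`` (undefined, not zero).
    """
    out: dict[int, Optional[Fraction]] = {}
    for s, nd, na in zip(table.score_values, table.dead_counts, table.alive_counts):
        out[s] = Fraction(nd, nd + na) if nd + na > 0 else None
    return out


def group_mean_score(
    table: ScoreOutcomeTable, group: Literal["dead", "alive"]
) -> Fraction:
    """Count-weighted mean score within one outcome group."""
    counts = table.dead_counts if group == "dead" else table.alive_counts
    n = sum(counts)
    if n == 0:
        raise DegenerateTableError(f"no patients in group {group!r}")
    return Fraction(sum(s * c for s, c in zip(table.score_values, counts)), n)


def evaluate_scores(
    scores,
    outcome: Sequence[bool] | str = "dead_30d",
    cutoffs: Optional[Sequence[int]] = None,
    percent_digits: int = 0,
) -> dict:
    """Full evaluation report for one or more score columns.

    Parameters
    ----------
    scores : pandas.DataFrame or ScoreOutcomeTable
        Either a per-patient table whose integer columns are scores, or a
        ready-made count table (evaluated as a single unnamed score).
    outcome : column name or boolean sequence
        30-day vital status (True = died) when ``scores`` is a DataFrame.
    cutoffs : optional explicit cutoffs to report in addition to the
        Youden-optimal one.

    Returns a JSON-serializable dict, deterministic for fixed input.
    """
    import pandas as pd

    if isinstance(scores, ScoreOutcomeTable):
        tables = {"score": scores}
    else:
        df = scores
        if isinstance(outcome, str):
            if outcome not in df.columns:
                raise KeyError(f"outcome column {outcome!r} not in table")
            dead = df[outcome].astype(bool)
            score_cols = [c for c in df.columns if c != outcome]
        else:
            dead = pd.Series(list(outcome), index=df.index).astype(bool)
            score_cols = list(df.columns)
        tables = {
            c: ScoreOutcomeTable.from_outcomes(df[c].astype(int), dead)
            for c in score_cols
        }

    report: dict = {"rounding": ROUNDING_RULE, "scores": {}}
    for name, table in tables.items():
        table.require_both_outcomes()
        a = auc(table)
        opt_cut, opt_j = youden_optimal_cutoff(table)
        wanted = sorted(set(cutoffs or []) | {opt_cut})
        report["scores"][name] = {
            "n_dead": table.n_dead,
            "n_alive": table.n_alive,
            "table": {
                "score_values": list(table.score_values),
                "dead_counts": list(table.dead_counts),
                "alive_counts": list(table.alive_counts),
            },
            "auc": {
                "exact": f"{a.numerator}/{a.denominator}",
                "value": round_half_up(a, 3),
            },
            "roc_points": [
                {
                    "fpr": float(p.fpr),
                    "tpr": float(p.tpr),
                    "cutoff": p.cutoff,
                }
                for p in roc_points(table)
            ],
            "youden_optimal": {
                "cutoff": opt_cut,
                "j": round_half_up(opt_j, 3),
            },
            "metrics_at_cutoffs": {
                str(c): metrics_at_cutoff(table, c).as_dict(
                    percent_digits=percent_digits
                )
                for c in wanted
            },
            "stratum_mortality_pct": {
                str(s): (None if m is None else round_half_up(m * 100, 1))
                for s, m in stratum_mortality(table).items()
            },
            "group_mean_score": {
                "dead": round_half_up(group_mean_score(table, "dead"), 2),
                "alive": round_half_up(group_mean_score(table, "alive"), 2),
            },
        }
    return report
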