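"""Trial selection and statistical comparison of dimensionality with
observer scores.

The experimental design is: per species and stimulus condition (0, 1 or 2
attractive stimuli), ten replicate trials are scored independently by two
observers on the 1-12 CBM scale; the three trials per cell with the
smallest between-observer disagreement are retained.  Embedding
dimensionality is then compared with CBM via a Pearson correlation t-test,
and across species/conditions via balanced ANOVA with Fisher's protected
LSD post-hoc comparisons.  Censored dimensionalities enter the analyses at
``d_max + 1`` (12 under the standard profile, matching the CBM scale top).
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrialRecord",
    "AnovaResult",
    "PosthocTable",
    "CorrelationResult",
    "select_reliable_trials",
    "correlation_test",
    "one_way_anova",
    "two_way_anova",
    "fisher_plsd",
    "trials_to_frame",
    "trials_from_frame",
]


@dataclass(frozen=True)
class TrialRecord:
    """One experimental trial of one species under one stimulus condition."""

    species: str
    condition: int
    trial_id: str
    dimensionality: int
    cbm_a: int
    cbm_b: int

    def __post_init__(self) -> None:
        if self.condition not in (0, 1, 2):
            raise ValueError("condition must be 0, 1 or 2 (number of stimuli)")
        for v in (self.cbm_a, self.cbm_b):
            if not 1 <= v <= 12:
                raise ValueError("CBM scores must lie in 1..12")
        if self.dimensionality < 1:
            raise ValueError("dimensionality must be >= 1")

    @property
    def cbm_mean(self) -> float:
        return 0.5 * (self.cbm_a + self.cbm_b)

    @property
    def disagreement(self) -> int:
        return abs(self.cbm_a - self.cbm_b)


@dataclass
class AnovaResult:
    """Balanced fixed-effects ANOVA summary.

    ``factors`` maps each factor name to its (F, df_num, p) triple;
    ``group_means`` maps factor name -> level -> mean response.  ``mse`` and
    ``df_den`` are the pooled error mean square and its degrees of freedom,
    shared by all factors and reused by the protected post-hoc tests.
    """

    factors: dict[str, tuple[float, int, float]]
    df_den: int
    mse: float
    group_means: dict[str, dict[object, float]]
    group_counts: dict[str, dict[object, int]] = field(default_factory=dict)
    n_obs: int = 0

    def f_statistic(self, factor: str) -> float:
        return self.factors[factor][0]

    def p_value(self, factor: str) -> float:
        return self.factors[factor][2]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, f, dfn, self.df_den, p)
            for name, (f, dfn, p) in self.factors.items()
        ]
        return pd.DataFrame(rows, columns=["factor", "F", "df_num", "df_den", "p"])


class PosthocRow(NamedTuple):
    level_i: object
    level_j: object
    mean_difference: float
    t: float
    p: float
    significant: bool


@dataclass
class PosthocTable:
    """Pairwise Fisher-LSD comparisons; empty (gated) when the parent
    omnibus effect was not significant."""

    rows: list[PosthocRow]
    gated: bool
    gate_reason: str = ""
    factor: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["level_i", "level_j", "mean_difference", "t", "p", "significant"],
        )


class CorrelationResult(NamedTuple):
    r: float
    r_squared: float
    t: float
    df: int
    p: float


def select_reliable_trials(
    trials: Sequence[TrialRecord], k: int = 3
) -> list[TrialRecord]:
    """Within each species x condition cell, keep the ``k`` trials with the
    smallest between-observer disagreement |cbm_a - cbm_b|; ties broken by
    trial_id order.  Raises if any cell holds fewer than ``k`` trials."""
    cells: dict[tuple[str, int], list[TrialRecord]] = defaultdict(list)
    for t in trials:
        cells[(t.species, t.condition)].append(t)
    selected: list[TrialRecord] = []
    for key in sorted(cells):
        group = cells[key]
        if len(group) < k:
            raise ValueError(
                f"cell species={key[0]!r} condition={key[1]} has only "
                f"{len(group)} trials, need {k}"
            )
        group = sorted(group, key=lambda t: (t.disagreement, t.trial_id))
        selected.extend(group[:k])
    return selected


def correlation_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with its t-test.

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom,
    two-sided p.  Inputs must be non-constant and of equal length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, r_squared=r * r, t=t, df=df, p=p)


def _response(records: Sequence[TrialRecord], response: str) -> np.ndarray:
    return np.array([getattr(r, response) for r in records], dtype=float)


def _levels(records: Sequence[TrialRecord], factor: str) -> np.ndarray:
    return np.array([getattr(r, factor) for r in records], dtype=object)


def one_way_anova(
    records: Sequence[TrialRecord],
    factor: str = "condition",
    response: str = "dimensionality",
) -> AnovaResult:
    """Fixed-effects one-way ANOVA of ``response`` across the levels of
    ``factor``."""
    y = _response(records, response)
    g = _levels(records, factor)
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least two factor levels")
    n = y.size
    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    means: dict[object, float] = {}
    counts: dict[object, int] = {}
    for lev in levels:
        yi = y[g == lev]
        if yi.size == 0:
            raise ValueError(f"empty level {lev!r}")
        means[lev] = float(yi.mean())
        counts[lev] = int(yi.size)
        ss_between += yi.size * (yi.mean() - grand) ** 2
        ss_within += float(((yi - yi.mean()) ** 2).sum())
    df_num = len(levels) - 1
    df_den = n - len(levels)
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")
    mse = ss_within / df_den
    if mse == 0:
        f_stat = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_num) / mse
        p = float(sps.f.sf(f_stat, df_num, df_den))
    return AnovaResult(
        factors={factor: (float(f_stat), df_num, p)},
        df_den=df_den,
        mse=mse,
        group_means={factor: means},
        group_counts={factor: counts},
        n_obs=n,
    )


def two_way_anova(
    records: Sequence[TrialRecord],
    factor_a: str = "species",
    factor_b: str = "condition",
    response: str = "dimensionality",
    interaction: bool = False,
) -> AnovaResult:
    """Balanced fixed-effects two-way ANOVA (main effects; interaction
    optional and pooled into the error when excluded).

    The design must be balanced: every factor-level combination must hold
    the same number of observations.
    """
    y = _response(records, response)
    a = _levels(records, factor_a)
    b = _levels(records, factor_b)
    levels_a = sorted(set(a.tolist()))
    levels_b = sorted(set(b.tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least two levels")
    cell_counts = {
        (la, lb): int(((a == la) & (b == lb)).sum())
        for la in levels_a for lb in levels_b
    }
    if min(cell_counts.values()) == 0:
        empty = [k for k, v in cell_counts.items() if v == 0]
        raise ValueError(f"empty design cells: {empty}")
    if len(set(cell_counts.values())) != 1:
        raise ValueError("two-way ANOVA requires a balanced design")
    n = y.size
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    def main_ss(g: np.ndarray, levels: list) -> tuple[float, dict, dict]:
        ss = 0.0
        means, counts = {}, {}
        for lev in levels:
            yi = y[g == lev]
            means[lev] = float(yi.mean())
            counts[lev] = int(yi.size)
            ss += yi.size * (yi.mean() - grand) ** 2
        return ss, means, counts

    ss_a, means_a, counts_a = main_ss(a, levels_a)
    ss_b, means_b, counts_b = main_ss(b, levels_b)
    ss_cells = 0.0
    for (la, lb), cnt in cell_counts.items():
        yi = y[(a == la) & (b == lb)]
        ss_cells += cnt * (yi.mean() - grand) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    if interaction:
        ss_err = ss_total - ss_cells
        df_den = n - len(levels_a) * len(levels_b)
    else:
        ss_err = ss_total - ss_a - ss_b
        df_den = n - df_a - df_b - 1
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")
    mse = ss_err / df_den

    def f_p(ss: float, df_num: int) -> tuple[float, float]:
        if mse == 0:
            return (math.inf, 0.0) if ss > 1e-12 else (0.0, 1.0)
        f_stat = (ss / df_num) / mse
        return float(f_stat), float(sps.f.sf(f_stat, df_num, df_den))

    fa, pa = f_p(ss_a, df_a)
    fb, pb = f_p(ss_b, df_b)
    factors = {factor_a: (fa, df_a, pa), factor_b: (fb, df_b, pb)}
    if interaction:
        fab, pab = f_p(ss_ab, df_ab)
        factors[f"{factor_a}:{factor_b}"] = (fab, df_ab, pab)
    return AnovaResult(
        factors=factors,
        df_den=df_den,
        mse=mse,
        group_means={factor_a: means_a, factor_b: means_b},
        group_counts={factor_a: counts_a, factor_b: counts_b},
        n_obs=n,
    )


def fisher_plsd(
    anova: AnovaResult,
    records: Sequence[TrialRecord],
    factor: str,
    response: str = "dimensionality",
    alpha: float = 0.05,
) -> PosthocTable:
    """Fisher's protected least-significant-difference pairwise comparisons.

    The "protected" gate: comparisons are emitted only when the parent
    ANOVA main effect for ``factor`` is significant at ``alpha``; otherwise
    an explicitly empty table is returned carrying the gate reason.  Each
    pairwise t uses the ANOVA pooled error mean square and its degrees of
    freedom.
    """
    if factor not in anova.factors:
        raise ValueError(f"factor {factor!r} not in the ANOVA result")
    parent_p = anova.p_value(factor)
    if not parent_p < alpha:
        return PosthocTable(
            rows=[],
            gated=True,
            gate_reason=(
                f"omnibus effect of {factor!r} not significant "
                f"(p = {parent_p:.3g} >= {alpha}); post-hoc tests withheld"
            ),
            factor=factor,
        )
    y = _response(records, response)
    g = _levels(records, factor)
    means = anova.group_means[factor]
    counts = anova.group_counts.get(factor) or {
        lev: int((g == lev).sum()) for lev in means
    }
    rows: list[PosthocRow] = []
    for li, lj in itertools.combinations(sorted(means), 2):
        diff = means[li] - means[lj]
        se = math.sqrt(anova.mse * (1.0 / counts[li] + 1.0 / counts[lj]))
        if se == 0:
            t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = 2.0 * float(sps.t.sf(abs(t), anova.df_den))
        rows.append(PosthocRow(li, lj, float(diff), float(t), p, p < alpha))
    return PosthocTable(rows=rows, gated=False, factor=factor)


# ---------------------------------------------------------------------------
# trial-table persistence

_TRIAL_COLUMNS = ["species", "condition", "trial_id", "dimensionality", "cbm_a", "cbm_b"]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.species, t.condition, t.trial_id, t.dimensionality, t.cbm_a, t.cbm_b)
         for t in trials],
        columns=_TRIAL_COLUMNS,
    )


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            species=str(r.species),
            condition=int(r.condition),
            trial_id=str(r.trial_id),
            dimensionality=int(r.dimensionality),
            cbm_a=int(r.cbm_a),
            cbm_b=int(r.cbm_b),
        )
        for r in df.itertuples(index=False)
    ]


def save_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def load_trials(path: str | Path) -> list[TrialRecord]:
    return trials_from_frame(pd.read_csv(path))
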