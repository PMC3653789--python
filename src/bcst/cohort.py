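"""Cohort simulation and the short-form validation battery.

A cohort of n simulated respondents is drawn from between-subject parameter
distributions, each respondent completes one session (own shuffled deck and
starting rule), and each session is scored three ways: full length, first
64 trials (the short form), and the remaining trials. For each of the four
measures — percent total errors, percent perseverative responses, percent
perseverative errors, and categories completed — two Pearson correlations
are computed across subjects:

* short vs long: first-64 score against the full-length score (a
  part–whole correlation, the short form's validity coefficient), and
* first vs second half: first-64 score against the remaining-trial score
  (a part–part correlation).

Part–whole correlations structurally dominate part–part correlations
because the part is contained in the whole; a well-behaved simulation
reproduces that ordinal pattern. Significance uses the standard t
transform with df = n − 2, two-sided, no multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agents import AgentDistributions, AgentParams, draw_agent_params, parametric_policy
from .scoring import ScoreSummary, score_session
from .session import SessionConfig, SessionRecord, run_session

__all__ = [
    "MEASURES",
    "UndefinedCorrelationError",
    "CohortResult",
    "pearson_r",
    "simulate_cohort",
    "validation_report",
]

#: The four reported measures, in the conventional order.
MEASURES = (
    "total_errors_pct",
    "persev_responses_pct",
    "persev_errors_pct",
    "categories_completed",
)

_MEASURE_LABELS = {
    "total_errors_pct": "Total errors (%)",
    "persev_responses_pct": "Persev. responses (%)",
    "persev_errors_pct": "Persev. errors (%)",
    "categories_completed": "Categories completed",
}

_SCOPES = ("full", "first64", "second_half")
_SCOPE_LABELS = {
    "full": "Full-length",
    "first64": "Short-form (1st half)",
    "second_half": "Short-form (2nd half)",
}


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (a constant input vector)."""


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises
    ------
    ValueError
        If lengths differ or fewer than 3 pairs are given.
    UndefinedCorrelationError
        If either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(
            f"x and y must be 1-D vectors of equal length, got {x.shape} and {y.shape}"
        )
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _r_and_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CohortResult:
    """Scores, tables and the correlation battery for one simulated cohort."""

    n_subjects: int
    master_seed: int
    params: tuple[AgentParams, ...]
    summaries: tuple[tuple[ScoreSummary, ScoreSummary, ScoreSummary], ...]
    #: One row per subject; columns ``<scope>_<measure>`` plus raw counts.
    scores: pd.DataFrame
    #: Indexed by measure; columns r/p for short_vs_long and half_vs_half.
    correlations: pd.DataFrame
    #: Mean (SD) grid shaped like the conventional report table.
    table: pd.DataFrame
    #: Measures whose between-subject variance collapsed (r undefined).
    degenerate_measures: tuple[str, ...] = ()
    groups: Optional[tuple[str, ...]] = None
    #: Per-group correlation batteries (groups with < 3 subjects skipped).
    group_correlations: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return len(self.degenerate_measures) > 0

    @property
    def df(self) -> int:
        """Degrees of freedom of the correlation tests (n − 2)."""
        return self.n_subjects - 2


def _subject_row(
    full: ScoreSummary, first: ScoreSummary, second: ScoreSummary
) -> dict[str, float]:
    row: dict[str, float] = {}
    for scope, s in zip(_SCOPES, (full, first, second)):
        row[f"{scope}_trials_scored"] = s.trials_scored
        row[f"{scope}_total_errors_raw"] = s.total_errors_raw
        row[f"{scope}_persev_responses_raw"] = s.persev_responses_raw
        row[f"{scope}_persev_errors_raw"] = s.persev_errors_raw
        row[f"{scope}_total_errors_pct"] = s.total_errors_pct
        row[f"{scope}_persev_responses_pct"] = s.persev_responses_pct
        row[f"{scope}_persev_errors_pct"] = s.persev_errors_pct
        row[f"{scope}_categories_completed"] = s.categories_completed
    return row


def _correlation_battery(scores: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    rows = []
    degenerate: list[str] = []
    for m in MEASURES:
        x = scores[f"first64_{m}"].to_numpy(float)
        y_full = scores[f"full_{m}"].to_numpy(float)
        y_second = scores[f"second_half_{m}"].to_numpy(float)
        row: dict[str, float] = {}
        for label, y in (("short_vs_long", y_full), ("half_vs_half", y_second)):
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                row[f"r_{label}"] = np.nan
                row[f"p_{label}"] = np.nan
                if m not in degenerate:
                    degenerate.append(m)
            else:
                r, p = _r_and_p(x, y)
                row[f"r_{label}"] = r
                row[f"p_{label}"] = p
        rows.append(row)
    return pd.DataFrame(rows, index=list(MEASURES)), tuple(degenerate)


def _mean_sd_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of raw and percent measures per scoring scope."""
    cells: dict[tuple[str, str], list[str]] = {}
    index = [
        "Total errors",
        "Persev. responses",
        "Persev. errors",
        "Categories completed",
    ]
    stems = ["total_errors", "persev_responses", "persev_errors"]
    for scope in _SCOPES:
        for kind in ("raw", "pct"):
            col = []
            for stem in stems:
                v = scores[f"{scope}_{stem}_{kind}"]
                col.append(f"{v.mean():.1f} ({v.std(ddof=1):.1f})")
            if kind == "raw":
                v = scores[f"{scope}_categories_completed"]
                col.append(f"{v.mean():.1f} ({v.std(ddof=1):.1f})")
            else:
                col.append("—")
            cells[(_SCOPE_LABELS[scope], kind.replace("pct", "%").replace("raw", "Raw"))] = col
    table = pd.DataFrame(cells, index=index)
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return table


def simulate_cohort(
    n: int,
    distributions: AgentDistributions | None = None,
    master_seed: int = 0,
    session_config: SessionConfig | None = None,
    groups: Sequence[str] | None = None,
    params: Sequence[AgentParams] | None = None,
    policy_factory=None,
) -> CohortResult:
    """Simulate a cohort of ``n`` respondents and compute the battery.

    Each respondent gets freshly drawn behavioral parameters, an
    individually shuffled deck, and a random starting rule, all derived
    reproducibly from ``master_seed``. Pass ``params`` to override the
    drawn parameters (e.g. a homogeneous cohort); length must equal ``n``.
    ``groups`` optionally labels each subject; per-group correlation
    batteries are computed for groups with at least 3 members.
    ``policy_factory(params, config) -> policy`` swaps in a different
    respondent model (e.g. an error-free oracle for degeneracy checks);
    the default builds the parametric win-stay/lose-shift agent.
    """
    if n < 10:
        raise ValueError(f"cohort size must be >= 10, got {n}")
    if groups is not None and len(groups) != n:
        raise ValueError("groups must have one label per subject")
    if params is not None and len(params) != n:
        raise ValueError("params must have one entry per subject")

    base_config = session_config if session_config is not None else SessionConfig()
    ss = np.random.SeedSequence(master_seed)
    param_ss, session_ss = ss.spawn(2)
    if params is None:
        params = draw_agent_params(n, distributions, seed=param_ss)
    params = tuple(params)

    rows = []
    summaries = []
    for child, p in zip(session_ss.spawn(n), params):
        s = child.generate_state(2)
        cfg = replace(
            base_config,
            deck_seed=int(s[0] % 2**31),
            start_rule_seed=int(s[1] % 2**31),
        )
        if policy_factory is None:
            respondent = parametric_policy(p, run_criterion=cfg.run_criterion)
        else:
            respondent = policy_factory(p, cfg)
        record = run_session(respondent, cfg)
        triple = score_session(record)
        summaries.append(triple)
        rows.append(_subject_row(*triple))

    scores = pd.DataFrame(rows)
    scores.insert(0, "subject", np.arange(1, n + 1))
    if groups is not None:
        scores.insert(1, "group", list(groups))

    correlations, degenerate = _correlation_battery(scores)
    if degenerate:
        warnings.warn(
            "degenerate cohort: zero between-subject variance for "
            + ", ".join(degenerate)
            + "; affected correlations reported as undefined",
            stacklevel=2,
        )

    group_correlations: dict[str, pd.DataFrame] = {}
    if groups is not None:
        for label, sub in scores.groupby("group", sort=True):
            if len(sub) < 3:
                warnings.warn(
                    f"group {label!r} has {len(sub)} subject(s); skipped "
                    "(correlation needs at least 3)",
                    stacklevel=2,
                )
                continue
            group_correlations[str(label)], _ = _correlation_battery(sub)

    return CohortResult(
        n_subjects=n,
        master_seed=master_seed,
        params=params,
        summaries=tuple(summaries),
        scores=scores,
        correlations=correlations,
        table=_mean_sd_table(scores),
        degenerate_measures=degenerate,
        groups=tuple(groups) if groups is not None else None,
        group_correlations=group_correlations,
    )


def _format_r(r: float, p: float, df: int) -> str:
    if np.isnan(r):
        return "undefined (zero variance)"
    p_str = "< .001" if p < 0.001 else f"= {p:.3f}"
    return f"r({df}) = {r:.2f}, p {p_str}"


def validation_report(result: CohortResult) -> str:
    """Human-readable report: mean (SD) grid plus the correlation battery."""
    df = result.df
    lines = [
        f"Simulated cohort: N = {result.n_subjects} "
        f"(master seed {result.master_seed})",
        "",
        "Mean (SD) by scoring scope",
        result.table.to_string(),
        "",
        f"Short form (first 64 trials) vs full length [df = {df}]",
    ]
    for m in MEASURES:
        row = result.correlations.loc[m]
        lines.append(
            f"  {_MEASURE_LABELS[m]:<24s} "
            f"{_format_r(row['r_short_vs_long'], row['p_short_vs_long'], df)}"
        )
    lines.append("")
    lines.append(f"First 64 trials vs remaining trials [df = {df}]")
    for m in MEASURES:
        row = result.correlations.loc[m]
        lines.append(
            f"  {_MEASURE_LABELS[m]:<24s} "
            f"{_format_r(row['r_half_vs_half'], row['p_half_vs_half'], df)}"
        )
    for label, corr in result.group_correlations.items():
        n_g = int((result.scores["group"] == label).sum())
        lines.append("")
        lines.append(f"Group {label!r} (n = {n_g}, df = {n_g - 2})")
        for m in MEASURES:
            row = corr.loc[m]
            lines.append(
                f"  {_MEASURE_LABELS[m]:<24s} "
                f"short-vs-long {_format_r(row['r_short_vs_long'], row['p_short_vs_long'], n_g - 2)}; "
                f"half-vs-half {_format_r(row['r_half_vs_half'], row['p_half_vs_half'], n_g - 2)}"
            )
    if result.degenerate:
        lines.append("")
        lines.append(
            "WARNING: degenerate measures (zero variance): "
            + ", ".join(result.degenerate_measures)
        )
    return "\n".join(lines)
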