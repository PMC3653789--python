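"""Reading and writing trial logs, score reports and cohort exports.

A session serializes to a plain UTF-8 CSV with the header::

    trial,set,active_rule,previous_rule,color,shape,number,chosen_pile,correct

Rule names are COLOR/SHAPE/NUMBER, ``previous_rule`` is empty during the
first set, and ``correct`` is 0/1. An optional leading comment line
``# config: {...}`` carries the session settings as JSON so a write→read
round trip is lossless; readers tolerate its absence and fall back to the
default settings (or an explicit ``config=`` argument).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .cards import Card, Dimension
from .scoring import ScoreSummary, completing_trials
from .session import SessionConfig, SessionRecord, TrialRecord

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "ParseError",
    "write_session_csv",
    "read_session_csv",
    "write_score_report_csv",
    "format_score_summaries",
]

TRIAL_LOG_COLUMNS = (
    "trial",
    "set",
    "active_rule",
    "previous_rule",
    "color",
    "shape",
    "number",
    "chosen_pile",
    "correct",
)

_SCORE_COLUMNS = (
    "scope",
    "trials_scored",
    "total_errors_raw",
    "persev_responses_raw",
    "persev_errors_raw",
    "categories_completed",
    "total_errors_pct",
    "persev_responses_pct",
    "persev_errors_pct",
)


class ParseError(ValueError):
    """A trial log failed to parse; carries the offending line number."""

    def __init__(self, path, line_number: int, message: str) -> None:
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def _config_to_json(config: SessionConfig) -> str:
    d = asdict(config)
    d["rule_order"] = [r.value for r in config.rule_order]
    return json.dumps(d, sort_keys=True)


def _config_from_json(text: str) -> SessionConfig:
    d = json.loads(text)
    d["rule_order"] = tuple(Dimension(r) for r in d["rule_order"])
    return SessionConfig(**d)


def write_session_csv(session: SessionRecord, path) -> None:
    """Write one session's trial log (one file per session)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config: {_config_to_json(session.config)}\n")
        writer = csv.writer(fh)
        writer.writerow(TRIAL_LOG_COLUMNS)
        for t in session.trials:
            writer.writerow(
                [
                    t.trial_index,
                    t.set_index,
                    t.active_rule.value,
                    t.previous_rule.value if t.previous_rule is not None else "",
                    t.card.color,
                    t.card.shape,
                    t.card.number,
                    t.chosen_pile,
                    int(t.correct),
                ]
            )


def read_session_csv(path, config: SessionConfig | None = None) -> SessionRecord:
    """Read a trial log back into a :class:`SessionRecord`.

    ``categories_completed`` is re-derived from the trial stream, so logs
    produced by other tools (same dialect) score identically.
    """
    path = Path(path)
    trials: list[TrialRecord] = []
    embedded_config: Optional[SessionConfig] = None
    with path.open("r", encoding="utf-8", newline="") as fh:
        line_no = 0
        first = fh.readline()
        line_no += 1
        if first.startswith("# config:"):
            try:
                embedded_config = _config_from_json(first.split(":", 1)[1])
            except (json.JSONDecodeError, TypeError, KeyError, ValueError) as exc:
                raise ParseError(path, line_no, f"bad config metadata: {exc}")
            header_line = fh.readline()
            line_no += 1
        else:
            header_line = first
        header = next(csv.reader([header_line])) if header_line else []
        if tuple(header) != TRIAL_LOG_COLUMNS:
            raise ParseError(
                path, line_no, f"expected header {','.join(TRIAL_LOG_COLUMNS)}"
            )
        for row in csv.reader(fh):
            line_no += 1
            if not row:
                continue
            if len(row) != len(TRIAL_LOG_COLUMNS):
                raise ParseError(
                    path, line_no, f"expected {len(TRIAL_LOG_COLUMNS)} fields, got {len(row)}"
                )
            try:
                trial = TrialRecord(
                    trial_index=int(row[0]),
                    set_index=int(row[1]),
                    active_rule=Dimension(row[2]),
                    previous_rule=Dimension(row[3]) if row[3] else None,
                    card=Card(row[4], row[5], int(row[6])),
                    chosen_pile=int(row[7]),
                    correct=bool(int(row[8])),
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(path, line_no, str(exc))
            trials.append(trial)

    if not trials:
        raise ParseError(path, line_no, "log contains no trials")
    for expected, t in enumerate(trials, start=1):
        if t.trial_index != expected:
            raise ParseError(
                path, 0, f"trial indices must be 1-based and contiguous "
                f"(expected {expected}, found {t.trial_index})"
            )

    cfg = config or embedded_config or SessionConfig()
    record = SessionRecord(trials=tuple(trials), categories_completed=0, config=cfg)
    categories = len(completing_trials(record))
    return SessionRecord(
        trials=tuple(trials), categories_completed=categories, config=cfg
    )


def _summary_row(scope: str, s: ScoreSummary) -> dict:
    return {
        "scope": scope,
        "trials_scored": s.trials_scored,
        "total_errors_raw": s.total_errors_raw,
        "persev_responses_raw": s.persev_responses_raw,
        "persev_errors_raw": s.persev_errors_raw,
        "categories_completed": s.categories_completed,
        "total_errors_pct": round(s.total_errors_pct, 4),
        "persev_responses_pct": round(s.persev_responses_pct, 4),
        "persev_errors_pct": round(s.persev_errors_pct, 4),
    }


def write_score_report_csv(summaries: Mapping[str, ScoreSummary], path) -> None:
    """Write a score report: one CSV row per summary scope."""
    rows = [_summary_row(scope, s) for scope, s in summaries.items()]
    pd.DataFrame(rows, columns=_SCORE_COLUMNS).to_csv(path, index=False)


def format_score_summaries(summaries: Mapping[str, ScoreSummary]) -> str:
    """Human-readable block of score summaries."""
    lines = []
    for scope, s in summaries.items():
        lines.append(f"{scope} ({s.trials_scored} trials)")
        lines.append(
            f"  total errors        {s.total_errors_raw:4d}  ({s.total_errors_pct:5.1f}%)"
        )
        lines.append(
            f"  persev. responses   {s.persev_responses_raw:4d}  ({s.persev_responses_pct:5.1f}%)"
        )
        lines.append(
            f"  persev. errors      {s.persev_errors_raw:4d}  ({s.persev_errors_pct:5.1f}%)"
        )
        lines.append(f"  categories completed {s.categories_completed:3d}")
    return "\n".join(lines)
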