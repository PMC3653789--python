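"""Write a session to the CSV trial-log dialect and score it from disk.

Simulates one respondent, serializes the session (header:
trial,set,active_rule,previous_rule,color,shape,number,chosen_pile,correct),
reads it back losslessly, and prints the score report. The same reader
scores logs produced by any tool emitting this dialect.
"""

import tempfile
from pathlib import Path

from bcst import (
    AgentParams,
    SessionConfig,
    format_score_summaries,
    parametric_policy,
    read_session_csv,
    run_session,
    score_session,
    write_session_csv,
)

record = run_session(
    parametric_policy(AgentParams(0.4, 0.05, 0.9, seed=2)),
    SessionConfig(deck_seed=1, start_rule_seed=4),
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "session.csv"
    write_session_csv(record, path)
    print(f"wrote {len(record.trials)} trials to {path.name}; first rows:")
    print("\n".join(path.read_text().splitlines()[:5]))
    print()

    loaded = read_session_csv(path)
    assert loaded.trials == record.trials  # lossless round trip
    full, first, second = score_session(loaded)
    print(format_score_summaries(
        {"full": full, "first64": first, "second_half": second}
    ))
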