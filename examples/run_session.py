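"""Run single card-sorting sessions and score them three ways.

Plays an error-free (oracle) respondent and a moderately perseverative
simulated respondent against the standard 128-card deck, then prints the
full-length, first-64 (short form) and remaining-trial score summaries.
The oracle realizes the 90-trial theoretical minimum with 9 categories and
zero errors; its perseverative-response count is still positive because
from the second set on the correct pile sometimes coincides with the
previous rule's pile.
"""

from bcst import (
    AgentParams,
    SessionConfig,
    format_score_summaries,
    oracle_policy,
    parametric_policy,
    run_session,
    score_session,
)

config = SessionConfig(deck_seed=7, start_rule_seed=3)

for label, policy in [
    ("oracle (error-free)", oracle_policy()),
    (
        "perseverative agent (persev=0.5, lapse=0.03, learning=0.85)",
        parametric_policy(AgentParams(0.5, 0.03, 0.85, seed=11)),
    ),
]:
    record = run_session(policy, config)
    full, first, second = score_session(record)
    print(f"--- {label}: {len(record.trials)} trials, "
          f"{record.categories_completed} categories")
    print(format_score_summaries(
        {"full": full, "first64": first, "second_half": second}
    ))
    print()
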