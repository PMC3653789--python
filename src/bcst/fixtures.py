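"""Canned reference sessions for golden tests and demonstrations.

Four deterministic sessions cover the behavioral corners of the task: an
error-free (oracle) run realizing the 90-trial minimum, a chance-level
random responder, a maximal perseverator that never abandons its first
reinforced rule, and a hand-verifiable "mixed" session — oracle play with
three deliberate errors injected during the second set, so the expected
counts can be checked by hand: 3 total errors and 98 trials, because the
errors defer the second set's completion from trial 20 to trial 28.
"""

from __future__ import annotations

import json
from pathlib import Path

from .agents import AgentParams, oracle_policy, parametric_policy, random_policy
from .cards import correct_pile
from .io import write_session_csv
from .session import Observation, SessionConfig, SessionRecord, run_session

__all__ = ["ScriptedErrorPolicy", "MIXED_ERROR_TRIALS", "build_fixture_sessions", "make_fixtures"]

#: Trial indices on which the mixed fixture deliberately errs (all in set 2:
#: with error-free play set 1 completes on trial 10).
MIXED_ERROR_TRIALS = (13, 15, 18)


class ScriptedErrorPolicy:
    """Oracle play except for deliberate wrong answers on given trials.

    On an error trial the policy sorts to the pile after the correct one
    (mod 4), guaranteeing an incorrect response. Because errors reset the
    consecutive-correct run, the surrounding session structure stays
    consistent: the engine, not the fixture author, decides where sets end.
    """

    sees_rule = True

    def __init__(self, error_trials=MIXED_ERROR_TRIALS) -> None:
        self.error_trials = frozenset(error_trials)

    def reset(self) -> None:  # stateless
        pass

    def __call__(self, obs: Observation) -> int:
        assert obs.active_rule is not None
        pile = correct_pile(obs.card, obs.active_rule, obs.keys)
        if obs.trial_index in self.error_trials:
            return pile % 4 + 1
        return pile


def build_fixture_sessions(seed: int) -> dict[str, SessionRecord]:
    """Build the four reference sessions, deterministically from ``seed``."""
    oracle_cfg = SessionConfig(deck_seed=seed, start_rule_seed=seed + 1)
    random_cfg = SessionConfig(deck_seed=seed + 2, start_rule_seed=seed + 3)
    persev_cfg = SessionConfig(deck_seed=seed + 4, start_rule_seed=seed + 5)
    mixed_cfg = SessionConfig(deck_seed=seed + 6, start_rule_seed=seed + 7)
    perseverator = AgentParams(
        persev_prob=1.0, lapse_prob=0.0, learning_rate=1.0, seed=seed
    )
    return {
        "oracle": run_session(oracle_policy(), oracle_cfg),
        "random": run_session(random_policy(seed + 100), random_cfg),
        "perseverator": run_session(parametric_policy(perseverator), persev_cfg),
        "mixed": run_session(ScriptedErrorPolicy(), mixed_cfg),
    }


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write the reference sessions as trial-log CSVs plus a manifest.

    Returns a mapping from fixture name to the written path. Regenerating
    with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = build_fixture_sessions(seed)
    paths: dict[str, Path] = {}
    manifest = {"seed": seed, "fixtures": {}}
    for name, session in sessions.items():
        path = out_dir / f"{name}.csv"
        write_session_csv(session, path)
        paths[name] = path
        manifest["fixtures"][name] = {
            "file": path.name,
            "trials": len(session.trials),
            "categories_completed": session.categories_completed,
            "deck_seed": session.config.deck_seed,
            "start_rule_seed": session.config.start_rule_seed,
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
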