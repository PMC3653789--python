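"""Simulated respondents for the card-sorting task.

No published respondent model exists for this task, so the parametric agent
is a minimal win-stay/lose-shift learner that reproduces the qualitative
signatures of human performance: runs of perseverative responses after a
rule switch, one or two non-perseverative search errors while discovering
the new rule, and a reduction of perseveration across sets as the mechanics
of the test are learned.

The agent maintains an *intended* sorting dimension:

* positive feedback reinforces the intended dimension (win-stay) and clears
  the search memory;
* on negative feedback the agent either sticks with the previously
  reinforced dimension with probability ``persev_prob`` (a perseverative
  response) or shifts to a dimension not yet ruled out in the current
  search episode (lose-shift without replacement);
* with probability ``lapse_prob`` a trial is an attentional slip: the
  response is a uniformly random pile and no credit assignment occurs;
* each time the agent registers a completed set (a criterion-length run of
  correct feedback) ``persev_prob`` is multiplied by ``learning_rate``.

Ambiguous positive feedback (a pile consistent with more than one
dimension) reinforces the dimension the agent intended, not every
consistent dimension. All randomness derives from ``AgentParams.seed``, so
replaying a session with the same seeds is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cards import DIMENSIONS, Dimension, correct_pile
from .session import Observation

__all__ = [
    "ParameterValidationError",
    "AgentParams",
    "AgentDistributions",
    "OraclePolicy",
    "RandomPolicy",
    "ParametricPolicy",
    "oracle_policy",
    "random_policy",
    "parametric_policy",
    "draw_agent_params",
]


class ParameterValidationError(ValueError):
    """An agent parameter is out of range; carries the offending field name."""

    def __init__(self, field_name: str, value) -> None:
        self.field_name = field_name
        self.value = value
        super().__init__(f"{field_name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one simulated respondent.

    persev_prob
        Probability of continuing to sort by the previously reinforced
        dimension after feedback turns negative.
    lapse_prob
        Probability that any trial is replaced by a uniformly random choice.
    learning_rate
        Multiplicative decay applied to ``persev_prob`` after each
        completed set (1.0 = no learning).
    seed
        Seed for the agent's private random stream.
    """

    persev_prob: float
    lapse_prob: float
    learning_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("persev_prob", "lapse_prob", "learning_rate"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ParameterValidationError(name, v)


class OraclePolicy:
    """Error-free respondent: always sorts to the correct pile.

    Test-harness privilege — this policy alone sees the active rule, which
    the engine grants to policies declaring ``sees_rule = True``. It
    realizes the theoretical-minimum session length (90 trials with the
    default criterion and 9 categories).
    """

    sees_rule = True

    def reset(self) -> None:  # stateless
        pass

    def __call__(self, obs: Observation) -> int:
        assert obs.active_rule is not None
        return correct_pile(obs.card, obs.active_rule, obs.keys)


class RandomPolicy:
    """Chance-level baseline: uniform choice over the four piles.

    The correct pile is unique, so the per-trial success probability is
    exactly 1/4.
    """

    sees_rule = False

    def __init__(self, seed: int) -> None:
        self.seed = seed
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def __call__(self, obs: Observation) -> int:
        return int(self._rng.integers(1, 5))


class ParametricPolicy:
    """Win-stay/lose-shift respondent parameterized by :class:`AgentParams`.

    ``run_criterion`` is the number of consecutive correct responses the
    agent treats as a completed set when applying its learning decay; it
    mirrors the task's own criterion (default 10), which participants know
    from the instructions only implicitly and learn from experience.
    """

    sees_rule = False

    def __init__(self, params: AgentParams, run_criterion: int = 10) -> None:
        self.params = params
        self.run_criterion = run_criterion
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.params.seed)
        self._persev = self.params.persev_prob
        self._reinforced: Dimension | None = None
        self._intended: Dimension = DIMENSIONS[int(self._rng.integers(3))]
        self._ruled_out: set[Dimension] = set()
        self._streak = 0
        self._n_seen = 0
        self._last_was_lapse = False

    # -- feedback processing -------------------------------------------------

    def _process_feedback(self, correct: bool) -> None:
        if correct:
            self._streak += 1
            if self._streak >= self.run_criterion:
                self._persev *= self.params.learning_rate
                self._streak = 0
        else:
            self._streak = 0

        if self._last_was_lapse:
            return  # slip: the outcome is not attributed to the intended rule

        if correct:
            self._reinforced = self._intended
            self._ruled_out = set()
            return

        if self._reinforced is not None and self._rng.random() < self._persev:
            self._intended = self._reinforced  # perseverate
            return

        self._ruled_out.add(self._intended)
        candidates = [d for d in DIMENSIONS if d not in self._ruled_out]
        if not candidates:
            # Only possible after misleading slips: restart the search.
            self._ruled_out = {self._intended}
            candidates = [d for d in DIMENSIONS if d not in self._ruled_out]
        self._intended = candidates[int(self._rng.integers(len(candidates)))]

    # -- responding ----------------------------------------------------------

    def __call__(self, obs: Observation) -> int:
        if len(obs.history) > self._n_seen:
            self._process_feedback(obs.history[-1].correct)
            self._n_seen = len(obs.history)

        if self._rng.random() < self.params.lapse_prob:
            self._last_was_lapse = True
            return int(self._rng.integers(1, 5))
        self._last_was_lapse = False
        return correct_pile(obs.card, self._intended, obs.keys)


def oracle_policy() -> OraclePolicy:
    """Policy that always chooses the correct pile under the active rule."""
    return OraclePolicy()


def random_policy(seed: int) -> RandomPolicy:
    """Policy choosing uniformly among piles 1..4, deterministic given seed."""
    return RandomPolicy(seed)


def parametric_policy(params: AgentParams, run_criterion: int = 10) -> ParametricPolicy:
    """Win-stay/lose-shift policy with the given behavioral parameters."""
    return ParametricPolicy(params, run_criterion=run_criterion)


# ---------------------------------------------------------------------------
# Between-subject parameter distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Dist:
    """A small univariate sampler: beta, uniform, or a fixed constant."""

    kind: str
    a: float = 0.0
    b: float = 0.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "beta":
            return float(rng.beta(self.a, self.b))
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        if self.kind == "fixed":
            return float(self.a)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @classmethod
    def from_spec(cls, spec) -> "_Dist":
        if isinstance(spec, (int, float)):
            return cls("fixed", float(spec))
        kind = spec.get("dist")
        if kind == "beta":
            return cls("beta", float(spec["a"]), float(spec["b"]))
        if kind == "uniform":
            return cls("uniform", float(spec["low"]), float(spec["high"]))
        if kind == "fixed":
            return cls("fixed", float(spec["value"]))
        raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass(frozen=True)
class AgentDistributions:
    """Between-subject distributions of the agent parameters.

    Defaults create heterogeneous cohorts with realistic variance:
    persev_prob ~ Beta(2, 3), lapse_prob ~ Beta(1, 20),
    learning_rate ~ Uniform(0.7, 1.0).
    """

    persev_prob: _Dist = field(default_factory=lambda: _Dist("beta", 2.0, 3.0))
    lapse_prob: _Dist = field(default_factory=lambda: _Dist("beta", 1.0, 20.0))
    learning_rate: _Dist = field(default_factory=lambda: _Dist("uniform", 0.7, 1.0))

    @classmethod
    def from_dict(cls, spec: dict) -> "AgentDistributions":
        """Build from a plain mapping, e.g. parsed from a YAML config.

        Each key maps to either a number (a fixed value) or a mapping like
        ``{dist: beta, a: 2, b: 3}``, ``{dist: uniform, low: 0.7, high: 1.0}``
        or ``{dist: fixed, value: 0.3}``.
        """
        defaults = cls()
        kwargs = {}
        for name in ("persev_prob", "lapse_prob", "learning_rate"):
            if name in spec:
                dist = _Dist.from_spec(spec[name])
                # Probabilities live in [0, 1]; reject impossible supports
                # up front, naming the offending field.
                if dist.kind == "fixed" and not 0.0 <= dist.a <= 1.0:
                    raise ParameterValidationError(name, dist.a)
                if dist.kind == "uniform" and not (
                    0.0 <= dist.a <= dist.b <= 1.0
                ):
                    raise ParameterValidationError(name, (dist.a, dist.b))
                kwargs[name] = dist
            else:
                kwargs[name] = getattr(defaults, name)
        unknown = set(spec) - {"persev_prob", "lapse_prob", "learning_rate"}
        if unknown:
            raise ValueError(f"unknown agent distribution fields: {sorted(unknown)}")
        return cls(**kwargs)


def draw_agent_params(
    n: int,
    distributions: AgentDistributions | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[AgentParams]:
    """Draw ``n`` independent respondents' parameters, reproducibly.

    Draws are clipped into [0, 1] (beta and uniform draws already are) and
    each respondent receives a private seed derived from ``seed``.
    """
    dists = distributions if distributions is not None else AgentDistributions()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            AgentParams(
                persev_prob=min(1.0, max(0.0, dists.persev_prob.draw(rng))),
                lapse_prob=min(1.0, max(0.0, dists.lapse_prob.draw(rng))),
                learning_rate=min(1.0, max(0.0, dists.learning_rate.draw(rng))),
                seed=int(rng.integers(2**31)),
            )
        )
    return out
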