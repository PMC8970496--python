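"""Stages 2-3: represent the user's needs and down-select candidate algorithms.

A :class:`RequirementSet` names the characteristics that matter for the
analysis at hand (full weight), the ones of minor consideration (reduced
weight, default 0.5) and any hard constraints (k-only parameterization,
maximum time-complexity class). Each KB algorithm is scored by the weighted
sum of the requirements it supports; ``unknown`` support contributes nothing
but is surfaced separately, so information gaps are visible rather than
penalized as violations.

Four ready-made requirement profiles mirror the validation scenarios of the
source framework: forensic explosives spectroscopy, laboratory (public)
spectroscopy, gene-expression, and classic machine-learning teaching data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kb import (
    AlgorithmKB,
    BOOLEAN_CHARACTERISTICS,
    Characteristic,
    TimeComplexity,
    as_characteristic,
)

#: Default weight for a minor-consideration characteristic.
MINOR_WEIGHT = 0.5


@dataclass(frozen=True)
class SelectionRule:
    """How the ranked list is cut to a selected subset.

    ``majority``: score strictly greater than half the attainable score;
    ``top_m``: the m best; ``threshold``: score >= theta.
    """

    kind: str = "majority"  # "majority" | "top_m" | "threshold"
    m: int | None = None
    theta: float | None = None

    def __post_init__(self):
        if self.kind not in ("majority", "top_m", "threshold"):
            raise ValueError(f"unknown selection rule {self.kind!r}")
        if self.kind == "top_m" and (self.m is None or self.m <= 0):
            raise ValueError("top_m rule needs m > 0")
        if self.kind == "threshold" and self.theta is None:
            raise ValueError("threshold rule needs theta")


@dataclass
class RequirementSet:
    """User-needs profile: required and minor characteristics plus hard
    constraints.

    ``efficiency`` may never appear as a soft characteristic (use
    ``hard_max_complexity``); ``parameter_simplicity`` is allowed only as a
    *minor* characteristic, where it is satisfied by k-only algorithms (use
    ``hard_k_only`` to make it a hard constraint).
    """

    required: frozenset = frozenset()
    minor: frozenset = frozenset()
    weights: dict = field(default_factory=dict)
    hard_k_only: bool | None = None
    hard_max_complexity: TimeComplexity | str | None = None
    rule: SelectionRule = field(default_factory=SelectionRule)

    def __post_init__(self):
        self.required = frozenset(as_characteristic(c) for c in self.required)
        self.minor = frozenset(as_characteristic(c) for c in self.minor)
        if self.required & self.minor:
            raise ValueError("required and minor characteristics must be disjoint")
        if Characteristic.EFFICIENCY in (self.required | self.minor):
            raise ValueError(
                "efficiency cannot be a soft characteristic; "
                "use hard_max_complexity instead"
            )
        if Characteristic.PARAMETER_SIMPLICITY in self.required:
            raise ValueError(
                "parameter_simplicity cannot carry full weight; list it under "
                "minor, or use the hard_k_only constraint"
            )
        if isinstance(self.hard_max_complexity, str):
            self.hard_max_complexity = TimeComplexity.parse(self.hard_max_complexity)
        weights = {c: 1.0 for c in self.required}
        weights.update({c: MINOR_WEIGHT for c in self.minor})
        weights.update(
            {as_characteristic(c): float(w) for c, w in self.weights.items()}
        )
        if any(w < 0 for w in weights.values()):
            raise ValueError("weights must be non-negative")
        self.weights = weights

    @property
    def soft(self) -> frozenset:
        return self.required | self.minor

    @property
    def max_score(self) -> float:
        return sum(self.weights[c] for c in self.soft)

    @property
    def has_hard_constraints(self) -> bool:
        return self.hard_k_only is not None or self.hard_max_complexity is not None


@dataclass
class MatchReport:
    """One algorithm's assessment against a requirement set."""

    algorithm: str
    satisfied: frozenset
    violated: frozenset
    unknown: frozenset
    score: float
    max_score: float
    passed_hard_constraints: bool

    @property
    def score_fraction(self) -> float:
        return self.score / self.max_score if self.max_score > 0 else 0.0


@dataclass
class SelectionResult:
    """Ranked match reports and the down-selected subset."""

    ranked: list  # MatchReport, descending score, KB order breaking ties
    selected: list  # algorithm names, subset of those passing hard constraints

    def report(self, name: str) -> MatchReport:
        for r in self.ranked:
            if r.algorithm == name:
                return r
        raise KeyError(name)


def _support_level(profile, c: Characteristic) -> str:
    if c is Characteristic.PARAMETER_SIMPLICITY:
        return "yes" if profile.parameters.k_only else "no"
    return profile.support_for(c).level


def match(kb: AlgorithmKB, req: RequirementSet) -> list[MatchReport]:
    """Assess every KB algorithm against the requirement set, in KB order."""
    if not req.soft and not req.has_hard_constraints:
        raise ValueError("requirement set is empty: no characteristics, no constraints")
    if req.has_hard_constraints:
        passing = kb.filter_constraints(
            k_only=req.hard_k_only, max_complexity=req.hard_max_complexity
        )
    else:
        passing = set(kb.names)
    reports = []
    for profile in kb:
        satisfied, violated, unknown = set(), set(), set()
        for c in req.soft:
            level = _support_level(profile, c)
            (satisfied if level == "yes" else violated if level == "no" else unknown).add(c)
        score = sum(req.weights[c] for c in satisfied)
        reports.append(
            MatchReport(
                algorithm=profile.name,
                satisfied=frozenset(satisfied),
                violated=frozenset(violated),
                unknown=frozenset(unknown),
                score=score,
                max_score=req.max_score,
                passed_hard_constraints=profile.name in passing,
            )
        )
    return reports


def down_select(
    reports: list[MatchReport], rule: SelectionRule = SelectionRule()
) -> SelectionResult:
    """Rank reports (descending score, input order breaking ties) and cut.

    Only algorithms passing the hard constraints are selectable. With the
    majority rule and a requirement set that is pure hard constraints
    (max_score 0), every passing algorithm is selected.
    """
    if not reports:
        raise ValueError("no match reports to select from")
    ranked = sorted(reports, key=lambda r: -r.score)  # stable: KB order on ties
    eligible = [r for r in ranked if r.passed_hard_constraints]
    if rule.kind == "majority":
        if reports[0].max_score == 0:
            chosen = eligible
        else:
            chosen = [r for r in eligible if r.score > r.max_score / 2]
    elif rule.kind == "top_m":
        chosen = eligible[: rule.m]
    else:  # threshold
        chosen = [r for r in eligible if r.score >= rule.theta]
    return SelectionResult(ranked=ranked, selected=[r.algorithm for r in chosen])


def select(kb: AlgorithmKB, req: RequirementSet) -> SelectionResult:
    """Convenience: match then down-select with the requirement's own rule."""
    return down_select(match(kb, req), req.rule)


def scenario_presets() -> dict:
    """The four encoded validation scenarios.

    - ``explosives``: forensic spectroscopy of homemade explosives — small,
      high-dimensional data with elongated, variable-density, unbalanced
      clusters including single-point clusters, needing hierarchical output;
      minor consideration to parameter count and determinism (automation).
    - ``public_spectroscopy``: laboratory spectroscopy — small,
      high-dimensional, non-spherical, variable density, noise/outliers,
      hierarchical output valued.
    - ``gene_expression``: very high-dimensional; efficiency at most n^2 as
      a hard constraint.
    - ``classic_ml``: teaching datasets — the single need is ease of use,
      expressed as the hard constraint of requiring only k.
    """
    C = Characteristic
    return {
        "explosives": RequirementSet(
            required=frozenset(
                {
                    C.SMALL_DATASETS,
                    C.HIGH_DIMENSIONS,
                    C.NON_SPHERICAL_SHAPE,
                    C.VARIABLE_CLUSTER_DENSITY,
                    C.SINGLE_POINT_CLUSTER,
                    C.UNEVEN_CLUSTER_SIZE,
                    C.MULTIMODAL_HIERARCHICAL,
                }
            ),
            minor=frozenset({C.PARAMETER_SIMPLICITY, C.DETERMINISTIC}),
        ),
        "public_spectroscopy": RequirementSet(
            required=frozenset(
                {
                    C.SMALL_DATASETS,
                    C.HIGH_DIMENSIONS,
                    C.NON_SPHERICAL_SHAPE,
                    C.VARIABLE_CLUSTER_DENSITY,
                    C.ROBUST_NOISE_OUTLIERS,
                    C.MULTIMODAL_HIERARCHICAL,
                }
            ),
        ),
        "gene_expression": RequirementSet(
            required=frozenset({C.HIGH_DIMENSIONS}),
            hard_max_complexity="n^2",
        ),
        "classic_ml": RequirementSet(hard_k_only=True),
    }


def get_preset(name: str) -> RequirementSet:
    presets = scenario_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
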