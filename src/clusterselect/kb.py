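"""Algorithm knowledge base: a machine-readable comparative matrix.

Fourteen candidate clustering algorithms are profiled against eleven
evaluation characteristics drawn from three sources — the dataset (size,
dimensionality), the cluster structure (shape, density, balance, singletons,
noise robustness, hierarchical output) and the algorithm itself (parameter
count, determinism, time complexity). Eight of the characteristics plus
determinism are yes/no/unknown support levels; parameter simplicity and
efficiency are structured constraints filtered separately.

The shipped default KB (``data/table3.yaml``) is a faithful encoding of the
published comparative matrix, including its blank cells (kept as ``unknown``,
never coerced to ``no``) and its footnoted caveats (order dependence,
hierarchy-inferable outputs, the single-point-vs-noise trade-off), which are
stored as free-text qualifiers on the support level.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


class Characteristic(str, enum.Enum):
    """The eleven evaluation characteristics (closed set)."""

    SMALL_DATASETS = "small_datasets"
    HIGH_DIMENSIONS = "high_dimensions"
    NON_SPHERICAL_SHAPE = "non_spherical_shape"
    VARIABLE_CLUSTER_DENSITY = "variable_cluster_density"
    SINGLE_POINT_CLUSTER = "single_point_cluster"
    UNEVEN_CLUSTER_SIZE = "uneven_cluster_size"
    ROBUST_NOISE_OUTLIERS = "robust_noise_outliers"
    MULTIMODAL_HIERARCHICAL = "multimodal_hierarchical"
    PARAMETER_SIMPLICITY = "parameter_simplicity"
    DETERMINISTIC = "deterministic"
    EFFICIENCY = "efficiency"


#: The eight yes/no characteristics stored in ``AlgorithmProfile.support``.
SUPPORT_CHARACTERISTICS: tuple[Characteristic, ...] = (
    Characteristic.SMALL_DATASETS,
    Characteristic.HIGH_DIMENSIONS,
    Characteristic.NON_SPHERICAL_SHAPE,
    Characteristic.VARIABLE_CLUSTER_DENSITY,
    Characteristic.SINGLE_POINT_CLUSTER,
    Characteristic.UNEVEN_CLUSTER_SIZE,
    Characteristic.ROBUST_NOISE_OUTLIERS,
    Characteristic.MULTIMODAL_HIERARCHICAL,
)

#: Characteristics answerable yes/no/unknown (support columns + determinism).
BOOLEAN_CHARACTERISTICS: tuple[Characteristic, ...] = SUPPORT_CHARACTERISTICS + (
    Characteristic.DETERMINISTIC,
)

#: The five cluster-structure characteristics measurable from labelled data.
CLUSTER_CHARACTERISTICS: tuple[Characteristic, ...] = (
    Characteristic.NON_SPHERICAL_SHAPE,
    Characteristic.VARIABLE_CLUSTER_DENSITY,
    Characteristic.SINGLE_POINT_CLUSTER,
    Characteristic.UNEVEN_CLUSTER_SIZE,
    Characteristic.ROBUST_NOISE_OUTLIERS,
)


def as_characteristic(value) -> Characteristic:
    """Coerce a string id to a :class:`Characteristic`; unknown ids error."""
    if isinstance(value, Characteristic):
        return value
    try:
        return Characteristic(value)
    except ValueError:
        valid = ", ".join(c.value for c in Characteristic)
        raise KeyError(f"unknown characteristic {value!r}; valid ids: {valid}")


@dataclass(frozen=True)
class SupportLevel:
    """A yes/no/unknown cell, optionally qualified by a free-text caveat.

    ``unknown`` records a genuine information gap in the source matrix and is
    distinct from ``no``: it neither satisfies nor violates a requirement.
    """

    level: str  # "yes" | "no" | "unknown"
    caveat: str | None = None

    _LEVELS = ("yes", "no", "unknown")

    def __post_init__(self):
        if self.level not in self._LEVELS:
            raise ValueError(f"support level must be one of {self._LEVELS}")

    @classmethod
    def parse(cls, value) -> "SupportLevel":
        if isinstance(value, SupportLevel):
            return value
        if value is None:
            return cls("unknown")
        if isinstance(value, dict):
            return cls(str(value["level"]), value.get("caveat"))
        return cls(str(value))

    def to_obj(self):
        if self.caveat is None:
            return self.level
        return {"level": self.level, "caveat": self.caveat}


# Complexity ranking. k, d and i are treated as data-independent factors, so
# classes are ordered primarily by the exponent of n; within a degree the
# conventional order of the classes that actually occur is fixed explicitly.
_RANK_TABLE = {
    # (n_exp, has_log, has_factors) -> rank
    (1, False, False): 0,  # n
    (1, True, False): 1,  # n log n
    (1, False, True): 2,  # n·k·d·i and friends
    (1, True, True): 2,
    (2, False, False): 3,  # n^2
    (2, False, True): 4,  # n^2·i, n^2·k^2
    (2, True, False): 5,  # n^2 log n
    (2, True, True): 5,
    (3, False, False): 6,  # n^3
    (3, False, True): 6,
    (3, True, False): 6,
    (3, True, True): 6,
}

_TOKEN_RE = re.compile(r"(log\s*n|[nkdi])(?:\s*\^\s*(\d+)|([²³]))?")
_SUPERSCRIPTS = {"²": 2, "³": 3}


@dataclass(frozen=True)
class TimeComplexity:
    """Symbolic growth order: a product of n, k, d, i and log n powers.

    Instances are totally ordered by growth order in ``n`` (k, d, i treated
    as data-independent): n < n log n < n·k·d·i < n² < n²·i < n² log n < n³.
    """

    n: int = 0
    k: int = 0
    d: int = 0
    i: int = 0
    log_n: int = 0

    @classmethod
    def parse(cls, expression: str) -> "TimeComplexity":
        """Parse strings like ``"n^2 log n"``, ``"n k d i"``, ``"n^3"``.

        A leading ``<`` (sub-linear-factor qualifier) is accepted and ignored
        for ranking purposes.
        """
        expr = expression.strip().lstrip("<").replace("*", " ").replace("·", " ")
        if not expr:
            raise ValueError("empty complexity expression")
        exps = {"n": 0, "k": 0, "d": 0, "i": 0, "log_n": 0}
        for m in _TOKEN_RE.finditer(expr):
            var, power, sup = m.group(1), m.group(2), m.group(3)
            p = int(power) if power else _SUPERSCRIPTS[sup] if sup else 1
            key = "log_n" if var.startswith("log") else var
            exps[key] += p
        leftover = _TOKEN_RE.sub("", expr).strip()
        if leftover:
            raise ValueError(f"cannot parse complexity expression {expression!r}")
        if exps["n"] == 0 and exps["log_n"] == 0:
            raise ValueError(f"complexity {expression!r} has no n dependence")
        return cls(n=exps["n"], k=exps["k"], d=exps["d"], i=exps["i"], log_n=exps["log_n"])

    @property
    def rank(self) -> int:
        has_factors = (self.k + self.d + self.i) > 0
        key = (min(self.n, 3), self.log_n > 0, has_factors)
        return _RANK_TABLE[key]

    def __le__(self, other: "TimeComplexity") -> bool:
        return self.rank <= other.rank

    def __lt__(self, other: "TimeComplexity") -> bool:
        return self.rank < other.rank

    def __str__(self) -> str:
        parts = []
        if self.n:
            parts.append("n" if self.n == 1 else f"n^{self.n}")
        if self.log_n:
            parts.append("log n" if self.log_n == 1 else f"(log n)^{self.log_n}")
        for var in ("k", "d", "i"):
            e = getattr(self, var)
            if e:
                parts.append(var if e == 1 else f"{var}^{e}")
        return " ".join(parts)


@dataclass(frozen=True)
class ParameterSpec:
    """The set of parameters a user must supply to run the algorithm."""

    required_parameters: frozenset[str]

    @property
    def k_only(self) -> bool:
        """True iff the only required parameter is the cluster count k."""
        return self.required_parameters == frozenset({"k"})

    @classmethod
    def parse(cls, value) -> "ParameterSpec":
        if isinstance(value, ParameterSpec):
            return value
        return cls(frozenset(str(p) for p in value))


@dataclass(frozen=True)
class AlgorithmProfile:
    """One row of the comparative matrix."""

    name: str
    family: str
    support: dict  # Characteristic -> SupportLevel, all 8 support columns
    parameters: ParameterSpec
    deterministic: SupportLevel
    complexity: TimeComplexity
    complexity_caveat: str | None = None

    _FAMILIES = ("hierarchical", "partition", "density", "graph/spectral", "model-based")

    def __post_init__(self):
        if self.family not in self._FAMILIES:
            raise ValueError(f"{self.name}: family must be one of {self._FAMILIES}")
        missing = [c for c in SUPPORT_CHARACTERISTICS if c not in self.support]
        if missing:
            raise ValueError(f"{self.name}: missing support entries for {missing}")

    def support_for(self, c: Characteristic) -> SupportLevel:
        """Support level for any yes/no characteristic (incl. determinism)."""
        c = as_characteristic(c)
        if c is Characteristic.DETERMINISTIC:
            return self.deterministic
        if c not in SUPPORT_CHARACTERISTICS:
            raise ValueError(
                f"{c.value} is not a yes/no characteristic; use the "
                "k-only/complexity constraint filters instead"
            )
        return self.support[c]


class AlgorithmKB:
    """Ordered collection of algorithm profiles with unique names.

    Row order is preserved and used downstream for deterministic
    tie-breaking in rankings.
    """

    def __init__(self, profiles: list[AlgorithmProfile]):
        names = [p.name for p in profiles]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate algorithm names in KB: {sorted(dupes)}")
        self.profiles: list[AlgorithmProfile] = list(profiles)
        self._by_name = {p.name: p for p in self.profiles}

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __eq__(self, other) -> bool:
        return isinstance(other, AlgorithmKB) and self.profiles == other.profiles

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def get(self, name: str) -> AlgorithmProfile:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"algorithm {name!r} not in KB; known: {self.names}")

    # ---------------------------------------------------------------- query

    def query_support(self, c) -> set[str]:
        """Names of algorithms whose support for ``c`` is ``yes``.

        ``c`` must be a yes/no characteristic; parameter simplicity and
        efficiency route to :meth:`filter_constraints`.
        """
        c = as_characteristic(c)
        if c not in BOOLEAN_CHARACTERISTICS:
            raise ValueError(
                f"{c.value} is not a yes/no characteristic; use "
                "filter_constraints(k_only=..., max_complexity=...) instead"
            )
        return {p.name for p in self.profiles if p.support_for(c).level == "yes"}

    def query_unknown(self, c) -> set[str]:
        """Names whose support for ``c`` is an information gap (unknown)."""
        c = as_characteristic(c)
        if c not in BOOLEAN_CHARACTERISTICS:
            raise ValueError(f"{c.value} is not a yes/no characteristic")
        return {p.name for p in self.profiles if p.support_for(c).level == "unknown"}

    def filter_constraints(
        self,
        k_only: bool | None = None,
        max_complexity: TimeComplexity | str | None = None,
    ) -> set[str]:
        """Names satisfying every given hard constraint.

        ``k_only=True`` keeps algorithms whose only required parameter is k;
        ``max_complexity`` keeps algorithms at or below the given growth
        order under the total ranking.
        """
        if k_only is None and max_complexity is None:
            raise ValueError("give at least one constraint")
        if isinstance(max_complexity, str):
            max_complexity = TimeComplexity.parse(max_complexity)
        out = set(self.names)
        if k_only is not None:
            out &= {p.name for p in self.profiles if p.parameters.k_only == k_only}
        if max_complexity is not None:
            out &= {p.name for p in self.profiles if p.complexity <= max_complexity}
        return out

    # ------------------------------------------------------------ serialize

    def to_obj(self) -> list[dict]:
        rows = []
        for p in self.profiles:
            row = {
                "name": p.name,
                "family": p.family,
                "support": {c.value: p.support[c].to_obj() for c in SUPPORT_CHARACTERISTICS},
                "parameters": sorted(p.parameters.required_parameters),
                "deterministic": p.deterministic.to_obj(),
                "complexity": str(p.complexity),
            }
            if p.complexity_caveat:
                row["complexity_caveat"] = p.complexity_caveat
            rows.append(row)
        return rows

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_obj(), fh, sort_keys=False)


def _profile_from_obj(row: dict) -> AlgorithmProfile:
    support = {}
    for key, val in (row.get("support") or {}).items():
        support[as_characteristic(key)] = SupportLevel.parse(val)
    for c in SUPPORT_CHARACTERISTICS:
        support.setdefault(c, SupportLevel("unknown"))
    return AlgorithmProfile(
        name=row["name"],
        family=row["family"],
        support=support,
        parameters=ParameterSpec.parse(row.get("parameters", [])),
        deterministic=SupportLevel.parse(row.get("deterministic")),
        complexity=TimeComplexity.parse(row["complexity"]),
        complexity_caveat=row.get("complexity_caveat"),
    )


def load_kb(path=None) -> AlgorithmKB:
    """Load a KB from a YAML/JSON file, or the shipped default matrix.

    Missing support cells become ``unknown``; duplicate names and unknown
    characteristic keys are errors.
    """
    if path is None:
        text = resources.files("clusterselect").joinpath("data/table3.yaml").read_text()
    else:
        text = Path(path).read_text()
    rows = yaml.safe_load(text)
    if not isinstance(rows, list):
        raise ValueError("KB file must be a list of algorithm entries")
    return AlgorithmKB([_profile_from_obj(r) for r in rows])
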