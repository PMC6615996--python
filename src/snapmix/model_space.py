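"""Discrete-state gene models, induction codes, and model-space enumeration.

A gene is modelled as a continuous-time Markov chain over ``S`` promoter
states per allele (default: a nearest-neighbour "ladder"), each state
transcribing mRNA at rate ``beta_i``; transcripts degrade at rate ``delta``.
An induction experiment switches one or more kinetic parameters from an
unstimulated (U) to a stimulated (S) value at a known time.  Which
parameters switch is encoded as a binary string over the ordered parameter
list — for the 3-state ladder:

    (kappa_01, kappa_12, kappa_21, kappa_10, beta_0, beta_1, beta_2, delta)

so e.g. ``"00110000"`` marks the two downward switching rates as induced.
The set of all such codes (optionally with positions pinned to '0') is the
candidate model space for Bayesian model selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneTopology",
    "ParameterSet",
    "InductionModel",
    "ModelClass",
    "parse_code",
    "enumerate_models",
    "free_parameter_count",
    "build_generator",
]

PHASES = ("U", "S")


class CodeFormatError(ValueError):
    """Raised for induction codes of the wrong length or alphabet."""


class ConsistencyError(ValueError):
    """Raised when a free/fixed mask contradicts an induction code."""


def _ladder_transitions(n_states: int) -> tuple[tuple[int, int], ...]:
    up = [(i, i + 1) for i in range(n_states - 1)]
    down = [(i + 1, i) for i in range(n_states - 1)]
    return tuple(up + down)


@dataclass(frozen=True)
class GeneTopology:
    """State space of a single allele plus the allele count of the cell.

    Parameters
    ----------
    n_states
        Number of promoter states ``S`` (>= 2 for switching models; ``S = 1``
        is accepted for constitutive-expression limits).
    n_alleles
        Number of identical, independent gene copies per cell (default 2,
        a diploid cell).
    transitions
        Allowed ordered state pairs ``(i, j)``.  Defaults to the ladder
        ``|i - j| = 1``.
    """

    n_states: int = 3
    n_alleles: int = 2
    transitions: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")
        if self.transitions is None:
            object.__setattr__(
                self, "transitions", _ladder_transitions(self.n_states)
            )
        else:
            trans = tuple((int(i), int(j)) for i, j in self.transitions)
            for i, j in trans:
                if i == j or not (0 <= i < self.n_states) or not (0 <= j < self.n_states):
                    raise ValueError(f"invalid transition ({i}, {j})")
            if len(set(trans)) != len(trans):
                raise ValueError("duplicate transitions")
            object.__setattr__(self, "transitions", trans)

    @property
    def is_ladder(self) -> bool:
        return set(self.transitions) == set(_ladder_transitions(self.n_states))

    def switch_parameter_names(self) -> list[str]:
        """Switching-rate names in canonical code order.

        For the ladder this is all upward rates in ascending order followed
        by all downward rates in descending order (kappa_01, kappa_12, ...,
        then ..., kappa_21, kappa_10); for a general graph, transitions
        sorted by (i, j).
        """
        if self.is_ladder:
            up = [(i, i + 1) for i in range(self.n_states - 1)]
            down = [(i + 1, i) for i in reversed(range(self.n_states - 1))]
            pairs = up + down
        else:
            pairs = sorted(self.transitions)
        return [f"kappa_{i}{j}" if max(i, j) < 10 else f"kappa_{i}_{j}" for i, j in pairs]

    def parameter_names(self) -> list[str]:
        """All kinetic-parameter names in canonical code order."""
        return (
            self.switch_parameter_names()
            + [f"beta_{i}" for i in range(self.n_states)]
            + ["delta"]
        )

    def transition_of(self, name: str) -> tuple[int, int]:
        names = self.switch_parameter_names()
        if self.is_ladder:
            up = [(i, i + 1) for i in range(self.n_states - 1)]
            down = [(i + 1, i) for i in reversed(range(self.n_states - 1))]
            pairs = up + down
        else:
            pairs = sorted(self.transitions)
        return pairs[names.index(name)]

    @property
    def n_parameters(self) -> int:
        return len(self.transitions) + self.n_states + 1


@dataclass
class ParameterSet:
    """Unstimulated (U) and stimulated (S) values for every kinetic parameter.

    ``free_mask[name]`` flags whether a parameter is inferred (True) or held
    fixed at its given value.  For parameters not induced by the model under
    study the U and S values must coincide.
    """

    topology: GeneTopology
    unstimulated: dict[str, float]
    stimulated: dict[str, float] = field(default_factory=dict)
    free_mask: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        names = self.topology.parameter_names()
        missing = [n for n in names if n not in self.unstimulated]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        self.unstimulated = {n: float(self.unstimulated[n]) for n in names}
        stim = dict(self.unstimulated)
        stim.update({k: float(v) for k, v in self.stimulated.items()})
        self.stimulated = {n: stim[n] for n in names}
        mask = {n: True for n in names}
        mask.update({k: bool(v) for k, v in self.free_mask.items()})
        self.free_mask = {n: mask[n] for n in names}
        for phase in PHASES:
            for n, v in self.values(phase).items():
                if v < 0:
                    raise ValueError(f"negative rate {n} ({phase}) = {v}")
        if self.unstimulated["delta"] <= 0 or self.stimulated["delta"] <= 0:
            raise ValueError("delta must be > 0")

    @classmethod
    def from_sequence(
        cls,
        topology: GeneTopology,
        values,
        stimulated_changes: dict[str, float] | None = None,
        free_mask: dict[str, bool] | None = None,
    ) -> "ParameterSet":
        """Build from values listed in canonical code order."""
        names = topology.parameter_names()
        values = list(values)
        if len(values) != len(names):
            raise ValueError(f"expected {len(names)} values, got {len(values)}")
        return cls(
            topology,
            dict(zip(names, values)),
            dict(stimulated_changes or {}),
            dict(free_mask or {}),
        )

    def values(self, phase: str) -> dict[str, float]:
        if phase == "U":
            return self.unstimulated
        if phase == "S":
            return self.stimulated
        raise ValueError(f"phase must be 'U' or 'S', got {phase!r}")

    def value(self, name: str, phase: str) -> float:
        return self.values(phase)[name]

    def replace(self, u=None, s=None) -> "ParameterSet":
        uu = dict(self.unstimulated)
        uu.update(u or {})
        ss = dict(self.stimulated)
        ss.update(s or {})
        return ParameterSet(self.topology, uu, ss, dict(self.free_mask))

    def beta(self, phase: str) -> np.ndarray:
        v = self.values(phase)
        return np.array([v[f"beta_{i}"] for i in range(self.topology.n_states)])

    def delta(self, phase: str) -> float:
        return self.values(phase)["delta"]

    def validate_against(self, model: "InductionModel") -> None:
        """Check U == S for every parameter the model does not induce."""
        induced = set(model.induced_parameters)
        for n in self.topology.parameter_names():
            if n not in induced and self.unstimulated[n] != self.stimulated[n]:
                raise ConsistencyError(
                    f"parameter {n} not induced by {model.code} but U != S"
                )


@dataclass(frozen=True)
class InductionModel:
    """A binary induction code: '1' marks a parameter with distinct U/S values."""

    code: str
    topology: GeneTopology

    def __post_init__(self):
        n = self.topology.n_parameters
        if len(self.code) != n:
            raise CodeFormatError(
                f"code {self.code!r} has length {len(self.code)}, expected {n}"
            )
        if set(self.code) - {"0", "1"}:
            raise CodeFormatError(f"code {self.code!r} must be binary")

    @property
    def induced_parameters(self) -> tuple[str, ...]:
        names = self.topology.parameter_names()
        return tuple(n for n, c in zip(names, self.code) if c == "1")

    def render(self) -> str:
        return self.code

    @property
    def n_induced(self) -> int:
        return self.code.count("1")


def parse_code(code: str, topology: GeneTopology) -> InductionModel:
    """Parse a binary induction code against a topology (round-trip safe)."""
    return InductionModel(str(code), topology)


@dataclass(frozen=True)
class ModelClass:
    """A family of induction models: a topology plus positions pinned to '0'.

    ``constraint_mask`` is either None (no constraints) or a string like
    ``"xxxx0xx0"`` where '0' pins a position and 'x' leaves it free.
    """

    topology: GeneTopology
    constraint_mask: str | None = None

    def __post_init__(self):
        if self.constraint_mask is not None:
            n = self.topology.n_parameters
            if len(self.constraint_mask) != n:
                raise CodeFormatError(
                    f"constraint mask length {len(self.constraint_mask)} != {n}"
                )
            if set(self.constraint_mask) - {"0", "x", "X"}:
                raise CodeFormatError("constraint mask must contain only '0'/'x'")

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        if self.constraint_mask is None:
            return ()
        return tuple(i for i, c in enumerate(self.constraint_mask) if c == "0")

    @property
    def n_free_positions(self) -> int:
        return self.topology.n_parameters - len(self.constrained_positions)


def enumerate_models(cls: ModelClass) -> list[InductionModel]:
    """All induction codes of a class, lexicographically ordered, no duplicates."""
    n = cls.topology.n_parameters
    pinned = set(cls.constrained_positions)
    free_pos = [i for i in range(n) if i not in pinned]
    out = []
    for bits in itertools.product("01", repeat=len(free_pos)):
        chars = ["0"] * n
        for pos, b in zip(free_pos, bits):
            chars[pos] = b
        out.append(InductionModel("".join(chars), cls.topology))
    return out


def free_parameter_count(model: InductionModel, params: ParameterSet) -> int:
    """Number of inferred values: free base parameters + one extra per induced.

    Each induced parameter carries two values (pre- and post-induction); its
    base (U) value must be free, otherwise the mask is inconsistent.
    """
    induced = set(model.induced_parameters)
    for name in induced:
        if not params.free_mask[name]:
            raise ConsistencyError(
                f"induced parameter {name} is flagged fixed in free_mask"
            )
    n_free_base = sum(bool(v) for v in params.free_mask.values())
    return n_free_base + len(induced)


def build_generator(params: ParameterSet, topology: GeneTopology, phase: str) -> np.ndarray:
    """Single-allele CTMC generator Q for one phase; rows sum to zero.

    ``Q[i, j]`` (i != j) is the switching rate i -> j; the diagonal is minus
    the row sum of the off-diagonals.
    """
    S = topology.n_states
    Q = np.zeros((S, S))
    vals = params.values(phase)
    for name in topology.switch_parameter_names():
        i, j = topology.transition_of(name)
        rate = vals[name]
        if rate < 0:
            raise ValueError(f"negative rate {name} = {rate}")
        Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
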