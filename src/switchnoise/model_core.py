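"""Stochastic reaction networks for ultrasensitive transcriptional switches.

Four promoter architectures are supported, all driving a single gene copy:

``cooperative_binding``
    A repressor R binds three DNA sites. The first, second and third bindings
    have dissociation constants K_r, c*K_r and c**2*K_r, so c < 1 makes
    occupied DNA a better substrate (cooperativity). Transcription occurs
    from every promoter state except the fully occupied one.

``sequestration``
    An activator A binds free DNA E_F (dissociation constant K_a) to form
    transcribing DNA E_A; the repressor sequesters free activator into an
    inert complex R_A (dissociation constant K_s).

``sequestration_blocking``
    Adds blocking: R binds the DNA-bound activator (K_b), giving a silenced
    promoter state E_R that still holds the activator.

``sequestration_blocking_displacement``
    Adds displacement: the repressor-activator complex leaves the DNA,
    E_R <-> E_F + R_A, with dissociation constant K_d.

Copy numbers are discrete molecules; all binding follows mass action with a
single association rate constant ``k_on`` and ``k_off = k_on * K`` per
reaction, so every declared dissociation constant is exactly k_off/k_on.
The mRNA decay rate ``beta`` sets the unit of time (beta = 1 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Architecture",
    "Turnover",
    "ParameterSet",
    "NormalizedParameters",
    "Reaction",
    "ReactionNetwork",
    "ConfigurationError",
    "ValidationError",
    "InvariantViolationError",
    "build_network",
    "conserved_totals",
    "thermo_cycle_gap",
    "constitutive_network",
    "telegraph_network",
]


class ConfigurationError(ValueError):
    """A required constant is missing or a config key is unknown."""


class ValidationError(ValueError):
    """A parameter value violates its declared invariant."""


class InvariantViolationError(RuntimeError):
    """A state broke a structural invariant (e.g. negative copy number)."""


class Architecture(str, Enum):
    """Switch architecture, named after its repression mechanisms."""

    COOPERATIVE = "cooperative_binding"
    SEQUESTRATION = "sequestration"
    SEQ_BLOCK = "sequestration_blocking"
    SEQ_BLOCK_DISP = "sequestration_blocking_displacement"

    @property
    def sequestration_family(self) -> bool:
        return self is not Architecture.COOPERATIVE

    @property
    def has_blocking(self) -> bool:
        return self in (Architecture.SEQ_BLOCK, Architecture.SEQ_BLOCK_DISP)

    @property
    def has_displacement(self) -> bool:
        return self is Architecture.SEQ_BLOCK_DISP

    @property
    def required_constants(self) -> tuple[str, ...]:
        if self is Architecture.COOPERATIVE:
            return ("K_r", "c")
        req = ["K_a", "K_s"]
        if self.has_blocking:
            req.append("K_b")
        if self.has_displacement:
            req.append("K_d")
        return tuple(req)

    @classmethod
    def from_name(cls, name: str) -> "Architecture":
        try:
            return cls(name)
        except ValueError:
            valid = ", ".join(a.value for a in cls)
            raise ConfigurationError(
                f"unknown architecture {name!r}; expected one of: {valid}"
            ) from None


@dataclass(frozen=True)
class Turnover:
    """Birth-death dynamics of the repressor.

    ``r_prod`` is a zero-order production rate (molecules/time) and ``r_deg``
    a first-order degradation rate (1/time).  With ``degrade_complexed``
    (the default) degradation also removes repressor held in the R_A complex
    and in the blocked promoter state, releasing the activator; the total
    repressor count is then an exact birth-death process with stationary
    distribution Poisson(r_prod/r_deg) regardless of sequestration depth.
    Degrading free repressor only (``degrade_complexed=False``) lets deep
    sequestration shelter complexed repressor from decay, so the total
    repressor pool grows until the activator is titrated at any load - a
    qualitatively different (and usually unintended) model.
    """

    r_prod: float
    r_deg: float
    degrade_complexed: bool = True

    def validate(self) -> None:
        if self.r_prod < 0 or self.r_deg <= 0:
            raise ValidationError(
                "turnover requires r_prod >= 0 and r_deg > 0, got "
                f"r_prod={self.r_prod}, r_deg={self.r_deg}"
            )

    @property
    def mean_copy_number(self) -> float:
        return self.r_prod / self.r_deg


@dataclass(frozen=True)
class ParameterSet:
    """All kinetic/thermodynamic constants of one switch instance.

    Dissociation constants are in molecules (for a fixed cell volume,
    concentration and copy number are proportional), rates in 1/time with the
    mRNA decay rate ``beta`` defining the time unit.  ``k_on`` is the common
    association rate constant used to split every dissociation constant into
    an on/off rate pair.
    """

    alpha: float = 50.0
    beta: float = 1.0
    K_r: Optional[float] = None
    c: Optional[float] = None
    K_a: Optional[float] = None
    K_s: Optional[float] = None
    K_b: Optional[float] = None
    K_d: Optional[float] = None
    A_T: int = 100
    R_T: int = 100
    k_on: float = 1.0
    turnover: Optional[Turnover] = None

    def validate(self, architecture: Optional[Architecture] = None) -> None:
        for name in ("alpha", "beta", "k_on"):
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        for name in ("K_r", "c", "K_a", "K_s", "K_b", "K_d"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if self.c is not None and self.c > 1:
            raise ValidationError(f"cooperativity factor c must satisfy c <= 1, got {self.c}")
        for name in ("A_T", "R_T"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")
        if self.turnover is not None:
            self.turnover.validate()
        if architecture is not None:
            for key in architecture.required_constants:
                if getattr(self, key) is None:
                    raise ConfigurationError(
                        f"architecture {architecture.value!r} requires constant {key!r}"
                    )
            self._warn_irrelevant(architecture)

    def _warn_irrelevant(self, architecture: Architecture) -> None:
        relevant = set(architecture.required_constants)
        all_arch_constants = {"K_r", "c", "K_a", "K_s", "K_b", "K_d"}
        for key in sorted(all_arch_constants - relevant):
            if getattr(self, key) is not None:
                logger.warning(
                    "parameter %s is irrelevant for architecture %s and is ignored",
                    key,
                    architecture.value,
                )

    def with_load(self, architecture: Architecture, load: float) -> "ParameterSet":
        """Return a copy with R_T set to the nearest integer realising a
        normalized repressor load (R_T/K_r cooperative, R_T/A_T otherwise)."""
        scale = self.K_r if architecture is Architecture.COOPERATIVE else self.A_T
        if scale is None:
            raise ConfigurationError("K_r is required to set a cooperative load")
        return replace(self, R_T=int(round(load * scale)))

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NormalizedParameters:
    """Dimensionless parameters: loads and K's scaled by A_T (or K_r)."""

    Rt_tilde: float
    Ka_tilde: Optional[float] = None
    Ks_tilde: Optional[float] = None
    Kb_tilde: Optional[float] = None
    Kd_tilde: Optional[float] = None

    @classmethod
    def from_params(
        cls, params: ParameterSet, architecture: Architecture
    ) -> "NormalizedParameters":
        if architecture is Architecture.COOPERATIVE:
            if params.K_r is None:
                raise ConfigurationError("K_r is required for the cooperative model")
            return cls(Rt_tilde=params.R_T / params.K_r)
        if params.A_T <= 0:
            raise ValidationError("A_T must be positive to normalize the sequestration family")
        a_t = params.A_T

        def norm(v):
            return None if v is None else v / a_t

        return cls(
            Rt_tilde=params.R_T / a_t,
            Ka_tilde=norm(params.K_a),
            Ks_tilde=norm(params.K_s),
            Kb_tilde=norm(params.K_b),
            Kd_tilde=norm(params.K_d),
        )


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction channel.

    ``reactants``/``products`` are tuples of ``(species_index, count)``;
    every channel here uses count 1.  The propensity of the channel in state
    ``x`` is ``rate * prod(x[i] for reactant species i)``.
    """

    name: str
    reactants: tuple[tuple[int, int], ...]
    products: tuple[tuple[int, int], ...]
    rate: float

    def delta(self, n_species: int) -> np.ndarray:
        d = np.zeros(n_species, dtype=np.int64)
        for i, n in self.reactants:
            d[i] -= n
        for i, n in self.products:
            d[i] += n
        return d


# promoter-state labels
COOP_STATES = ("E_000", "E_001", "E_010", "E_100", "E_011", "E_101", "E_110", "E_111")
SEQ_STATES = ("E_F", "E_A")
SEQ_BLOCK_STATES = ("E_F", "E_A", "E_R")


class ReactionNetwork:
    """An explicit finite reaction network for one architecture.

    Species are integer copy numbers; the promoter is encoded as a set of
    indicator species exactly one of which equals 1.  Conservation of total
    activator and repressor is a consequence of the stoichiometry and is
    exposed as coefficient vectors for verification.
    """

    def __init__(
        self,
        architecture: Optional[Architecture],
        params: Optional[ParameterSet],
        species: Sequence[str],
        reactions: Sequence[Reaction],
        promoter_species: Sequence[str],
        transcribing_species: Sequence[str],
        init_state: Sequence[int],
        a_vector: Optional[np.ndarray] = None,
        r_vector: Optional[np.ndarray] = None,
        mrna_species: str = "M",
    ) -> None:
        self.architecture = architecture
        self.params = params
        self.species = tuple(species)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.reactions = tuple(reactions)
        self.promoter_species = tuple(promoter_species)
        self.transcribing_species = frozenset(transcribing_species)
        self.init_state = np.asarray(init_state, dtype=np.int64)
        self.a_vector = None if a_vector is None else np.asarray(a_vector, dtype=np.int64)
        self.r_vector = None if r_vector is None else np.asarray(r_vector, dtype=np.int64)
        self.mrna_species = mrna_species
        self.mrna_index = self.index[mrna_species] if mrna_species in self.index else None
        if len(self.init_state) != len(self.species):
            raise ValueError("init_state length does not match species list")

    # -- structural views -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometry(self) -> np.ndarray:
        """(n_reactions, n_species) net state-change matrix."""
        return np.array([r.delta(self.n_species) for r in self.reactions], dtype=np.int64)

    def reactant_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Padded reactant index/count arrays plus per-reaction rates,
        suitable for a compiled propensity kernel."""
        kmax = max((len(r.reactants) for r in self.reactions), default=1)
        kmax = max(kmax, 1)
        idx = np.zeros((self.n_reactions, kmax), dtype=np.int64)
        cnt = np.zeros((self.n_reactions, kmax), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for k, (i, n) in enumerate(r.reactants):
                idx[j, k] = i
                cnt[j, k] = n
        rates = np.array([r.rate for r in self.reactions], dtype=np.float64)
        return idx, cnt, rates

    def propensity(self, state: np.ndarray, j: int) -> float:
        r = self.reactions[j]
        a = r.rate
        for i, n in r.reactants:
            if n == 1:
                a *= state[i]
            else:  # falling factorial for higher multiplicities
                a *= math.perm(int(state[i]), n)
        return float(a)

    def propensities(self, state: np.ndarray) -> np.ndarray:
        return np.array(
            [self.propensity(state, j) for j in range(self.n_reactions)], dtype=np.float64
        )

    def promoter_label(self, state: np.ndarray) -> str:
        labels = [s for s in self.promoter_species if state[self.index[s]] == 1]
        if len(labels) != 1:
            raise InvariantViolationError(
                f"expected exactly one promoter indicator set, found {labels}"
            )
        return labels[0]

    def is_transcribing(self, state: np.ndarray) -> bool:
        return self.promoter_label(state) in self.transcribing_species

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        arch = self.architecture.value if self.architecture else "custom"
        return (
            f"<ReactionNetwork {arch}: {self.n_species} species, "
            f"{self.n_reactions} reactions>"
        )


def _coop_occupancy(label: str) -> int:
    return label.count("1")


def _build_cooperative(params: ParameterSet) -> ReactionNetwork:
    species = list(COOP_STATES) + ["R", "M"]
    index = {s: i for i, s in enumerate(species)}
    k_on, K_r, c = params.k_on, params.K_r, params.c
    reactions: list[Reaction] = []
    # single-site binding/unbinding between promoter microstates
    for label in COOP_STATES:
        occ = _coop_occupancy(label)
        pattern = label[2:]  # site-occupancy bits after the "E_" prefix
        for site in range(3):
            if pattern[site] == "0":
                bound = "E_" + pattern[:site] + "1" + pattern[site + 1 :]
                # association to a state with occ bound sites: Kd = c**occ * K_r
                reactions.append(
                    Reaction(
                        name=f"bind_{label}->{bound}",
                        reactants=((index[label], 1), (index["R"], 1)),
                        products=((index[bound], 1),),
                        rate=k_on,
                    )
                )
                reactions.append(
                    Reaction(
                        name=f"unbind_{bound}->{label}",
                        reactants=((index[bound], 1),),
                        products=((index[label], 1), (index["R"], 1)),
                        rate=k_on * (c**occ) * K_r,
                    )
                )
    for label in COOP_STATES:
        if label != "E_111":
            reactions.append(
                Reaction(
                    name=f"transcribe_{label}",
                    reactants=((index[label], 1),),
                    products=((index[label], 1), (index["M"], 1)),
                    rate=params.alpha,
                )
            )
    reactions.append(
        Reaction("mRNA_decay", ((index["M"], 1),), (), params.beta)
    )
    if params.turnover is not None:
        reactions.append(Reaction("R_production", (), ((index["R"], 1),), params.turnover.r_prod))
        reactions.append(
            Reaction("R_degradation", ((index["R"], 1),), (), params.turnover.r_deg)
        )
    init = np.zeros(len(species), dtype=np.int64)
    init[index["E_000"]] = 1
    init[index["R"]] = params.R_T
    r_vec = np.zeros(len(species), dtype=np.int64)
    r_vec[index["R"]] = 1
    for label in COOP_STATES:
        r_vec[index[label]] = _coop_occupancy(label)
    transcribing = [s for s in COOP_STATES if s != "E_111"]
    return ReactionNetwork(
        Architecture.COOPERATIVE,
        params,
        species,
        reactions,
        promoter_species=COOP_STATES,
        transcribing_species=transcribing,
        init_state=init,
        a_vector=None,
        r_vector=None if params.turnover is not None else r_vec,
    )


def _build_sequestration_family(
    architecture: Architecture, params: ParameterSet
) -> ReactionNetwork:
    promoter = SEQ_BLOCK_STATES if architecture.has_blocking else SEQ_STATES
    species = list(promoter) + ["A", "R", "R_A", "M"]
    index = {s: i for i, s in enumerate(species)}
    k_on = params.k_on
    reactions = [
        Reaction(
            "activator_binding",
            ((index["A"], 1), (index["E_F"], 1)),
            ((index["E_A"], 1),),
            k_on,
        ),
        Reaction(
            "activator_unbinding",
            ((index["E_A"], 1),),
            ((index["A"], 1), (index["E_F"], 1)),
            k_on * params.K_a,
        ),
        Reaction(
            "sequestration",
            ((index["A"], 1), (index["R"], 1)),
            ((index["R_A"], 1),),
            k_on,
        ),
        Reaction(
            "complex_dissociation",
            ((index["R_A"], 1),),
            ((index["A"], 1), (index["R"], 1)),
            k_on * params.K_s,
        ),
    ]
    if architecture.has_blocking:
        reactions += [
            Reaction(
                "blocking",
                ((index["R"], 1), (index["E_A"], 1)),
                ((index["E_R"], 1),),
                k_on,
            ),
            Reaction(
                "unblocking",
                ((index["E_R"], 1),),
                ((index["R"], 1), (index["E_A"], 1)),
                k_on * params.K_b,
            ),
        ]
    if architecture.has_displacement:
        reactions += [
            Reaction(
                "displacement",
                ((index["E_R"], 1),),
                ((index["E_F"], 1), (index["R_A"], 1)),
                k_on * params.K_d,
            ),
            Reaction(
                "complex_rebinding",
                ((index["E_F"], 1), (index["R_A"], 1)),
                ((index["E_R"], 1),),
                k_on,
            ),
        ]
    reactions.append(
        Reaction(
            "transcription",
            ((index["E_A"], 1),),
            ((index["E_A"], 1), (index["M"], 1)),
            params.alpha,
        )
    )
    reactions.append(Reaction("mRNA_decay", ((index["M"], 1),), (), params.beta))
    if params.turnover is not None:
        t = params.turnover
        reactions.append(Reaction("R_production", (), ((index["R"], 1),), t.r_prod))
        reactions.append(Reaction("R_degradation", ((index["R"], 1),), (), t.r_deg))
        if t.degrade_complexed:
            reactions.append(
                Reaction("RA_R_degradation", ((index["R_A"], 1),), ((index["A"], 1),), t.r_deg)
            )
            if architecture.has_blocking:
                reactions.append(
                    Reaction(
                        "ER_R_degradation", ((index["E_R"], 1),), ((index["E_A"], 1),), t.r_deg
                    )
                )
    init = np.zeros(len(species), dtype=np.int64)
    init[index["E_F"]] = 1
    init[index["A"]] = params.A_T
    init[index["R"]] = params.R_T
    a_vec = np.zeros(len(species), dtype=np.int64)
    a_vec[index["A"]] = 1
    a_vec[index["R_A"]] = 1
    a_vec[index["E_A"]] = 1
    if architecture.has_blocking:
        a_vec[index["E_R"]] = 1
    r_vec = np.zeros(len(species), dtype=np.int64)
    r_vec[index["R"]] = 1
    r_vec[index["R_A"]] = 1
    if architecture.has_blocking:
        r_vec[index["E_R"]] = 1
    return ReactionNetwork(
        architecture,
        params,
        species,
        reactions,
        promoter_species=promoter,
        transcribing_species=("E_A",),
        init_state=init,
        a_vector=a_vec,
        r_vector=None if params.turnover is not None else r_vec,
    )


def build_network(architecture: Architecture, params: ParameterSet) -> ReactionNetwork:
    """Assemble the explicit reaction network for an architecture.

    Raises :class:`ConfigurationError` when a required dissociation constant
    is missing and :class:`ValidationError` for out-of-range values.
    Constants irrelevant to the architecture are ignored with a warning.
    """
    if isinstance(architecture, str):
        architecture = Architecture.from_name(architecture)
    params.validate(architecture)
    if architecture is Architecture.COOPERATIVE:
        return _build_cooperative(params)
    return _build_sequestration_family(architecture, params)


def conserved_totals(
    network: ReactionNetwork, state: np.ndarray
) -> tuple[Optional[int], Optional[int]]:
    """Total activator and repressor implied by a state.

    Counts molecules bound in complexes and on the promoter.  Returns None
    for a total that is not conserved (no activator in the cooperative
    model; no repressor total under turnover).  Raises
    :class:`InvariantViolationError` on negative copy numbers.
    """
    state = np.asarray(state)
    if (state < 0).any():
        bad = [network.species[i] for i in np.nonzero(state < 0)[0]]
        raise InvariantViolationError(f"negative copy number for species {bad}")
    a_tot = None if network.a_vector is None else int(network.a_vector @ state)
    r_tot = None if network.r_vector is None else int(network.r_vector @ state)
    return a_tot, r_tot


def thermo_cycle_gap(params: ParameterSet) -> float:
    """Detailed-balance diagnostic (K_a*K_b)/(K_s*K_d) of the promoter
    binding cycle E_F -> E_A -> E_R -> E_F in the displacement model.

    Equals 1 exactly when the cycle satisfies detailed balance, in which
    case the stationary promoter occupancies are independent of the kinetic
    splitting of the dissociation constants; any other value means the
    cycle is thermodynamically driven.
    """
    for key in ("K_a", "K_s", "K_b", "K_d"):
        if getattr(params, key) is None:
            raise ConfigurationError(f"thermo_cycle_gap requires constant {key!r}")
    return (params.K_a * params.K_b) / (params.K_s * params.K_d)


# -- small reference networks used as engine oracles ----------------------

def constitutive_network(alpha: float, beta: float) -> ReactionNetwork:
    """Unregulated birth-death gene: stationary mRNA is Poisson(alpha/beta)."""
    species = ["G", "M"]
    reactions = [
        Reaction("transcription", ((0, 1),), ((0, 1), (1, 1)), alpha),
        Reaction("mRNA_decay", ((1, 1),), (), beta),
    ]
    return ReactionNetwork(
        None,
        ParameterSet(alpha=alpha, beta=beta),
        species,
        reactions,
        promoter_species=("G",),
        transcribing_species=("G",),
        init_state=[1, 0],
    )


def telegraph_network(
    k_act: float, k_deact: float, alpha: float, beta: float
) -> ReactionNetwork:
    """Two-state random-telegraph promoter; closed-form mean and Fano factor
    make it a standard exactness oracle for the master-equation engine."""
    species = ["G_off", "G_on", "M"]
    reactions = [
        Reaction("activate", ((0, 1),), ((1, 1),), k_act),
        Reaction("deactivate", ((1, 1),), ((0, 1),), k_deact),
        Reaction("transcription", ((1, 1),), ((1, 1), (2, 1)), alpha),
        Reaction("mRNA_decay", ((2, 1),), (), beta),
    ]
    return ReactionNetwork(
        None,
        ParameterSet(alpha=alpha, beta=beta),
        species,
        reactions,
        promoter_species=("G_off", "G_on"),
        transcribing_species=("G_on",),
        init_state=[1, 0, 0],
    )
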