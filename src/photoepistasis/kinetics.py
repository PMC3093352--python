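"""Reaction network of the invertebrate phototransduction cascade.

The single-photon response is generated by a G-protein coupled cascade: an
activated metarhodopsin (M*) catalyses G-protein activation; G* activates
phospholipase C (PLC*), which produces a diffusible activator D (diacylglycerol
or a downstream messenger); D opens transduction channels, letting Ca2+ into
the microvillus.  Calcium closes two feedback loops, both parametrised as Hill
functions: a fast positive feedback f_p(Ca) that promotes further channel
opening, and a slower negative feedback f_n that — via a Ca-binding
intermediary B* — accelerates channel closing and the shutdown of upstream
activity, terminating the quantum bump.

This module only *describes* the network: species, reactions with mass-action
propensities, and the feedback modulation map.  Simulation lives in
:mod:`photoepistasis.simulate`.

All rates are per millisecond; calcium concentrations are in micromolar;
molecular species are copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterSet",
    "FeedbackSpec",
    "Reaction",
    "ReactionNetwork",
    "hill",
    "build_network",
    "load_parameters",
    "reference_parameters",
    "SPECIES",
    "CONTINUOUS_SPECIES",
]

#: Discrete species, in canonical order.  Calcium is the single continuous
#: variable and is tracked separately from these copy-number species.
SPECIES: tuple[str, ...] = (
    "Mstar",       # activated metarhodopsin
    "G",           # inactive G-protein
    "Gstar",       # activated G-protein
    "G_inactive",  # post-PLC refractory G pool, recycles to G
    "PLC",         # phospholipase C
    "PLCstar",     # activated PLC
    "D",           # activator (diacylglycerol / downstream messenger)
    "C_closed",    # closed transduction channels
    "C_open",      # open transduction channels
    "B",           # inactive negative-feedback mediator
    "Bstar",       # Ca-activated negative-feedback mediator
)

CONTINUOUS_SPECIES: str = "Ca"


class ConfigurationError(KeyError):
    """A parameter or species referenced by the network is not defined."""


def hill(x: float | np.ndarray, K: float, m: float) -> float | np.ndarray:
    """Saturating Hill response ``x^m / (x^m + K^m)``, in [0, 1].

    Used for both calcium feedbacks and for the cooperative dependence of
    channel opening on the activator.  ``m >= 1`` gives a sigmoidal switch
    with half-saturation at ``x = K``.
    """
    if K <= 0:
        raise ValueError(f"Hill constant must be positive, got K={K}")
    if m < 1:
        raise ValueError(f"Hill exponent must be >= 1, got m={m}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill function argument must be non-negative")
    with np.errstate(over="ignore"):
        xm = x**m
        out = xm / (xm + K**m)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ParameterSet:
    """Named positive rate/feedback constants and initial copy numbers.

    ``locus_eligible`` marks the parameters that are treated as genetic loci
    in the epistasis analysis (biallelic perturbation targets); the remaining
    entries — Hill exponents, pool sizes, calcium constants — stay at their
    reference values in every genotype.
    """

    values: Mapping[str, float]
    units: Mapping[str, str] = field(default_factory=dict)
    locus_eligible: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "units", dict(self.units))
        object.__setattr__(self, "locus_eligible", frozenset(self.locus_eligible))
        for name, value in self.values.items():
            if value < 0:
                raise ValueError(f"parameter {name!r} must be non-negative, got {value}")
        for name in ("m_d", "m_p", "m_n"):
            if name in self.values and self.values[name] < 1:
                raise ValueError(f"Hill exponent {name!r} must be >= 1")
        for name in ("n_g", "n_plc", "n_channels", "n_b"):
            if name in self.values:
                v = self.values[name]
                if v < 0 or v != int(v):
                    raise ValueError(f"copy number {name!r} must be a non-negative integer")

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ConfigurationError(f"parameter {name!r} is not defined") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def replace(self, **updates: float) -> "ParameterSet":
        """New ParameterSet with some values overridden."""
        unknown = set(updates) - set(self.values)
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        merged = {**self.values, **updates}
        return ParameterSet(merged, self.units, self.locus_eligible)

    def locus_names(self) -> list[str]:
        """Locus-eligible parameter names, in file order."""
        return [n for n in self.values if n in self.locus_eligible]


@dataclass(frozen=True)
class FeedbackSpec:
    """Hill parametrisation of the two calcium feedbacks.

    f_p = hill(Ca, K_p, m_p) and f_n = hill(B*, K_n, m_n); a reaction tagged
    with a feedback has its propensity multiplied by ``1 + gain * f`` so the
    feedback accelerates the step without abolishing its baseline kinetics.
    ``modulates`` maps each feedback to the reaction names it acts on.
    """

    K_p: float
    m_p: float
    K_n: float
    m_n: float
    gain_p: float
    gain_n: float
    modulates: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "fp": ("channel_opening",),
            "fn": ("channel_closing", "mstar_deactivation", "plcstar_deactivation"),
        }
    )

    def __post_init__(self) -> None:
        if self.K_p <= 0 or self.K_n <= 0:
            raise ValueError("feedback Hill constants must be positive")
        if self.m_p < 1 or self.m_n < 1:
            raise ValueError("feedback Hill exponents must be >= 1")

    def f_p(self, ca: float) -> float:
        return hill(ca, self.K_p, self.m_p)

    def f_n(self, bstar: float) -> float:
        return hill(bstar, self.K_n, self.m_n)


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel of the network.

    ``reactants`` lists (species, stoichiometric order) pairs entering the
    combinatorial propensity factor; ``stoich`` is the state change applied
    when the reaction fires.  ``feedback`` names the Hill multiplier tag
    (``None``, ``"fp"`` or ``"fn"``); ``activator_hill`` optionally multiplies
    the propensity by ``hill(count(species), K, m)``; ``ca_linear`` multiplies
    by the instantaneous calcium concentration (Ca-catalysed step).
    """

    name: str
    rate_key: str
    reactants: tuple[tuple[str, int], ...]
    stoich: Mapping[str, int]
    feedback: str | None = None
    activator_hill: tuple[str, str, str] | None = None  # (species, K key, m key)
    ca_linear: bool = False


@dataclass(frozen=True)
class ReactionNetwork:
    """Full declarative network: species, reactions, feedbacks, parameters."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    feedback: FeedbackSpec
    params: ParameterSet

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        """Resting copy numbers with a single activated metarhodopsin."""
        counts = np.zeros(len(self.species), dtype=np.int64)
        counts[self.species_index("Mstar")] = 1
        counts[self.species_index("G")] = int(self.params["n_g"])
        counts[self.species_index("PLC")] = int(self.params["n_plc"])
        counts[self.species_index("C_closed")] = int(self.params["n_channels"])
        counts[self.species_index("B")] = int(self.params["n_b"])
        return counts

    def propensities(self, counts: Sequence[int] | np.ndarray, ca: float) -> np.ndarray:
        """Instantaneous reaction propensities at a given discrete state.

        Each entry is base rate x mass-action combinatorial factor x the
        reaction's modulation factors (activator Hill term, feedback
        multiplier, linear Ca dependence).
        """
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError("negative species count in state")
        if ca < 0:
            raise ValueError("negative calcium concentration")
        fp_mult = 1.0 + self.feedback.gain_p * self.feedback.f_p(ca)
        bstar = counts[self.species_index("Bstar")]
        fn_mult = 1.0 + self.feedback.gain_n * self.feedback.f_n(float(bstar))
        out = np.empty(len(self.reactions))
        for r, rxn in enumerate(self.reactions):
            a = self.params[rxn.rate_key]
            for sp, order in rxn.reactants:
                n = counts[self.species_index(sp)]
                for j in range(order):
                    a *= max(n - j, 0)
                if order == 2:
                    a /= 2.0
            if rxn.activator_hill is not None:
                sp, k_key, m_key = rxn.activator_hill
                a *= hill(
                    float(counts[self.species_index(sp)]),
                    self.params[k_key],
                    self.params[m_key],
                )
            if rxn.ca_linear:
                a *= ca
            if rxn.feedback == "fp" and rxn.name in self.feedback.modulates.get("fp", ()):
                a *= fp_mult
            elif rxn.feedback == "fn" and rxn.name in self.feedback.modulates.get("fn", ()):
                a *= fn_mult
            out[r] = a
        return out


def build_network(params: ParameterSet, feedback: FeedbackSpec | None = None) -> ReactionNetwork:
    """Assemble the canonical phototransduction reaction list.

    The topology follows the cascade prose: M* decays; M* catalyses G -> G*;
    G* reacts with PLC producing PLC* while the G-protein enters a refractory
    pool that recycles to G; PLC* decays and, while active, produces the
    activator D; D degrades; D opens channels cooperatively (positive
    feedback amplified); channels close (negative feedback accelerated);
    calcium activates the inhibitor mediator B -> B*, which decays back.
    Calcium itself is continuous and handled by the simulator:

        dCa/dt = k_ca_in * C_open * ca_ext  -  gamma_ca * (Ca - ca_eq)
    """
    if feedback is None:
        feedback = FeedbackSpec(
            K_p=params["kp_ca"],
            m_p=params["m_p"],
            K_n=params["kn_b"],
            m_n=params["m_n"],
            gain_p=params["amp_p"],
            gain_n=params["gain_n"],
        )
    reactions = (
        Reaction(
            "mstar_deactivation", "k_m_decay",
            (("Mstar", 1),), {"Mstar": -1}, feedback="fn",
        ),
        Reaction(
            "g_activation", "k_g_act",
            (("Mstar", 1), ("G", 1)), {"G": -1, "Gstar": +1},
        ),
        Reaction(
            "plc_activation", "k_gstar_plc",
            (("Gstar", 1), ("PLC", 1)),
            {"Gstar": -1, "PLC": -1, "PLCstar": +1, "G_inactive": +1},
        ),
        Reaction(
            "g_recovery", "k_g_recover",
            (("G_inactive", 1),), {"G_inactive": -1, "G": +1},
        ),
        Reaction(
            "plcstar_deactivation", "k_plc_decay",
            (("PLCstar", 1),), {"PLCstar": -1, "PLC": +1}, feedback="fn",
        ),
        Reaction(
            "d_production", "k_d_prod",
            (("PLCstar", 1),), {"D": +1},
        ),
        Reaction(
            "d_degradation", "k_d_decay",
            (("D", 1),), {"D": -1},
        ),
        Reaction(
            "channel_opening", "k_open",
            (("C_closed", 1),), {"C_closed": -1, "C_open": +1},
            feedback="fp", activator_hill=("D", "kd_d", "m_d"),
        ),
        Reaction(
            "channel_closing", "k_close",
            (("C_open", 1),), {"C_open": -1, "C_closed": +1}, feedback="fn",
        ),
        Reaction(
            "b_activation", "k_b_act",
            (("B", 1),), {"B": -1, "Bstar": +1}, ca_linear=True,
        ),
        Reaction(
            "b_deactivation", "k_b_decay",
            (("Bstar", 1),), {"Bstar": -1, "B": +1},
        ),
    )
    network = ReactionNetwork(SPECIES, reactions, feedback, params)
    for rxn in reactions:
        _ = params[rxn.rate_key]  # raises ConfigurationError naming the key
        if rxn.activator_hill is not None:
            _ = params[rxn.activator_hill[1]]
            _ = params[rxn.activator_hill[2]]
    for key in ("k_ca_in", "gamma_ca", "ca_ext", "ca_eq", "n_g", "n_plc", "n_channels", "n_b"):
        _ = params[key]
    return network


def load_parameters(path) -> ParameterSet:
    """Read a flat parameter table: name, value, unit, locus-eligible flag.

    Tab-separated, one parameter per line, ``#`` comments allowed.
    """
    values: dict[str, float] = {}
    units: dict[str, str] = {}
    eligible: set[str] = set()
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ConfigurationError(f"malformed parameter line: {line!r}")
        name, value, unit, flag = fields
        if name == "name":
            continue  # header
        values[name] = float(value)
        units[name] = unit
        if flag.strip().lower() in ("1", "true", "yes"):
            eligible.add(name)
    return ParameterSet(values, units, frozenset(eligible))


def reference_parameters() -> ParameterSet:
    """The shipped reference (wild-type) parameter set."""
    ref = resources.files("photoepistasis").joinpath("data/reference_params.tsv")
    with resources.as_file(ref) as path:
        return load_parameters(path)
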