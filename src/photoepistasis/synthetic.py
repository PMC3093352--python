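"""Analytic trait generators with known Walsh spectra.

These closed-form phenotypes stand in for the stochastic simulator when
exercising the allele machinery and the decomposition: their exact spectra
and their scaling with the perturbation scale eps are known, so every
downstream statistic can be checked in milliseconds.  They are evaluated
through the same genotype -> ParameterSet path as the simulator traits,
which keeps the bit-order and sign conventions of the whole pipeline under
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .kinetics import ParameterSet

__all__ = [
    "AnalyticTrait",
    "make_additive_trait",
    "make_interaction_trait",
    "make_loglinear_trait",
    "make_noisy_trait",
    "sum_traits",
    "registry",
]


@dataclass(frozen=True)
class AnalyticTrait:
    """Deterministic phenotype map with (when known) its exact Walsh spectrum.

    ``fn(params, genotype) -> float``; ``expected_spectrum`` maps subset
    bitmasks to coefficients for genotype-defined traits (None when the
    spectrum depends on the allele table, as for parameter-space traits).
    Calling the trait with ``(params, genotype, seed)`` matches the
    landscape-evaluator protocol and returns ``(value, 0.0)``.
    """

    name: str
    fn: Callable[[ParameterSet, np.ndarray], float]
    expected_spectrum: Mapping[int, float] | None = None

    def __call__(self, params: ParameterSet, genotype: np.ndarray, seed: int = 0
                 ) -> tuple[float, float]:
        return float(self.fn(params, genotype)), 0.0


def make_additive_trait(weights: Sequence[float]) -> AnalyticTrait:
    """Purely additive landscape ``F(s) = sum_i w_i s_i``; spectrum f_i = w_i."""
    w = np.asarray(weights, dtype=float)
    spectrum = {1 << i: float(w[i]) for i in range(w.size) if w[i] != 0.0}

    def fn(params: ParameterSet, s: np.ndarray) -> float:
        return float(np.dot(w, s))

    return AnalyticTrait("additive", fn, spectrum)


def make_interaction_trait(subset: Sequence[int], coefficient: float) -> AnalyticTrait:
    """Single pure interaction ``F(s) = c * prod_{i in S} s_i``."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("interaction subset must be non-empty")
    mask = 0
    for i in subset:
        mask |= 1 << i
    idx = np.array(subset)

    def fn(params: ParameterSet, s: np.ndarray) -> float:
        return float(coefficient * np.prod(s[idx]))

    return AnalyticTrait(f"interaction_k{len(subset)}", fn, {mask: float(coefficient)})


def make_loglinear_trait(
    loci: Sequence[str],
    c0: float = 0.0,
    linear: Mapping[str, float] | None = None,
    quadratic: Mapping[tuple[str, str], float] | None = None,
    cubic: Mapping[tuple[str, str, str], float] | None = None,
    reference: ParameterSet | None = None,
) -> AnalyticTrait:
    """Smooth parameter-space trait, polynomial in log-parameters:

        F(p) = c0 + sum c_i log p_i + sum c_ij log p_i log p_j
                  + sum c_ijk log p_i log p_j log p_k.

    With log-Gaussian alleles ``p = p_ref exp(eps xi)`` this is a polynomial
    in eps, so Walsh coefficients scale exactly: purely linear terms give
    additive landscapes at every eps (D_1 ~ eps^2, no epistasis); each
    order-m cross term contributes an m-locus coefficient ~ eps^m, hence
    D_m ~ eps^{2m} — the clean test bed for scaling-exponent fits.  Passing
    ``reference`` centres the logs at the reference values (log p/p_ref),
    making each cross term a *pure* product of the Gaussian draws.
    """
    loci = tuple(loci)
    linear = dict(linear or {})
    quadratic = dict(quadratic or {})
    cubic = dict(cubic or {})
    for name in linear:
        if name not in loci:
            raise ValueError(f"linear coefficient for unknown locus {name!r}")
    for key in (*quadratic, *cubic):
        for name in key:
            if name not in loci:
                raise ValueError(f"coefficient for unknown locus {name!r}")
    offsets = {
        name: (np.log(reference[name]) if reference is not None else 0.0)
        for name in loci
    }

    def fn(params: ParameterSet, s: np.ndarray) -> float:
        logs = {}
        for name in loci:
            with np.errstate(divide="ignore"):
                lg = np.log(params[name])
            if not np.isfinite(lg):
                raise ValueError(f"non-positive parameter {name!r}")
            logs[name] = lg - offsets[name]
        out = c0
        for name, c in linear.items():
            out += c * logs[name]
        for (i, j), c in quadratic.items():
            out += c * logs[i] * logs[j]
        for (i, j, k), c in cubic.items():
            out += c * logs[i] * logs[j] * logs[k]
        return float(out)

    return AnalyticTrait("loglinear", fn, None)


def make_noisy_trait(base: AnalyticTrait, sigma: float, seed: int) -> AnalyticTrait:
    """Add i.i.d. vertex-keyed Gaussian noise of std ``sigma`` to a base trait.

    The noise at a vertex depends only on ``(seed, vertex)``, so landscapes
    stay deterministic and evaluation-order independent.  Emulates the
    finite-sampling noise of simulator traits; each Walsh coefficient picks
    up noise variance ``sigma^2 / 2^L``.
    """
    if sigma < 0:
        raise ValueError("noise std must be non-negative")

    def fn(params: ParameterSet, s: np.ndarray) -> float:
        value, _ = base(params, s)
        if sigma == 0:
            return value
        bits = ((s + 1) // 2).astype(np.int64)
        vertex = int(np.sum(bits << np.arange(s.size)))
        rng = np.random.default_rng([seed, vertex])
        return value + sigma * rng.standard_normal()

    return AnalyticTrait(f"{base.name}+noise", fn, None)


def sum_traits(*traits: AnalyticTrait) -> AnalyticTrait:
    """Pointwise sum; spectra add when all summands declare one."""
    spectra = [t.expected_spectrum for t in traits]
    combined: dict[int, float] | None
    if any(sp is None for sp in spectra):
        combined = None
    else:
        combined = {}
        for sp in spectra:
            for mask, c in sp.items():  # type: ignore[union-attr]
                combined[mask] = combined.get(mask, 0.0) + c

    def fn(params: ParameterSet, s: np.ndarray) -> float:
        return sum(t(params, s)[0] for t in traits)

    return AnalyticTrait("+".join(t.name for t in traits), fn, combined)


def registry(n_loci: int, loci: Sequence[str] | None = None) -> dict[str, AnalyticTrait]:
    """Named analytic traits for CLI use (``--evaluator analytic:<name>``)."""
    reg = {
        "additive": make_additive_trait(np.linspace(1.0, 0.2, n_loci)),
        "pair": make_interaction_trait((0, 1), 1.0),
        "triple": make_interaction_trait((0, 1, 2), 1.0) if n_loci >= 3 else None,
    }
    if loci is not None and len(loci) >= 2:
        reg["loglinear"] = make_loglinear_trait(
            loci,
            linear={loci[0]: 1.0, loci[1]: 0.5},
            quadratic={(loci[0], loci[1]): 0.8},
        )
    return {k: v for k, v in reg.items() if v is not None}
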