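"""Biallelic allele tables and exhaustive genotype hypercube evaluation.

Each locus is one kinetic parameter.  An allele table assigns to locus ``i``
two positive values ``(p_i^-, p_i^+)`` drawn around the reference by
log-Gaussian perturbation of scale ``eps``:

    p_i^{+/-} = p_ref,i * exp(eps * xi_i^{+/-}),   xi ~ N(0, 1) independent.

A genotype is a vector ``s`` in ``{-1,+1}^L`` selecting one allele per locus;
the ``2^L`` genotypes are the vertices of the hypercube, indexed by the
integer whose bit ``i`` is set when ``s_i = +1``.  Evaluating a trait at
every vertex yields a TraitLandscape, the input to the Walsh decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .kinetics import ConfigurationError, ParameterSet
from .simulate import derive_seed

__all__ = [
    "AlleleTable",
    "TraitLandscape",
    "generate_allele_table",
    "rescale_allele_table",
    "genotype_from_int",
    "int_from_genotype",
    "genotype_to_params",
    "evaluate_trait_landscape",
]

MAX_LOCI = 24  # 2^L enumeration guard


@dataclass(frozen=True)
class AlleleTable:
    """Per-locus allele pair plus the generating draws, scale and seed."""

    loci: tuple[str, ...]
    p_minus: np.ndarray
    p_plus: np.ndarray
    xi_minus: np.ndarray
    xi_plus: np.ndarray
    epsilon: float
    seed: int
    mode: str = "log"  # "log": p_ref*exp(eps*xi); "additive": p_ref*(1+eps*xi)

    def __post_init__(self) -> None:
        if len(self.loci) > MAX_LOCI:
            raise ValueError(f"at most {MAX_LOCI} loci supported, got {len(self.loci)}")
        for arr_name in ("p_minus", "p_plus", "xi_minus", "xi_plus"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            if arr.shape != (len(self.loci),):
                raise ValueError(f"{arr_name} must have one entry per locus")
            object.__setattr__(self, arr_name, arr)
        if np.any(self.p_minus <= 0) or np.any(self.p_plus <= 0):
            raise ValueError("allele parameter values must be strictly positive")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.loci,
                "p_minus": self.p_minus,
                "p_plus": self.p_plus,
                "xi_minus": self.xi_minus,
                "xi_plus": self.xi_plus,
            }
        )


@dataclass(frozen=True)
class TraitLandscape:
    """A trait value (and its standard error) for every hypercube vertex."""

    trait_name: str
    values: np.ndarray
    stderr: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        stderr = np.asarray(self.stderr, dtype=float)
        n = values.size
        if n == 0 or n & (n - 1):
            raise ValueError("landscape length must be a power of two")
        if stderr.shape != values.shape:
            raise ValueError("stderr must match values in shape")
        if not np.all(np.isfinite(values)):
            missing = np.flatnonzero(~np.isfinite(values))
            raise ValueError(f"landscape has missing vertices: {missing.tolist()[:10]}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "stderr", stderr)

    @property
    def n_loci(self) -> int:
        return self.values.size.bit_length() - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_int": np.arange(self.values.size),
                "trait_value": self.values,
                "stderr": self.stderr,
            }
        )


def generate_allele_table(
    reference: ParameterSet,
    loci: Sequence[str],
    epsilon: float,
    seed: int,
    mode: str = "log",
    xi: tuple[np.ndarray, np.ndarray] | None = None,
) -> AlleleTable:
    """Draw one biallelic table around the reference at perturbation scale eps.

    Two independent standard-normal draws per locus (one per allele).  Pass
    ``xi=(xi_minus, xi_plus)`` to reuse fixed draws (shared-xi mode, used for
    clean eps-scaling studies); otherwise draws come from a generator seeded
    with ``seed``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    loci = tuple(loci)
    missing = [name for name in loci if name not in reference]
    if missing:
        raise ConfigurationError(f"unknown loci: {missing}")
    if xi is None:
        rng = np.random.default_rng(seed)
        xi_minus = rng.standard_normal(len(loci))
        xi_plus = rng.standard_normal(len(loci))
    else:
        xi_minus = np.asarray(xi[0], dtype=float)
        xi_plus = np.asarray(xi[1], dtype=float)
    p_ref = np.array([reference[name] for name in loci])
    if mode == "log":
        p_minus = p_ref * np.exp(epsilon * xi_minus)
        p_plus = p_ref * np.exp(epsilon * xi_plus)
    elif mode == "additive":
        p_minus = p_ref * (1.0 + epsilon * xi_minus)
        p_plus = p_ref * (1.0 + epsilon * xi_plus)
        if np.any(p_minus <= 0) or np.any(p_plus <= 0):
            raise ValueError("additive-mode perturbation produced non-positive values")
    else:
        raise ValueError(f"unknown allele mode {mode!r}")
    return AlleleTable(loci, p_minus, p_plus, xi_minus, xi_plus, epsilon, seed, mode)


def rescale_allele_table(table: AlleleTable, reference: ParameterSet,
                         epsilon: float) -> AlleleTable:
    """Same xi draws at a different eps (shared-xi mode across an eps grid)."""
    return generate_allele_table(
        reference, table.loci, epsilon, table.seed, table.mode,
        xi=(table.xi_minus, table.xi_plus),
    )


def genotype_from_int(vertex: int, n_loci: int) -> np.ndarray:
    """Vertex integer -> spin vector; bit i set means s_i = +1."""
    if not 0 <= vertex < 2**n_loci:
        raise ValueError(f"vertex {vertex} out of range for L={n_loci}")
    bits = (vertex >> np.arange(n_loci)) & 1
    return (2 * bits - 1).astype(np.int8)


def int_from_genotype(s: Sequence[int] | np.ndarray) -> int:
    """Spin vector -> vertex integer (inverse of :func:`genotype_from_int`)."""
    s = np.asarray(s)
    if not np.all(np.abs(s) == 1):
        raise ValueError("genotype entries must be +-1")
    bits = (s + 1) // 2
    return int(np.sum(bits.astype(np.int64) << np.arange(s.size)))


def genotype_to_params(
    table: AlleleTable, s: Sequence[int] | np.ndarray, reference: ParameterSet
) -> ParameterSet:
    """Substitute the selected allele at each locus into the reference set."""
    s = np.asarray(s)
    if s.size != table.n_loci:
        raise ValueError(f"genotype length {s.size} != {table.n_loci} loci")
    chosen = np.where(s > 0, table.p_plus, table.p_minus)
    return reference.replace(**dict(zip(table.loci, chosen)))


def evaluate_trait_landscape(
    table: AlleleTable,
    reference: ParameterSet,
    evaluator: Callable[[ParameterSet, np.ndarray, int], tuple[float, float]],
    trait_name: str,
    base_seed: int = 0,
) -> TraitLandscape:
    """Evaluate a trait at every one of the ``2^L`` genotypes.

    ``evaluator(params, genotype, seed) -> (value, stderr)`` is either the
    stochastic simulator pipeline or an analytic trait; every vertex gets a
    deterministic seed derived from ``base_seed`` and the vertex integer, so
    landscapes are reproducible and order-independent.
    """
    n = 2**table.n_loci
    values = np.full(n, np.nan)
    stderr = np.zeros(n)
    failures: list[int] = []
    for vertex in range(n):
        s = genotype_from_int(vertex, table.n_loci)
        params = genotype_to_params(table, s, reference)
        seed = derive_seed(base_seed, vertex)
        try:
            value, err = evaluator(params, s, seed)
        except Exception:  # noqa: BLE001 - failed vertices block decomposition below
            failures.append(vertex)
            continue
        values[vertex] = value
        stderr[vertex] = err
    if failures:
        raise RuntimeError(f"evaluator failed at vertices {failures[:10]}")
    return TraitLandscape(
        trait_name,
        values,
        stderr,
        provenance={
            "epsilon": table.epsilon,
            "table_seed": table.seed,
            "base_seed": base_seed,
            "loci": list(table.loci),
            "mode": table.mode,
        },
    )
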