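"""Walsh-Hadamard decomposition of trait landscapes on the genotype hypercube.

A trait landscape assigns a real value ``F(s)`` to every vertex ``s`` of the
``L``-dimensional hypercube ``{-1,+1}^L``.  Any such function expands uniquely
as

    F(s) = F0 + sum_i f_i s_i + sum_{i<j} f_ij s_i s_j + ...

with one coefficient ``f_S`` per locus subset ``S``.  ``F0`` is the grand
mean, the singleton coefficients are the additive allele effects and the
higher orders quantify physiological epistasis.  Coefficients carry the
``2^-L`` averaging factor, so ``f_S`` is literally the uniform-background
average of the trait weighted by the product character of ``S``.

Bit convention (fixed throughout the package): bit ``i`` of a vertex or
subset integer refers to locus ``i``; a set bit means ``s_i = +1`` (vertex)
or ``i in S`` (subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "WalshSpectrum",
    "PowerSpectrum",
    "LocusVariances",
    "walsh_transform",
    "inverse_walsh",
    "brute_force_coefficient",
    "power_spectrum",
    "locus_variances",
    "total_variance",
    "subset_order",
]


def subset_order(masks: np.ndarray | int) -> np.ndarray | int:
    """Interaction order |S| of each subset bitmask (popcount)."""
    return np.bitwise_count(np.asarray(masks, dtype=np.uint64)).astype(np.int64)


@dataclass(frozen=True)
class WalshSpectrum:
    """All ``2^L`` Walsh coefficients of a landscape, indexed by subset bitmask."""

    n_loci: int
    coefficients: np.ndarray  # shape (2**n_loci,), coefficients[mask] = f_S

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (2**self.n_loci,):
            raise ValueError(
                f"expected {2**self.n_loci} coefficients for L={self.n_loci}, "
                f"got shape {coeffs.shape}"
            )
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def grand_mean(self) -> float:
        """F0, the landscape mean over the uniform genotype distribution."""
        return float(self.coefficients[0])

    @property
    def orders(self) -> np.ndarray:
        """|S| for every coefficient, aligned with ``coefficients``."""
        return subset_order(np.arange(2**self.n_loci, dtype=np.uint64))

    def additive_effects(self) -> np.ndarray:
        """The L singleton coefficients f_i, locus order."""
        masks = np.uint64(1) << np.arange(self.n_loci, dtype=np.uint64)
        return self.coefficients[masks.astype(np.int64)]

    def coefficient(self, loci: tuple[int, ...] | list[int]) -> float:
        """f_S for an explicit locus tuple, e.g. ``(0, 3)`` for f_{0,3}."""
        mask = 0
        for i in loci:
            if not 0 <= i < self.n_loci:
                raise IndexError(f"locus {i} out of range for L={self.n_loci}")
            mask |= 1 << i
        return float(self.coefficients[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset_bitmask": np.arange(2**self.n_loci),
                "order_k": self.orders,
                "coefficient": self.coefficients,
            }
        )


@dataclass(frozen=True)
class PowerSpectrum:
    """Epistatic power spectrum: mean squared coefficient per interaction order.

    ``d_k[k]`` is the average of ``f_S^2`` over the ``C(L,k)`` subsets of size
    ``k``; ``total_k[k] = C(L,k) * d_k[k]`` is the total trait variance
    contributed by order-``k`` interactions.
    """

    n_loci: int
    d_k: np.ndarray  # shape (L+1,)
    total_k: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        d_k = np.asarray(self.d_k, dtype=float)
        if d_k.shape != (self.n_loci + 1,):
            raise ValueError("d_k must have one entry per order 0..L")
        object.__setattr__(self, "d_k", d_k)
        n_subsets = np.array([comb(self.n_loci, k) for k in range(self.n_loci + 1)])
        object.__setattr__(self, "total_k", n_subsets * d_k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(self.n_loci + 1), "D_k": self.d_k, "total_k": self.total_k}
        )


@dataclass(frozen=True)
class LocusVariances:
    """Per-locus split of trait variance into additive and epistatic parts.

    ``v_add[i] = f_i^2`` is the background-independent (additive) variance of
    locus ``i``; ``v_epi[i]`` sums ``f_S^2`` over every subset of size >= 2
    containing ``i`` — the part of the locus effect that depends on the
    genetic background.
    """

    n_loci: int
    v_add: np.ndarray
    v_epi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus": np.arange(self.n_loci), "v_add": self.v_add, "v_epi": self.v_epi}
        )


def _landscape_values(landscape) -> tuple[int, np.ndarray]:
    """Accept a TraitLandscape-like object or a bare array of 2^L values."""
    values = getattr(landscape, "values", landscape)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0 or values.size & (values.size - 1):
        raise ValueError("landscape must be a 1-D array of 2^L values")
    if not np.all(np.isfinite(values)):
        raise ValueError("landscape contains missing or non-finite vertices")
    n_loci = values.size.bit_length() - 1
    return n_loci, values


def walsh_transform(landscape) -> WalshSpectrum:
    """Fast Walsh-Hadamard transform of a complete trait landscape.

    Runs the in-place butterfly in ``O(L 2^L)``; the result carries the
    ``2^-L`` averaging normalisation, so the empty-set coefficient is the
    landscape mean.

    Parameters
    ----------
    landscape
        A :class:`~photoepistasis.genotypes.TraitLandscape` or any 1-D array
        of ``2^L`` finite trait values in vertex-integer order.
    """
    n_loci, values = _landscape_values(landscape)
    work = values.copy()
    for bit in range(n_loci):
        shaped = work.reshape(-1, 2 << bit)
        lo = shaped[:, : 1 << bit].copy()
        hi = shaped[:, 1 << bit :].reshape(-1, 1 << bit)
        shaped[:, : 1 << bit] = lo + hi
        shaped[:, 1 << bit :] = (hi - lo).reshape(shaped[:, 1 << bit :].shape)
    return WalshSpectrum(n_loci=n_loci, coefficients=work / values.size)


def inverse_walsh(spectrum: WalshSpectrum) -> np.ndarray:
    """Synthesise the landscape ``F(s) = sum_S f_S prod_{i in S} s_i``.

    Exact inverse of :func:`walsh_transform` up to round-off.
    """
    work = spectrum.coefficients.copy()
    for bit in range(spectrum.n_loci):
        shaped = work.reshape(-1, 2 << bit)
        lo = shaped[:, : 1 << bit].copy()
        hi = shaped[:, 1 << bit :].reshape(-1, 1 << bit)
        shaped[:, : 1 << bit] = lo - hi
        shaped[:, 1 << bit :] = (lo + hi).reshape(shaped[:, 1 << bit :].shape)
    return work


def brute_force_coefficient(landscape, loci: tuple[int, ...] | list[int] | int) -> float:
    """Direct subset-average evaluation of one Walsh coefficient.

    ``f_S = 2^-L sum_s F(s) prod_{i in S} s_i`` computed literally, vertex by
    vertex.  Quadratic overall, kept as the independent oracle for
    :func:`walsh_transform`.

    ``loci`` may be a bitmask or an iterable of locus indices.
    """
    n_loci, values = _landscape_values(landscape)
    if isinstance(loci, (int, np.integer)):
        mask = int(loci)
    else:
        mask = 0
        for i in loci:
            mask |= 1 << i
    if mask >= values.size:
        raise ValueError("subset refers to loci beyond the landscape dimension")
    total = 0.0
    for vertex in range(values.size):
        # product of s_i over i in S: one -1 per unset bit of the vertex in S
        sign = -1.0 if (mask & ~vertex).bit_count() % 2 else 1.0
        total += sign * values[vertex]
    return total / values.size


def power_spectrum(spectrum: WalshSpectrum) -> PowerSpectrum:
    """Average squared coefficient per interaction order (epistatic spectrum)."""
    orders = spectrum.orders
    sq = spectrum.coefficients**2
    sums = np.bincount(orders, weights=sq, minlength=spectrum.n_loci + 1)
    n_subsets = np.array(
        [comb(spectrum.n_loci, k) for k in range(spectrum.n_loci + 1)], dtype=float
    )
    return PowerSpectrum(n_loci=spectrum.n_loci, d_k=sums / n_subsets)


def locus_variances(spectrum: WalshSpectrum) -> LocusVariances:
    """Additive (f_i^2) and background-dependent variance per locus."""
    masks = np.arange(2**spectrum.n_loci, dtype=np.uint64)
    orders = spectrum.orders
    sq = spectrum.coefficients**2
    v_add = spectrum.additive_effects() ** 2
    v_epi = np.empty(spectrum.n_loci)
    epistatic = orders >= 2
    for i in range(spectrum.n_loci):
        contains = (masks >> np.uint64(i)) & np.uint64(1) == 1
        v_epi[i] = sq[contains & epistatic].sum()
    return LocusVariances(n_loci=spectrum.n_loci, v_add=v_add, v_epi=v_epi)


def total_variance(spectrum: WalshSpectrum) -> float:
    """Sum of squared non-constant coefficients.

    By Parseval this equals the population variance of the landscape over the
    uniform genotype distribution.
    """
    return float(np.sum(spectrum.coefficients[1:] ** 2))
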