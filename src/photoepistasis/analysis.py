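"""Experiment orchestration: ensembles over allele sets and eps values.

Reproduces the study design end to end: draw random allele tables at each
perturbation scale eps, evaluate the trait over all ``2^L`` genotypes,
Walsh-decompose every landscape, and summarise the epistatic power spectrum
``D_k``, its scaling with eps, per-locus additive/epistatic splits, the
pairwise additive-vs-epistatic scatter, and the recovery of epistatic
variance from the top additively ranked loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    TraitLandscape,
    evaluate_trait_landscape,
    generate_allele_table,
    rescale_allele_table,
)
from .kinetics import ParameterSet, build_network
from .simulate import compile_network, derive_seed, simulate_ensemble
from .traits import TraitDefinition, compute_trait
from .walsh import (
    WalshSpectrum,
    locus_variances,
    power_spectrum,
    total_variance,
    walsh_transform,
)

__all__ = [
    "EnsembleSummary",
    "SubsetRecovery",
    "ssa_evaluator",
    "default_trial_schedule",
    "run_ensemble",
    "fit_scaling_exponent",
    "split_half_floor",
    "pair_scatter",
    "exceedance_fraction",
    "top_additive_subset",
    "cumulative_variance_curves",
]

#: Default eps grid: five logarithmically spaced perturbation scales from
#: near-linear response to multi-fold allele differences.
DEFAULT_EPS_GRID = (0.01, 0.03, 0.1, 0.3, 1.0)


def default_trial_schedule(epsilons: Sequence[float]) -> dict[float, int]:
    """More trials at small eps, where allele effects approach sampling noise."""
    schedule = {}
    for eps in epsilons:
        if eps <= 0.03:
            schedule[eps] = 5000
        elif eps <= 0.3:
            schedule[eps] = 2000
        else:
            schedule[eps] = 1000
    return schedule


def ssa_evaluator(
    trait: TraitDefinition,
    n_trials: int,
    t_max: float = 500.0,
    dt_record: float = 0.5,
) -> Callable[[ParameterSet, np.ndarray, int], tuple[float, float]]:
    """Wrap the stochastic simulator as a landscape evaluator.

    Each call builds the network for the vertex's parameters, simulates
    ``n_trials`` quantum bumps and computes the trait.
    """

    def evaluate(params: ParameterSet, genotype: np.ndarray, seed: int) -> tuple[float, float]:
        compiled = compile_network(build_network(params))
        ensemble = simulate_ensemble(
            compiled, n_trials, seed, t_max=t_max, dt_record=dt_record, params=params
        )
        tv = compute_trait(ensemble, trait)
        return tv.value, tv.stderr

    return evaluate


@dataclass(frozen=True)
class EnsembleSummary:
    """D_k and per-locus variance split over (eps, allele-set replicate) cells."""

    epsilons: tuple[float, ...]
    n_sets: int
    n_loci: int
    d_k: np.ndarray    # (n_eps, n_sets, L+1)
    v_add: np.ndarray  # (n_eps, n_sets, L)
    v_epi: np.ndarray  # (n_eps, n_sets, L)
    provenance: dict = field(default_factory=dict)

    def mean_d_k(self) -> np.ndarray:
        """Mean D_k over allele-set replicates, shape (n_eps, L+1)."""
        return self.d_k.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        mean = self.mean_d_k()
        sd = self.d_k.std(axis=1, ddof=1) if self.n_sets > 1 else np.zeros_like(mean)
        for ie, eps in enumerate(self.epsilons):
            for k in range(self.n_loci + 1):
                rows.append(
                    {"epsilon": eps, "k": k, "D_k_mean": mean[ie, k], "D_k_sd": sd[ie, k]}
                )
        return pd.DataFrame(rows)

    def locus_frame(self) -> pd.DataFrame:
        rows = []
        for ie, eps in enumerate(self.epsilons):
            for i in range(self.n_loci):
                rows.append(
                    {
                        "epsilon": eps,
                        "locus": i,
                        "v_add_mean": self.v_add[ie, :, i].mean(),
                        "v_add_sd": self.v_add[ie, :, i].std(ddof=1) if self.n_sets > 1 else 0.0,
                        "v_epi_mean": self.v_epi[ie, :, i].mean(),
                        "v_epi_sd": self.v_epi[ie, :, i].std(ddof=1) if self.n_sets > 1 else 0.0,
                    }
                )
        return pd.DataFrame(rows)


def run_ensemble(
    reference: ParameterSet,
    loci: Sequence[str],
    epsilons: Sequence[float],
    n_sets: int,
    evaluator,
    base_seed: int = 0,
    shared_xi: bool = False,
    trait_name: str = "trait",
    evaluator_per_eps: bool = False,
) -> EnsembleSummary:
    """Full experiment: replicate allele tables x eps grid -> spectra summary.

    ``evaluator`` is a landscape evaluator ``(params, genotype, seed) ->
    (value, stderr)``, or with ``evaluator_per_eps=True`` a factory
    ``f(eps) -> evaluator`` (used to raise trial counts at small eps).
    In shared-xi mode each replicate draws one pair of Gaussian vectors and
    rescales them across the whole eps grid, isolating eps-scaling from
    generator randomness.
    """
    epsilons = tuple(epsilons)
    if any(e < 0 for e in epsilons):
        raise ValueError("epsilons must be non-negative")
    loci = tuple(loci)
    n_loci = len(loci)
    d_k = np.empty((len(epsilons), n_sets, n_loci + 1))
    v_add = np.empty((len(epsilons), n_sets, n_loci))
    v_epi = np.empty((len(epsilons), n_sets, n_loci))
    for rep in range(n_sets):
        shared_table = None
        if shared_xi:
            shared_table = generate_allele_table(
                reference, loci, 1.0, derive_seed(base_seed, rep)
            )
        for ie, eps in enumerate(epsilons):
            if shared_xi:
                table = rescale_allele_table(shared_table, reference, eps)
            else:
                table = generate_allele_table(
                    reference, loci, eps,
                    derive_seed(base_seed, ie * n_sets + rep),
                )
            vertex_seed = derive_seed(base_seed, 7919 * (ie * n_sets + rep) + 1)
            this_eval = evaluator(eps) if evaluator_per_eps else evaluator
            landscape = evaluate_trait_landscape(
                table, reference, this_eval, trait_name, base_seed=vertex_seed
            )
            spectrum = walsh_transform(landscape)
            d_k[ie, rep] = power_spectrum(spectrum).d_k
            lv = locus_variances(spectrum)
            v_add[ie, rep] = lv.v_add
            v_epi[ie, rep] = lv.v_epi
    return EnsembleSummary(
        epsilons, n_sets, n_loci, d_k, v_add, v_epi,
        provenance={
            "base_seed": base_seed,
            "shared_xi": shared_xi,
            "loci": list(loci),
            "trait": trait_name,
        },
    )


class NoiseFloorError(RuntimeError):
    """D_k indistinguishable from sampling noise in the requested window."""


def fit_scaling_exponent(
    summary: EnsembleSummary,
    k: int,
    eps_window: tuple[float, float] | None = None,
    noise_floor: Mapping[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares slope of log D_k versus log eps.

    For smooth traits the slope tends to ``2k`` as eps -> 0: order-k Walsh
    coefficients are k-th mixed derivatives times eps^k, so their variance
    scales as eps^{2k}.  Refuses to fit when fewer than three eps points lie
    in the window or when mean D_k does not exceed the supplied per-eps noise
    floor.
    """
    if not 1 <= k <= summary.n_loci:
        raise ValueError(f"order k={k} out of range")
    eps = np.array(summary.epsilons)
    dk = summary.mean_d_k()[:, k]
    keep = np.ones(eps.size, dtype=bool)
    if eps_window is not None:
        keep &= (eps >= eps_window[0]) & (eps <= eps_window[1])
    if keep.sum() < 3:
        raise ValueError("need at least three eps points in the fit window")
    bad = []
    for ie in np.flatnonzero(keep):
        floor = noise_floor.get(eps[ie], 0.0) if noise_floor else 0.0
        if dk[ie] <= floor:
            bad.append(float(eps[ie]))
    if bad:
        raise NoiseFloorError(
            f"D_{k} at or below the noise floor at eps={bad}; cannot fit"
        )
    res = stats.linregress(np.log(eps[keep]), np.log(dk[keep]))
    return float(res.slope), float(res.stderr)


def split_half_floor(landscape_a: TraitLandscape, landscape_b: TraitLandscape) -> np.ndarray:
    """Per-order noise floor from two landscapes built on disjoint trial halves.

    The spectrum of half the difference estimates the per-coefficient noise
    variance of the averaged landscape; returns the order-k means (length
    L+1), comparable directly with D_k of the mean landscape.
    """
    diff = (landscape_a.values - landscape_b.values) / 2.0
    return power_spectrum(walsh_transform(diff)).d_k


def pair_scatter(spectrum: WalshSpectrum, comparator: str = "rms") -> pd.DataFrame:
    """Additive versus epistatic strength for every pair of loci.

    ``additive_strength`` combines the two single-locus effects
    (default root-sum-square; ``"sum"`` and ``"max"`` available);
    ``epistatic_strength`` is |f_ij|.
    """
    f_i = spectrum.additive_effects()
    rows = []
    for i in range(spectrum.n_loci):
        for j in range(i + 1, spectrum.n_loci):
            if comparator == "rms":
                add = np.hypot(f_i[i], f_i[j])
            elif comparator == "sum":
                add = abs(f_i[i]) + abs(f_i[j])
            elif comparator == "max":
                add = max(abs(f_i[i]), abs(f_i[j]))
            else:
                raise ValueError(f"unknown comparator {comparator!r}")
            rows.append(
                {
                    "locus_i": i,
                    "locus_j": j,
                    "additive_strength": float(add),
                    "epistatic_strength": abs(spectrum.coefficient((i, j))),
                }
            )
    return pd.DataFrame(rows)


def exceedance_fraction(scatter: pd.DataFrame, threshold: float = 1.0) -> float:
    """Fraction of pairs whose interaction reaches ``threshold`` x additive part."""
    return float(
        (scatter["epistatic_strength"] >= threshold * scatter["additive_strength"]).mean()
    )


def top_additive_subset(spectrum: WalshSpectrum, m: int) -> np.ndarray:
    """The m loci with the largest additive variance f_i^2, strongest first.

    Ties break deterministically by locus index.
    """
    if not 1 <= m <= spectrum.n_loci:
        raise ValueError(f"m={m} out of range for L={spectrum.n_loci}")
    strength = spectrum.additive_effects() ** 2
    order = np.lexsort((np.arange(spectrum.n_loci), -strength))
    return order[:m]


@dataclass(frozen=True)
class SubsetRecovery:
    """Cumulative variance fractions recovered by the top-m additive loci.

    ``additive[m-1]`` is the additive variance of the top-m loci;
    ``additive_plus_pairs`` adds the pairwise interactions wholly inside the
    subset; ``total`` adds interactions of every order inside the subset —
    all as fractions of the full landscape variance.  Each curve is
    nondecreasing in m; ``total`` reaches 1 at m = L.
    """

    ranking: np.ndarray
    additive: np.ndarray
    additive_plus_pairs: np.ndarray
    total: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        m = np.arange(1, self.ranking.size + 1)
        return pd.DataFrame(
            {
                "m": m,
                "locus_added": self.ranking,
                "cum_additive": self.additive,
                "cum_additive_plus_pairs": self.additive_plus_pairs,
                "cum_total": self.total,
            }
        )


def cumulative_variance_curves(spectrum: WalshSpectrum) -> SubsetRecovery:
    """Fig-4-style recovery curves over the additive locus ranking.

    For each m, loci are the top-m by additive strength; a subset S of loci
    contributes once all its members are in the ranking prefix.
    """
    total = total_variance(spectrum)
    if total <= 0:
        raise ValueError("landscape has zero variance; fractions undefined")
    n_loci = spectrum.n_loci
    ranking = top_additive_subset(spectrum, n_loci)
    rank_of = np.empty(n_loci, dtype=np.int64)
    rank_of[ranking] = np.arange(n_loci)
    masks = np.arange(2**n_loci, dtype=np.int64)
    orders = spectrum.orders
    sq = spectrum.coefficients**2
    # m needed before subset `mask` lies inside the top-m prefix
    needed = np.zeros(masks.size, dtype=np.int64)
    for i in range(n_loci):
        has_i = (masks >> i) & 1 == 1
        needed[has_i] = np.maximum(needed[has_i], rank_of[i] + 1)
    additive = np.zeros(n_loci)
    pairs = np.zeros(n_loci)
    higher = np.zeros(n_loci)
    for sel, out in (((orders == 1), additive), ((orders == 2), pairs), ((orders >= 2), higher)):
        contrib = np.bincount(needed[sel], weights=sq[sel], minlength=n_loci + 1)
        out += np.cumsum(contrib[1:])
    return SubsetRecovery(
        ranking=ranking,
        additive=additive / total,
        additive_plus_pairs=(additive + pairs) / total,
        total=(additive + higher) / total,
    )
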