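"""Likelihoods over the six species-tree configurations and their maximisation.

Three input modes are supported:

* hard topology counts ``(n_ab, n_ac, n_bc)`` -- multinomial likelihood in
  the analytic topology probabilities;
* bootstrap-weighted counts -- per-locus topology proportions summed into
  real-valued pseudo-counts ``d`` (with hard assignments this reduces
  exactly to the count likelihood);
* gene trees with coalescence times -- a product over loci of the joint
  topology/time densities.

Topology-only data identify only the internal branch length, so the fit
optimises ``(M, dtau)`` with ``tau1`` pinned at 0 and ``dtau`` bounded by
the discordance-level heuristic; with branch lengths ``(M, tau1, tau2)``
are optimised jointly, bounded by the smallest observed coalescence times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from tasti.model import (
    CANONICAL_TOPOLOGIES,
    Configuration,
    ModelParameters,
    ParameterError,
    all_configurations,
    internal_branch_bound,
    joint_density,
    topology_probabilities,
)

_NEG_INF = float("-inf")
_TINY_PROB = 1e-300


class InputError(ValueError):
    """Raised for malformed observation data."""


def cherry_pairs(species: Sequence[str]) -> tuple[frozenset, frozenset, frozenset]:
    """The three possible cherry pairs of a sorted species triple, in the
    fixed order ((X,Y),Z), ((X,Z),Y), ((Y,Z),X)."""
    x, y, z = sorted(species)
    return (frozenset((x, y)), frozenset((x, z)), frozenset((y, z)))


def topology_label(pair: frozenset, species: Sequence[str]) -> str:
    """Canonical string for the rooted triple whose cherry is ``pair``."""
    a, b = sorted(pair)
    (z,) = set(species) - pair
    return f"(({a},{b}),{z})"


@dataclass(frozen=True)
class TopologyCounts:
    """Observed (or bootstrap-weighted) counts of the three rooted triples.

    ``counts`` is aligned with :func:`cherry_pairs` of the sorted species
    names; entries are nonnegative reals (integers for hard assignments).
    """

    species: tuple[str, str, str]
    counts: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(sorted(self.species)))
        cts = tuple(float(c) for c in self.counts)
        if len(cts) != 3 or any(c < 0 or not math.isfinite(c) for c in cts):
            raise InputError(f"counts must be three nonnegative reals, got {cts}")
        object.__setattr__(self, "counts", cts)
        if len(set(self.species)) != 3:
            raise InputError("species names must be three distinct labels")

    @property
    def K(self) -> float:
        return sum(self.counts)

    @classmethod
    def from_mapping(cls, species, mapping: Mapping[frozenset, float]) -> "TopologyCounts":
        pairs = cherry_pairs(species)
        unknown = set(mapping) - set(pairs)
        if unknown:
            raise InputError(f"counts keyed by unknown pairs: {unknown}")
        return cls(tuple(sorted(species)), tuple(mapping.get(p, 0.0) for p in pairs))

    def count(self, pair: frozenset) -> float:
        return self.counts[cherry_pairs(self.species).index(pair)]

    def relabel(self, mapping: Mapping[str, str]) -> "TopologyCounts":
        """Counts after renaming species via ``mapping`` (a bijection)."""
        new = {
            frozenset(mapping[s] for s in pair): self.count(pair)
            for pair in cherry_pairs(self.species)
        }
        return TopologyCounts.from_mapping([mapping[s] for s in self.species], new)


@dataclass(frozen=True)
class GeneTreeObservation:
    """One locus: a rooted-triple topology, optionally with its two
    coalescence times (mutation units, ``t1 <= t2``)."""

    pair: frozenset
    t1: Optional[float] = None
    t2: Optional[float] = None

    def __post_init__(self):
        if (self.t1 is None) != (self.t2 is None):
            raise InputError("provide both coalescence times or neither")
        if self.t1 is not None and not 0 <= self.t1 <= self.t2:
            raise InputError(f"need 0 <= t1 <= t2, got ({self.t1}, {self.t2})")

    @property
    def has_times(self) -> bool:
        return self.t1 is not None


# ---------------------------------------------------------------------------
# Log-likelihoods
# ---------------------------------------------------------------------------


def species_probabilities(omega: ModelParameters) -> dict[frozenset, float]:
    """Topology probabilities keyed by cherry pair of species names."""
    probs = topology_probabilities(omega)
    return {
        omega.config.gene_topology(lbl): p
        for lbl, p in zip(CANONICAL_TOPOLOGIES, probs)
    }


def loglik_topology_counts(y: TopologyCounts, omega: ModelParameters) -> float:
    """Multinomial log-likelihood ``sum_g n_g log P[G=g|Omega]``."""
    if set(y.species) != set(omega.config.topology):
        raise InputError("counts and parameters name different species")
    probs = species_probabilities(omega)
    ll = 0.0
    for pair in cherry_pairs(y.species):
        n = y.count(pair)
        if n == 0:
            continue
        p = probs[pair]
        if p < _TINY_PROB:
            return _NEG_INF
        ll += n * math.log(p)
    return ll


def weighted_counts(
    bootstrap_proportions: Iterable[Sequence[float]],
    species: Sequence[str],
    tol: float = 1e-6,
) -> TopologyCounts:
    """Bootstrap-weighted pseudo-counts ``d`` from per-locus topology
    proportion rows (aligned with :func:`cherry_pairs` order).

    Each row must sum to 1 within ``tol``; the output sums to the number of
    loci.  Hard rows (a single 1) reproduce integer counts exactly.
    """
    totals = np.zeros(3)
    n_rows = 0
    for k, row in enumerate(bootstrap_proportions):
        arr = np.asarray(row, dtype=float)
        if arr.shape != (3,) or (arr < 0).any():
            raise InputError(f"locus {k}: need three nonnegative proportions")
        if abs(arr.sum() - 1.0) > tol:
            raise InputError(f"locus {k}: proportions sum to {arr.sum()}, not 1")
        totals += arr / arr.sum()
        n_rows += 1
    if n_rows == 0:
        raise InputError("no proportion rows supplied")
    return TopologyCounts(tuple(sorted(species)), tuple(totals))


def loglik_branch_lengths(
    obs: Sequence[GeneTreeObservation], omega: ModelParameters
) -> float:
    """Log-likelihood of gene trees with coalescence times:
    ``sum_i log sum_j f_j(t1_i, t2_i, g_i)``."""
    if not obs:
        raise InputError("empty observation list")
    pair_to_canonical = {
        omega.config.gene_topology(lbl): lbl for lbl in CANONICAL_TOPOLOGIES
    }
    ll = 0.0
    for ob in obs:
        if not ob.has_times:
            raise InputError(
                "observation lacks coalescence times; use topology-count mode"
            )
        g = pair_to_canonical.get(ob.pair)
        if g is None:
            raise InputError(f"observation pair {set(ob.pair)} names unknown species")
        dens = sum(joint_density(j, ob.t1, ob.t2, g, omega) for j in (1, 2, 3, 4))
        if dens < _TINY_PROB:
            return _NEG_INF
        ll += math.log(dens)
    return ll


# ---------------------------------------------------------------------------
# Bounds and optimisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterBounds:
    M: tuple[float, float]
    dtau: Optional[tuple[float, float]] = None
    tau1: Optional[tuple[float, float]] = None
    tau2: Optional[tuple[float, float]] = None


def parameter_bounds(
    mode: str,
    obs,
    theta: float,
    N: float,
    p_min: float = 0.05,
    m_lower: float = 1e-2,
) -> ParameterBounds:
    """Search bounds for the constrained maximisation.

    ``M`` ranges up to ``4N/theta`` (the effectively unstructured limit).
    Topology mode bounds the internal branch by the length at which
    discordance drops to ``p_min``; branch-length mode bounds the
    divergence times by the smallest observed coalescence times.
    """
    m_hi = 4.0 * N / theta
    if mode == "topology":
        return ParameterBounds(M=(m_lower, m_hi), dtau=(0.0, internal_branch_bound(theta, p_min)))
    if mode == "branch_lengths":
        obs = list(obs)
        if not obs:
            raise InputError("empty observation set")
        min_t1 = min(ob.t1 for ob in obs)
        min_t2 = min(ob.t2 for ob in obs)
        return ParameterBounds(M=(m_lower, m_hi), tau1=(0.0, min_t1), tau2=(0.0, min_t2))
    raise InputError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class FitOptions:
    n_m: int = 20  # log-spaced migration-rate grid points
    n_tau: int = 20  # divergence-time grid points
    n_starts: int = 3  # grid points refined locally
    refine: bool = True
    p_min: float = 0.05  # minimum assumed discordance (topology mode bound)
    m_lower: float = 1e-2
    star_tol: float = 1e-9  # tau below this counts as zero (star tree)
    tie_tol: float = 1e-6  # log-likelihood ties among configurations


@dataclass(frozen=True)
class ConfigFit:
    """Maximum-likelihood result for one species-tree configuration."""

    config: Configuration
    M: float
    tau1: float
    tau2: float
    loglik: float
    converged: bool = True

    @property
    def dtau(self) -> float:
        return self.tau2 - self.tau1


@dataclass(frozen=True)
class FitResult:
    """Per-configuration table plus the maximum-likelihood species tree."""

    fits: tuple[ConfigFit, ...]
    best: Optional[Configuration]
    unresolved: bool
    tie_set: tuple[Configuration, ...] = ()
    mode: str = "topology"

    @property
    def topology(self) -> str:
        if self.unresolved or self.best is None:
            x, y, z = sorted(self.fits[0].config.topology)
            return f"({x},{y},{z})"
        return self.best.label()

    @property
    def best_fit(self) -> Optional[ConfigFit]:
        if self.best is None:
            return None
        return next(f for f in self.fits if f.config == self.best)


_CANON_CFG = Configuration(("A", "B", "C"), shared="B")


def _canonical_omega(M: float, dtau: float, theta: float, N: float) -> ModelParameters:
    return ModelParameters.symmetric(_CANON_CFG, 0.0, dtau, theta, M, N)


def _count_vector(y: TopologyCounts, config: Configuration) -> np.ndarray:
    """Counts ordered as (n_ab, n_ac, n_bc) in the configuration's roles."""
    return np.array([y.count(config.gene_topology(lbl)) for lbl in CANONICAL_TOPOLOGIES])


def _loglik_from_triple(n: np.ndarray, probs) -> float:
    ll = 0.0
    for ni, pi in zip(n, probs):
        if ni == 0:
            continue
        if pi < _TINY_PROB:
            return _NEG_INF
        ll += ni * math.log(pi)
    return ll


def fit_configuration(
    config: Configuration,
    data,
    theta: float,
    N: float = 5e4,
    options: FitOptions = FitOptions(),
) -> ConfigFit:
    """Bounded maximisation of the log-likelihood for one configuration.

    ``data`` is a :class:`TopologyCounts` (topology mode, optimising
    ``(M, dtau)``) or a sequence of timed :class:`GeneTreeObservation`
    (branch-length mode, optimising ``(M, tau1, tau2)``).  A coarse
    deterministic grid is followed by local refinement from the best
    ``options.n_starts`` grid points.
    """
    if isinstance(data, TopologyCounts):
        return _fit_topology(config, data, float(theta), float(N), options)
    return _fit_branch_lengths(config, list(data), float(theta), float(N), options)


def _fit_topology(config, y, theta, N, opt) -> ConfigFit:
    bounds = parameter_bounds("topology", None, theta, N, opt.p_min, opt.m_lower)
    n = _count_vector(y, config)
    m_lo, m_hi = bounds.M
    d_hi = bounds.dtau[1]
    m_grid = np.logspace(math.log10(m_lo), math.log10(m_hi), opt.n_m)
    d_grid = np.linspace(d_hi / opt.n_tau, d_hi, opt.n_tau)

    def nll(x):
        m = 10.0 ** x[0]
        d = min(max(x[1], 0.0), d_hi)
        if not m_lo <= m <= m_hi:
            return 1e18
        probs = topology_probabilities(_canonical_omega(m, d, theta, N))
        ll = _loglik_from_triple(n, probs)
        return 1e18 if ll == _NEG_INF else -ll

    evals = []
    for m in m_grid:
        for d in d_grid:
            evals.append((nll((math.log10(m), d)), math.log10(m), d))
    evals.sort(key=lambda e: (e[0], e[1], e[2]))
    best_val, best_lm, best_d = evals[0]
    converged = True
    if opt.refine:
        for val, lm, d in evals[: opt.n_starts]:
            res = optimize.minimize(
                nll,
                x0=[lm, d],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
            )
            if res.fun < best_val:
                best_val, (best_lm, best_d) = res.fun, res.x
    best_d = min(max(best_d, 0.0), d_hi)
    return ConfigFit(config, 10.0 ** best_lm, 0.0, best_d, -best_val, converged)


def _fit_branch_lengths(config, obs, theta, N, opt) -> ConfigFit:
    bounds = parameter_bounds("branch_lengths", obs, theta, N, opt.p_min, opt.m_lower)
    m_lo, m_hi = bounds.M
    t1_hi = bounds.tau1[1]
    t2_hi = bounds.tau2[1]

    def loglik(m, tau1, tau2):
        om = ModelParameters(config, tau1, tau2, (theta,) * 4, (m,) * 4, N)
        return loglik_branch_lengths(obs, om)

    def nll(x):
        m = 10.0 ** x[0]
        tau1 = min(max(x[1], 0.0), t1_hi)
        tau2 = min(max(x[2], tau1), t2_hi)
        if not m_lo <= m <= m_hi:
            return 1e18
        ll = loglik(m, tau1, tau2)
        return 1e18 if ll == _NEG_INF else -ll

    n_tau = max(4, opt.n_tau // 3)
    n_m = max(4, opt.n_m // 3)
    m_grid = np.logspace(math.log10(m_lo), math.log10(m_hi), n_m)
    t1_grid = np.linspace(0.0, t1_hi, n_tau)
    fr_grid = np.linspace(0.0, 1.0, n_tau)
    evals = []
    for m in m_grid:
        lm = math.log10(m)
        for t1 in t1_grid:
            for fr in fr_grid:
                t2 = t1 + fr * (t2_hi - t1)
                evals.append((nll((lm, t1, t2)), lm, t1, t2))
    evals.sort(key=lambda e: e[:1] + e[1:])
    best_val, best_lm, best_t1, best_t2 = evals[0]
    converged = best_val < 1e18
    if opt.refine and converged:
        for val, lm, t1, t2 in evals[: opt.n_starts]:
            res = optimize.minimize(
                nll,
                x0=[lm, t1, t2],
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 400},
            )
            if res.fun < best_val:
                best_val, (best_lm, best_t1, best_t2) = res.fun, res.x
    best_t1 = min(max(best_t1, 0.0), t1_hi)
    best_t2 = min(max(best_t2, best_t1), t2_hi)
    return ConfigFit(
        config, 10.0 ** best_lm, best_t1, best_t2, -best_val, converged
    )


def infer_species_tree(
    data,
    theta: float,
    N: float = 5e4,
    options: FitOptions = FitOptions(),
    species: Optional[Sequence[str]] = None,
) -> FitResult:
    """Fit all six configurations and return the maximum-likelihood tree.

    Ties (log-likelihoods within ``options.tie_tol``) across different
    topologies yield an unresolved result with the tie set reported; in
    branch-length mode a star-tree fit (``tau1 = tau2 = 0``) is likewise
    unresolved.
    """
    if isinstance(data, TopologyCounts):
        names = data.species
        mode = "topology"
    else:
        data = list(data)
        if species is None:
            names = sorted({s for ob in data for s in ob.pair} | set())
            if len(names) != 3:
                raise InputError(
                    "cannot infer the species triple from observations; "
                    "pass species= explicitly"
                )
        else:
            names = sorted(species)
        mode = "branch_lengths"
    fits = tuple(
        fit_configuration(cfg, data, theta, N, options)
        for cfg in all_configurations(names)
    )
    best_ll = max(f.loglik for f in fits)
    tie = tuple(f.config for f in fits if f.loglik >= best_ll - options.tie_tol)
    tied_topologies = {c.topology for c in tie}
    best_fit = next(f for f in fits if f.loglik == best_ll)
    unresolved = len(tied_topologies) > 1
    if unresolved:
        warnings.warn(
            "configurations tie within tolerance; returning the unresolved triple",
            stacklevel=2,
        )
    if mode == "branch_lengths" and not unresolved:
        if best_fit.tau1 < options.star_tol and best_fit.tau2 < options.star_tol:
            unresolved = True  # star tree: divergence times collapsed to zero
    return FitResult(
        fits=fits,
        best=None if unresolved else best_fit.config,
        unresolved=unresolved,
        tie_set=tie if len(tie) > 1 else (),
        mode=mode,
    )
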