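"""Parametric-bootstrap test of panmixia versus ancestral structure.

Under the null of unstructured (panmictic) ancestry the two minority
gene-tree topologies are exchangeable, so their expected counts are equal.
The test simulates topology counts under the fitted structured model,
compares each bootstrap sample against symmetric expected counts (the
observed maximum kept, the two minority cells averaged) with a chi-square
goodness-of-fit statistic on 1 degree of freedom, and combines the
bootstrap p-values with Simes' procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from tasti.likelihood import InputError, TopologyCounts
from tasti.model import Configuration, ModelParameters


def expected_counts(O: Sequence[float]) -> np.ndarray:
    """Null-symmetric expected counts: the maximal observed cell is kept
    and the two remaining cells are replaced by their mean.  Argmax ties
    break toward the first index."""
    O = np.asarray(O, dtype=float)
    if O.shape != (3,) or (O < 0).any():
        raise InputError("need three nonnegative counts")
    if O.sum() <= 0:
        raise InputError("all-zero counts")
    i = int(np.argmax(O))  # np.argmax takes the first index on ties
    rest = [k for k in range(3) if k != i]
    E = np.empty(3)
    E[i] = O[i]
    E[rest] = O[rest].mean()
    return E


def gof_pvalue(O: Sequence[float]) -> float:
    """Upper-tail chi-square (1 df) probability of ``sum (O-E)^2/E``."""
    O = np.asarray(O, dtype=float)
    E = expected_counts(O)
    if (E == 0).any():
        raise InputError(
            "expected count of zero; the goodness-of-fit statistic is undefined"
        )
    stat = float(((O - E) ** 2 / E).sum())
    return float(stats.chi2.sf(stat, df=1))


def simes_combine(pvalues: Sequence[float]) -> float:
    """Simes' combination ``min_i B * p_(i) / i`` of B p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InputError("no p-values to combine")
    if (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    p = np.sort(p)
    ranks = np.arange(1, p.size + 1)
    return float(min(1.0, (p.size * p / ranks).min()))


@dataclass(frozen=True)
class StructureTestResult:
    B: int
    observed: tuple  # per-replicate count triples (n_ab, n_ac, n_bc)
    expected: tuple  # per-replicate expected triples
    pvalues: tuple
    combined: float
    alpha: float
    reject: bool
    seed: object = None


_CANON = Configuration(("A", "B", "C"), shared="B")


def test_ancestral_structure(
    M_hat: float,
    dtau_hat: float,
    theta: float,
    K: int,
    B: int = 100,
    alpha: float = 0.01,
    seed=None,
    N: float = 5e4,
) -> StructureTestResult:
    """Parametric bootstrap of H0: panmixia vs H1: ancestral structure.

    ``B`` bootstrap samples of ``K`` locus topologies are simulated under
    the fitted ``(M_hat, dtau_hat)``; each is scored by :func:`gof_pvalue`
    against the null-symmetric expected counts and the p-values are
    Simes-combined.  H0 is rejected when the combined p-value is <= alpha.
    """
    from tasti.simulate import simulate_topology_counts  # deferred: avoid cycle

    if K < 1:
        raise InputError("K must be a positive integer")
    if B < 1:
        raise InputError("B must be a positive integer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    omega = ModelParameters.symmetric(_CANON, 0.0, dtau_hat, theta, M_hat, N)
    obs, exp, pvals = [], [], []
    for _ in range(B):
        y = simulate_topology_counts(omega, K, rng)
        O = np.array([
            y.count(_CANON.gene_topology(lbl))
            for lbl in ("((ab)c)", "((ac)b)", "((bc)a)")
        ])
        obs.append(tuple(O))
        exp.append(tuple(expected_counts(O)))
        pvals.append(gof_pvalue(O))
    combined = simes_combine(pvals)
    return StructureTestResult(
        B=B,
        observed=tuple(obs),
        expected=tuple(exp),
        pvalues=tuple(pvals),
        combined=combined,
        alpha=alpha,
        reject=combined <= alpha,
        seed=seed,
    )
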