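"""Structured-coalescent model for three species with two ancestral demes.

The model relates three species X, Y, Z through a rooted species tree
((XY)Z) with divergence times ``tau1 <= tau2`` measured in mutation units
(expected substitutions per site).  Every ancestral species is split into
two subpopulations; lineages migrate between them at mutation-scaled rates
``M_j = 4*N*m_j/theta_j`` (the rate of moving *to* subpopulation ``j``) and
coalesce within subpopulation ``i`` at rate ``c_i = 2/theta_i`` with
``theta_i = 4*N_i*mu``.  One ingroup lineage starts in subpopulation 1, the
other in subpopulation 2, and the outgroup lineage enters subpopulation 2
at the root.  Gene-tree histories are a continuous-time Markov chain on
small explicit state spaces:

* ``Q_AB`` (6 states) -- the two ingroup lineages on the internal branch,
  states ``a1b2, a2b1, a1b1, a2b2, (ab)1, (ab)2``;
* ``Q_ABC`` (20 states) -- three lineages above the root, 8 uncoalesced
  states plus 12 absorbing once-coalesced states grouped by which pair
  coalesced first;
* ``Q_XY`` (6 states) -- a coalesced pair plus the remaining lineage above
  the root, isomorphic to ``Q_AB`` with root-population parameters.

State indices in the public API are 1-based, matching the labels above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate
from scipy.linalg import expm


class ParameterError(ValueError):
    """Raised when model parameters lie outside their domain."""


# ---------------------------------------------------------------------------
# State spaces
# ---------------------------------------------------------------------------

STATES_AB: tuple[str, ...] = ("a1b2", "a2b1", "a1b1", "a2b2", "(ab)1", "(ab)2")
STATES_XY: tuple[str, ...] = ("x1y2", "x2y1", "x1y1", "x2y2", "(xy)1", "(xy)2")

# Subpopulation assignments (a, b) for the four uncoalesced pair states,
# in the order of STATES_AB.
_PAIR_POSITIONS: tuple[tuple[int, int], ...] = ((1, 2), (2, 1), (1, 1), (2, 2))

# Uncoalesced triple states 1-8: the (a, b) block order of STATES_AB crossed
# with the position of c -- c in subpopulation 1 for states 1-4, in 2 for 5-8.
_ABC_UNCOALESCED: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c) for c in (1, 2) for (a, b) in _PAIR_POSITIONS
)

# Coalesced triple states 9-20 in blocks (ab): 9-12, (ac): 13-16, (bc): 17-20,
# each block ordered (pair)1&other1, (pair)1&other2, (pair)2&other1, (pair)2&other2.
_ABC_COALESCED: tuple[tuple[str, int, int], ...] = tuple(
    (pair, i, j) for pair in ("ab", "ac", "bc") for i in (1, 2) for j in (1, 2)
)


def _abc_label(state: tuple) -> str:
    if len(state) == 3 and isinstance(state[0], int):
        a, b, c = state
        return f"a{a}b{b}c{c}"
    pair, i, j = state
    other = ({"ab": "c", "ac": "b", "bc": "a"})[pair]
    return f"({pair}){i}{other}{j}"


STATES_ABC: tuple[str, ...] = tuple(
    _abc_label(s) for s in _ABC_UNCOALESCED + _ABC_COALESCED
)

#: phi1 maps a coalesced Q_AB state to the Q_XY state it occupies at the root,
#: where the outgroup lineage enters subpopulation 2.
PHI1: dict[int, int] = {5: 1, 6: 4}

#: phi2 maps an uncoalesced Q_AB state to the Q_ABC state obtained when the
#: outgroup lineage enters subpopulation 2.  (a1b1 joined by c in deme 2 is
#: a1b1c2, i.e. state 7.)
PHI2: dict[int, int] = {1: 5, 2: 6, 3: 7, 4: 8}

#: phi3 maps a coalesced Q_ABC state to the Q_XY state with the same deme
#: occupancy of the coalesced pair and the remaining singleton.
PHI3: dict[int, int] = {}
for _idx, (_pair, _i, _j) in enumerate(_ABC_COALESCED, start=9):
    PHI3[_idx] = {(1, 2): 1, (2, 1): 2, (1, 1): 3, (2, 2): 4}[(_i, _j)]


def map_state(mapping: str, s: int) -> int:
    """Apply one of the state mappings ``phi1``, ``phi2`` or ``phi3``.

    Raises :class:`ParameterError` when ``s`` is outside the mapping's domain
    (phi1: coalesced pair states {5, 6}; phi2: uncoalesced pair states
    {1..4}; phi3: coalesced triple states {9..20}).
    """
    table = {"phi1": PHI1, "phi2": PHI2, "phi3": PHI3}.get(mapping)
    if table is None:
        raise ParameterError(f"unknown mapping {mapping!r}")
    if s not in table:
        raise ParameterError(f"state {s} outside the domain of {mapping}")
    return table[s]


# ---------------------------------------------------------------------------
# Species-tree configurations and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Configuration:
    """A rooted-triple species tree plus its deme assignment.

    ``topology`` holds ``(sister_x, sister_y, outgroup)`` with the sisters in
    sorted order.  ``shared`` names the ingroup species whose lineage starts
    in the same ancestral subpopulation (deme 2) as the outgroup lineage;
    the other sister starts in deme 1.  Three topologies times two deme
    assignments give the six configurations of the model.
    """

    topology: tuple[str, str, str]
    shared: str

    def __post_init__(self):
        x, y, z = self.topology
        if len({x, y, z}) != 3:
            raise ParameterError("species names must be distinct")
        if (x, y) != tuple(sorted((x, y))):
            object.__setattr__(self, "topology", (*sorted((x, y)), z))
        if self.shared not in self.topology[:2]:
            raise ParameterError(
                f"shared species {self.shared!r} is not an ingroup species "
                f"of {self.topology}"
            )

    @property
    def sisters(self) -> tuple[str, str]:
        return self.topology[:2]

    @property
    def outgroup(self) -> str:
        return self.topology[2]

    @property
    def solo(self) -> str:
        """The sister species whose lineage starts alone in deme 1."""
        x, y = self.sisters
        return y if self.shared == x else x

    def gene_topology(self, canonical: str) -> frozenset:
        """Cherry pair (as a frozenset of species) of the gene-tree topology
        named by a canonical label ``((ab)c)``, ``((ac)b)`` or ``((bc)a)``,
        where ``a`` = the deme-1 sister, ``b`` = the deme-2 sister and
        ``c`` = the outgroup."""
        roles = {"a": self.solo, "b": self.shared, "c": self.outgroup}
        pair = {"((ab)c)": "ab", "((ac)b)": "ac", "((bc)a)": "bc"}[canonical]
        return frozenset(roles[ch] for ch in pair)

    def label(self) -> str:
        return f"(({self.topology[0]},{self.topology[1]}),{self.topology[2]})"


def all_configurations(species: Iterable[str]) -> list[Configuration]:
    """The six configurations for three named species, in a fixed order."""
    names = sorted(species)
    if len(names) != 3:
        raise ParameterError("exactly three species names are required")
    configs = []
    for out in names:
        sisters = tuple(n for n in names if n != out)
        for shared in sisters:
            configs.append(Configuration((*sisters, out), shared))
    return configs


CANONICAL_TOPOLOGIES: tuple[str, str, str] = ("((ab)c)", "((ac)b)", "((bc)a)")


def _positive4(v, name: str) -> tuple[float, float, float, float]:
    try:
        vals = tuple(float(x) for x in v)
    except TypeError:
        vals = (float(v),) * 4
    if len(vals) == 1:
        vals = vals * 4
    if len(vals) != 4:
        raise ParameterError(f"{name} must be a scalar or 4 values")
    if any(not math.isfinite(x) or x <= 0 for x in vals):
        raise ParameterError(f"{name} entries must be positive, got {vals}")
    return vals


@dataclass(frozen=True)
class ModelParameters:
    """The full parameter set of the two-deme model.

    ``theta`` and ``M`` hold ``(AB,1), (AB,2), (ABC,1), (ABC,2)`` slots: the
    internal-branch and above-root values for each subpopulation.  ``N`` is
    the per-deme effective size and only bounds the migration rate by
    ``M <= 4N/theta`` (the ``m = 1`` limit, where the ancestry is effectively
    unstructured).
    """

    config: Configuration
    tau1: float
    tau2: float
    theta: tuple[float, float, float, float]
    M: tuple[float, float, float, float]
    N: float = 5e4

    def __post_init__(self):
        object.__setattr__(self, "theta", _positive4(self.theta, "theta"))
        object.__setattr__(self, "M", _positive4(self.M, "M"))
        object.__setattr__(self, "tau1", float(self.tau1))
        object.__setattr__(self, "tau2", float(self.tau2))
        if not 0 <= self.tau1 <= self.tau2:
            raise ParameterError(
                f"need 0 <= tau1 <= tau2, got ({self.tau1}, {self.tau2})"
            )
        if self.N <= 0:
            raise ParameterError("N must be positive")
        for m, th in zip(self.M, self.theta):
            if m > 4 * self.N / th * (1 + 1e-12):
                raise ParameterError(
                    f"M={m} exceeds its upper bound 4N/theta={4 * self.N / th}"
                )

    @classmethod
    def symmetric(cls, config, tau1, tau2, theta, M, N=5e4) -> "ModelParameters":
        """All four theta slots equal and all four M slots equal (the tying
        used throughout the simulation study)."""
        return cls(config, tau1, tau2, (theta,) * 4, (M,) * 4, N)

    @property
    def dtau(self) -> float:
        return self.tau2 - self.tau1


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Generator:
    """An instantaneous rate matrix over one of the model state spaces."""

    kind: str
    matrix: np.ndarray
    theta: tuple[float, float]
    M: tuple[float, float]

    @property
    def labels(self) -> tuple[str, ...]:
        return {"AB": STATES_AB, "XY": STATES_XY, "ABC": STATES_ABC}[self.kind]


def _pair_rate_matrix(c: tuple[float, float], M: tuple[float, float]) -> np.ndarray:
    q = np.zeros((6, 6))
    c1, c2 = c
    m1, m2 = M
    q[0, 2] = m1  # x1y2: y moves to deme 1
    q[0, 3] = m2  # x1y2: x moves to deme 2
    q[1, 2] = m1
    q[1, 3] = m2
    q[2, 0] = m2  # x1y1: y moves to deme 2
    q[2, 1] = m2  # x1y1: x moves to deme 2
    q[2, 4] = c1
    q[3, 0] = m1
    q[3, 1] = m1
    q[3, 5] = c2
    q[4, 5] = m2  # coalesced pair migrates as one lineage
    q[5, 4] = m1
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def _triple_rate_matrix(c: tuple[float, float], M: tuple[float, float]) -> np.ndarray:
    """The 20x20 generator for three uncoalesced lineages above the root.

    Coalesced states (9-20) are absorbing: the chain is stopped at the first
    coalescence, after which dynamics continue on the 6-state pair chain via
    the phi3 mapping.  When all three lineages share deme ``i`` each of the
    three pairs coalesces at ``c_i``, for a total coalescence rate ``3*c_i``.
    """
    q = np.zeros((20, 20))
    uncoal_index = {s: k for k, s in enumerate(_ABC_UNCOALESCED)}
    coal_index = {s: k + 8 for k, s in enumerate(_ABC_COALESCED)}
    for k, (a, b, cpos) in enumerate(_ABC_UNCOALESCED):
        positions = {"a": a, "b": b, "c": cpos}
        # single-lineage migration
        for lin, pos in positions.items():
            dest = 2 if pos == 1 else 1
            moved = dict(positions, **{lin: dest})
            tgt = uncoal_index[(moved["a"], moved["b"], moved["c"])]
            q[k, tgt] += M[dest - 1]
        # pairwise coalescence within a deme
        for pair, other in (("ab", "c"), ("ac", "b"), ("bc", "a")):
            p1, p2 = positions[pair[0]], positions[pair[1]]
            if p1 == p2:
                tgt = coal_index[(pair, p1, positions[other])]
                q[k, tgt] += c[p1 - 1]
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def build_generator(kind: str, theta: Sequence[float], M: Sequence[float]) -> Generator:
    """Build the instantaneous rate matrix of the requested chain.

    ``theta`` and ``M`` are the two per-deme values for the relevant epoch;
    coalescence rates are ``c_i = 2/theta_i`` and a lone lineage moves to
    deme ``j`` at rate ``M_j``.
    """
    th = tuple(float(x) for x in theta)
    mm = tuple(float(x) for x in M)
    if len(th) != 2 or len(mm) != 2:
        raise ParameterError("theta and M must each hold two per-deme values")
    if any(x <= 0 for x in th) or any(x <= 0 for x in mm):
        raise ParameterError("theta and M must be positive")
    c = (2.0 / th[0], 2.0 / th[1])
    if kind in ("AB", "XY"):
        mat = _pair_rate_matrix(c, mm)
    elif kind == "ABC":
        mat = _triple_rate_matrix(c, mm)
    else:
        raise ParameterError(f"unknown generator kind {kind!r}")
    return Generator(kind, mat, th, mm)


# The unique transient predecessor of each coalesced triple state, and the
# deme in which that coalescence happens: state s is entered only from
# pre(s) by a single coalescence at rate c_{deme(s)}.
_ABC_PRE: dict[int, tuple[int, int]] = {}
for _k, (_pair, _i, _j) in enumerate(_ABC_COALESCED, start=9):
    _src = {"ab": (_i, _i, _j), "ac": (_i, _j, _i), "bc": (_j, _i, _i)}[_pair]
    _ABC_PRE[_k] = (_ABC_UNCOALESCED.index(_src) + 1, _i)


def transition_matrix(gen: Generator, t: float) -> np.ndarray:
    """``exp(Q t)``: the row-stochastic transition matrix at elapsed time t."""
    if t < 0:
        raise ParameterError(f"elapsed time must be nonnegative, got {t}")
    return expm(gen.matrix * t)


class _Propagator:
    """Fast e^{Qt} by eigendecomposition, falling back to expm when the
    eigenbasis is ill-conditioned (e.g. near-defective Q)."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.ok = False
        self._memo: dict[float, np.ndarray] = {}
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            self.w, self.V, self.Vinv = w, V, Vinv
            scale = np.abs(Q).max()
            tref = 1.0 / scale if scale > 0 else 1.0
            approx = self(tref, _check=False)
            self.ok = np.abs(approx - expm(Q * tref)).max() < 1e-9
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float, _check: bool = True) -> np.ndarray:
        if _check:
            hit = self._memo.get(t)
            if hit is not None:
                return hit
        if _check and not self.ok:
            out = expm(self.Q * t)
        else:
            out = np.real((self.V * np.exp(self.w * t)) @ self.Vinv)
        if _check:
            if len(self._memo) > 4096:
                self._memo.clear()
            self._memo[t] = out
        return out


@lru_cache(maxsize=128)
def _chains(omega: ModelParameters):
    """Generators and propagators for each epoch of a parameter set."""
    qab = build_generator("AB", omega.theta[:2], omega.M[:2])
    qxy = build_generator("XY", omega.theta[2:], omega.M[2:])
    qabc = build_generator("ABC", omega.theta[2:], omega.M[2:])
    return {
        "AB": (qab, _Propagator(qab.matrix)),
        "XY": (qxy, _Propagator(qxy.matrix)),
        "ABC": (qabc, _Propagator(qabc.matrix)),
    }


# ---------------------------------------------------------------------------
# Marginal densities and joint densities
# ---------------------------------------------------------------------------


def marginal_density_h(which: str, t: float, states, omega: ModelParameters) -> float:
    """The per-epoch occupation probabilities and first-passage densities.

    ``hAB22(t, s)`` -- probability the ingroup pair, started in a1b2, is in
    uncoalesced state ``s`` in {1..4} after elapsed time t (no coalescence
    yet).  ``hAB21(t, s)`` -- density of the pair first coalescing at time t
    into state ``s`` in {5, 6}.  ``hABC21(t, s)`` -- density of the final
    coalescence at time t for the pair chain above the root started in
    uncoalesced state ``s`` in {1..4}.  ``hABC32(t, (s1, s2))`` -- density of
    the three-lineage chain started in ``s1`` in {5..8} being absorbed at
    time t into coalesced state ``s2`` in {9..20}.

    First-passage densities are the rate into the absorbing state times the
    occupation probability of its unique pre-coalescent transient state.
    """
    if t < 0:
        raise ParameterError(f"elapsed time must be nonnegative, got {t}")
    chains = _chains(omega)
    if which == "hAB22":
        s = int(states)
        if s not in (1, 2, 3, 4):
            raise ParameterError(f"hAB22 needs a state in 1..4, got {s}")
        _, prop = chains["AB"]
        return float(prop(t)[0, s - 1])
    if which == "hAB21":
        s = int(states)
        if s not in (5, 6):
            raise ParameterError(f"hAB21 needs a state in {{5, 6}}, got {s}")
        gen, prop = chains["AB"]
        c = 2.0 / gen.theta[s - 5]
        pre = 3 if s == 5 else 4
        return float(c * prop(t)[0, pre - 1])
    if which == "hABC21":
        s = int(states)
        if s not in (1, 2, 3, 4):
            raise ParameterError(f"hABC21 needs a state in 1..4, got {s}")
        gen, prop = chains["XY"]
        c1, c2 = 2.0 / gen.theta[0], 2.0 / gen.theta[1]
        p = prop(t)
        return float(c1 * p[s - 1, 2] + c2 * p[s - 1, 3])
    if which == "hABC32":
        s1, s2 = (int(x) for x in states)
        if s1 not in (5, 6, 7, 8):
            raise ParameterError(f"hABC32 needs a start state in 5..8, got {s1}")
        if s2 not in _ABC_PRE:
            raise ParameterError(f"hABC32 needs an absorbing state in 9..20, got {s2}")
        gen, prop = chains["ABC"]
        pre, deme = _ABC_PRE[s2]
        c = 2.0 / gen.theta[deme - 1]
        return float(c * prop(t)[s1 - 1, pre - 1])
    raise ParameterError(f"unknown marginal density {which!r}")


_BLOCKS = {2: range(9, 13), 3: range(13, 17), 4: range(17, 21)}
_TOPOLOGY_OF_F = {1: "((ab)c)", 2: "((ab)c)", 3: "((ac)b)", 4: "((bc)a)"}


def joint_density(j: int, t1: float, t2: float, g: str, omega: ModelParameters) -> float:
    """Joint density ``f_j(t1, t2, g)`` of topology and coalescence times.

    ``f1`` carries the histories where the ingroup pair coalesces on the
    internal branch (``tau1 <= t1 < tau2 <= t2``, necessarily topology
    ((ab)c)); ``f2``-``f4`` carry histories with both coalescences above the
    root (``tau2 <= t1 < t2``) and first coalescence of pair ab, ac, bc
    respectively.  Outside the support (or for a mismatched topology) the
    density is zero.
    """
    if j not in (1, 2, 3, 4):
        raise ParameterError(f"j must be in 1..4, got {j}")
    if g != _TOPOLOGY_OF_F[j]:
        return 0.0
    tau1, tau2 = omega.tau1, omega.tau2
    chains = _chains(omega)
    if j == 1:
        if not (tau1 <= t1 < tau2 <= t2):
            return 0.0
        _, prop_ab = chains["AB"]
        bridge = prop_ab(tau2 - t1)
        total = 0.0
        for s1 in (5, 6):
            d1 = marginal_density_h("hAB21", t1 - tau1, s1, omega)
            if d1 == 0.0:
                continue
            inner = sum(
                bridge[s1 - 1, s2 - 1]
                * marginal_density_h("hABC21", t2 - tau2, PHI1[s2], omega)
                for s2 in (5, 6)
            )
            total += d1 * inner
        return float(total)
    if not (tau2 <= t1 < t2):
        return 0.0
    total = 0.0
    for s1 in (1, 2, 3, 4):
        occ = marginal_density_h("hAB22", tau2 - tau1, s1, omega)
        if occ == 0.0:
            continue
        inner = 0.0
        for s2 in _BLOCKS[j]:
            inner += marginal_density_h(
                "hABC32", t1 - tau2, (PHI2[s1], s2), omega
            ) * marginal_density_h("hABC21", t2 - t1, PHI3[s2], omega)
        total += occ * inner
    return float(total)


# ---------------------------------------------------------------------------
# Topology probabilities
# ---------------------------------------------------------------------------


def _topology_probabilities_absorption(omega: ModelParameters) -> tuple[float, float, float]:
    chains = _chains(omega)
    _, prop_ab = chains["AB"]
    gen_abc, _ = chains["ABC"]
    row = prop_ab(omega.dtau)[0]
    p_ab = row[4] + row[5]
    v = np.zeros(8)
    for s in (1, 2, 3, 4):
        v[PHI2[s] - 1] = row[s - 1]
    Q = gen_abc.matrix
    hit = np.linalg.solve(-Q[:8, :8], Q[:8, 8:])  # transient -> absorbing
    h = v @ hit
    return (
        float(p_ab + h[:4].sum()),
        float(h[4:8].sum()),
        float(h[8:].sum()),
    )


def _graded_nodes(upper: float, order: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on (0, upper) with panels
    graded geometrically toward 0, resolving structure across ~10 decades
    of timescales."""
    edges = [0.0] + list(upper * 2.0 ** np.arange(-34.0, 1.0))
    gl_x, gl_w = np.polynomial.legendre.leggauss(order)
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        nodes.append(0.5 * (b - a) * (gl_x + 1.0) + a)
        weights.append(0.5 * (b - a) * gl_w)
    return np.concatenate(nodes), np.concatenate(weights)


def _half_line_nodes(scale: float, order: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights on (0, ~46*scale): the exponential tail beyond is
    ~e^-46 and is discarded."""
    return _graded_nodes(46.0 * scale, order)


def _topology_probabilities_quadrature(omega: ModelParameters) -> tuple[float, float, float]:
    """Numerical integration of the joint topology/time densities over
    their supports: an independent cross-check of the absorption route."""
    chains = _chains(omega)
    gen_ab, prop_ab = chains["AB"]
    gen_xy, prop_xy = chains["XY"]
    gen_abc, prop_abc = chains["ABC"]
    dtau = omega.dtau
    # slowest relaxation of the above-root chains sets the tail scale
    lam = min(2.0 * min(omega.M), 2.0 / max(omega.theta))
    scale = max(1.0 / lam, max(omega.theta))

    # density of the final coalescence on the pair chain, per start state
    y_nodes, y_w = _half_line_nodes(scale)
    c1, c2 = 2.0 / gen_xy.theta[0], 2.0 / gen_xy.theta[1]
    pxy = np.stack([prop_xy(t) for t in y_nodes])  # (ny, 6, 6)
    habc21 = c1 * pxy[:, :4, 2] + c2 * pxy[:, :4, 3]  # (ny, start s=1..4)
    int_habc21 = y_w @ habc21  # integral over t2 spacing, per start state

    # f1: first coalescence on the internal branch
    p1 = 0.0
    if dtau > 0:
        xs, ws = _graded_nodes(dtau)
        cab = (2.0 / gen_ab.theta[0], 2.0 / gen_ab.theta[1])
        for x, w in zip(xs, ws):
            pab_x = prop_ab(x)
            bridge = prop_ab(dtau - x)
            for s1, pre in ((5, 3), (6, 4)):
                d1 = cab[s1 - 5] * pab_x[0, pre - 1]
                inner = sum(
                    bridge[s1 - 1, s2 - 1] * int_habc21[PHI1[s2] - 1]
                    for s2 in (5, 6)
                )
                p1 += w * d1 * inner

    # f2-f4: both coalescences above the root
    occ = prop_ab(dtau)[0, :4]  # hAB22(dtau, s1)
    x_nodes, x_w = _half_line_nodes(scale)
    pabc = np.stack([prop_abc(t) for t in x_nodes])  # (nx, 20, 20)
    probs = [p1, 0.0, 0.0]
    for block, out_idx in ((range(9, 13), 0), (range(13, 17), 1), (range(17, 21), 2)):
        total = 0.0
        for s1 in (1, 2, 3, 4):
            if occ[s1 - 1] == 0.0:
                continue
            inner = 0.0
            for s2 in block:
                pre, deme = _ABC_PRE[s2]
                c = 2.0 / gen_abc.theta[deme - 1]
                habc32 = c * pabc[:, PHI2[s1] - 1, pre - 1]  # density over t1-tau2
                inner += (x_w @ habc32) * int_habc21[PHI3[s2] - 1]
            total += occ[s1 - 1] * inner
        probs[out_idx] += total
    return tuple(float(p) for p in probs)


@lru_cache(maxsize=100_000)
def _cached_absorption(omega: ModelParameters) -> tuple[float, float, float]:
    return _topology_probabilities_absorption(omega)


def topology_probabilities(
    omega: ModelParameters, method: str = "absorption"
) -> tuple[float, float, float]:
    """Probabilities ``(P_ab, P_ac, P_bc)`` of the three gene-tree topologies.

    ``a`` is the deme-1 sister, ``b`` the deme-2 sister, ``c`` the outgroup
    of ``omega.config``.  The default route propagates the pair chain to the
    root with a matrix exponential and solves the absorbing-class hitting
    probabilities of the triple chain exactly; ``method="quadrature"``
    integrates the joint densities instead (slow; used as a cross-check).
    """
    if method == "absorption":
        return _cached_absorption(omega)
    if method == "quadrature":
        return _topology_probabilities_quadrature(omega)
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Discordance closed form
# ---------------------------------------------------------------------------


def discordance_probability(delta_tau: float, theta: float) -> float:
    """``P[G != sigma] = (2/3) exp(-2*dtau/theta)`` for an internal branch of
    length ``delta_tau`` and within-deme diversity ``theta``."""
    if theta <= 0:
        raise ParameterError("theta must be positive")
    if delta_tau < 0:
        raise ParameterError("delta_tau must be nonnegative")
    return (2.0 / 3.0) * math.exp(-2.0 * delta_tau / theta)


def internal_branch_bound(theta: float, p_min: float = 0.05) -> float:
    """The internal branch length at which discordance falls to ``p_min``:
    the search bound used when fitting topology-only data."""
    if theta <= 0:
        raise ParameterError("theta must be positive")
    if not 0 < p_min < 2.0 / 3.0:
        raise ParameterError("p_min must lie in (0, 2/3)")
    return -(theta / 2.0) * math.log(1.5 * p_min)
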