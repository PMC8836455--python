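"""Flip-model gating algebra and generator matrices.

The flip mechanism describes activation of a ligand-gated channel as a
three-step sequence at each ligation level: agonist binding, a concerted
pre-opening conformational change ("flipping") and pore opening.  At
ligation level ``i`` the flipped/resting equilibrium constant is
``F_i = flip_on_i / flip_off_i`` and the open/shut equilibrium of the
flipped channel is ``E_i = open_rate_i / close_rate_i``.

Because a partial agonist can fail either to flip or to open the flipped
channel, the two steps combine into a single *effective* gating constant

    E_eff = E * F / (F + 1)

and the maximum cluster open probability at saturating agonist (with
desensitisation excised) is

    max Popen = E_eff / (E_eff + 1).

These two relations, together with their inverses, are the desk algebra
used throughout the package; the generator-matrix machinery below turns a
full ``FlipMechanism`` into a continuous-time Markov model for stochastic
and deterministic simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import yaml

__all__ = [
    "FlipMechanism",
    "EfficacyEstimate",
    "GeneratorMatrix",
    "efficacy_from_EF",
    "max_popen_from_efficacy",
    "efficacy_from_max_popen",
    "potency_shift_from_efficacy_fold",
    "build_generator",
    "build_saturated_core",
    "equilibrium_distribution",
    "saturating_concentration",
]

CLASS_OPEN = "open"
CLASS_SHUT = "shut"
CLASS_DESENS = "desensitized"


# ---------------------------------------------------------------------------
# efficacy algebra
# ---------------------------------------------------------------------------

def efficacy_from_EF(E: float, F: float) -> float:
    """Overall gating equilibrium constant E_eff = E*F/(F+1).

    ``E`` is the open/shut equilibrium of the flipped channel and ``F``
    the flipped/resting equilibrium at the same ligation level.
    """
    if E < 0 or F < 0:
        raise ValueError("equilibrium constants must be non-negative")
    return E * F / (F + 1.0)


def max_popen_from_efficacy(e_eff: float) -> float:
    """Maximum open probability E_eff/(E_eff+1) at saturating agonist."""
    if e_eff < 0:
        raise ValueError("E_eff must be non-negative")
    return e_eff / (e_eff + 1.0)


def efficacy_from_max_popen(p: float) -> float:
    """Invert the Popen relation: E_eff = p/(1-p) for p in [0, 1)."""
    if not 0.0 <= p < 1.0:
        raise ValueError("max Popen must lie in [0, 1); p=1 implies infinite efficacy")
    return p / (1.0 - p)


def potency_shift_from_efficacy_fold(fold: float, n_sites: int = 3) -> float:
    """EC50 shift predicted from a fold-change in efficacy alone.

    With ``n_sites`` agonist molecules required for maximal opening, a
    k-fold drop in gating efficacy shifts the EC50 by only k**(1/n_sites)
    (~1.5-fold for k=3 and three binding sites).
    """
    if fold <= 0:
        raise ValueError("fold-change must be positive")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return fold ** (1.0 / n_sites)


@dataclass(frozen=True)
class EfficacyEstimate:
    """Bundle of E, F, the derived E_eff and the implied maximum Popen."""

    E: float | None
    F: float | None
    E_eff: float
    max_popen: float

    @classmethod
    def from_EF(cls, E: float, F: float) -> "EfficacyEstimate":
        e_eff = efficacy_from_EF(E, F)
        return cls(E=E, F=F, E_eff=e_eff, max_popen=max_popen_from_efficacy(e_eff))

    @classmethod
    def from_max_popen(cls, p: float) -> "EfficacyEstimate":
        e_eff = efficacy_from_max_popen(p)
        return cls(E=None, F=None, E_eff=e_eff, max_popen=p)


# ---------------------------------------------------------------------------
# mechanism definition
# ---------------------------------------------------------------------------

def _as_tuple(values, n: int, name: str) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n)
    if arr.size != n:
        raise ValueError(f"{name} must have {n} entries (one per ligation level)")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} entries must be finite and non-negative")
    return tuple(float(x) for x in arr)


@dataclass(frozen=True)
class FlipMechanism:
    """Rate-constant description of an n-site flip mechanism.

    Per-level rate tuples are indexed by ligation level 1..n_sites
    (index 0 = one agonist bound).  ``binding_on[i]`` is the per-site
    association rate constant (/M/s) for the binding step i -> i+1 and
    ``binding_off[i]`` the per-site dissociation rate (/s); statistical
    factors for identical sites are applied when the generator is built.
    Desensitisation couples the fully liganded resting (shut) state to a
    single long-lived desensitised state and is used only to shape
    clusters in simulation.
    """

    n_sites: int = 3
    binding_on: tuple[float, ...] = (5e6, 5e6, 5e6)
    binding_off: tuple[float, ...] = (2000.0, 2000.0, 2000.0)
    flip_on: tuple[float, ...] = (1200.0, 12000.0, 120000.0)
    flip_off: tuple[float, ...] = (15000.0, 15000.0, 15000.0)
    open_rate: tuple[float, ...] = (2660.0, 26600.0, 266000.0)
    close_rate: tuple[float, ...] = (7000.0, 7000.0, 7000.0)
    desens_on: float = 0.0
    desens_off: float = 0.0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        n = self.n_sites
        for name in ("binding_on", "binding_off", "flip_on", "flip_off",
                     "open_rate", "close_rate"):
            object.__setattr__(self, name, _as_tuple(getattr(self, name), n, name))
        for name in ("desens_on", "desens_off"):
            v = float(getattr(self, name))
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, v)

    # -- derived equilibrium constants ------------------------------------
    @property
    def F_levels(self) -> tuple[float, ...]:
        return tuple(fon / foff if foff > 0 else math.inf
                     for fon, foff in zip(self.flip_on, self.flip_off))

    @property
    def E_levels(self) -> tuple[float, ...]:
        return tuple(op / cl if cl > 0 else math.inf
                     for op, cl in zip(self.open_rate, self.close_rate))

    @property
    def E_eff(self) -> float:
        """Effective gating constant of the fully liganded level."""
        return efficacy_from_EF(self.E_levels[-1], self.F_levels[-1])

    @property
    def max_popen(self) -> float:
        return max_popen_from_efficacy(self.E_eff)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_equilibrium(
        cls,
        E: float,
        F: float,
        n_sites: int = 3,
        close_rate: float = 7000.0,
        flip_off: float = 15000.0,
        binding_on: float = 5e6,
        binding_off: float = 2000.0,
        partial_scale: float = 0.1,
        desens_on: float = 0.0,
        desens_off: float = 0.0,
    ) -> "FlipMechanism":
        """Build a mechanism constrained only by fully liganded E and F.

        Absolute rates default to close_rate=7000 /s and flip_off=15000 /s
        with open_rate = E*close_rate and flip_on = F*flip_off; partially
        liganded levels are scaled down by ``partial_scale`` per vacant
        site (E_i = E*scale**(n-i), same for F_i).
        """
        levels = np.arange(1, n_sites + 1)
        E_i = E * partial_scale ** (n_sites - levels)
        F_i = F * partial_scale ** (n_sites - levels)
        return cls(
            n_sites=n_sites,
            binding_on=tuple([binding_on] * n_sites),
            binding_off=tuple([binding_off] * n_sites),
            flip_on=tuple(F_i * flip_off),
            flip_off=tuple([flip_off] * n_sites),
            open_rate=tuple(E_i * close_rate),
            close_rate=tuple([close_rate] * n_sites),
            desens_on=desens_on,
            desens_off=desens_off,
        )

    @classmethod
    def reference(cls, **kwargs) -> "FlipMechanism":
        """Mammalian homomeric reference mechanism (fully liganded E=38, F=8)."""
        return cls.from_equilibrium(E=38.0, F=8.0, **kwargs)

    def with_efficacy_divided(self, fold: float) -> "FlipMechanism":
        """Return a copy with every level's opening rate divided by ``fold``.

        This divides E_i (and hence E_eff) by the same factor, the simplest
        kinetic realisation of a uniform loss of gating efficacy.
        """
        if fold <= 0:
            raise ValueError("fold must be positive")
        return replace(self, open_rate=tuple(r / fold for r in self.open_rate))

    def with_desensitization(self, desens_on: float, desens_off: float) -> "FlipMechanism":
        return replace(self, desens_on=desens_on, desens_off=desens_off)

    # -- config round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "binding_on": list(self.binding_on),
            "binding_off": list(self.binding_off),
            "flip_on": list(self.flip_on),
            "flip_off": list(self.flip_off),
            "open_rate": list(self.open_rate),
            "close_rate": list(self.close_rate),
            "desens_on": self.desens_on,
            "desens_off": self.desens_off,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlipMechanism":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FlipMechanism":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# generator matrices
# ---------------------------------------------------------------------------

@dataclass
class GeneratorMatrix:
    """Continuous-time generator over a mechanism's states at fixed agonist.

    ``rates[i, j]`` is the transition rate (/s) from state i to state j;
    rows sum to zero.  ``state_classes`` labels each state open/shut/
    desensitized for dwell-class aggregation.
    """

    rates: np.ndarray
    state_classes: list[str]
    concentration: float | None = None
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        q = np.asarray(self.rates, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("rates must be a square matrix")
        if len(self.state_classes) != q.shape[0]:
            raise ValueError("state_classes length must match the matrix")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        scale = max(np.abs(q).max(), 1.0)
        if np.any(np.abs(q.sum(axis=1)) > 1e-12 * scale):
            raise ValueError("generator rows must sum to zero")
        self.rates = q
        if not self.state_names:
            self.state_names = [f"s{i}" for i in range(q.shape[0])]

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    @property
    def open_states(self) -> np.ndarray:
        return np.asarray([c == CLASS_OPEN for c in self.state_classes])


def _state_layout(mech: FlipMechanism, with_desens: bool):
    n = mech.n_sites
    names = [f"R{i}" for i in range(n + 1)]
    names += [f"F{i}" for i in range(1, n + 1)]
    names += [f"O{i}" for i in range(1, n + 1)]
    classes = [CLASS_SHUT] * (2 * n + 1) + [CLASS_OPEN] * n
    if with_desens:
        names.append("D")
        classes.append(CLASS_DESENS)
    return names, classes


def build_generator(mech: FlipMechanism, concentration: float) -> GeneratorMatrix:
    """Assemble the generator matrix of ``mech`` at a fixed agonist level.

    Binding transitions scale linearly with concentration and carry the
    statistical factors for identical, independent sites: the forward rate
    for step i -> i+1 is (n-i)*binding_on[i]*c and the backward rate
    (i+1)*binding_off[i].
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    n = mech.n_sites
    with_desens = mech.desens_on > 0 or mech.desens_off > 0
    names, classes = _state_layout(mech, with_desens)
    idx = {name: k for k, name in enumerate(names)}
    m = len(names)
    q = np.zeros((m, m))

    def connect(a: str, b: str, fwd: float, back: float):
        q[idx[a], idx[b]] = fwd
        q[idx[b], idx[a]] = back
        if fwd == 0.0 and back == 0.0:
            _zero_edges.append((a, b))

    _zero_edges: list[tuple[str, str]] = []
    for i in range(n):  # binding along the resting chain
        connect(f"R{i}", f"R{i + 1}",
                (n - i) * mech.binding_on[i] * concentration,
                (i + 1) * mech.binding_off[i])
    for i in range(1, n + 1):  # flipping and opening per liganded level
        connect(f"R{i}", f"F{i}", mech.flip_on[i - 1], mech.flip_off[i - 1])
        connect(f"F{i}", f"O{i}", mech.open_rate[i - 1], mech.close_rate[i - 1])
    if with_desens:
        connect(f"R{n}", "D", mech.desens_on, mech.desens_off)

    # connectivity of the underlying scheme (concentration-independent
    # zero rates disconnect the graph; c=0 alone does not)
    structural = [e for e in _zero_edges
                  if not (e[0].startswith("R") and e[1].startswith("R"))]
    if structural:
        raise ValueError(f"mechanism graph is disconnected at edges {structural}")

    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return GeneratorMatrix(rates=q, state_classes=classes,
                           concentration=concentration, state_names=names)


def build_saturated_core(
    E: float,
    F: float,
    close_rate: float = 7000.0,
    flip_off: float = 15000.0,
    desens_on: float = 0.0,
    desens_off: float = 0.0,
) -> GeneratorMatrix:
    """Three-state saturated flip core AnR <-> AnF <-> AnO.

    At saturating agonist the binding steps are never vacated and the
    mechanism collapses to resting/flipped/open of the top ligation level
    (plus an optional desensitised state off the resting state).  This is
    the minimal model whose equilibrium open occupancy is exactly
    max_popen_from_efficacy(efficacy_from_EF(E, F)).
    """
    flip_on = F * flip_off
    open_rate = E * close_rate
    names = ["R", "F", "O"]
    classes = [CLASS_SHUT, CLASS_SHUT, CLASS_OPEN]
    with_desens = desens_on > 0 or desens_off > 0
    m = 4 if with_desens else 3
    q = np.zeros((m, m))
    q[0, 1], q[1, 0] = flip_on, flip_off
    q[1, 2], q[2, 1] = open_rate, close_rate
    if with_desens:
        names.append("D")
        classes.append(CLASS_DESENS)
        q[0, 3], q[3, 0] = desens_on, desens_off
    np.fill_diagonal(q, -q.sum(axis=1))
    return GeneratorMatrix(rates=q, state_classes=classes,
                           concentration=math.inf, state_names=names)


def equilibrium_distribution(Q: GeneratorMatrix) -> np.ndarray:
    """Stationary occupancy vector of a generator.

    Solved via the null space of the transposed generator.  The chain must
    possess a unique closed communicating class (irreducible chains
    trivially do; a reducible chain with several closed classes has no
    unique stationary law and is rejected).
    """
    q = Q.rates
    n = q.shape[0]
    if n == 1:
        return np.ones(1)
    adj = scipy.sparse.csr_matrix((q - np.diag(np.diag(q))) > 0)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong")
    if n_comp > 1:
        # a class is closed iff no edge leaves it
        closed = []
        for c in range(n_comp):
            members = labels == c
            if not np.any(q[members][:, ~members] > 0):
                closed.append(c)
        if len(closed) != 1:
            raise ValueError("reducible generator: no unique stationary distribution")
    ns = scipy.linalg.null_space(q.T)
    if ns.shape[1] != 1:
        raise ValueError("generator null space is not one-dimensional")
    v = ns[:, 0]
    v = v / v.sum()
    v[np.abs(v) < 1e-15] = 0.0
    if np.any(v < 0):
        raise ValueError("stationary solve produced negative occupancy")
    resid = np.abs(v @ q).max()
    if resid > 1e-10 * max(np.abs(q).max(), 1.0):
        raise ValueError(f"stationary residual too large: {resid:g}")
    return v


def equilibrium_open_probability(Q: GeneratorMatrix) -> float:
    """Equilibrium occupancy of the open class."""
    return float(equilibrium_distribution(Q)[Q.open_states].sum())


def saturating_concentration(mech: FlipMechanism, threshold: float = 1e-3,
                             c_start: float = 1e-6, c_max: float = 10.0) -> float:
    """Smallest doubling concentration at which sub-maximally liganded
    states hold less than ``threshold`` total equilibrium occupancy.

    Desensitisation is zeroed for this computation (it is orthogonal to
    ligation saturation).
    """
    core = replace(mech, desens_on=0.0, desens_off=0.0)
    n = mech.n_sites
    c = c_start
    while c <= c_max:
        Q = build_generator(core, c)
        v = equilibrium_distribution(Q)
        sub = sum(v[i] for i, name in enumerate(Q.state_names)
                  if name not in (f"R{n}", f"F{n}", f"O{n}"))
        if sub < threshold:
            return c
        c *= 2.0
    raise ValueError("no saturating concentration found below c_max")
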