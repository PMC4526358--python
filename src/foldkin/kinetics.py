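"""First-order kinetic schemes with denaturant-dependent elementary rates.

A folding reaction is modeled as a continuous-time first-order network of
conformational states (e.g. the sequential chain ``U <-> I <-> M <-> N' <-> N``
for apomyoglobin).  Each directed transition carries a rate law

    k(urea) = k0 * exp(m_dagger * [urea] / (R*T))

so that ln k is linear in denaturant concentration; ``m_dagger`` (the kinetic
m-value, kcal/mol/M) is negative for steps slowed by urea (folding steps) and
positive for steps accelerated by urea (unfolding steps).

The module builds the probability-conserving generator matrix of a scheme
(columns = source species, columns sum to zero), solves it by
eigendecomposition, and derives the experimental observables: species
populations versus time, fluorescence time courses through a per-species
linear spectral signature, multi-exponential phases with dead-time
(burst-phase) bookkeeping, and free-energy diagrams on the alpha-value
reaction coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "Constants",
    "UreaRateLaw",
    "KineticScheme",
    "SpectralSignature",
    "RateMatrixSolution",
    "PredictedPhase",
    "PhasePrediction",
    "FreeEnergyDiagram",
    "DegenerateRatesError",
    "evaluate_rate",
    "build_rate_matrix",
    "solve_scheme",
    "populations_vs_time",
    "equilibrium_distribution",
    "state_free_energies",
    "predict_fluorescence",
    "predict_phases",
    "free_energy_diagram",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Default temperature: 8 degrees C, the temperature of the reference study.
DEFAULT_TEMPERATURE_K = 281.15

#: Relative tolerance below which an eigenvalue is treated as the stationary
#: (zero) mode of the generator matrix.
ZERO_EIGENVALUE_RTOL = 1e-9

#: Default pre-exponential factor for activation free energies, s^-1.
DEFAULT_PREFACTOR = 1.0e6

#: Default amplitude floor (relative fluorescence) below which an attenuated
#: phase is booked as a burst phase.
DEFAULT_AMPLITUDE_FLOOR = 0.01


class DegenerateRatesError(ValueError):
    """Raised when a rate matrix is defective (degenerate apparent rates)."""


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants: gas constant and absolute temperature."""

    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError("temperature must be positive and finite")
        if not np.isfinite(self.gas_constant) or self.gas_constant <= 0:
            raise ValueError("gas_constant must be positive and finite")

    @property
    def RT(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class UreaRateLaw:
    """Log-linear denaturant dependence of one elementary rate constant.

    Parameters
    ----------
    k0:
        Elementary rate constant at 0 M urea, s^-1 (must be positive).
    m_dagger:
        Kinetic m-value, kcal mol^-1 M^-1.  Sign free: negative slows the
        step with urea, positive accelerates it.
    """

    k0: float
    m_dagger: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.k0) or self.k0 <= 0:
            raise ValueError(f"k0 must be positive and finite, got {self.k0}")
        if not np.isfinite(self.m_dagger):
            raise ValueError("m_dagger must be finite")

    def rate(self, urea: float, constants: Constants) -> float:
        """Evaluate k(urea) = k0 * exp(m_dagger * urea / RT)."""
        return evaluate_rate(self, urea, constants)


def evaluate_rate(law: UreaRateLaw, urea, constants: Constants):
    """Elementary rate constant at a given urea concentration.

    Accepts a scalar or array urea (M, must be >= 0 and finite); returns
    rate(s) in s^-1.
    """
    urea = np.asarray(urea, dtype=float)
    if not np.all(np.isfinite(urea)) or np.any(urea < 0):
        raise ValueError("urea concentrations must be finite and >= 0")
    out = law.k0 * np.exp(law.m_dagger * urea / constants.RT)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KineticScheme:
    """A reversible first-order network of species with urea-dependent rates.

    ``transitions`` maps directed pairs ``(source, target)`` to rate laws.
    Every transition must have its reverse present (microscopic
    reversibility), self-transitions are forbidden, and the network must be
    connected.
    """

    species: tuple[str, ...]
    transitions: Mapping[tuple[str, str], UreaRateLaw]
    constants: Constants = field(default_factory=Constants)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if len(self.species) < 2:
            raise ValueError("a scheme needs at least two species")
        for (a, b) in self.transitions:
            if a == b:
                raise ValueError(f"self-transition {a}->{b} not allowed")
            if a not in self.species or b not in self.species:
                raise ValueError(f"transition {a}->{b} uses unknown species")
            if (b, a) not in self.transitions:
                raise ValueError(f"reverse of transition {a}->{b} is missing")
        if not self._connected():
            raise ValueError("kinetic scheme is disconnected")

    def _adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {s: set() for s in self.species}
        for (a, b) in self.transitions:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def _connected(self) -> bool:
        adj = self._adjacency()
        seen = {self.species[0]}
        stack = [self.species[0]]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(self.species)

    @property
    def is_chain(self) -> bool:
        """True if the connectivity is a linear chain (every degree <= 2)."""
        degs = [len(v) for v in self._adjacency().values()]
        return max(degs) <= 2 and degs.count(1) == 2

    def chain_path(self, start: str) -> tuple[str, ...]:
        """Species ordered along the chain starting from endpoint ``start``."""
        if not self.is_chain:
            raise ValueError("scheme is not a linear chain")
        adj = self._adjacency()
        if len(adj[start]) != 1:
            raise ValueError(f"{start!r} is not a chain endpoint")
        path = [start]
        prev = None
        while len(path) < len(self.species):
            nxt = [s for s in adj[path[-1]] if s != prev]
            prev = path[-1]
            path.append(nxt[0])
        return tuple(path)

    @classmethod
    def chain(
        cls,
        species: Sequence[str],
        laws: Mapping[tuple[str, str], UreaRateLaw],
        constants: Constants | None = None,
    ) -> "KineticScheme":
        """Build a sequential chain from adjacent-pair rate laws."""
        return cls(tuple(species), dict(laws), constants or Constants())

    def rate_matrix(self, urea: float) -> np.ndarray:
        return build_rate_matrix(self, urea)

    def index(self, species: str) -> int:
        return self.species.index(species)


@dataclass(frozen=True)
class SpectralSignature:
    """Per-species relative fluorescence: intercept at 0 M urea plus a linear
    urea slope (relative to the acid-unfolded protein at pH 2.0 == 1)."""

    values: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for sp, (intercept, slope) in self.values.items():
            if not np.isfinite(intercept) or intercept <= 0:
                raise ValueError(f"intercept for {sp!r} must be positive")
            if not np.isfinite(slope):
                raise ValueError(f"slope for {sp!r} must be finite")

    def signal(self, species: str, urea: float) -> float:
        intercept, slope = self.values[species]
        return intercept + slope * urea

    def vector(self, species_order: Sequence[str], urea: float) -> np.ndarray:
        missing = [s for s in species_order if s not in self.values]
        if missing:
            raise KeyError(f"spectral signature missing species {missing}")
        return np.array([self.signal(s, urea) for s in species_order])


def build_rate_matrix(scheme: KineticScheme, urea: float) -> np.ndarray:
    """Probability-conserving generator matrix of a scheme at one urea.

    Entry ``(j, i)`` (row = target, column = source) is the elementary rate
    of the ``i -> j`` transition; diagonal entries are minus the column sums,
    so every column sums to zero (mass conservation by construction).
    """
    n = len(scheme.species)
    K = np.zeros((n, n))
    for (a, b), law in scheme.transitions.items():
        K[scheme.index(b), scheme.index(a)] = evaluate_rate(law, urea, scheme.constants)
    K[np.diag_indices(n)] = -K.sum(axis=0)
    return K


@dataclass(frozen=True)
class RateMatrixSolution:
    """Eigendecomposition of a generator matrix.

    ``eigenvalues`` are real and sorted ascending in magnitude (the first is
    the stationary zero mode); ``eigenvectors`` holds the matching right
    eigenvectors as columns; ``equilibrium`` is the stationary distribution
    normalized to sum to one.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    equilibrium: np.ndarray

    @property
    def apparent_rates(self) -> np.ndarray:
        """Magnitudes of the nonzero eigenvalues, sorted ascending."""
        return np.abs(self.eigenvalues[1:])


def _perturb_degenerate(matrix: np.ndarray) -> np.ndarray:
    """Deterministically perturb off-diagonal rates by 1 part in 1e9."""
    n = matrix.shape[0]
    out = matrix.copy()
    for i in range(n):
        for j in range(n):
            if i != j and out[i, j] > 0:
                out[i, j] *= 1.0 + 1e-9 * ((i + n * j) % (n * n)) / (n * n)
    out[np.diag_indices(n)] = 0.0
    out[np.diag_indices(n)] = -out.sum(axis=0)
    return out


def solve_scheme(matrix: np.ndarray) -> RateMatrixSolution:
    """Solve a generator matrix: eigenvalues, eigenvectors, equilibrium.

    For a connected reversible scheme there is exactly one zero eigenvalue
    (within ``ZERO_EIGENVALUE_RTOL`` relative to the largest magnitude) and
    all others are negative; apparent (observable) rate constants are the
    magnitudes of the nonzero eigenvalues.  Raises
    :class:`DegenerateRatesError` if the matrix is defective within
    tolerance even after an infinitesimal deterministic perturbation.
    """
    matrix = np.asarray(matrix, dtype=float)
    colsums = matrix.sum(axis=0)
    scale = np.max(np.abs(matrix)) or 1.0
    if np.max(np.abs(colsums)) > 1e-8 * scale:
        raise ValueError("not a generator matrix: columns do not sum to zero")

    vals, vecs = np.linalg.eig(matrix)
    if np.max(np.abs(vals.imag)) > 1e-8 * scale:
        raise DegenerateRatesError("complex eigenvalues: scheme is not reversible")
    vals = vals.real
    vecs = vecs.real

    # Detect (near-)degenerate nonzero eigenvalues -> perturb and warn.
    svals = np.sort(np.abs(vals))
    gaps = np.diff(svals[1:])
    if len(gaps) and np.any(gaps < 1e-9 * svals[-1]):
        warnings.warn(
            "near-degenerate apparent rates; rates perturbed by 1 part in 1e9",
            stacklevel=2,
        )
        matrix = _perturb_degenerate(matrix)
        vals, vecs = np.linalg.eig(matrix)
        vals, vecs = vals.real, vecs.real
        svals = np.sort(np.abs(vals))
        gaps = np.diff(svals[1:])
        if len(gaps) and np.any(gaps < 1e-12 * svals[-1]):
            raise DegenerateRatesError("degenerate apparent rate constants")

    order = np.argsort(np.abs(vals))
    vals = vals[order]
    vecs = vecs[:, order]

    zero_mask = np.abs(vals) < ZERO_EIGENVALUE_RTOL * np.max(np.abs(vals))
    if zero_mask.sum() != 1:
        raise DegenerateRatesError(
            f"expected exactly one stationary mode, found {int(zero_mask.sum())}"
        )
    vals[0] = 0.0

    eq = vecs[:, 0]
    eq = eq / eq.sum()
    if np.any(eq < -1e-12):
        raise DegenerateRatesError("stationary distribution has negative entries")
    eq = np.clip(eq, 0.0, None)
    eq = eq / eq.sum()
    return RateMatrixSolution(matrix=matrix, eigenvalues=vals, eigenvectors=vecs, equilibrium=eq)


def populations_vs_time(
    solution: RateMatrixSolution,
    initial: Sequence[float],
    times: Sequence[float],
) -> np.ndarray:
    """Species fraction trajectories, shape ``(n_species, n_times)``.

    ``initial`` must be a probability vector.  Trajectories conserve total
    probability at every time and converge to ``solution.equilibrium`` as
    t -> infinity.
    """
    p0 = np.asarray(initial, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial fractions must be nonnegative and sum to 1")
    coef = np.linalg.solve(solution.eigenvectors, p0)
    # (n, k) @ (k, nt)
    return solution.eigenvectors @ (coef[:, None] * np.exp(np.outer(solution.eigenvalues, t)))


def equilibrium_distribution(scheme: KineticScheme, urea: float) -> dict[str, float]:
    """Stationary species fractions of a scheme at one urea concentration."""
    sol = solve_scheme(build_rate_matrix(scheme, urea))
    return dict(zip(scheme.species, sol.equilibrium))


def state_free_energies(scheme: KineticScheme, urea: float, reference: str = "N") -> dict[str, float]:
    """Free energies (kcal/mol) of every species relative to ``reference``.

    Computed from the stationary distribution, G_s = -RT ln(p_s / p_ref),
    which for a reversible chain equals the cumulative -RT ln of stepwise
    equilibrium constants.
    """
    eq = equilibrium_distribution(scheme, urea)
    RT = scheme.constants.RT
    pref = eq[reference]
    return {s: -RT * np.log(p / pref) for s, p in eq.items()}


def predict_fluorescence(
    scheme: KineticScheme,
    signature: SpectralSignature,
    initial: Sequence[float],
    urea: float,
    times: Sequence[float],
) -> np.ndarray:
    """Noise-free fluorescence trace F(t) = sum_s p_s(t) * f_s(urea)."""
    f = signature.vector(scheme.species, urea)
    sol = solve_scheme(build_rate_matrix(scheme, urea))
    return f @ populations_vs_time(sol, initial, times)


@dataclass(frozen=True)
class PredictedPhase:
    """One exponential phase of the observable fluorescence decay."""

    rate: float                 # apparent rate constant |lambda|, s^-1
    amplitude: float            # true amplitude F_i at t = 0
    attenuated_amplitude: float  # amplitude surviving the dead time
    observable: bool            # False -> booked as a burst phase


@dataclass(frozen=True)
class PhasePrediction:
    """Exact phase decomposition of a predicted trace plus burst bookkeeping.

    ``cumulative`` maps each observable phase index (into ``phases``) to the
    cumulative amplitude F_eq + sum of this and all slower observable
    amplitudes -- the fluorescence the trace would show at t = 0 in the
    absence of the faster phases.
    """

    F_eq: float
    phases: tuple[PredictedPhase, ...]   # sorted by rate, descending
    cumulative: Mapping[int, float]
    urea: float
    dead_time: float

    @property
    def observable_phases(self) -> tuple[PredictedPhase, ...]:
        return tuple(p for p in self.phases if p.observable)

    def value_at(self, t: float) -> float:
        return self.F_eq + sum(p.amplitude * np.exp(-p.rate * t) for p in self.phases)


def predict_phases(
    scheme: KineticScheme,
    signature: SpectralSignature,
    initial: Sequence[float],
    urea: float,
    dead_time: float = 0.0,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
) -> PhasePrediction:
    """Exact amplitudes and rates of the observable phases of a trace.

    Amplitudes come from the eigenvector projection of the initial condition
    onto the fluorescence observable.  A phase is flagged unobservable
    (burst) when dead-time attenuation brings its amplitude below
    ``amplitude_floor`` or when its relaxation time is shorter than a fifth
    of the dead time.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    f = signature.vector(scheme.species, urea)
    sol = solve_scheme(build_rate_matrix(scheme, urea))
    p0 = np.asarray(initial, dtype=float)
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial fractions must be nonnegative and sum to 1")
    coef = np.linalg.solve(sol.eigenvectors, p0)
    amps = (f @ sol.eigenvectors) * coef  # amplitude of each eigenmode
    F_eq = float(amps[0])

    phases = []
    for lam, amp in zip(sol.eigenvalues[1:], amps[1:]):
        rate = float(abs(lam))
        att = float(amp * np.exp(-rate * dead_time))
        observable = abs(att) >= amplitude_floor and (1.0 / rate) >= dead_time / 5.0
        phases.append(
            PredictedPhase(
                rate=rate, amplitude=float(amp),
                attenuated_amplitude=att, observable=observable,
            )
        )
    phases.sort(key=lambda p: p.rate, reverse=True)

    cumulative: dict[int, float] = {}
    running = F_eq
    for idx in reversed(range(len(phases))):  # slow -> fast
        if phases[idx].observable:
            running += phases[idx].amplitude
            cumulative[idx] = running
    return PhasePrediction(
        F_eq=F_eq, phases=tuple(phases), cumulative=cumulative,
        urea=urea, dead_time=dead_time,
    )


@dataclass(frozen=True)
class FreeEnergyDiagram:
    """Free energies of states and barriers on the alpha reaction coordinate.

    ``states`` and ``barriers`` list ``(label, alpha, dG)`` with dG in
    kcal/mol relative to the native state; the barrier dG is the absolute
    height (departing-state dG plus the activation free energy
    -RT ln(k0/A0) - m_dagger * [urea]).  alpha is the cumulative kinetic
    m-value from N normalized so alpha(N) = 0 and alpha(U) = 1.
    """

    states: tuple[tuple[str, float, float], ...]
    barriers: tuple[tuple[str, float, float], ...]
    urea: float
    A0: float

    def state(self, label: str) -> tuple[float, float]:
        for lab, alpha, dg in self.states:
            if lab == label:
                return alpha, dg
        raise KeyError(label)


def free_energy_diagram(
    scheme: KineticScheme,
    urea: float,
    A0: float = DEFAULT_PREFACTOR,
    native: str = "N",
    unfolded: str = "U",
) -> FreeEnergyDiagram:
    """Free-energy diagram of a chain scheme at one urea concentration.

    The chain is traversed from the native end; state free energies
    accumulate -RT ln of the stepwise equilibrium constants, barrier heights
    follow from the elementary rates and the pre-exponential factor ``A0``,
    and the alpha coordinate accumulates the kinetic m-values from N,
    normalized to 1 at the unfolded end.
    """
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    path = scheme.chain_path(native)
    if path[-1] != unfolded:
        raise ValueError(f"chain does not end at {unfolded!r}")
    RT = scheme.constants.RT

    states = [(native, 0.0, 0.0)]
    barriers = []
    g = 0.0
    pos = 0.0
    for a, b in zip(path[:-1], path[1:]):  # a closer to N
        away = scheme.transitions[(a, b)]
        back = scheme.transitions[(b, a)]
        dg_act = -RT * np.log(away.k0 / A0) - away.m_dagger * urea
        barriers.append((f"{a}-{b}", pos + away.m_dagger, g + dg_act))
        g = g + (-RT * np.log(away.k0 / back.k0)) - (away.m_dagger - back.m_dagger) * urea
        pos = pos + away.m_dagger - back.m_dagger
        states.append((b, pos, g))
    total = pos
    if abs(total) < 1e-12:
        raise ValueError("total kinetic m-value is zero; alpha undefined")
    states = tuple((lab, p / total, dg) for lab, p, dg in states)
    barriers = tuple((lab, p / total, dg) for lab, p, dg in barriers)
    return FreeEnergyDiagram(states=states, barriers=barriers, urea=urea, A0=A0)
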