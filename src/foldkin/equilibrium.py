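"""Three-state linear-extrapolation (LEM) equilibrium unfolding analysis.

The equilibrium unfolding of a protein populating a native (N), intermediate
(M) and unfolded (U) state is described by two sequential transitions
N <-> M <-> U, each with a linear free-energy dependence on denaturant:

    dG_i(urea) = dG0_i - m_i * [urea],   dG0_i = m_i * Cm_i

Species fractions follow from the two equilibrium constants; the observable
signal on every spectroscopic channel (a fluorescence wavelength or a CD
band) is the fraction-weighted sum of per-species linear baselines.  A
global fit shares the thermodynamic parameters (Cm_i, m_i) across channels
while each channel keeps its own baselines.

The fit is parameterized in (Cm, m) with dG derived, and exploits the fact
that, given the thermodynamic parameters, the baselines enter linearly: the
inner linear problem is solved exactly per channel (variable projection), so
the nonlinear search runs over four parameters only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .kinetics import Constants

__all__ = [
    "EquilibriumModel",
    "ChannelBaselines",
    "GlobalFitResult",
    "three_state_fractions",
    "max_intermediate",
    "predict_channel",
    "global_fit",
    "helix_content",
]

SPECIES = ("N", "M", "U")

#: Mean-residue ellipticity references at 222 nm (deg cm^2 dmol^-1) for the
#: fully helical and random-coil limits, per the Chen et al. convention.
#: Both are configuration, not fitted quantities.
HELIX_REFERENCE_222 = -32640.0
COIL_REFERENCE_222 = -2340.0


@dataclass(frozen=True)
class EquilibriumModel:
    """Shared thermodynamics of the three-state model.

    Transition 1 is N <-> M and transition 2 is M <-> U (folding direction
    N -> M -> U as the rows of the reference parameter table).  ``dG`` values
    and the composite N <-> U parameters are derived: dG_i = m_i * Cm_i,
    dG3 = dG1 + dG2, m3 = m1 + m2.
    """

    m1: float
    Cm1: float
    m2: float
    Cm2: float
    constants: Constants = field(default_factory=Constants)

    def __post_init__(self) -> None:
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("m-values must be positive")
        if self.Cm1 < 0 or self.Cm2 < 0:
            raise ValueError("midpoints must be >= 0")

    @property
    def dG1(self) -> float:
        return self.m1 * self.Cm1

    @property
    def dG2(self) -> float:
        return self.m2 * self.Cm2

    @property
    def dG3(self) -> float:
        return self.dG1 + self.dG2

    @property
    def m3(self) -> float:
        return self.m1 + self.m2

    @property
    def Cm3(self) -> float:
        return self.dG3 / self.m3


def three_state_fractions(model: EquilibriumModel, urea):
    """Fractions (fN, fM, fU) at one or many urea concentrations.

    K1 = exp((m1*urea - dG1)/RT) governs N <-> M and K2 the M <-> U step;
    fN = 1/(1 + K1 + K1*K2), fM = K1*fN, fU = K1*K2*fN.
    """
    urea = np.asarray(urea, dtype=float)
    if np.any(urea < 0):
        raise ValueError("urea must be >= 0")
    RT = model.constants.RT
    K1 = np.exp(np.clip((model.m1 * urea - model.dG1) / RT, -500, 500))
    K2 = np.exp(np.clip((model.m2 * urea - model.dG2) / RT, -500, 500))
    fN = 1.0 / (1.0 + K1 + K1 * K2)
    fM = K1 * fN
    fU = K1 * K2 * fN
    return fN, fM, fU


def max_intermediate(model: EquilibriumModel) -> float:
    """Urea concentration maximizing the intermediate fraction fM.

    At the maximum the stationarity condition m1 = m2 * K1 * K2 holds.  The
    maximum is found by bounded 1-D minimization of -fM; it is unbounded
    (never reached) if m2 <= 0, which the model constructor already rejects.
    """
    def neg_fM(u):
        return -three_state_fractions(model, u)[1]

    hi = model.Cm1 + model.Cm2 + 10.0
    res = scipy.optimize.minimize_scalar(neg_fM, bounds=(0.0, hi), method="bounded",
                                         options={"xatol": 1e-10})
    return float(res.x)


@dataclass(frozen=True)
class ChannelBaselines:
    """Per-channel, per-species linear baselines.

    ``values[channel][species]`` is an ``(intercept, slope)`` pair giving the
    pure-species signal intercept at 0 M urea and its linear urea slope.
    """

    values: Mapping[str, Mapping[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        for ch, per_species in self.values.items():
            missing = [s for s in SPECIES if s not in per_species]
            if missing:
                raise ValueError(f"channel {ch!r} missing baselines for {missing}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.values.keys())

    def signal(self, channel: str, species: str, urea) -> np.ndarray:
        intercept, slope = self.values[channel][species]
        return intercept + slope * np.asarray(urea, dtype=float)


def predict_channel(
    model: EquilibriumModel,
    baselines: ChannelBaselines,
    channel: str,
    urea,
):
    """Observable signal of one channel: fraction-weighted species baselines."""
    if channel not in baselines.values:
        raise KeyError(f"unknown channel {channel!r}")
    fractions = three_state_fractions(model, urea)
    out = sum(
        f * baselines.signal(channel, sp, urea)
        for sp, f in zip(SPECIES, fractions)
    )
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class GlobalFitResult:
    model: EquilibriumModel
    baselines: ChannelBaselines
    stderr: Mapping[str, float]          # on (m1, Cm1, m2, Cm2)
    rss: float
    n_points: int
    multistart_rss: tuple[float, ...]    # best objective per start


def _design_matrix(fractions, urea, free_slopes):
    """Per-channel linear design: columns are species intercepts then the
    species slopes that are free."""
    fN, fM, fU = fractions
    cols = [fN, fM, fU]
    for i, sp in enumerate(SPECIES):
        if sp in free_slopes:
            cols.append([fN, fM, fU][i] * urea)
    return np.column_stack(cols)


def global_fit(
    dataset: pd.DataFrame,
    init: EquilibriumModel,
    n_starts: int = 8,
    seed: int = 0,
    fixed_zero_slopes: Mapping[str, Sequence[str]] | None = None,
    channel_sigma: Mapping[str, float] | None = None,
) -> GlobalFitResult:
    """Global nonlinear least-squares fit of multi-channel unfolding curves.

    ``dataset`` needs columns ``channel``, ``urea_M``, ``signal``.  The four
    thermodynamic parameters are shared across channels; per-channel species
    baselines (intercept + slope) are local and solved exactly by linear
    least squares at every step (variable projection).  A seeded multistart
    (>= 8 starts, log-perturbed around ``init``) guards against local
    minima; standard errors on the shared parameters come from the
    goodness-of-fit-based Jacobian covariance at the optimum.

    Channels are weighted by their noise: an explicit ``channel_sigma``
    mapping, a ``sigma`` column in the dataset, or (by default) a two-pass
    estimate from the per-channel residual spread of an unweighted first
    fit -- necessary when channels live on different signal scales (e.g.
    fluorescence next to ellipticity).

    ``fixed_zero_slopes`` pins selected per-channel species slopes at zero
    (e.g. the weakly identifiable intermediate baseline slope of a CD
    channel); by default all slopes are free.
    """
    required = {"channel", "urea_M", "signal"}
    if not required.issubset(dataset.columns):
        raise ValueError(f"dataset must have columns {sorted(required)}")
    fixed_zero_slopes = dict(fixed_zero_slopes or {})
    channels = list(dict.fromkeys(dataset["channel"]))
    groups = {}
    for ch in channels:
        sub = dataset[dataset["channel"] == ch]
        if channel_sigma is not None:
            sig = float(channel_sigma[ch])
        elif "sigma" in dataset.columns:
            sig = float(sub["sigma"].iloc[0])
        else:
            sig = None  # filled by the two-pass estimate below
        groups[ch] = [sub["urea_M"].to_numpy(float),
                      sub["signal"].to_numpy(float), sig]
    for ch, (u, _, _) in groups.items():
        if len(u) < 6:
            warnings.warn(f"channel {ch!r} has fewer than 6 urea points")
    constants = init.constants

    def free_slopes(ch):
        pinned = set(fixed_zero_slopes.get(ch, ()))
        return [s for s in SPECIES if s not in pinned]

    def residuals(theta, use_weights=True):
        m1, Cm1 = np.exp(theta[0]), theta[1]
        m2, Cm2 = np.exp(theta[2]), theta[3]
        try:
            model = EquilibriumModel(m1, max(Cm1, 0.0), m2, max(Cm2, 0.0),
                                     constants=constants)
        except ValueError:
            return np.full(len(dataset), 1e6)
        res = []
        for ch in channels:
            u, y, sig = groups[ch]
            w = 1.0 / sig if (use_weights and sig) else 1.0 / max(np.ptp(y), 1e-12)
            fr = three_state_fractions(model, u)
            X = _design_matrix(fr, u, free_slopes(ch))
            if not np.all(np.isfinite(X)):
                return np.full(len(dataset), 1e6)
            try:
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            except np.linalg.LinAlgError:
                return np.full(len(dataset), 1e6)
            res.append(w * (y - X @ beta))
        return np.concatenate(res)

    def pack(model):
        return np.array([np.log(model.m1), model.Cm1, np.log(model.m2), model.Cm2])

    rng = np.random.default_rng(seed)
    lo = np.array([-5.0, 0.0, -5.0, 0.0])
    hi = np.array([5.0, 20.0, 5.0, 20.0])

    def solve_from(theta0):
        return scipy.optimize.least_squares(
            residuals, np.clip(theta0, lo, hi), method="trf", bounds=(lo, hi),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)

    best = None
    start_rss = []
    for k in range(max(n_starts, 1)):
        theta0 = pack(init)
        if k > 0:
            theta0 = theta0 + rng.normal(scale=[0.3, 0.3, 0.3, 0.3])
            theta0[1] = abs(theta0[1])
            theta0[3] = abs(theta0[3])
        sol = solve_from(theta0)
        rss = float(np.sum(sol.fun ** 2))
        start_rss.append(rss)
        if best is None or rss < best[0] * (1 - 1e-10):
            best = (rss, sol)
    rss, sol = best

    if any(groups[ch][2] is None for ch in channels):
        # second pass: estimate per-channel noise at the optimum, reweight
        theta = sol.x
        model = EquilibriumModel(float(np.exp(theta[0])), float(theta[1]),
                                 float(np.exp(theta[2])), float(theta[3]),
                                 constants=constants)
        for ch in channels:
            u, y, _ = groups[ch]
            fr = three_state_fractions(model, u)
            X = _design_matrix(fr, u, free_slopes(ch))
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            # unbiased noise estimate: account for the fitted local (and a
            # share of the shared) parameters
            dof_ch = max(len(y) - X.shape[1] - 4 / len(channels), 1.0)
            sig = float(np.sqrt(np.sum(resid ** 2) / dof_ch))
            groups[ch][2] = max(sig, 1e-10 * max(np.ptp(y), 1.0))
        sol = solve_from(sol.x)
        rss = float(np.sum(sol.fun ** 2))

    theta = sol.x
    model = EquilibriumModel(float(np.exp(theta[0])), float(theta[1]),
                             float(np.exp(theta[2])), float(theta[3]),
                             constants=constants)

    # Recover per-channel baselines at the optimum.
    base = {}
    for ch in channels:
        u, y, _ = groups[ch]
        fr = three_state_fractions(model, u)
        fs = free_slopes(ch)
        X = _design_matrix(fr, u, fs)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        per = {}
        for i, sp in enumerate(SPECIES):
            slope = beta[3 + fs.index(sp)] if sp in fs else 0.0
            per[sp] = (float(beta[i]), float(slope))
        base[ch] = per
    baselines = ChannelBaselines(base)

    # Standard errors from the Jacobian of the projected objective.
    n, p = len(dataset), 4
    J = sol.jac
    dof = max(n - (p + sum(3 + len(free_slopes(ch)) for ch in channels)), 1)
    s2 = rss / dof
    JTJ = J.T @ J
    sv = np.linalg.svd(JTJ, compute_uv=False)
    if sv[-1] < 1e-12 * sv[0]:
        warnings.warn(
            "rank-deficient design: one transition's parameters are "
            "unidentifiable from the supplied channels"
        )
        cov = np.linalg.pinv(JTJ) * s2
    else:
        cov = np.linalg.inv(JTJ) * s2
    se_theta = np.sqrt(np.diag(cov))
    # delta method for the log-parameterized m-values
    stderr = {
        "m1": float(se_theta[0] * model.m1),
        "Cm1": float(se_theta[1]),
        "m2": float(se_theta[2] * model.m2),
        "Cm2": float(se_theta[3]),
    }
    return GlobalFitResult(
        model=model, baselines=baselines, stderr=stderr,
        rss=rss, n_points=n, multistart_rss=tuple(start_rss),
    )


def helix_content(
    mre222: float,
    coil_reference: float = COIL_REFERENCE_222,
    helix_reference: float = HELIX_REFERENCE_222,
) -> float:
    """Helix fraction from mean-residue ellipticity at 222 nm.

    Linear map (mre222 - coil)/(helix - coil), clipped to [0, 1] with a
    warning outside.  ``helix_reference`` must be below ``coil_reference``
    (both are configurable conventions).
    """
    if helix_reference == coil_reference:
        raise ValueError("helix and coil references must differ")
    if helix_reference > coil_reference:
        raise ValueError("helix_reference must be below coil_reference")
    frac = (mre222 - coil_reference) / (helix_reference - coil_reference)
    if frac < 0 or frac > 1:
        warnings.warn(f"helix content {frac:.3f} outside [0, 1]; clipped")
    return float(np.clip(frac, 0.0, 1.0))
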