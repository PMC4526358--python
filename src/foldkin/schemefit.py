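"""Global optimization of kinetic schemes against folding observables.

The experimental summary of a folding study -- apparent rate constants
(chevron plot), cumulative amplitudes, and the equilibrium signal versus
denaturant -- is confronted with candidate first-order schemes.  The
elementary rate laws and species fluorescence intercepts are optimized by
seeded multistart bounded least squares; rate residuals are taken in log
space (the observables span four decades) while amplitude and equilibrium
residuals are linear, and the three blocks are weighted to contribute
equally per degree of freedom by default.

For a step that equilibrates within the instrument dead time (U <-> I in
the reference five-state scheme) only the equilibrium ratio of its two rate
constants is identifiable; such steps are parameterized as (ratio, fixed
fast exchange rate), with the exchange fixed at ten times the dead-rate.

Derived thermodynamics (stepwise and aggregate stabilities, m-values and
midpoints) are computed from the elementary constants, and candidate
schemes (the five-state chain, four-state chains lacking one intermediate,
and off-pathway permutations) are ranked by their optimized residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.optimize

from .kinetics import (
    Constants,
    KineticScheme,
    SpectralSignature,
    UreaRateLaw,
    build_rate_matrix,
    equilibrium_distribution,
    predict_phases,
    solve_scheme,
)
from .traces import REFOLD_08M, REFOLD_PH2, UNFOLD

__all__ = [
    "ObservationSet",
    "DerivedThermo",
    "SchemeParameterization",
    "SchemeFitResult",
    "objective",
    "residual_vector",
    "build_observations",
    "heuristic_init",
    "fit_scheme",
    "derived_thermo",
    "compare_schemes",
    "default_candidates",
    "recover_burst_intensity",
]

#: Log-space residual assigned when an observed phase has no predicted
#: counterpart (large, finite, keeps the objective differentiable elsewhere).
MISSING_PHASE_PENALTY = 10.0

#: Fixed unfolding-direction kinetic m-value of a ratio-parameterized
#: (sub-dead-time) exchange step, kcal/mol/M.
RATIO_STEP_M_UNFOLD = 0.20

LN_K_BOUNDS = (np.log(1e-3), np.log(1e8))
M_BOUND = 5.0


@dataclass(frozen=True)
class ObservationSet:
    """Observables a scheme is fitted against.

    ``chevron`` is the table produced by :func:`foldkin.traces.assemble_chevron`
    (plus a ``dead_time`` column); ``equilibrium`` optionally adds
    (urea_M, signal) points of the equilibrium fluorescence on the same
    relative scale as the kinetic signature.
    """

    chevron: pd.DataFrame
    equilibrium: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        need = {"urea_M", "phase_label", "rate_s", "F_eq", "condition"}
        if not need.issubset(self.chevron.columns):
            raise ValueError(f"chevron table must have columns {sorted(need)}")
        if len(self.chevron) == 0:
            raise ValueError("empty observation set")
        if "dead_time" not in self.chevron.columns:
            raise ValueError("chevron table needs a dead_time column")


def build_observations(chevron: pd.DataFrame,
                       equilibrium: pd.DataFrame | None = None,
                       amplitude_floor: float = 0.01) -> ObservationSet:
    """Curate an assembled chevron table into fit-ready observations.

    Continuous-flow and stopped-flow traces each resolve only part of the
    kinetics, so records are filtered by what the observation window can
    actually determine:

    * phase rows whose relaxation time exceeds half the trace window
      (rate < 2 / t_max) are dropped -- their rate and the trace's F_eq are
      extrapolations, although the plateau combinations (the cumulative
      amplitudes) remain well determined and are kept;
    * phase rows whose dead-time-attenuated amplitude falls below
      ``amplitude_floor``, or below three times the trace's residual noise
      level, are dropped: the instrument that produced the trace could not
      genuinely resolve them (the same observability rule applied to model
      predictions, plus a signal-to-noise guard);
    * F_eq is blanked for traces whose slowest phase was unresolved;
    * the deepest cumulative amplitude (F0R1 / F0U1) is blanked for
      single-phase fits whose lone phase is the slow one, because the trace
      cannot back-extrapolate through a fast phase it never saw (it lies
      within the dead time of that device).
    """
    chev = chevron.copy()
    if "t_max" not in chev.columns:
        chev["t_max"] = np.inf
    in_window = chev["rate_s"] >= 2.0 / chev["t_max"]
    resolved = in_window.copy()
    if "amplitude" in chev.columns:
        attenuated = (chev["amplitude"].abs()
                      * np.exp(-chev["rate_s"] * chev["dead_time"]))
        floor = amplitude_floor
        if "noise_sd" in chev.columns:
            floor = np.maximum(amplitude_floor, 3.0 * chev["noise_sd"])
        resolved &= attenuated >= floor
    if "fit_flags" in chev.columns:
        resolved &= ~chev["fit_flags"].fillna("").str.contains("ill-conditioned")
    for (urea, cond, dead), grp in chev.groupby(["urea_M", "condition", "dead_time"],
                                                sort=False):
        idx = grp.index
        slowest = grp["rate_s"].idxmin()
        if not in_window[slowest]:
            chev.loc[idx, "F_eq"] = np.nan
        if "n_phases" in chev.columns and (grp["n_phases"] == 1).all():
            if set(grp["phase_label"]) == {"2"}:
                col = "F0R1" if cond == REFOLD_PH2 else "F0U1"
                if col in chev.columns:
                    chev.loc[idx, col] = np.nan
    chev = chev[resolved].reset_index(drop=True)
    return ObservationSet(chevron=chev, equilibrium=equilibrium)


def initial_populations_for(scheme: KineticScheme, condition: str) -> np.ndarray:
    """Initial fractions for a condition, for an arbitrary scheme containing
    a ``U`` species: all-U for refolding from the acid-unfolded state, the
    0.8 M equilibrium for refolding from 0.8 M urea, and the 0 M equilibrium
    for unfolding."""
    if condition == REFOLD_PH2:
        p = np.zeros(len(scheme.species))
        p[scheme.index("U")] = 1.0
        return p
    urea0 = 0.8 if condition == REFOLD_08M else 0.0
    eq = equilibrium_distribution(scheme, urea0)
    return np.array([eq[s] for s in scheme.species])


def _labeled_prediction(scheme, signature, condition, urea, dead_time,
                        amplitude_floor=0.01):
    """Predicted observable phases labeled like the experimental ones.

    Returns (labels -> (rate, cumulative amplitude), F_eq).
    """
    p0 = initial_populations_for(scheme, condition)
    pred = predict_phases(scheme, signature, p0, urea, dead_time, amplitude_floor)
    return _label_prediction_phases(pred, condition), pred.F_eq


def _label_prediction_phases(pred, condition):
    obs = [(i, p) for i, p in enumerate(pred.phases) if p.observable]
    labels: dict[str, tuple[float, float]] = {}
    if obs:
        fast_i, fast = obs[0]
        slow_i, slow = obs[-1]
        if condition == REFOLD_08M:
            labels["2'"] = (slow.rate, pred.cumulative[slow_i])
        elif condition == REFOLD_PH2:
            if len(obs) >= 2:
                labels["1"] = (fast.rate, pred.cumulative[fast_i])
                labels["2"] = (slow.rate, pred.cumulative[slow_i])
            else:
                labels["1" if fast.amplitude < 0 else "2"] = (
                    fast.rate, pred.cumulative[fast_i])
        else:  # unfolding
            if len(obs) >= 2:
                labels["3"] = (fast.rate, pred.cumulative[fast_i])
                labels["2"] = (slow.rate, pred.cumulative[slow_i])
            else:
                labels["2"] = (fast.rate, pred.cumulative[fast_i])
    return labels


_CUMULATIVE_COLUMN = {
    (REFOLD_PH2, "1"): "F0R1",
    (REFOLD_PH2, "2"): "F0R2",
    (UNFOLD, "3"): "F0U1",
    (UNFOLD, "2"): "F0U2",
}


class _ObsPlan:
    """Pre-extracted observation arrays (avoids pandas in the inner loop)."""

    def __init__(self, observations: ObservationSet):
        chev = observations.chevron
        self.groups = []
        for (cond, urea, dead), grp in chev.groupby(
                ["condition", "urea_M", "dead_time"], sort=False):
            records = []
            for _, row in grp.iterrows():
                lab = row["phase_label"]
                col = _CUMULATIVE_COLUMN.get((cond, lab))
                cum = row[col] if col and col in row else np.nan
                records.append((lab, np.log(row["rate_s"]),
                                float(cum) if np.isfinite(cum) else None))
            feq = grp["F_eq"].iloc[0]
            self.groups.append((cond, float(urea), float(dead), records,
                                float(feq) if np.isfinite(feq) else None))
        if observations.equilibrium is not None:
            self.eq_urea = observations.equilibrium["urea_M"].to_numpy(float)
            self.eq_signal = observations.equilibrium["signal"].to_numpy(float)
        else:
            self.eq_urea = None


_PLAN_CACHE: dict[int, _ObsPlan] = {}


def _plan_for(observations: ObservationSet) -> _ObsPlan:
    key = id(observations)
    plan = _PLAN_CACHE.get(key)
    if plan is None:
        _PLAN_CACHE.clear()  # keep at most one
        plan = _PLAN_CACHE[key] = _ObsPlan(observations)
    return plan


def residual_vector(
    scheme: KineticScheme,
    signature: SpectralSignature,
    observations: ObservationSet,
    weights: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Weighted residuals: log-rates, linear amplitudes, equilibrium signal.

    Default weights scale each block by sqrt(N_total / (3 * N_block)) so the
    three blocks contribute equally per degree of freedom.
    """
    plan = _plan_for(observations)
    rate_res: list[float] = []
    amp_res: list[float] = []
    eq_res: list[float] = []

    p0_cache: dict[str, np.ndarray] = {}
    for cond, urea, dead, records, feq_obs in plan.groups:
        try:
            if cond not in p0_cache:
                p0_cache[cond] = initial_populations_for(scheme, cond)
            pred = predict_phases(scheme, signature, p0_cache[cond], urea, dead)
            labels = _label_prediction_phases(pred, cond)
            feq_pred = pred.F_eq
        except Exception:
            labels, feq_pred = {}, np.nan

        for lab, log_rate_obs, cum_obs in records:
            if lab in labels:
                rate_res.append(np.log(labels[lab][0]) - log_rate_obs)
            else:
                rate_res.append(MISSING_PHASE_PENALTY)
            if cum_obs is not None:
                if lab in labels:
                    amp_res.append(labels[lab][1] - cum_obs)
                else:
                    amp_res.append(MISSING_PHASE_PENALTY)
        if feq_obs is not None:
            amp_res.append((feq_pred if np.isfinite(feq_pred) else 1e3) - feq_obs)

    if plan.eq_urea is not None:
        for u, y in zip(plan.eq_urea, plan.eq_signal):
            eq = equilibrium_distribution(scheme, float(u))
            pred = sum(eq[s] * signature.signal(s, u) for s in scheme.species)
            eq_res.append(pred - y)

    blocks = {"rates": np.asarray(rate_res), "amplitudes": np.asarray(amp_res),
              "equilibrium": np.asarray(eq_res)}
    n_tot = sum(len(b) for b in blocks.values())
    n_blocks = sum(1 for b in blocks.values() if len(b))
    out = []
    for name, vec in blocks.items():
        if not len(vec):
            continue
        if weights and name in weights:
            w = weights[name]
        else:
            w = np.sqrt(n_tot / (n_blocks * len(vec)))
        out.append(w * vec)
    return np.concatenate(out)


def objective(scheme, signature, observations, weights=None) -> float:
    """Scalar weighted sum of squared residuals (deterministic)."""
    return float(np.sum(residual_vector(scheme, signature, observations, weights) ** 2))


# ---------------------------------------------------------------------------
# Parameterization and fitting
# ---------------------------------------------------------------------------

@dataclass
class SchemeParameterization:
    """Maps a chain scheme plus signature to a bounded parameter vector.

    The chain is described from its unfolded end; each adjacent step
    contributes either four parameters (ln k0 and m_dagger for both
    directions) or, for steps listed in ``ratio_steps`` (sub-dead-time
    exchange), two parameters: the log equilibrium ratio toward the folded
    side at 0 M urea and the step m-value, with the total exchange rate
    pinned at ``exchange_rate``.  Fluorescence intercepts of all species
    except the two anchored ones (U and N, set by the experimental
    baselines) are fitted; slopes stay fixed.
    """

    path: tuple[str, ...]                    # from unfolded end to native end
    constants: Constants
    ratio_steps: tuple[tuple[str, str], ...] = ()
    exchange_rate: float = 10.0 / 1.5e-4
    fixed_species: tuple[str, ...] = ("U", "N")
    slopes: Mapping[str, float] = field(default_factory=dict)

    def _steps(self):
        return list(zip(self.path[:-1], self.path[1:]))  # (far, near) pairs

    def names(self) -> list[str]:
        out = []
        for far, near in self._steps():
            if (far, near) in self.ratio_steps or (near, far) in self.ratio_steps:
                out += [f"lnK0[{far}->{near}]", f"m[{far}<->{near}]"]
            else:
                out += [f"lnk0[{far}->{near}]", f"m[{far}->{near}]",
                        f"lnk0[{near}->{far}]", f"m[{near}->{far}]"]
        out += [f"F[{s}]" for s in self.path if s not in self.fixed_species]
        return out

    def pack(self, scheme: KineticScheme, signature: SpectralSignature) -> np.ndarray:
        x = []
        for far, near in self._steps():
            kf = scheme.transitions[(far, near)]
            ku = scheme.transitions[(near, far)]
            if (far, near) in self.ratio_steps or (near, far) in self.ratio_steps:
                x += [np.log(kf.k0 / ku.k0), ku.m_dagger - kf.m_dagger]
            else:
                x += [np.log(kf.k0), kf.m_dagger, np.log(ku.k0), ku.m_dagger]
        x += [signature.values[s][0] for s in self.path
              if s not in self.fixed_species]
        return np.array(x)

    def unpack(self, x: np.ndarray,
               base_signature: SpectralSignature) -> tuple[KineticScheme, SpectralSignature]:
        laws = {}
        i = 0
        for far, near in self._steps():
            if (far, near) in self.ratio_steps or (near, far) in self.ratio_steps:
                lnK, mstep = x[i], x[i + 1]
                i += 2
                K0 = np.exp(lnK)
                m_unf = RATIO_STEP_M_UNFOLD
                laws[(far, near)] = UreaRateLaw(
                    k0=self.exchange_rate * K0 / (1 + K0), m_dagger=m_unf - mstep)
                laws[(near, far)] = UreaRateLaw(
                    k0=self.exchange_rate / (1 + K0), m_dagger=m_unf)
            else:
                laws[(far, near)] = UreaRateLaw(k0=np.exp(x[i]), m_dagger=x[i + 1])
                laws[(near, far)] = UreaRateLaw(k0=np.exp(x[i + 2]), m_dagger=x[i + 3])
                i += 4
        values = dict(base_signature.values)
        for s in self.path:
            if s not in self.fixed_species:
                slope = values[s][1] if s in values else self.slopes.get(s, 0.045)
                values[s] = (max(float(x[i]), 1e-6), slope)
                i += 1
        scheme = KineticScheme(tuple(self.path), laws, self.constants)
        return scheme, SpectralSignature(values)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for far, near in self._steps():
            if (far, near) in self.ratio_steps or (near, far) in self.ratio_steps:
                lo += [-20.0, -M_BOUND]
                hi += [20.0, M_BOUND]
            else:
                lo += [LN_K_BOUNDS[0], -M_BOUND, LN_K_BOUNDS[0], -M_BOUND]
                hi += [LN_K_BOUNDS[1], M_BOUND, LN_K_BOUNDS[1], M_BOUND]
        n_free = sum(1 for s in self.path if s not in self.fixed_species)
        lo += [0.05] * n_free
        hi += [5.0] * n_free
        return np.array(lo), np.array(hi)

    @classmethod
    def for_scheme(cls, scheme: KineticScheme, dead_time: float = 1.5e-4,
                   unfolded: str = "U") -> "SchemeParameterization":
        """Auto parameterization: chain path from the unfolded end; steps
        whose relaxation at 0 M urea beats twice the dead-rate are treated
        as ratio-only exchange steps."""
        path = scheme.chain_path(unfolded)
        ratio = []
        for a, b in zip(path[:-1], path[1:]):
            relax = scheme.transitions[(a, b)].k0 + scheme.transitions[(b, a)].k0
            if relax > 2.0 / dead_time:
                ratio.append((a, b))
        return cls(path=path, constants=scheme.constants,
                   ratio_steps=tuple(ratio), exchange_rate=10.0 / dead_time)


def heuristic_init(
    observations: ObservationSet,
    base_signature: SpectralSignature,
    constants: Constants | None = None,
) -> tuple[KineticScheme, SpectralSignature]:
    """Data-driven initial guess for the five-state chain.

    Reads the chevron the way a practitioner would: the slow refolding limb
    gives the M -> N' rate law, the slow unfolding limb beyond the rollover
    gives N' -> M, the fast unfolding phase gives the N <-> N' exchange, the
    fast refolding plateau gives I -> M through the U/I pre-equilibrium, and
    the cumulative amplitudes at low urea give the intercepts of M and I.
    Quantities the data do not pin down (the U <-> I ratio, the M -> I
    stability) start from generic folding-study magnitudes.  The result is
    meant as a multistart center, not an estimate.
    """
    constants = constants or Constants()
    RT = constants.RT
    chev = observations.chevron

    def block(cond, label, lo=-np.inf, hi=np.inf):
        sub = chev[(chev.condition == cond) & (chev.phase_label == label)
                   & (chev.urea_M >= lo) & (chev.urea_M <= hi)]
        return sub["urea_M"].to_numpy(float), sub["rate_s"].to_numpy(float), sub

    def loglinear(u, lam, fallback):
        if len(u) >= 2:
            slope, intercept = np.polyfit(u, np.log(lam), 1)
            return float(np.exp(intercept)), float(slope * RT)
        return fallback

    # slow phase, refolding limb -> M -> N'
    u, lam, _ = block(REFOLD_PH2, "2", hi=1.01)
    k_MN0, m_MN = loglinear(u, lam, (2.0, -0.5))
    # slow phase, unfolding limb beyond the rollover -> N' -> M (the N/N'
    # pre-equilibrium contributes roughly a factor-two suppression)
    u, lam, _ = block(UNFOLD, "2", lo=4.0)
    kN_M_eff, m_NM = loglinear(u, lam, (2.5, 0.45))
    k_NM0 = 2.0 * kN_M_eff
    # fast unfolding phase -> N <-> N' exchange (sum ~ lambda3, ratio ~ 1
    # near its rollover)
    u, lam, _ = block(UNFOLD, "3")
    if len(u):
        u3 = float(np.mean(u))
        lam3 = float(np.exp(np.mean(np.log(lam))))
        if len(u) >= 2:
            s3, _ = np.polyfit(u, np.log(lam), 1)
        else:
            s3 = 0.3 / RT
        m_sum = float(s3 * RT * 2)
        m_NNp, m_NpN = m_sum + 0.1, -0.1
        k_NNp0 = lam3 / 2 * np.exp(-m_NNp * u3 / RT)
        k_NpN0 = lam3 / 2 * np.exp(-m_NpN * u3 / RT)
    else:
        k_NNp0, m_NNp, k_NpN0, m_NpN = 200.0, 0.4, 3000.0, -0.1
    # fast refolding phase and burst amplitudes -> U/I pool and I -> M
    K0, m_r = 3.0, 0.7  # generic: burst pool favors I at low urea
    u, lam, _ = block(REFOLD_PH2, "1", hi=2.21)
    if len(u):
        i0 = int(np.argmin(u))
        lam1 = lam[i0]
        _, s1 = loglinear(u, lam, (1.0, -0.2))
        m_IM = s1 + (1 - K0 / (1 + K0)) * m_r
    else:
        lam1, m_IM = 1e4, -0.1
    k_IM0 = lam1 * (1 + K0) / K0
    k_MI0 = k_IM0 / 60.0        # generic ~2.3 kcal/mol step stability
    m_MI = m_IM + m_r

    values = dict(base_signature.values)
    amp = chev[(chev.condition == REFOLD_PH2)].sort_values("urea_M")
    F_U = values["U"]
    if "F0R2" in amp.columns and amp["F0R2"].notna().any():
        row = amp[amp["F0R2"].notna()].iloc[0]
        values["M"] = (float(row["F0R2"]) - 0.045 * row["urea_M"], 0.045)
    if "F0R1" in amp.columns and amp["F0R1"].notna().any():
        row = amp[amp["F0R1"].notna()].iloc[0]
        fI = K0 / (1 + K0)
        FI = (row["F0R1"] - (1 - fI) * (F_U[0] + F_U[1] * row["urea_M"])) / fI
        values["I"] = (max(float(FI) - 0.060 * row["urea_M"], 0.1), 0.060)
    values.setdefault("N'", (0.5 * (values["M"][0] + values["N"][0]), 0.045))

    k_UI0 = 10.0 / 1.5e-4 * K0 / (1 + K0)
    k_IU0 = 10.0 / 1.5e-4 / (1 + K0)
    laws = {
        ("U", "I"): UreaRateLaw(k_UI0, RATIO_STEP_M_UNFOLD - m_r),
        ("I", "U"): UreaRateLaw(k_IU0, RATIO_STEP_M_UNFOLD),
        ("I", "M"): UreaRateLaw(max(k_IM0, 1e-3), m_IM),
        ("M", "I"): UreaRateLaw(max(k_MI0, 1e-3), m_MI),
        ("M", "N'"): UreaRateLaw(max(k_MN0, 1e-3), m_MN),
        ("N'", "M"): UreaRateLaw(max(k_NM0, 1e-3), m_NM),
        ("N'", "N"): UreaRateLaw(max(k_NpN0, 1e-3), m_NpN),
        ("N", "N'"): UreaRateLaw(max(k_NNp0, 1e-3), m_NNp),
    }
    scheme = KineticScheme(("U", "I", "M", "N'", "N"), laws, constants)
    return scheme, SpectralSignature(values)


@dataclass(frozen=True)
class SchemeFitResult:
    scheme: KineticScheme
    signature: SpectralSignature
    rss: float
    params: np.ndarray
    names: tuple[str, ...]
    stderr: np.ndarray
    active_bounds: tuple[str, ...]
    multistart_rss: tuple[float, ...]
    n_residuals: int

    @property
    def n_params(self) -> int:
        return len(self.params)

    def identifiability(self) -> pd.DataFrame:
        """Relative parameter uncertainty from the residual curvature."""
        rel = self.stderr / np.maximum(np.abs(self.params), 1e-12)
        return pd.DataFrame({"parameter": self.names, "estimate": self.params,
                             "stderr": self.stderr, "relative_stderr": rel})


def fit_scheme(
    observations: ObservationSet,
    init_scheme: KineticScheme,
    init_signature: SpectralSignature,
    parameterization: SchemeParameterization | None = None,
    n_starts: int = 8,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
    max_nfev: int = 800,
) -> SchemeFitResult:
    """Seeded multistart bounded least squares over rate laws and intercepts.

    Start 0 is the supplied initial guess; further starts perturb it
    log-normally.  Reports per-parameter standard errors from the Jacobian
    curvature at the optimum (flat directions signal unidentifiable
    parameters) and flags parameters that ended on a bound.
    """
    dead = float(observations.chevron["dead_time"].min())
    par = parameterization or SchemeParameterization.for_scheme(init_scheme, dead)
    x0 = par.pack(init_scheme, init_signature)
    lo, hi = par.bounds()
    x0 = np.clip(x0, lo, hi)

    def fun(x):
        try:
            scheme, sig = par.unpack(x, init_signature)
        except ValueError:
            return np.full(n_res, 1e3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return residual_vector(scheme, sig, observations, weights)

    n_res = len(fun(x0))
    rng = np.random.default_rng(seed)
    scales = np.where([n.startswith(("lnk0", "lnK0")) for n in par.names()], 0.25,
                      np.where([n.startswith("m") for n in par.names()], 0.15, 0.08))
    best = None
    start_rss = []
    for k in range(max(n_starts, 1)):
        if k == 0:
            xk = x0
        else:
            xk = np.clip(x0 + rng.normal(scale=scales), lo, hi)
            if k % 2 == 0:
                # broad starts: the exchange ratio(s) and intercepts form a
                # bimodal trade-off, so sample them over their plausible
                # range instead of perturbing the initial guess
                for i, name in enumerate(par.names()):
                    if name.startswith("lnK0"):
                        xk[i] = rng.uniform(-2.0, 4.0)
                    elif name.startswith("F["):
                        xk[i] = rng.uniform(0.3, 2.5)
        sol = scipy.optimize.least_squares(
            fun, xk, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_nfev,
        )
        rss = float(np.sum(sol.fun ** 2))
        start_rss.append(rss)
        if best is None or rss < best[0] * (1 - 1e-10):
            best = (rss, sol)
    rss, sol = best
    scheme, sig = par.unpack(sol.x, init_signature)

    J = sol.jac
    dof = max(n_res - len(sol.x), 1)
    s2 = rss / dof
    cov = np.linalg.pinv(J.T @ J) * s2
    stderr = np.sqrt(np.clip(np.diag(cov), 0, None))
    tol = 1e-6 * np.maximum(np.abs(hi - lo), 1.0)
    active = tuple(
        name for name, xi, l, h, t in zip(par.names(), sol.x, lo, hi, tol)
        if xi - l < t or h - xi < t
    )
    if active:
        warnings.warn(f"parameters at bounds: {active}")
    return SchemeFitResult(
        scheme=scheme, signature=sig, rss=rss, params=sol.x,
        names=tuple(par.names()), stderr=stderr, active_bounds=active,
        multistart_rss=tuple(start_rss), n_residuals=n_res,
    )


# ---------------------------------------------------------------------------
# Derived thermodynamics
# ---------------------------------------------------------------------------

#: Aggregation of kinetic species into the equilibrium-resolved species.
AGGREGATES = {"N_eq": ("N", "N'"), "M_eq": ("M",), "U_eq": ("I", "U")}


@dataclass(frozen=True)
class DerivedThermo:
    """Stepwise and aggregate stabilities derived from elementary rates.

    ``steps`` lists each adjacent pair (from the native end) with its
    unfolding free energy dG0 = -RT ln(k0_unfold/k0_fold) (positive when
    the more native member is more stable at 0 M urea), equilibrium m-value
    |m_unfold - m_fold| and midpoint Cm = dG0/m.  ``aggregates`` gives the
    same quantities for the transitions between the equilibrium-resolved
    groups N_eq = {N, N'}, M_eq = {M}, U_eq = {I, U} plus their sum, using
    Boltzmann-aggregated free energies.
    """

    steps: pd.DataFrame
    aggregates: pd.DataFrame
    state_G0: Mapping[str, float]
    state_m: Mapping[str, float]

    def gap(self, a: str, b: str) -> float:
        """Single-state free-energy gap G(b) - G(a) at 0 M urea."""
        return self.state_G0[b] - self.state_G0[a]


def derived_thermo(scheme: KineticScheme, native: str = "N") -> DerivedThermo:
    """Thermodynamics of a reversible chain from its elementary rate laws."""
    RT = scheme.constants.RT
    path = scheme.chain_path(native)

    G = {native: 0.0}
    m = {native: 0.0}
    rows = []
    for near, far in zip(path[:-1], path[1:]):
        k_fold = scheme.transitions[(far, near)]
        k_unf = scheme.transitions[(near, far)]
        dg = RT * np.log(k_fold.k0 / k_unf.k0)
        dm = k_unf.m_dagger - k_fold.m_dagger
        G[far] = G[near] + dg
        m[far] = m[near] + dm
        mstep = abs(dm)
        rows.append({"pair": f"{near}<->{far}", "dG0": dg, "m": mstep,
                     "Cm": dg / mstep if mstep > 0 else np.nan,
                     "flag": "" if mstep > 0 else "m = 0: Cm undefined"})
    steps = pd.DataFrame(rows)

    def agg_G(members):
        gs = np.array([G[s] for s in members if s in G])
        return -RT * np.log(np.sum(np.exp(-gs / RT)))

    present = {k: [s for s in v if s in G] for k, v in AGGREGATES.items()}
    arows = []
    if all(present.values()):
        gN, gM, gU = (agg_G(present[k]) for k in ("N_eq", "M_eq", "U_eq"))
        mN = 0.0
        mM, mU = m["M"], m["U"]
        pairs = [("N_eq<->M_eq", gM - gN, mM - mN),
                 ("M_eq<->U_eq", gU - gM, mU - mM),
                 ("N_eq<->U_eq", gU - gN, mU - mN)]
        for name, dg, mm in pairs:
            arows.append({"pair": name, "dG0": dg, "m": mm,
                          "Cm": dg / mm if mm > 0 else np.nan})
    aggregates = pd.DataFrame(arows)
    return DerivedThermo(steps=steps, aggregates=aggregates, state_G0=G, state_m=m)


# ---------------------------------------------------------------------------
# Candidate schemes and model comparison
# ---------------------------------------------------------------------------

def _merge_step(scheme, a, mid, b):
    """Initial guess for a step a<->b replacing the pair a<->mid<->b:
    effective forward rate through the fast pre-equilibrium."""
    k1 = scheme.transitions[(a, mid)]
    k1r = scheme.transitions[(mid, a)]
    k2 = scheme.transitions[(mid, b)]
    k2r = scheme.transitions[(b, mid)]
    frac = k1.k0 / (k1.k0 + k1r.k0)
    fwd = UreaRateLaw(k0=max(frac * k2.k0, 1e-3), m_dagger=k2.m_dagger)
    rev = UreaRateLaw(k0=k2r.k0, m_dagger=k2r.m_dagger)
    return fwd, rev


def default_candidates(reference_scheme: KineticScheme,
                       reference_signature: SpectralSignature):
    """Candidate schemes initialized around a five-state reference:
    the five-state chain itself, the three four-state chains lacking I, M
    or N', and the two off-pathway permutations (I or M branching from U).
    Returns a mapping name -> (scheme, signature, parameterization)."""
    sch, sig = reference_scheme, reference_signature
    cst = sch.constants
    T = sch.transitions
    cands = {}

    cands["five_state"] = (sch, sig, SchemeParameterization(
        path=sch.chain_path("U"), constants=cst, ratio_steps=(("U", "I"),)))

    # four-state lacking I: U <-> M <-> N' <-> N
    fwd, rev = _merge_step(sch, "U", "I", "M")
    laws = {("U", "M"): fwd, ("M", "U"): rev,
            ("M", "N'"): T[("M", "N'")], ("N'", "M"): T[("N'", "M")],
            ("N'", "N"): T[("N'", "N")], ("N", "N'"): T[("N", "N'")]}
    s4 = KineticScheme(("U", "M", "N'", "N"), laws, cst)
    cands["four_state_no_I"] = (s4, sig, SchemeParameterization(
        path=("U", "M", "N'", "N"), constants=cst))

    # four-state lacking M: U <-> I <-> N' <-> N
    laws = {("U", "I"): T[("U", "I")], ("I", "U"): T[("I", "U")],
            ("I", "N'"): T[("M", "N'")], ("N'", "I"): T[("N'", "M")],
            ("N'", "N"): T[("N'", "N")], ("N", "N'"): T[("N", "N'")]}
    s4 = KineticScheme(("U", "I", "N'", "N"), laws, cst)
    cands["four_state_no_M"] = (s4, sig, SchemeParameterization(
        path=("U", "I", "N'", "N"), constants=cst, ratio_steps=(("U", "I"),)))

    # four-state lacking N': U <-> I <-> M <-> N
    fwd, rev = _merge_step(sch, "M", "N'", "N")
    laws = {("U", "I"): T[("U", "I")], ("I", "U"): T[("I", "U")],
            ("I", "M"): T[("I", "M")], ("M", "I"): T[("M", "I")],
            ("M", "N"): fwd, ("N", "M"): rev}
    s4 = KineticScheme(("U", "I", "M", "N"), laws, cst)
    cands["four_state_no_Nprime"] = (s4, sig, SchemeParameterization(
        path=("U", "I", "M", "N"), constants=cst, ratio_steps=(("U", "I"),)))

    # off-pathway I: I <-> U <-> M <-> N' <-> N (I a dead end off U)
    laws = {("U", "I"): T[("U", "I")], ("I", "U"): T[("I", "U")],
            ("U", "M"): T[("I", "M")], ("M", "U"): T[("M", "I")],
            ("M", "N'"): T[("M", "N'")], ("N'", "M"): T[("N'", "M")],
            ("N'", "N"): T[("N'", "N")], ("N", "N'"): T[("N", "N'")]}
    s5 = KineticScheme(("I", "U", "M", "N'", "N"), laws, cst)
    cands["off_pathway_I"] = (s5, sig, SchemeParameterization(
        path=("I", "U", "M", "N'", "N"), constants=cst, ratio_steps=(("I", "U"),),
        fixed_species=("U", "N")))

    # off-pathway M: M <-> U <-> I <-> N' <-> N (M a dead end off U; the
    # on-pathway intermediate feeding N' is relabeled I, with its
    # fluorescence free to take the former M value)
    laws = {("U", "M"): T[("I", "M")], ("M", "U"): T[("M", "I")],
            ("U", "I"): T[("U", "I")], ("I", "U"): T[("I", "U")],
            ("I", "N'"): UreaRateLaw(1e2, T[("M", "N'")].m_dagger),
            ("N'", "I"): T[("N'", "M")],
            ("N'", "N"): T[("N'", "N")], ("N", "N'"): T[("N", "N'")]}
    s5 = KineticScheme(("M", "U", "I", "N'", "N"), laws, cst)
    cands["off_pathway_M"] = (s5, sig, SchemeParameterization(
        path=("M", "U", "I", "N'", "N"), constants=cst, ratio_steps=(("U", "I"),),
        fixed_species=("U", "N")))
    return cands


def compare_schemes(
    observations: ObservationSet,
    candidates: Mapping[str, tuple] | None = None,
    reference_scheme: KineticScheme | None = None,
    reference_signature: SpectralSignature | None = None,
    n_starts: int = 8,
    seed: int = 0,
    max_nfev: int = 300,
) -> pd.DataFrame:
    """Optimize every candidate scheme and rank by best residual.

    Returns a table with the candidate name, parameter count, best residual
    sum of squares across the multistart, and an information-criterion
    convenience value (AIC on Gaussian residuals); sorted by rss.
    """
    if candidates is None:
        if reference_scheme is None or reference_signature is None:
            raise ValueError("need candidates or a reference scheme/signature")
        candidates = default_candidates(reference_scheme, reference_signature)
    rows = []
    fits = {}
    for name, (scheme, sig, par) in candidates.items():
        res = fit_scheme(observations, scheme, sig, parameterization=par,
                         n_starts=n_starts, seed=seed, max_nfev=max_nfev)
        fits[name] = res
        n = res.n_residuals
        rows.append({"scheme": name, "n_params": res.n_params, "rss": res.rss,
                     "aic": n * np.log(max(res.rss, 1e-300) / n) + 2 * res.n_params})
    df = pd.DataFrame(rows).sort_values("rss").reset_index(drop=True)
    df.attrs["fits"] = fits
    return df


# ---------------------------------------------------------------------------
# Burst-phase amplitude analysis
# ---------------------------------------------------------------------------

def recover_burst_intensity(
    scheme: KineticScheme,
    signature: SpectralSignature,
    fits,
    species: str = "I",
    amplitude_floor: float = 0.01,
) -> float:
    """Fluorescence intercept of a burst-phase species from fitted F0R1.

    The back-extrapolated cumulative amplitude F0R1 of a refolding trace is
    the fluorescence of the observable (non-burst) eigenmodes at t = 0 -- a
    known linear functional of the per-species fluorescence.  Given the
    scheme's rates and the intensities of the other species, the intercept
    of the burst-phase intermediate is obtained by inverting that linear
    relation at each fitted trace and averaging; this mirrors how burst
    intensities are determined experimentally from missing amplitude.

    ``fits`` is a sequence of :class:`foldkin.traces.PhaseFit` for
    refolding traces (condition ``refold_from_pH2``) at low urea.
    """
    idx = scheme.index(species)
    estimates = []
    for fit in fits:
        if fit.condition != REFOLD_PH2 or "F0R1" not in fit.cumulative:
            continue
        urea = fit.urea
        p0 = initial_populations_for(scheme, fit.condition)
        sol = solve_scheme(build_rate_matrix(scheme, urea))
        coef = np.linalg.solve(sol.eigenvectors, p0)
        f = signature.vector(scheme.species, urea)
        # per-species weights of the stationary mode plus observable modes
        w = coef[0] * sol.eigenvectors[:, 0]
        for k in range(1, len(coef)):
            rate = abs(sol.eigenvalues[k])
            amp = float(f @ sol.eigenvectors[:, k] * coef[k])
            att = amp * np.exp(-rate * fit.dead_time)
            if abs(att) >= amplitude_floor and 1.0 / rate >= fit.dead_time / 5.0:
                w = w + coef[k] * sol.eigenvectors[:, k]
        if abs(w[idx]) < 1e-6:
            continue
        others = sum(w[j] * f[j] for j in range(len(f)) if j != idx)
        slope_term = signature.values[species][1] * urea
        estimates.append((fit.cumulative["F0R1"] - others) / w[idx] - slope_term)
    if not estimates:
        raise ValueError("no usable refolding fits supplied")
    return float(np.mean(estimates))
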