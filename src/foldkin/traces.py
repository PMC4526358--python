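"""Multi-exponential fitting of kinetic fluorescence traces.

Observed traces are fitted to

    F_obs(t) = F_eq + sum_i F_i * exp(-lambda_i * t)

where F_i and lambda_i are the amplitude and apparent rate constant of the
i-th phase.  Cumulative amplitudes -- the fluorescence a trace would show at
t = 0 in the absence of the preceding faster phases -- are the bookkeeping
used to detect burst phases: for refolding initiated from the acid-unfolded
state, F0R2 = F_eq + F_2 and F0R1 = F_eq + F_2 + F_1; for unfolding,
F0U2 = F_eq + F_2 and F0U1 = F_eq + F_2 + F_3.

Fitting is performed in log-rate space (the observable rates span four
decades) with a deterministic decade-spaced multistart; for fixed rates the
amplitudes enter linearly and are solved exactly, so the nonlinear search
runs over the rates only.  The number of phases is chosen by an F-test on
the residual sum of squares.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "REFOLD_PH2",
    "REFOLD_08M",
    "UNFOLD",
    "CONDITIONS",
    "KineticTrace",
    "PhaseFit",
    "fit_multiexponential",
    "select_n_phases",
    "cumulative_amplitudes",
    "assemble_chevron",
]

REFOLD_PH2 = "refold_from_pH2"
REFOLD_08M = "refold_from_0.8M"
UNFOLD = "unfold"
CONDITIONS = (REFOLD_PH2, REFOLD_08M, UNFOLD)

#: Decade-spaced initial apparent rates for the multistart, s^-1.
MULTISTART_RATES = tuple(10.0 ** k for k in range(0, 6))


@dataclass(frozen=True)
class KineticTrace:
    """One fluorescence kinetic trace at a single final urea concentration.

    Times are seconds from mixing and start at (or after) the instrument
    dead time; fluorescence is relative to the acid-unfolded protein at
    pH 2.0.
    """

    times: np.ndarray
    fluorescence: np.ndarray
    urea: float
    dead_time: float
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "fluorescence", np.asarray(self.fluorescence, dtype=float))
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if len(self.times) < 10:
            raise ValueError("a trace needs at least 10 points")
        if len(self.times) != len(self.fluorescence):
            raise ValueError("times and fluorescence must have equal length")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.fluorescence))):
            raise ValueError("trace values must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < self.dead_time * (1 - 1e-9):
            raise ValueError("times must start at or after the dead time")


@dataclass(frozen=True)
class PhaseFit:
    """Result of a multi-exponential fit of one trace.

    ``phases`` holds ``(amplitude, rate)`` pairs sorted by rate descending.
    ``cumulative`` holds the condition-appropriate cumulative amplitudes
    (keys F0R1/F0R2 or F0U1/F0U2).  ``flags`` collects diagnostics such as
    near-zero amplitudes or ill-conditioned rate separation.
    """

    F_eq: float
    phases: tuple[tuple[float, float], ...]
    condition: str
    urea: float
    dead_time: float
    rss: float
    n_points: int
    t_max: float = np.inf            # last observed time of the trace
    cumulative: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(rate for _, rate in self.phases)

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(amp for amp, _ in self.phases)

    def value_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.F_eq, dtype=float)
        for amp, rate in self.phases:
            out = out + amp * np.exp(-rate * t)
        return out


def _varpro_rss(log_rates: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Exact amplitudes for fixed rates; returns (residuals, F_eq, amps)."""
    rates = np.exp(log_rates)
    X = np.column_stack([np.ones_like(t)] + [np.exp(-r * t) for r in rates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta, float(beta[0]), beta[1:]


def fit_multiexponential(trace: KineticTrace, n_phases: int) -> PhaseFit:
    """Least-squares fit of a trace to 1 or 2 exponential phases.

    Deterministic: the nonlinear search over log rates starts from every
    decade (or ordered decade pair) in 10^0..10^5 s^-1 and keeps the best
    converged solution.  Amplitudes and F_eq are profiled out exactly.
    Warns when the two fitted rates are separated by less than a factor of
    three (ill-conditioned amplitudes).
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = trace.times, trace.fluorescence
    if n_phases == 1:
        starts = [[np.log(r)] for r in MULTISTART_RATES]
    else:
        starts = [
            [np.log(r1), np.log(r2)]
            for r1, r2 in itertools.combinations(MULTISTART_RATES, 2)
        ]

    best = None
    for x0 in starts:
        try:
            sol = scipy.optimize.least_squares(
                lambda lr: _varpro_rss(lr, t, y)[0], x0,
                method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0] * (1 - 1e-12):
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError(
            f"multi-exponential fit failed to converge "
            f"(condition={trace.condition}, urea={trace.urea} M, n={n_phases})"
        )
    rss, log_rates = best
    _, F_eq, amps = _varpro_rss(log_rates, t, y)
    rates = np.exp(log_rates)
    order = np.argsort(rates)[::-1]
    phases = tuple((float(amps[i]), float(rates[i])) for i in order)

    flags = []
    yspan = np.ptp(y) or 1.0
    if any(abs(a) < 1e-8 * yspan for a, _ in phases):
        flags.append("near-zero amplitude")
    if n_phases == 2 and max(rates) / min(rates) < 3.0:
        warnings.warn(
            f"fitted rates separated by less than 3x at {trace.urea} M urea; "
            "amplitudes are ill-conditioned"
        )
        flags.append("ill-conditioned rate separation")

    fit = PhaseFit(
        F_eq=F_eq, phases=phases, condition=trace.condition, urea=trace.urea,
        dead_time=trace.dead_time, rss=rss, n_points=len(t),
        t_max=float(t[-1]), flags=tuple(flags),
    )
    return PhaseFit(**{**fit.__dict__, "cumulative": cumulative_amplitudes(fit)})


def select_n_phases(trace: KineticTrace, alpha: float = 0.01) -> int:
    """Smallest phase count in {1, 2} supported by an F-test on the RSS.

    The second phase is kept only if the F-test on the reduction of the
    residual sum of squares is significant at level ``alpha``.
    """
    fit1 = fit_multiexponential(trace, 1)
    n = fit1.n_points
    tss = float(np.sum((trace.fluorescence - trace.fluorescence.mean()) ** 2)) or 1.0
    if fit1.rss <= 1e-18 * tss:  # single exponential already exact
        return 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit2 = fit_multiexponential(trace, 2)
    p1, p2 = 3, 5
    if fit2.rss <= 0:
        return 2
    fstat = ((fit1.rss - fit2.rss) / (p2 - p1)) / (fit2.rss / max(n - p2, 1))
    pval = scipy.stats.f.sf(fstat, p2 - p1, max(n - p2, 1))
    return 2 if pval < alpha else 1


#: Amplitude (relative fluorescence) below which a dead-time-attenuated
#: phase is treated as an unresolved artifact of the fit.
ARTIFACT_FLOOR = 0.01


def _genuine_mask(fit: PhaseFit, floor: float = ARTIFACT_FLOOR) -> list[bool]:
    """True for phases the instrument could genuinely resolve: the amplitude
    surviving the dead time is above ``floor`` (phases faster than the dead
    time back-extrapolate to arbitrary values and carry no information)."""
    return [abs(a) * np.exp(-r * fit.dead_time) >= floor for a, r in fit.phases]


def cumulative_amplitudes(fit: PhaseFit, condition: str | None = None) -> dict[str, float]:
    """Cumulative amplitudes per the refolding/unfolding definitions.

    Refolding: F0R2 = F_eq + F_2 and F0R1 = F_eq + F_2 + F_1 where phase 1
    is the faster (rising) phase.  Unfolding: F0U2 = F_eq + F_2 and
    F0U1 = F_eq + F_2 + F_3 where phase 3 is the faster phase.  A
    single-phase fit propagates its lone amplitude into the matching slot
    (by amplitude sign for refolding: a rising phase, negative amplitude,
    is phase 1).  Phases attenuated below the artifact floor by the dead
    time are excluded from the bookkeeping (their slots reduce to F_eq).
    """
    condition = condition or fit.condition
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    F_eq = fit.F_eq
    phases = [p for p, ok in zip(fit.phases, _genuine_mask(fit)) if ok]
    out: dict[str, float] = {}
    if condition in (REFOLD_PH2, REFOLD_08M):
        if len(phases) == 2:
            (A1, _), (A2, _) = phases  # fast, slow
            out["F0R2"] = F_eq + A2
            out["F0R1"] = F_eq + A2 + A1
        elif len(phases) == 1:
            (A, _), = phases
            if A < 0:  # rising phase -> phase 1, no slower phase resolved
                out["F0R2"] = F_eq
                out["F0R1"] = F_eq + A
            else:      # decreasing phase -> phase 2
                out["F0R2"] = F_eq + A
                out["F0R1"] = F_eq + A
        else:
            out["F0R2"] = out["F0R1"] = F_eq
    else:
        if len(phases) == 2:
            (A3, _), (A2, _) = phases
            out["F0U2"] = F_eq + A2
            out["F0U1"] = F_eq + A2 + A3
        elif len(phases) == 1:
            (A, _), = phases
            out["F0U2"] = F_eq + A
            out["F0U1"] = F_eq + A
        else:
            out["F0U2"] = out["F0U1"] = F_eq
    return out


def _labels_for(fit: PhaseFit) -> list[str]:
    """Phase labels by condition, amplitude sign and rate ordering.

    Artifact phases (below the dead-time floor) get the label ``-`` and are
    excluded from the ordering used to name the genuine phases.
    """
    mask = _genuine_mask(fit)
    n_real = sum(mask)
    labels = ["-"] * len(fit.phases)
    real_idx = [i for i, ok in enumerate(mask) if ok]
    if fit.condition == REFOLD_08M:
        for i in real_idx:
            labels[i] = "2'"
    elif fit.condition == REFOLD_PH2:
        if n_real == 2:
            a_fast = fit.amplitudes[real_idx[0]]
            a_slow = fit.amplitudes[real_idx[1]]
            if a_fast < 0 <= a_slow or a_slow < 0 <= a_fast:
                labels[real_idx[0]] = "1" if a_fast < 0 else "2"
                labels[real_idx[1]] = "1" if a_slow < 0 else "2"
            else:
                labels[real_idx[0]], labels[real_idx[1]] = "1", "2"
        elif n_real == 1:
            labels[real_idx[0]] = "1" if fit.amplitudes[real_idx[0]] < 0 else "2"
    else:  # unfolding: fast phase 3, slow phase 2 (window drift counts as slow)
        if n_real == 2:
            labels[real_idx[0]], labels[real_idx[1]] = "3", "2"
        elif n_real == 1:
            others = [r for i, (a, r) in enumerate(fit.phases) if i not in real_idx]
            i = real_idx[0]
            slower_real = [r for r in others if r < fit.phases[i][1]]
            labels[i] = "3" if slower_real else "2"
    return labels


def assemble_chevron(fits: Sequence[PhaseFit]) -> pd.DataFrame:
    """Assemble phase fits into a chevron dataset.

    One row per fitted phase with columns ``urea_M``, ``phase_label``,
    ``rate_s``, ``F_eq``, the cumulative amplitudes and ``condition``.
    Phase labels follow condition, amplitude sign and rate ordering:
    1 = fast refolding rise, 2 = slow refolding decrease / slow unfolding,
    2' = sole phase of refolding from 0.8 M urea, 3 = fast unfolding.
    Conflicting labels (duplicates within one trace's condition and urea)
    are kept but flagged.
    """
    rows = []
    for fit in fits:
        labels = _labels_for(fit)
        cum = fit.cumulative or cumulative_amplitudes(fit)
        for label, (amp, rate) in zip(labels, fit.phases):
            rows.append({
                "urea_M": fit.urea,
                "phase_label": label,
                "rate_s": rate,
                "amplitude": amp,
                "F_eq": fit.F_eq,
                "F0R1": cum.get("F0R1", np.nan),
                "F0R2": cum.get("F0R2", np.nan),
                "F0U1": cum.get("F0U1", np.nan),
                "F0U2": cum.get("F0U2", np.nan),
                "condition": fit.condition,
                "dead_time": fit.dead_time,
                "t_max": fit.t_max,
                "n_phases": len(fit.phases),
                "noise_sd": np.sqrt(fit.rss / max(fit.n_points - 1 - 2 * len(fit.phases), 1)),
                "fit_flags": ";".join(fit.flags),
                "flagged": False,
            })
    df = pd.DataFrame(rows)
    if len(df):
        dup = df.duplicated(subset=["urea_M", "condition", "phase_label"], keep=False)
        if dup.any():
            warnings.warn("conflicting phase labels; duplicates kept and flagged")
            df.loc[dup, "flagged"] = True
    return df
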