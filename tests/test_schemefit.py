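"""Objective, scheme fitting, derived thermodynamics, model comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from foldkin import kinetics as K
from foldkin import schemefit, synth
from foldkin.schemefit import _labeled_prediction


def exact_observations(ref, with_equilibrium=False):
    """Observation tables computed directly from the model's own labeled
    phase predictions (no trace fitting): the self-consistency oracle."""
    rows = []
    groups = [("refold_from_pH2", 1.5e-4, np.arange(0.0, 2.21, 0.4)),
              ("unfold", 1.5e-4, (3.7, 3.9, 4.1)),
              ("refold_from_pH2", 5.3e-3, np.arange(0.1, 1.71, 0.3)),
              ("unfold", 5.3e-3, np.arange(2.3, 5.31, 0.5)),
              ("refold_from_0.8M", 5.3e-3, (0.13, 0.4))]
    for cond, dead, grid in groups:
        for u in grid:
            labels, feq = _labeled_prediction(ref.scheme, ref.signature,
                                              cond, float(u), dead)
            for lab, (rate, cum) in labels.items():
                col = schemefit._CUMULATIVE_COLUMN.get((cond, lab))
                rows.append({"urea_M": float(u), "phase_label": lab,
                             "rate_s": rate, "F_eq": feq, "condition": cond,
                             "dead_time": dead,
                             **({col: cum} if col else {})})
    chev = pd.DataFrame(rows)
    eq = None
    if with_equilibrium:
        grid = np.arange(0.0, 8.01, 0.5)
        sig = []
        for u in grid:
            p = K.equilibrium_distribution(ref.scheme, u)
            sig.append(sum(p[s] * ref.signature.signal(s, u) for s in p))
        eq = pd.DataFrame({"urea_M": grid, "signal": sig})
    return schemefit.ObservationSet(chevron=chev, equilibrium=eq)


class TestObjective:
    def test_zero_at_generating_parameters(self, ref):
        obs = exact_observations(ref, with_equilibrium=True)
        assert schemefit.objective(ref.scheme, ref.signature, obs) < 1e-18

    @pytest.mark.parametrize("pair", [("I", "M"), ("M", "N'"), ("N'", "N")])
    def test_increases_when_any_rate_doubles(self, ref, pair):
        obs = exact_observations(ref)
        laws = dict(ref.scheme.transitions)
        law = laws[pair]
        laws[pair] = K.UreaRateLaw(2 * law.k0, law.m_dagger)
        perturbed = K.KineticScheme(ref.scheme.species, laws, ref.scheme.constants)
        assert schemefit.objective(perturbed, ref.signature, obs) > 1e-4

    def test_weights_rescale_blocks(self, ref):
        obs = exact_observations(ref)
        laws = dict(ref.scheme.transitions)
        laws[("M", "N'")] = K.UreaRateLaw(3.6, -0.52)
        perturbed = K.KineticScheme(ref.scheme.species, laws, ref.scheme.constants)
        r1 = schemefit.residual_vector(perturbed, ref.signature, obs,
                                       weights={"rates": 1.0, "amplitudes": 1.0})
        r2 = schemefit.residual_vector(perturbed, ref.signature, obs,
                                       weights={"rates": 2.0, "amplitudes": 1.0})
        n_rates = (obs.chevron["rate_s"] > 0).sum()
        assert np.allclose(r2[:n_rates], 2 * r1[:n_rates])
        assert np.allclose(r2[n_rates:], r1[n_rates:])

    def test_missing_phase_penalized(self, ref):
        obs = exact_observations(ref)
        row = obs.chevron.iloc[[0]].copy()
        row["phase_label"] = "3"  # no unfolding phase in a refolding trace
        bad = schemefit.ObservationSet(
            chevron=pd.concat([obs.chevron, row], ignore_index=True))
        r = schemefit.residual_vector(ref.scheme, ref.signature, bad)
        assert np.max(np.abs(r)) >= schemefit.MISSING_PHASE_PENALTY * 0.5


def perturbed_init(ref, seed, scale=0.3):
    par = schemefit.SchemeParameterization.for_scheme(ref.scheme, 1.5e-4)
    x = par.pack(ref.scheme, ref.signature)
    rng = np.random.default_rng(seed)
    x = x + rng.normal(scale=scale, size=x.shape) * np.where(
        [n.startswith("F") for n in par.names()], 0.3, 1.0)
    scheme, sig = par.unpack(np.clip(x, *par.bounds()), ref.signature)
    return scheme, sig, par


def assert_recovery(ref, res, rel=0.05, check_urea=3.9):
    """Identifiable-parameter comparison: the U<->I ratio and step m, the
    I<->M and M<->N' rate laws and the fitted intercepts are compared at
    0 M; the N<->N' step (whose 0 M values are long extrapolations from the
    3-4 M data) is compared through its rates at ``check_urea``."""
    T, Tf = ref.scheme.transitions, res.scheme.transitions
    c = ref.scheme.constants
    K0 = T[("U", "I")].k0 / T[("I", "U")].k0
    K0f = Tf[("U", "I")].k0 / Tf[("I", "U")].k0
    assert K0f == pytest.approx(K0, rel=rel)
    for pair in [("I", "M"), ("M", "I"), ("M", "N'"), ("N'", "M")]:
        assert Tf[pair].k0 == pytest.approx(T[pair].k0, rel=rel)
        assert Tf[pair].m_dagger == pytest.approx(T[pair].m_dagger, abs=rel)
    for pair in [("N'", "N"), ("N", "N'")]:
        assert Tf[pair].rate(check_urea, c) == pytest.approx(
            T[pair].rate(check_urea, c), rel=rel)
    for sp in ("I", "M", "N'"):
        assert res.signature.values[sp][0] == pytest.approx(
            ref.signature.values[sp][0], rel=rel)


class TestFitScheme:
    def test_noise_free_round_trip_recovery(self, ref, obs_noisefree):
        """Traces -> multi-exponential fits -> chevron -> scheme fit,
        initialized from the data alone, recovers the generator's
        identifiable parameters within 5%."""
        scheme0, sig0 = schemefit.heuristic_init(obs_noisefree, ref.signature)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = schemefit.fit_scheme(obs_noisefree, scheme0, sig0,
                                       n_starts=2, seed=0, max_nfev=1000)
        assert_recovery(ref, res, rel=0.05)

    def test_fast_phases_of_fitted_scheme_match_anchors(self, ref, obs_noisefree):
        scheme0, sig0 = schemefit.heuristic_init(obs_noisefree, ref.signature)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = schemefit.fit_scheme(obs_noisefree, scheme0, sig0,
                                       n_starts=1, seed=1, max_nfev=1000)
        refold = K.predict_phases(
            res.scheme, res.signature,
            schemefit.initial_populations_for(res.scheme, "refold_from_pH2"),
            0.0, dead_time=1.5e-4)
        fast = [p for p in refold.phases if p.observable][0]
        assert fast.rate == pytest.approx(1e4, rel=0.15)
        unfold = K.predict_phases(
            res.scheme, res.signature,
            schemefit.initial_populations_for(res.scheme, "unfold"),
            3.5, dead_time=1.5e-4)
        fast_u = [p for p in unfold.phases if p.observable][0]
        assert fast_u.rate == pytest.approx(4e3, rel=0.15)

    @pytest.mark.parametrize("rep", range(3))
    def test_noisy_observation_recovery_within_20pc(self, ref, rep):
        """Scaled-down replicate study: 1% multiplicative noise on rates and
        0.01 additive noise on amplitudes; identifiable parameters within
        20%."""
        obs0 = exact_observations(ref)
        rng = np.random.default_rng(900 + rep)
        chev = obs0.chevron.copy()
        chev["rate_s"] *= np.exp(rng.normal(scale=0.01, size=len(chev)))
        for col in ("F_eq", "F0R1", "F0R2", "F0U1", "F0U2"):
            if col in chev.columns:
                mask = chev[col].notna()
                chev.loc[mask, col] += rng.normal(scale=0.01, size=mask.sum())
        obs = schemefit.ObservationSet(chevron=chev)
        scheme0, sig0 = schemefit.heuristic_init(obs, ref.signature)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = schemefit.fit_scheme(obs, scheme0, sig0,
                                       n_starts=1, seed=rep, max_nfev=600)
        assert_recovery(ref, res, rel=0.20)


class TestDerivedThermo:
    def test_aggregate_stabilities_match_printed_sums(self, ref):
        dt = schemefit.derived_thermo(ref.scheme)
        agg = dt.aggregates.set_index("pair")
        assert agg.loc["N_eq<->M_eq", "dG0"] == pytest.approx(0.9, abs=0.1)
        assert agg.loc["M_eq<->U_eq", "dG0"] == pytest.approx(2.2, abs=0.1)
        assert agg.loc["N_eq<->U_eq", "dG0"] == pytest.approx(3.1, abs=0.1)
        assert agg.loc["N_eq<->U_eq", "dG0"] == pytest.approx(
            agg.loc["N_eq<->M_eq", "dG0"] + agg.loc["M_eq<->U_eq", "dG0"],
            rel=1e-12)
        assert agg.loc["N_eq<->U_eq", "m"] == pytest.approx(2.8, abs=0.1)

    def test_N_to_M_gap_about_1_kcal(self, ref):
        dt = schemefit.derived_thermo(ref.scheme)
        assert dt.gap("N", "M") == pytest.approx(1.0, abs=0.1)

    def test_cycle_closure_with_population_free_energies(self, ref):
        """Chain-accumulated free energies from the elementary constants
        agree with the eigen-solution population free energies."""
        dt = schemefit.derived_thermo(ref.scheme)
        G_pop = K.state_free_energies(ref.scheme, 0.0)
        for sp, g in dt.state_G0.items():
            assert g == pytest.approx(G_pop[sp], abs=1e-6)

    def test_symmetric_two_state_has_zero_dG_and_Cm(self):
        laws = {("U", "N"): K.UreaRateLaw(5.0, -0.7),
                ("N", "U"): K.UreaRateLaw(5.0, 0.7)}
        scheme = K.KineticScheme(("U", "N"), laws)
        dt = schemefit.derived_thermo(scheme)
        assert dt.steps["dG0"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert dt.steps["Cm"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_m_step_flags_undefined_Cm(self):
        laws = {("U", "N"): K.UreaRateLaw(9.0, 0.0),
                ("N", "U"): K.UreaRateLaw(1.0, 0.0)}
        dt = schemefit.derived_thermo(K.KineticScheme(("U", "N"), laws))
        assert np.isnan(dt.steps["Cm"].iloc[0])
        assert "undefined" in dt.steps["flag"].iloc[0]


class TestCompareSchemes:
    def test_five_state_beats_every_four_state_noise_free(self, ref, obs_noisefree):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = schemefit.compare_schemes(
                obs_noisefree, reference_scheme=ref.scheme,
                reference_signature=ref.signature, n_starts=2, seed=0,
                max_nfev=120)
        t = table.set_index("scheme")
        five = t.loc["five_state", "rss"]
        for name in ("four_state_no_I", "four_state_no_M", "four_state_no_Nprime"):
            assert t.loc[name, "rss"] > five * 5

    def test_off_pathway_indistinguishable_on_noisy_data(self, ref, obs_noisy):
        """With realistic noise, the off-pathway permutation of the
        five-state scheme fits as well as the on-pathway one (both at the
        noise floor), while the four-state schemes remain clearly worse."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = schemefit.compare_schemes(
                obs_noisy, reference_scheme=ref.scheme,
                reference_signature=ref.signature, n_starts=2, seed=0,
                max_nfev=120)
        t = table.set_index("scheme")
        five = t.loc["five_state", "rss"]
        assert t.loc["off_pathway_I", "rss"] <= five * 1.2
        for name in ("four_state_no_I", "four_state_no_M", "four_state_no_Nprime"):
            assert t.loc[name, "rss"] > five * 1.1

    def test_two_state_data_fit_by_two_state_candidate(self):
        laws = {("U", "N"): K.UreaRateLaw(50.0, -1.0),
                ("N", "U"): K.UreaRateLaw(0.5, 1.0)}
        scheme = K.KineticScheme(("U", "N"), laws)
        sig = K.SpectralSignature({"U": (1.0, 0.05), "N": (2.0, 0.05)})
        rows = []
        for u in np.arange(0.0, 4.01, 0.5):
            labels, feq = _labeled_prediction(scheme, sig, "unfold", u, 1e-4)
            for lab, (rate, cum) in labels.items():
                rows.append({"urea_M": u, "phase_label": lab, "rate_s": rate,
                             "F_eq": feq, "condition": "unfold",
                             "dead_time": 1e-4})
        obs = schemefit.ObservationSet(chevron=pd.DataFrame(rows))
        par = schemefit.SchemeParameterization(path=("U", "N"),
                                               constants=scheme.constants,
                                               fixed_species=("U", "N"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = schemefit.fit_scheme(obs, scheme, sig, parameterization=par,
                                       n_starts=2, seed=0, max_nfev=100)
        assert res.rss < 1e-12

    def test_ranking_stable_across_seeds(self, ref, obs_noisy):
        """The five-state vs four-state ordering does not depend on the
        multistart seed."""
        cands = schemefit.default_candidates(ref.scheme, ref.signature)
        keep = {k: cands[k] for k in ("five_state", "four_state_no_I")}
        orders = []
        for seed in (3, 4):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = schemefit.compare_schemes(obs_noisy, candidates=keep,
                                              n_starts=2, seed=seed,
                                              max_nfev=100)
            orders.append(tuple(t["scheme"]))
        assert orders[0] == orders[1] == ("five_state", "four_state_no_I")


class TestBurstRecovery:
    def test_intermediate_fluorescence_recovered(self, ref, chevron_noisefree):
        fits, _ = chevron_noisefree
        low = [f for f in fits
               if f.condition == "refold_from_pH2" and f.urea <= 0.8
               and f.dead_time < 1e-3]
        value = schemefit.recover_burst_intensity(ref.scheme, ref.signature, low)
        assert value == pytest.approx(0.80, abs=0.01)
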