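"""Shared fixtures: the reference system and its synthetic datasets.

The canonical kinetic dataset mirrors how the instruments partition the
observables: continuous flow (CF) resolves the fast refolding/unfolding
phases and the burst-phase amplitudes, stopped flow (SF) resolves the slow
phase and the equilibrium signal, and the two are combined into one chevron.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from foldkin import synth, traces, schemefit


#: Urea grids per device and condition for the canonical synthetic study.
CANONICAL_GRIDS = {
    ("CF", "refold_from_pH2"): tuple(np.round(np.arange(0.0, 2.21, 0.4), 3)) + (2.6, 3.0),
    ("CF", "unfold"): (3.7, 3.9, 4.1),
    ("SF", "refold_from_pH2"): tuple(np.round(np.arange(0.1, 1.71, 0.3), 3)),
    ("SF", "unfold"): tuple(np.round(np.arange(2.3, 5.31, 0.5), 3)),
    ("SF", "refold_from_0.8M"): (0.13, 0.25, 0.4, 0.53),
}


@pytest.fixture(scope="session")
def ref():
    return synth.reference_parameters()


@pytest.fixture(scope="session")
def table1_model():
    return synth.reference_equilibrium_model()


def _fit_all(params, noise_scale: float, base_seed: int):
    fits = []
    for i, ((device, condition), grid) in enumerate(CANONICAL_GRIDS.items()):
        noise = None if noise_scale else 0.0
        design = synth.ExperimentDesign(
            device=device, condition=condition, urea_grid=grid,
            noise_sd=noise, points_per_decade=40, seed=base_seed + i,
        )
        if noise_scale and noise_scale != 1.0:
            design = synth.ExperimentDesign(
                device=device, condition=condition, urea_grid=grid,
                noise_sd=design.noise_sd * noise_scale,
                points_per_decade=40, seed=base_seed + i,
            )
        for tr in synth.generate_traces(params, design):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n = traces.select_n_phases(tr)
                fits.append(traces.fit_multiexponential(tr, n))
    return fits


@pytest.fixture(scope="session")
def chevron_noisefree(ref):
    fits = _fit_all(ref, noise_scale=0.0, base_seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fits, traces.assemble_chevron(fits)


@pytest.fixture(scope="session")
def obs_noisefree(chevron_noisefree):
    _, chev = chevron_noisefree
    return schemefit.build_observations(chev)


@pytest.fixture(scope="session")
def obs_noisy(ref):
    fits = _fit_all(ref, noise_scale=1.0, base_seed=211)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chev = traces.assemble_chevron(fits)
    return schemefit.build_observations(chev)
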