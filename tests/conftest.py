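"""Shared fixtures: small synthetic-observer worlds on reduced pixel grids.

Heavy objects (cochleograms at 16 kHz, simulated trial tables) are
session-scoped so the suite computes them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from aci.cochleogram import CochleogramConfig, compute_cochleogram, make_filterbank
from aci.estimation import TrialTable, balance_trials
from aci.observer import ObserverSpec, ideal_template_from_targets, simulate_pixel_trials
from aci.stimuli import default_targets


@pytest.fixture(scope="session")
def audio_world():
    """Targets, filterbank and target cochleograms at 16 kHz (faster than 48k)."""
    fs = 16_000
    ccfg = CochleogramConfig(sample_rate=fs)
    fb = make_filterbank(ccfg)
    targets = default_targets(fs)
    tcoch = [compute_cochleogram(t.samples, fb, ccfg) for t in targets]
    labels = [t.response_class for t in targets]
    return dict(fs=fs, ccfg=ccfg, fb=fb, targets=targets, tcoch=tcoch,
                labels=labels)


def make_pixel_world(grid=(12, 14), contrast=0.5, signal=2.17, noise=2.0,
                     seed=3):
    """A synthetic observer world directly on a pixel grid.

    Class means are a smooth background plus (for 'ga') a smooth blob;
    the observer uses the ideal contrast template.  ``signal`` is the
    decision-variable half-separation (gain * Delta / 2) and ``noise``
    the decision-variable noise sd (gain * pixel_sd); the defaults put
    the observer at 79.4% correct (the staircase's convergence level)
    with a stimulus-noise share giving ~70% ideal response predictability
    on balanced trials, the published operating characteristics.
    """
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.standard_normal(grid), 3) + 3.0
    blob = np.zeros(grid)
    t0, f0 = int(grid[0] * 0.35), int(grid[1] * 0.35)
    blob[t0:t0 + max(2, grid[0] // 3), f0:f0 + max(2, grid[1] // 3)] = 1.0
    blob = gaussian_filter(blob, 1.5)
    da, ga = base, base + contrast * blob
    tpl = ideal_template_from_targets([da, ga], [0, 1])
    delta = float(np.vdot(ga - da, tpl))
    gain = 2.0 * signal / delta
    pixel_sd = noise / gain
    mid = 0.5 * (np.vdot(da, tpl) + np.vdot(ga, tpl))
    obs = ObserverSpec(template=tpl, bias=-gain * mid, gain=gain)
    return dict(grid=grid, da=da, ga=ga, template=tpl, observer=obs,
                pixel_sd=pixel_sd, gain=gain)


def simulate_table(world, n_trials, seed, balance=True) -> TrialTable:
    X, r, cls = simulate_pixel_trials(world["observer"], [world["da"],
                                                         world["ga"]],
                                      n_trials, world["pixel_sd"], seed=seed)
    table = TrialTable(X=X, response=r, correct=(r == cls),
                       grid_shape=world["grid"], target_class=cls)
    if balance:
        table = balance_trials(table, np.random.default_rng(seed + 1))
    return table


@pytest.fixture(scope="session")
def pixel_world():
    return make_pixel_world()


@pytest.fixture(scope="session")
def balanced_table(pixel_world):
    """~2,000 balanced trials from the reduced-grid observer."""
    return simulate_table(pixel_world, 4800, seed=11)
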