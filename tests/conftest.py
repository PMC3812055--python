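"""Shared fixtures.

Desk-scale simulations (100x100 PYs, 50x50 INs per network, 8 s) take tens
of seconds each, so they are built lazily and cached for the whole session;
several tests share each run.
"""

from __future__ import annotations

import numpy as np
import pytest

from cortexsim.topology import DESK_GRID, GridSpec, LRPConfig

# study conditions used by the dynamics tests (chosen once):
# LRP coupling at the exemplar strength G(LRP) = 0.06, P(local) = 0.99;
# tACS runs use the 10 ms delay exemplar.
LRP_D = lambda delay: LRPConfig(p_local=0.99, g_lrp=0.06, delay_ms=delay)
TACS_LRP = LRPConfig(p_local=0.99, g_lrp=0.06, delay_ms=10.0)

SMALL_GRID = GridSpec(30, 30, 15, 15)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


class _RunCache:
    """Lazily build and cache desk-scale simulation records."""

    def __init__(self):
        self._cache = {}

    def get(self, kind: str, seed: int):
        key = (kind, seed)
        if key not in self._cache:
            from cortexsim.engine import SimConfig, simulate

            if kind == "nolrp":
                cfg = SimConfig(duration_s=8.0, seed=seed)
            elif kind == "d0":
                cfg = SimConfig(duration_s=8.0, seed=seed, lrp=LRP_D(0.0))
            elif kind == "d50":
                cfg = SimConfig(duration_s=8.0, seed=seed, lrp=LRP_D(50.0))
            elif kind in ("inphase", "antiphase"):
                cfg = SimConfig(duration_s=8.0, seed=seed, lrp=TACS_LRP, tacs=kind)
            else:
                raise KeyError(kind)
            self._cache[key] = simulate(cfg)
        return self._cache[key]


@pytest.fixture(scope="session")
def desk_runs():
    return _RunCache()


@pytest.fixture(scope="session")
def small_run():
    """One quick small-grid run with all optional recordings enabled."""
    from cortexsim.engine import SimConfig, simulate

    cfg = SimConfig(
        grid=SMALL_GRID,
        duration_s=8.0,
        seed=3,
        trace_py=tuple(range(0, 900, 90)),
        volt_every_steps=10,
        d_snapshot_times=(2.0,),
        record_d_mean=True,
    )
    return simulate(cfg)
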