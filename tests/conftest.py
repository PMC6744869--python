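"""Shared fixtures: wild-type parameters, experiment designs and helpers
that run the per-condition free-energy inference for one strain."""

import numpy as np
import pytest

import simrep as sr
from simrep.inference import (
    MCMCSettings,
    infer_empirical_F,
    infer_fold_change_moments,
)


@pytest.fixture(scope="session")
def wt_params():
    return sr.WT_ALLOSTERIC


@pytest.fixture(scope="session")
def wt_o2_260():
    """The standard fitting strain: O2 operator, ~260 repressors/cell."""
    return sr.wild_type_context("O2", 260.0)


@pytest.fixture(scope="session")
def design():
    return sr.default_design()


@pytest.fixture(scope="session")
def c_grid(design):
    return np.asarray(design.iptg_ladder)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler settings for unit tests; acceptance checks use the
    full defaults."""
    return MCMCSettings(n_walkers=16, n_warmup=300, n_steps=400,
                        rhat_threshold=1.1)


def strain_F(df, strain_id, seed):
    """Empirical free-energy posterior per concentration for one strain."""
    out = {}
    sub = df[df["strain_id"] == strain_id]
    for i, (c, grp) in enumerate(sub.groupby("iptg_uM", sort=True)):
        moments = infer_fold_change_moments(grp["fold_change"].to_numpy(),
                                            seed=seed + i)
        out[float(c)] = infer_empirical_F(moments)
    return out


@pytest.fixture(scope="session")
def infer_f_per_strain():
    return strain_F
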