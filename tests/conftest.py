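"""Shared fixtures: small generated ensembles reused across test modules."""

from dataclasses import replace

import pytest

from phytotraj import synth


@pytest.fixture(scope="session")
def small_sh_ensemble():
    """300-trajectory surface-hopping ensemble with full geometry."""
    cfg = replace(synth.get_preset("agp2-sh", seed=11), n_traj=300)
    return cfg, synth.generate_sh_ensemble(cfg)


@pytest.fixture(scope="session")
def sh_records_preset():
    """Full-size (3028) preset hop records, no geometry."""
    cfg = synth.get_preset("agp2-sh", seed=1)
    return cfg, synth.generate_sh_ensemble(cfg, trajectories=False)


@pytest.fixture(scope="session")
def lumi_ensemble():
    """The 63-member relaxation ensemble at its preset seed."""
    return synth.generate_relaxation_ensemble(synth.get_preset("lumi-f-63"))
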