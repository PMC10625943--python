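"""Shared fixtures: a small synthetic study generated once per session."""

import numpy as np
import pytest

from tissuedom.pipeline import config_from_bundle_paths, make_fixtures, run_pipeline
from tissuedom.simulate import SimConfig


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """200-gene study bundle with written files."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg, bundle, paths = make_fixtures("tiny", outdir=str(outdir), seed=1)
    return {"cfg": cfg, "bundle": bundle, "paths": paths}


@pytest.fixture(scope="session")
def tiny_results(tiny_bundle, tmp_path_factory):
    """Full pipeline results on the tiny bundle."""
    outdir = tmp_path_factory.mktemp("run")
    rc = config_from_bundle_paths(tiny_bundle["paths"], str(outdir), seed=1)
    results = run_pipeline(rc, log=lambda *a: None)
    return {"results": results, "config": rc, "outdir": str(outdir)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    return SimConfig(n_genes=200, n_chromosomes=2, seed=1)
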