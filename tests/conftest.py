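import numpy as np
import pytest

from stnlfp import RunConfig, SimConfig
from stnlfp.pipeline import run_all


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_cfg():
    """Desk-scale generator config: 2 subjects, 1 block/depth, 4 kHz raw."""
    return SimConfig(n_subjects=2, blocks_per_depth=1, fs_raw=4000.0, seed=11)


@pytest.fixture(scope="session")
def mini_run_dirs(tmp_path_factory):
    """Two end-to-end runs of an identical small RunConfig (for structure and
    byte-determinism checks). Built once per session."""
    dirs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp("bundle") / name
        cfg = RunConfig(
            sim=SimConfig(n_subjects=2, blocks_per_depth=1, fs_raw=4000.0, seed=11),
            out_dir=str(out),
            log_level="WARNING",
        )
        result = run_all(cfg)
        dirs.append((out, result))
    return dirs
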