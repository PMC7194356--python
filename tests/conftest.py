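import numpy as np
import pytest

from gms import simdata
from gms.keyfile import MarkerPanel, make_key_record


@pytest.fixture
def tiny_panel() -> MarkerPanel:
    """Three 21-bp markers with distinct SNP codes and positions."""
    entries = [
        ("mA", "ACGTACGTACRTACGTACGTA"),   # R at 10 -> A/G
        ("mB", "TTGCATTGCAYGCATTGCATT"),   # Y at 10 -> C/T
        ("mC", "GGATCGGATCMATCGGATCGG"),   # M at 10 -> A/C
    ]
    return MarkerPanel(
        records=[make_key_record(m, s)[0] for m, s in entries]
    )


@pytest.fixture
def small_sim():
    """A small simulated RIL run with off-targets and errors, plus its truth."""
    cfg = simdata.SimConfig(
        rng_seed=7, n_markers=12, n_samples=4, mean_depth=60,
        per_base_error_rate=0.002,
    )
    rng = np.random.default_rng(cfg.rng_seed)
    panel, gmap, offtargets = simdata.simulate_panel(cfg, rng)
    genotypes = simdata.simulate_population(cfg, panel, rng)
    batch, truth = simdata.simulate_reads(
        cfg, panel, genotypes, offtargets=offtargets, rng=rng
    )
    truth.gmap = gmap
    return cfg, panel, genotypes, batch, truth
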