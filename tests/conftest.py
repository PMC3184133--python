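import warnings

import numpy as np
import pytest

from emtcre.motifscan import PWM, MotifLibrary


def consensus_pwm(name: str, consensus: str, strength: float = 100.0) -> PWM:
    """Near-deterministic PWM whose only high-scoring window is the consensus."""
    counts = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus.upper()):
        counts["ACGT".index(b), j] = strength
    return PWM(name=name, counts=counts)


@pytest.fixture(scope="session")
def toy_library() -> MotifLibrary:
    return MotifLibrary([
        consensus_pwm("FTS-1", "TGATTGATCCT"),
        consensus_pwm("SRY", "AACAATG"),
        consensus_pwm("GC-Box", "GGGGCGGGG"),
    ])


@pytest.fixture(scope="session")
def small_experiment():
    """One simulated two-condition experiment shared across tests."""
    from emtcre import SimConfig, normalize_experiment, simulate_probe_matrix

    cfg = SimConfig(n_genes=300, probes_per_gene=8, timepoints=("T0", "T6"),
                    n_replicates=3, frac_up=0.05, frac_down=0.05,
                    planted_log2fc=1.5, seed=7)
    pm, truth = simulate_probe_matrix(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nm = normalize_experiment(pm)
    return cfg, pm, truth, nm
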