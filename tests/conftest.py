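import numpy as np
import pytest

from isletdiff import (
    SimulationConfig,
    assign_stages,
    run_de,
    simulate_all,
    simulate_counts,
)


@pytest.fixture(scope="session")
def planted_blc():
    """End-to-end dataset with markers planted at every stage and credible
    intervals planted over BLC markers (the study conditions at desk scale)."""
    config = SimulationConfig(n_genes=2000, planted_locus_stage="BLC", seed=1)
    cm, truth, ann, ivs, snps = simulate_all(config)
    de = run_de(cm)
    asn = assign_stages(de)
    return {
        "config": config,
        "cm": cm,
        "truth": truth,
        "ann": ann,
        "ivs": ivs,
        "snps": snps,
        "de": de,
        "asn": asn,
    }


@pytest.fixture(scope="session")
def null_run():
    """Pure-null simulation (no planted effects) pushed through the DE engine."""
    config = SimulationConfig(n_genes=5000, marker_frac_per_stage=0.0, seed=7)
    cm, truth = simulate_counts(config)
    de = run_de(cm)
    return {"config": config, "cm": cm, "truth": truth, "de": de}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
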