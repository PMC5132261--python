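import numpy as np
import pytest

from coenrich.coenrichment import ExperimentDesign
from coenrich.psm_filter import (
    accept_proteins,
    assign_decoy_status,
    estimate_fdr,
    filter_psms,
)
from coenrich.sequence_db import map_peptides, mapping_index
from coenrich.spectral_quant import build_count_matrix, quantify_run
from coenrich.synthetic import SimulationConfig, simulate_experiment


def run_full_pipeline(sim):
    """Run filter -> protein acceptance -> quant -> classification on a
    simulated experiment; returns a dict of intermediates."""
    psms = sim.psms()
    mapping = mapping_index(map_peptides({p.peptide for p in psms}, sim.database))
    assign_decoy_status(psms, mapping)
    result = filter_psms(psms, mapping)
    accepted_proteins = accept_proteins(result.accepted, mapping)
    quant_proteins = {a for a in accepted_proteins if not a.startswith("DECOY_")}
    lengths = {r.accession: r.length for r in sim.database}
    design = ExperimentDesign()
    quants = []
    for run in design.all_runs:
        quants.extend(
            quantify_run(result.accepted, mapping, quant_proteins, lengths, run)
        )
    matrix = build_count_matrix(quants, design.all_runs)
    return {
        "psms": psms,
        "mapping": mapping,
        "filter_result": result,
        "fdr": estimate_fdr(result.accepted),
        "accepted_proteins": accepted_proteins,
        "quant_proteins": quant_proteins,
        "quants": quants,
        "matrix": matrix,
        "design": design,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated experiment shared across tests."""
    return simulate_experiment(
        SimulationConfig(n_target_proteins=60, n_complex_members=3, run_depth=600, seed=11)
    )


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    return run_full_pipeline(small_sim)


@pytest.fixture(scope="session")
def recovery_replicates():
    """Twenty seeded end-to-end replicates at the default study conditions;
    shared by the recovery and FDR-calibration checks."""
    import pandas as pd

    out = []
    for seed in range(20):
        sim = simulate_experiment(SimulationConfig(seed=seed))
        stages = run_full_pipeline(sim)
        truth = pd.concat(sim.psm_tables.values())
        correct = dict(zip(zip(truth.run_id, truth.scan_id), truth.correct))
        accepted = stages["filter_result"].accepted
        true_fdr = 1.0 - np.mean([correct[(p.run_id, p.scan_id)] for p in accepted])
        out.append(
            {
                "sim": sim,
                "stages": stages,
                "true_fdr": float(true_fdr),
                "est_fdr": stages["fdr"].fdr,
                "n_accepted": len(accepted),
            }
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
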