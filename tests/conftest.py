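import numpy as np
import pandas as pd
import pytest

from adaptsig import preprocess, response, simulate
from adaptsig.pls import PLSRModel


def run_signal_pipeline(cfg, scanner="A", cell_line=None):
    """Generate -> collapse -> design/response for one cell line."""
    tensor, truth = simulate.generate_rppa(cfg)
    cl = cell_line or cfg.cell_lines[0]
    fc = preprocess.collapse_log2fc(tensor[tensor["scanner"] == scanner])
    design = preprocess.assemble_design(
        fc[fc["cell_line"] == cl], signals=list(cfg.signals),
        times=list(cfg.times_signal), drugs=list(cfg.drugs))
    pheno = simulate.generate_phenotype(cfg, truth)
    viab = response.nonapoptotic_viability(pheno)
    y = response.assemble_response(viab, cell_line=cl)
    return tensor, truth, fc, design, pheno, viab, y


@pytest.fixture(scope="session")
def default_study():
    """One default-design synthetic study (single cell line) fitted once.

    The full 5-drug x 7-dose x 21-signal x 5-time design with 4x2 replicates
    and the 24/48/72 h phenotype block, shared read-only across tests.
    """
    cfg = simulate.SimConfig(n_cell_lines=1, seed=1)
    tensor, truth, fc, design, pheno, viab, y = run_signal_pipeline(cfg)
    model = PLSRModel.from_design(design, y)
    res = model.fit(3)
    return {
        "cfg": cfg, "tensor": tensor, "truth": truth, "fc": fc,
        "design": design, "pheno": pheno, "viab": viab, "y": y,
        "model": model, "results": res,
    }


@pytest.fixture(scope="session")
def recovery_cfg():
    """Planted-recovery conditions: 10 informative (signal, time) variables
    (2 informative signals x 5 times), effect size 5x the replicate noise."""
    def make(seed):
        return simulate.SimConfig(
            n_cell_lines=1, n_signals=10, informative_fraction=0.2,
            n_latent=2, noise_sd=0.1, effect_size=0.5, seed=seed)
    return make


def make_phenotype_frame(cell_line="CL", drug="drugA", doses=(1.0, 0.1),
                         times=(48.0, 72.0), total=1000, apoptotic=200,
                         n_rep=2, control_total=1000, control_apoptotic=0):
    """Small hand-built phenotype table with vehicle controls."""
    rows = []
    for t in times:
        for r in range(n_rep):
            rows.append((cell_line, "DMSO", 0.0, t, r + 1,
                         control_total, control_apoptotic))
            for d in doses:
                rows.append((cell_line, drug, d, t, r + 1, total, apoptotic))
    return pd.DataFrame(rows, columns=[
        "cell_line", "drug", "dose", "time", "replicate",
        "total_cells", "apoptotic_cells"])


def make_tensor(values_by_condition, cell_line="CL", antibody="ab1",
                time=1.0, scanner="A"):
    """Long-format replicate tensor from {(drug, dose): [replicates]}."""
    rows = []
    for (drug, dose), vals in values_by_condition.items():
        for i, v in enumerate(vals):
            rows.append((cell_line, drug, dose, time, antibody,
                         i // 2 + 1, i % 2 + 1, scanner, v))
    return pd.DataFrame(rows, columns=[
        "cell_line", "drug", "dose", "time", "antibody",
        "bio_rep", "tech_rep", "scanner", "value"])
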