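import numpy as np
import pytest

from lrxtalk import synthetic_data as sd
from lrxtalk.hurdle_de import de_table
from lrxtalk.preprocess_annotate import normalize_log


@pytest.fixture(scope="session")
def null_cohort():
    """Two populations, no planted signal at all; for calibration checks."""
    cfg = sd.SimConfig(
        n_genes=1200,
        populations=(
            sd.PopulationSpec("t", 200, "tumor"),
            sd.PopulationSpec("n", 200, "normal"),
        ),
        n_marker_genes_per_type=0,
        n_de_lr_pairs_up=0,
        n_de_lr_pairs_down=0,
        n_prognostic_genes=0,
        seed=7,
    )
    counts, ann, truth = sd.generate_sc_cohort(cfg)
    expr = normalize_log(counts)
    return cfg, counts, ann, truth, expr


@pytest.fixture(scope="session")
def null_de(null_cohort):
    _, _, ann, _, expr = null_cohort
    cells_t = list(ann.loc[ann["population"] == "t", "cell"])
    cells_n = list(ann.loc[ann["population"] == "n", "cell"])
    return de_table(expr, cells_t, cells_n)


@pytest.fixture(scope="session")
def planted_cohort():
    """End-to-end fixture: 200 cells/group, de_fc 4, planted_rho 0.5, 500 bulk."""
    cfg = sd.SimConfig(
        n_genes=800,
        populations=(
            sd.PopulationSpec("tumor_cells", 200, "tumor"),
            sd.PopulationSpec("epithelial", 200, "normal"),
        ),
        n_marker_genes_per_type=3,
        marker_fc=8.0,
        n_de_lr_pairs_up=10,
        n_de_lr_pairs_down=10,
        de_fc=4.0,
        n_bulk_samples=500,
        planted_rho=0.5,
        n_prognostic_genes=5,
        prognostic_beta=1.0,
        seed=11,
    )
    counts, ann, truth = sd.generate_sc_cohort(cfg)
    bulk, surv = sd.generate_bulk_cohort(cfg, truth)
    expr = normalize_log(counts)
    return cfg, counts, ann, truth, expr, bulk, surv


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
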