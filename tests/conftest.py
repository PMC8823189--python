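import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from decondseq.datatypes import ExpressionMatrix
from decondseq.normalize import renormalize_coding_tpm
from decondseq.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_sheet(rows):
    """Build a sample sheet from (subject, pair, sex, intervention) tuples."""
    out = []
    for subject, pair, sex, intervention in rows:
        for tp, suffix in (("baseline", "Pre"), ("post", "Post")):
            out.append(
                {
                    "sample_id": f"{subject}-{suffix}",
                    "subject_id": subject,
                    "pair_id": pair,
                    "sex": sex,
                    "intervention": intervention,
                    "timepoint": tp,
                    "age": 30,
                    "mapped_genic_reads": 20_000_000,
                }
            )
    return pd.DataFrame(out)


@pytest.fixture
def toy_sheet():
    return make_sheet(
        [
            ("1A", "Pair 1", "M", "control"),
            ("1B", "Pair 1", "M", "exercise"),
        ]
    )


@pytest.fixture
def toy_catalog():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "symbol": ["A", "B", "C"],
            "is_coding": [True, True, False],
        }
    )


@pytest.fixture
def toy_matrix(toy_sheet):
    values = pd.DataFrame(
        {s: [100.0, 300.0, 600.0] for s in toy_sheet["sample_id"]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return ExpressionMatrix(values=values)


@pytest.fixture(scope="session")
def default_study():
    """One full default synthetic study, renormalized, shared across tests."""
    config = SimulationConfig(seed=0)
    matrix, sheet, catalog, truth = simulate_study(config)
    norm = renormalize_coding_tpm(matrix, catalog)
    return config, norm, sheet, catalog, truth


@pytest.fixture(scope="session")
def small_config():
    """A reduced study for fast pipeline-level tests."""
    return SimulationConfig(
        n_genes=1500,
        n_deg_control=60,
        n_deg_exercise=12,
        n_shared_same_direction=4,
        n_shared_opposing=2,
        seed=0,
    )


def hide_intervention(sheet):
    """Blind a sample sheet: constant placeholder intervention labels."""
    return sheet.drop(columns=["intervention"]).assign(intervention="control")
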