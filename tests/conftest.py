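import numpy as np
import pandas as pd
import pytest

from kinactbench import (
    KSEdge,
    KSLibrary,
    PhosphoMatrix,
    SimConfig,
    SiteID,
    format_site_id,
)


@pytest.fixture
def toy_library() -> KSLibrary:
    """Three kinases with 5-6 substrate sites each, one shared site."""
    edges = []
    shared = SiteID("SHR1", "S", 10)
    for ki, kinase in enumerate(["AKT1", "CDK1", "SRC"]):
        for j in range(5):
            edges.append(
                KSEdge(kinase, SiteID(f"G{ki}{j}", "S", 10 + j), source="toy")
            )
        edges.append(KSEdge(kinase, shared, source="toy"))
    return KSLibrary(edges=edges)


@pytest.fixture
def toy_matrix(toy_library) -> PhosphoMatrix:
    """One row per library site plus 4 background rows, 3 experiments."""
    rng = np.random.default_rng(42)
    rows = sorted({format_site_id(e.site) for e in toy_library.edges})
    rows += [f"BKG{i}|S{i + 1}" for i in range(4)]
    data = pd.DataFrame(
        rng.normal(size=(len(rows), 3)), index=rows, columns=["e1", "e2", "e3"]
    )
    return PhosphoMatrix(data=data)


@pytest.fixture(scope="session")
def perturb_fixture():
    """Default synthetic perturbation study (library, matrix, annotation)."""
    from kinactbench import generate_library, simulate_perturbation_dataset

    cfg = SimConfig(seed=11)
    lib, truth = generate_library(cfg)
    mat, ann, shift_truth = simulate_perturbation_dataset(lib, cfg)
    return {"cfg": cfg, "lib": lib, "truth": truth, "mat": mat, "ann": ann}
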