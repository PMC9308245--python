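"""Shared fixtures: a small synthetic cohort and hand-built tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ewasviz import (
    BetaMatrix,
    EwasResultTable,
    SimulationSpec,
    TraitTable,
    assign_global_positions,
    generate_dataset,
    read_annotation,
    read_beta_matrix,
    read_catalog_counts,
    read_ewas_results,
    read_multimodal_list,
    read_trait_table,
)

SEX_MAPPING = {"1": "female", "2": "male"}


@pytest.fixture(scope="session")
def sim_spec() -> SimulationSpec:
    return SimulationSpec(n_individuals=50, n_probes=80, n_traits=2,
                          missing_rate=0.02, seed=11)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory, sim_spec):
    """Generated on-disk cohort plus its loaded in-memory objects."""
    out = tmp_path_factory.mktemp("cohort")
    artifacts = generate_dataset(sim_spec, out)
    betas, _ = read_beta_matrix(artifacts["beta_matrix"])
    traits, _ = read_trait_table(artifacts["traits"], SEX_MAPPING)
    annotation, _ = read_annotation(artifacts["annotation"])
    results = {}
    for trait, path in artifacts["results"].items():
        results[trait], _ = read_ewas_results(path)
    return {
        "dir": out,
        "spec": sim_spec,
        "artifacts": artifacts,
        "betas": betas,
        "traits": traits,
        "annotation": assign_global_positions(annotation),
        "results": results,
        "multimodal": read_multimodal_list(artifacts["multimodal"]),
        "catalog": read_catalog_counts(artifacts["catalog"]),
        "truth": artifacts["truth"],
    }


@pytest.fixture
def tiny_results() -> EwasResultTable:
    data = pd.DataFrame({
        "probe_id": ["cgA", "cgB", "cgC", "cgD", "cgE"],
        "p_value": [1e-8, 1e-3, 0.5, 1e-3, 0.9],
        "beta": [0.1, -0.2, 0.05, 0.3, -0.1],
        "delta_meth": [0.3, -0.2, 0.1, 0.25, 0.05],
    })
    return EwasResultTable(trait_name="demo", data=data)


@pytest.fixture
def tiny_betas() -> BetaMatrix:
    rng = np.random.default_rng(5)
    probes = [f"cg{i:03d}" for i in range(6)]
    individuals = [f"I{i:02d}" for i in range(10)]
    values = pd.DataFrame(rng.uniform(0.1, 0.9, size=(6, 10)),
                          index=probes, columns=individuals)
    return BetaMatrix(values=values)


@pytest.fixture
def tiny_traits(tiny_betas) -> TraitTable:
    rng = np.random.default_rng(6)
    individuals = list(tiny_betas.individual_ids)
    data = pd.DataFrame({
        "sex": ["female", "male"] * 5,
        "conc": rng.lognormal(0.0, 1.0, size=len(individuals)),
    }, index=pd.Index(individuals, name="ID"))
    return TraitTable(data=data)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def kruskal_mst_weight(points: np.ndarray) -> float:
    """Brute-force MST total weight over all pairwise edges (Kruskal)."""
    n = len(points)
    edges = sorted(
        (float(np.linalg.norm(points[i] - points[j])), i, j)
        for i in range(n) for j in range(i + 1, n))
    parent = list(range(n))

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    total, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += w
            used += 1
            if used == n - 1:
                break
    return total


def two_pass_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation over complete pairs."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    denom = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((dx * dy).sum() / denom)
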