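import numpy as np
import pandas as pd
import pytest

from mpeqtl.data import ExpressionMatrix, GenotypeMatrix, MarkerInfo, SampleInfo
from mpeqtl.sdp import FOUNDERS
from mpeqtl.simulate import PlantedEffect, SimConfig, simulate_dataset


def make_expression(values: np.ndarray, layer: str = "normalized", roles=None) -> ExpressionMatrix:
    """Small expression matrix; each column its own mpRIL unless roles given."""
    G, S = values.shape
    if roles is None:
        samples = [SampleInfo(f"s{j}", "mpRIL", f"s{j}", 1) for j in range(S)]
    else:
        samples = roles
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(G)], columns=[s.id for s in samples])
    return ExpressionMatrix(df, samples, layer)


def parental_samples() -> list[SampleInfo]:
    out = []
    for f in FOUNDERS:
        out += [SampleInfo(f"{f}_r1", "parent", f, 1), SampleInfo(f"{f}_r2", "parent", f, 2)]
    return out


def make_genotypes(X: np.ndarray, chroms=None, positions=None, sdps=None) -> GenotypeMatrix:
    """Genotype matrix from a markers x lines array with simple metadata."""
    m, n = X.shape
    chroms = chroms or ["I"] * m
    positions = positions or list(range(1, m + 1))
    sdps = sdps or ["14"] * m
    markers = [MarkerInfo(f"m{i}", chroms[i], positions[i], sdps[i]) for i in range(m)]
    df = pd.DataFrame(
        X.astype(float), index=[mk.id for mk in markers], columns=[f"L{j}" for j in range(n)]
    )
    return GenotypeMatrix(df, markers)


@pytest.fixture(scope="session")
def planted_dataset():
    """Moderate synthetic dataset with one cis and one trans-band effect."""
    cfg = SimConfig(
        n_lines=150,
        n_markers=420,
        n_genes=350,
        effects=(
            PlantedEffect("cis", ("II", 7_000_000), 6.0, "JU1941"),
            PlantedEffect("trans_band", ("V", 10_000_000), 2.0, "JU1931", n_targets=60),
        ),
        dev_covariate_sd=0.2,
        seed=20260101,
    )
    genos, expr, annotation, go_map, truth = simulate_dataset(cfg)
    return cfg, genos, expr, annotation, go_map, truth
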