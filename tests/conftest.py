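import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from ffrpnet.genome_binding import GenomeAnnotation
from ffrpnet.expression_compendium import ExpressionCompendium
from ffrpnet import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Hand-built annotation: a 3-gene + strand operon, a - strand gene, and
    two singletons on a 10 kb replicon."""
    genes = pd.DataFrame(
        [
            # gene_id, replicon, strand, start, end, start_codon, operon, rank
            ("g1", "chr", "+", 1000, 1600, 1000, "op1", 1),
            ("g2", "chr", "+", 1650, 2250, 1650, "op1", 2),
            ("g3", "chr", "+", 2300, 2900, 2300, "op1", 3),
            ("g4", "chr", "-", 4000, 4800, 4800, None, np.nan),
            ("g5", "chr", "+", 6000, 6860, 6000, None, np.nan),
            ("g6", "chr", "+", 8000, 8600, 8000, None, np.nan),
        ],
        columns=["gene_id", "replicon", "strand", "start", "end",
                 "start_codon", "operon_id", "operon_rank"],
    )
    return GenomeAnnotation(genes, {"chr": 10000})


def make_sites(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["tf", "replicon", "position", "intensity", "pvalue"])


@pytest.fixture
def small_study() -> sd.SyntheticStudy:
    """A compact synthetic study with one planted activator and one repressor."""
    base = sd.SimulationConfig(n_genes=300, n_operons=80, n_tfs=3,
                               n_condition_sets=8, arrays_per_set=(8, 12),
                               targets_per_tf=(30, 50), seed=42)
    ann = sd.generate_annotation(base)
    gt0 = sd.plant_ground_truth(base, ann)
    tfs = gt0.tf_ids
    cfg = sd.SimulationConfig(
        n_genes=300, n_operons=80, n_tfs=3, n_condition_sets=8,
        arrays_per_set=(8, 12), targets_per_tf=(30, 50), seed=42,
        planted_regulons=[
            sd.PlantedRegulon(tfs[0], "cs02", "activator"),
            sd.PlantedRegulon(tfs[1], "cs05", "repressor"),
        ])
    return sd.simulate_study(cfg)


def small_compendium(n_genes=12, sets=(("cs1", 5), ("cs2", 6)), seed=0,
                     missing_rate=0.0) -> ExpressionCompendium:
    """Small i.i.d.-noise compendium for statistic-level tests."""
    rng = np.random.default_rng(seed)
    arrays, manifest = [], {}
    for cs, m in sets:
        for _ in range(m):
            aid = f"A{len(arrays)+1:03d}"
            arrays.append(aid)
            manifest[aid] = cs
    genes = [f"g{i:03d}" for i in range(1, n_genes + 1)]
    X = rng.normal(0, 1, size=(n_genes, len(arrays)))
    if missing_rate:
        X[rng.random(X.shape) < missing_rate] = np.nan
    return ExpressionCompendium(pd.DataFrame(X, index=genes, columns=arrays),
                                pd.Series(manifest))
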