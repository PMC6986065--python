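import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import marbling as m

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study (alpha = 0.1, 5000 genes)."""
    return m.generate(seed=7)


@pytest.fixture(scope="session")
def gene_table(dataset):
    """Gene-level IMF vs SC score table for the default dataset."""
    table = m.score_table(dataset.matrix, "IMF", "SC", dataset.probe_map)
    return m.collapse_probes(table)


def analyse(seed: int, alpha: float) -> dict:
    """Run the full pipeline on one synthetic study and return its pieces."""
    cfg = m.SyntheticConfig(alpha=alpha)
    ds = m.generate(cfg, seed)
    means = m.depot_mean_table(ds.matrix)
    gtable = m.collapse_probes(m.score_table(ds.matrix, "IMF", "SC", ds.probe_map))
    background = list(gtable["gene"])
    naive_up = list(m.select_extreme(gtable, 0.01, "up")["gene"])
    report = m.run_named_queries(means, ds.probe_map).set_index("query")
    return {
        "dataset": ds,
        "gtable": gtable,
        "background": background,
        "naive_up": naive_up,
        "report": report,
    }


def muscle_fraction(genes, truth) -> float:
    muscle = set(truth.genes_in_class("muscle"))
    genes = set(genes)
    return len(genes & muscle) / max(len(genes), 1)


def muscle_q(genes, background, gene_sets) -> float:
    res = m.enrich(genes, background, gene_sets)
    return float(res.set_index("set").loc[m.synthetic.MUSCLE_SET_NAME, "q"])


@pytest.fixture(scope="session")
def contaminated_runs():
    """Twenty seeded pipeline runs at the reference contamination, alpha = 0.1."""
    return [analyse(seed, alpha=0.1) for seed in range(20)]
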