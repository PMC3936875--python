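import numpy as np
import pandas as pd
import pytest

import smokenet as sk


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-group cohort with 20 planted effect probes."""
    cspec = sk.CohortSpec(n_probes=400, n_genes=40, n_effect_probes=20,
                          effect_delta_range=(0.12, 0.15), noise_sd=0.05, seed=0)
    pspec = sk.ReferencePanelSpec(n_probes=400, n_celltype_probes=50, seed=0)
    betas, sheet, annotation, truth = sk.generate_cohort(cspec, pspec)
    return betas, sheet, annotation, truth


@pytest.fixture(scope="session")
def small_panel():
    pspec = sk.ReferencePanelSpec(n_probes=400, n_celltype_probes=50, seed=0)
    return sk.generate_reference_panel(pspec)


@pytest.fixture(scope="session")
def gene_table(small_cohort):
    betas, sheet, annotation, _ = small_cohort
    mapping = sk.assign_promoter_probes(annotation)
    return sk.promoter_t_tests(betas, sheet, mapping)


@pytest.fixture()
def toy_weighted_network():
    """Hand-built weighted graph: a heavy triangle hanging off a light path."""
    import networkx as nx

    g = nx.Graph()
    for a, b, w in [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0),
                    ("C", "D", 1.0), ("D", "E", 0.2), ("E", "F", 0.1)]:
        g.add_edge(a, b, weight=w)
    for n in g.nodes:
        g.nodes[n]["adjusted_p"] = 0.5
        g.nodes[n]["neg_log10_p"] = 0.3
    return g
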