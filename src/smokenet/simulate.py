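"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates a two-group 450K-style cohort (smokers vs non-smokers with
planted effect probes, slide/plate batch structure and a latent
cell-type mixture), a purified-cell reference panel, a protein
interaction network with dense modules planted among low-p genes, and a
flat GO annotation with planted enrichment — everything the analysis
needs, with a ground-truth record sufficient to score every downstream
stage.

All generators are deterministic functions of their spec seeds; each
operation draws from its own ``numpy.random.Generator`` stream so that
running one stage never shifts another's randomness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import BetaMatrix, EdgeList, GeneSetCollection, ProbeAnnotation, SampleSheet

DEFAULT_CELL_TYPES = ("CD4T", "CD8T", "CD14MONO", "CD19B", "CD56NK")
# monocyte/lymphocyte-dominant mixtures; fixed by convention
DIRICHLET_ALPHA = (10.0, 10.0, 8.0, 4.0, 2.0)


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic smoking cohort.

    Group sizes default to the 50 smokers / 61 non-smokers of the cohort
    this generator emulates, with 12 slides bisulfite-converted in
    batches ("plates") of 8 slides.
    """

    n_smokers: int = 50
    n_nonsmokers: int = 61
    n_probes: int = 20000
    n_genes: int = 2000
    n_effect_probes: int = 300
    effect_delta_range: tuple = (0.03, 0.15)
    n_slides: int = 12
    slide_sd: float = 0.01
    plate_sd: float = 0.01
    noise_sd: float = 0.05
    confound_mixing: float = 0.0  # >0 couples cell mixture to smoking status
    seed: int = 0

    def __post_init__(self):
        if min(self.n_smokers, self.n_nonsmokers, self.n_probes, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.effect_delta_range
        if self.n_effect_probes and not (0 < lo <= hi <= 0.5):
            raise ValueError("effect deltas must lie in (0, 0.5]")
        if self.n_effect_probes > self.n_probes:
            raise ValueError("n_effect_probes exceeds n_probes")


@dataclass
class ReferencePanelSpec:
    """Parameters of the purified-cell reference panel."""

    cell_types: tuple = DEFAULT_CELL_TYPES
    n_replicates_per_type: int = 6
    n_probes: int = 20000
    n_celltype_probes: int = 200
    celltype_delta: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if len(self.cell_types) < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_celltype_probes > self.n_probes:
            raise ValueError("n_celltype_probes exceeds n_probes")


@dataclass
class PlantedTruth:
    """Ground truth of the planted signal, for scoring downstream stages."""

    effect_probes: dict = field(default_factory=dict)   # probe_id -> signed delta
    effect_genes: set = field(default_factory=set)
    celltype_probes: list = field(default_factory=list)
    mixing: pd.DataFrame | None = None                  # samples x cell types
    modules: list = field(default_factory=list)         # list of frozensets of genes
    enriched_terms: dict = field(default_factory=dict)  # term_id -> module index


def _probe_ids(n: int) -> list:
    return [f"cg{i:08d}" for i in range(n)]


def _gene_ids(n: int) -> list:
    return [f"G{i + 1:06d}" for i in range(n)]


def _panel_profiles(n_probes: int, panel: ReferencePanelSpec):
    """Baseline betas and per-cell-type offsets, derived from the panel seed.

    The cohort and reference-panel generators share this stream so the
    cell-type-informative probes agree between the two artifacts. The
    informative probes are the last ``n_celltype_probes`` of the array;
    per probe, per-type offsets are centered and rescaled so that the
    between-type spread equals ``celltype_delta`` exactly.
    """
    rng = np.random.default_rng([panel.seed, 101])
    # bimodal baseline typical of methylation fractions, squeezed into (0.05, 0.95)
    baseline = 0.05 + 0.9 * rng.beta(0.4, 0.4, size=n_probes)
    k = len(panel.cell_types)
    nc = panel.n_celltype_probes
    celltype_idx = np.arange(n_probes - nc, n_probes)
    raw = rng.uniform(-1.0, 1.0, size=(nc, k))
    raw -= raw.mean(axis=1, keepdims=True)
    spread = raw.max(axis=1) - raw.min(axis=1)
    offsets = raw * (panel.celltype_delta / spread)[:, None]
    return baseline, celltype_idx, offsets


def _annotation(spec: CohortSpec, rng) -> tuple[ProbeAnnotation, dict]:
    """Probe -> gene/placement/island assignment.

    The first two probes of each gene are its promoter probes (TSS200 and
    TSS1500), guaranteeing every gene at least one promoter-category
    probe; remaining probes are spread over gene bodies/UTRs or left
    intergenic.
    """
    n = spec.n_probes
    probes = _probe_ids(n)
    genes = _gene_ids(spec.n_genes)
    if 2 * spec.n_genes > n:
        raise ValueError("need at least 2 probes per gene for promoter coverage")
    gene_syms = []
    placements = []
    other_placements = np.array(["Body", "Body", "5'UTR", "1stExon", "3'UTR"])
    for i in range(n):
        if i < 2 * spec.n_genes:
            gene_syms.append((genes[i // 2],))
            placements.append("TSS200" if i % 2 == 0 else "TSS1500")
        elif rng.random() < 0.6:
            gene_syms.append((genes[rng.integers(spec.n_genes)],))
            placements.append(str(rng.choice(other_placements)))
        else:
            gene_syms.append(())
            placements.append("intergenic")
    island = rng.choice(
        ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "open_sea"],
        size=n, p=[0.3, 0.1, 0.1, 0.05, 0.05, 0.4],
    )
    table = pd.DataFrame(
        {"gene_symbols": gene_syms, "placement": placements, "island_status": island},
        index=pd.Index(probes, name="probe_id"),
    )
    promoter_probe_of_gene = {genes[g]: (probes[2 * g], probes[2 * g + 1]) for g in range(spec.n_genes)}
    return ProbeAnnotation(table), promoter_probe_of_gene


def generate_cohort(spec: CohortSpec, panel: ReferencePanelSpec | None = None):
    """Simulate the two-group cohort.

    Each sample is a Dirichlet-weighted mixture of cell-type methylation
    profiles plus additive slide/plate offsets and probe-level Gaussian
    noise, clipped to [0,1]. Effect probes are the promoter probes of a
    leading block of genes, shifted by a signed delta in smokers only.

    Returns ``(BetaMatrix, SampleSheet, ProbeAnnotation, PlantedTruth)``.
    """
    panel = panel or ReferencePanelSpec(n_probes=spec.n_probes)
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_smokers + spec.n_nonsmokers
    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    smoker = np.array([1] * spec.n_smokers + [0] * spec.n_nonsmokers)

    baseline, celltype_idx, offsets = _panel_profiles(spec.n_probes, panel)
    annotation, promoter_of = _annotation(spec, rng)
    probes = list(annotation.probe_ids)

    # effect probes: promoter probes of the leading genes, disjoint from
    # the cell-type-informative block by construction
    genes = _gene_ids(spec.n_genes)
    promoter_pool = [p for g in genes for p in promoter_of[g]]
    if spec.n_effect_probes > len(promoter_pool):
        raise ValueError("n_effect_probes exceeds available promoter probes")
    effect_probe_ids = promoter_pool[: spec.n_effect_probes]
    effect_idx = np.array([probes.index(p) for p in effect_probe_ids], dtype=int)
    deltas = rng.uniform(*spec.effect_delta_range, size=spec.n_effect_probes)
    signs = rng.choice([-1.0, 1.0], size=spec.n_effect_probes)
    signed = deltas * signs
    effect_genes = {annotation.table.loc[p, "gene_symbols"][0] for p in effect_probe_ids}

    # per-sample cell mixture
    k = len(panel.cell_types)
    alpha = np.asarray(DIRICHLET_ALPHA[:k] if k <= len(DIRICHLET_ALPHA) else DIRICHLET_ALPHA + (2.0,) * (k - len(DIRICHLET_ALPHA)))
    mix = np.empty((n, k))
    for i in range(n):
        a = alpha.copy()
        if spec.confound_mixing > 0 and smoker[i]:
            a[0] *= 1.0 + spec.confound_mixing
            a[-1] /= 1.0 + spec.confound_mixing
        mix[i] = rng.dirichlet(a)

    # expected beta per probe per sample
    values = np.tile(baseline[:, None], (1, n))
    values[celltype_idx, :] += offsets @ mix.T
    values[effect_idx[:, None], np.nonzero(smoker)[0][None, :]] += signed[:, None]

    # technical structure: slide within plate (8 slides per bisulfite batch)
    slides = rng.permutation(np.arange(n) % spec.n_slides)
    plates = slides // 8
    slide_eff = rng.normal(0.0, spec.slide_sd, size=spec.n_slides)
    plate_eff = rng.normal(0.0, spec.plate_sd, size=int(plates.max()) + 1)
    values += slide_eff[slides][None, :] + plate_eff[plates][None, :]

    values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    np.clip(values, 0.0, 1.0, out=values)

    bm = BetaMatrix(pd.DataFrame(values, index=annotation.probe_ids, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame(
        {"smoker": smoker,
         "slide": [f"slide{s + 1:02d}" for s in slides],
         "plate": [f"plate{p + 1}" for p in plates]},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    truth = PlantedTruth(
        effect_probes=dict(zip(effect_probe_ids, signed)),
        effect_genes=effect_genes,
        celltype_probes=[probes[i] for i in celltype_idx],
        mixing=pd.DataFrame(mix, index=sample_ids, columns=list(panel.cell_types)),
    )
    return bm, sheet, annotation, truth


def generate_reference_panel(spec: ReferencePanelSpec):
    """Simulate the purified-cell reference panel.

    Returns ``(BetaMatrix, labels, PlantedTruth)`` where ``labels`` is a
    Series mapping panel sample id to cell type. The informative probes
    carry a between-type mean spread of exactly ``celltype_delta``; all
    other probes are exchangeable across types.
    """
    rng = np.random.default_rng([spec.seed, 2])
    baseline, celltype_idx, offsets = _panel_profiles(spec.n_probes, spec)
    probes = _probe_ids(spec.n_probes)
    sample_ids, types = [], []
    for ct in spec.cell_types:
        for r in range(spec.n_replicates_per_type):
            sample_ids.append(f"{ct}_r{r + 1}")
            types.append(ct)
    n = len(sample_ids)
    values = np.tile(baseline[:, None], (1, n))
    type_idx = np.array([list(spec.cell_types).index(t) for t in types])
    values[celltype_idx[:, None], np.arange(n)[None, :]] += offsets[:, type_idx]
    values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    np.clip(values, 0.0, 1.0, out=values)
    bm = BetaMatrix(pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=sample_ids))
    labels = pd.Series(types, index=sample_ids, name="cell_type")
    truth = PlantedTruth(celltype_probes=[probes[i] for i in celltype_idx])
    return bm, labels, truth


def generate_ppi(
    gene_pvalues: pd.Series,
    n_modules: int = 2,
    module_size_range: tuple = (5, 24),
    background_degree: float = 4.0,
    seed: int = 0,
    module_sizes: tuple | None = None,
    clique_dropout: float = 0.15,
    boundary_degree: int = 1,
):
    """Simulate a PPI edge list with dense modules planted among low-p genes.

    Planted modules are cliques with edge dropout (connectivity restored
    by a spanning path) over genes sampled from the low-p tail of
    ``gene_pvalues``; each module node also sends ``boundary_degree``
    edges to a small set of hub neighbors in the background (interactome
    modules typically reach the rest of the network through a few hub
    proteins), so modules are embedded, not isolated components. The
    background is a configuration-model-style random graph with the
    given expected degree.

    Returns ``(EdgeList, PlantedTruth)``.
    """
    rng = np.random.default_rng([seed, 3])
    genes = list(gene_pvalues.index)
    if module_sizes is None:
        lo, hi = module_size_range
        module_sizes = tuple(int(s) for s in rng.integers(lo, hi + 1, size=n_modules))
    for s in module_sizes:
        if not 4 <= s <= 30:
            raise ValueError(f"module size {s} outside [4, 30]")
    total = sum(module_sizes)
    order = gene_pvalues.sort_values(kind="stable").index
    pool = list(order[:total])
    if total > len(pool) or total > len(genes) - 10:
        raise ValueError("planted modules larger than the available low-p gene pool")
    chosen = list(rng.choice(pool, size=total, replace=False))
    chosen.sort(key=lambda g: (gene_pvalues[g], g))  # smallest modules get the strongest genes
    assigned, pos = {}, 0
    for i in np.argsort(module_sizes, kind="stable"):
        s = module_sizes[i]
        assigned[int(i)] = frozenset(chosen[pos: pos + s])
        pos += s
    modules = [assigned[i] for i in range(len(module_sizes))]

    pairs = set()
    module_members = set().union(*modules) if modules else set()
    background = sorted(set(genes) - module_members)
    for members in modules:
        mem = sorted(members)
        for a, b in itertools.combinations(mem, 2):
            if rng.random() > clique_dropout:
                pairs.add((a, b) if a < b else (b, a))
        perm = list(rng.permutation(mem))  # spanning path guarantees connectivity
        for a, b in zip(perm, perm[1:]):
            pairs.add((a, b) if a < b else (b, a))
        # embed the module: each member reaches the background through a
        # distinct well-connected hub, the way complexes sit in a
        # scale-free interactome
        hubs = rng.choice(background, size=len(mem), replace=False)
        for node, h in zip(mem, hubs):
            pairs.add((node, h) if node < h else (h, node))
            targets = rng.choice(background, size=12, replace=False)
            for t in targets:
                if t != h:
                    pairs.add((h, t) if h < t else (t, h))
    n_bg_edges = int(round(len(background) * background_degree / 2))
    while n_bg_edges > 0:
        a, b = rng.choice(background, size=2, replace=False)
        e = (a, b) if a < b else (b, a)
        if e not in pairs:
            pairs.add(e)
            n_bg_edges -= 1
    # every included background gene interacts at least twice (pendant
    # nodes are uninformative for module search)
    g = nx.Graph(pairs)
    bg_set = set(background)
    for node in [n for n in g.nodes if g.degree[n] <= 1 and n in bg_set]:
        need = 2 - g.degree[node]
        if need <= 0:
            continue
        choices = [b for b in background if b != node and not g.has_edge(node, b)]
        for b in rng.choice(choices, size=need, replace=False):
            g.add_edge(node, b)
            pairs.add((node, b) if node < b else (b, node))
    # emit a single connected network (the analysis runs on the giant
    # component of a real interactome): link stray components together
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    for comp in comps[1:]:
        a = rng.choice(sorted(comp))
        b = rng.choice(sorted(comps[0]))
        pairs.add((a, b) if a < b else (b, a))
    return EdgeList(sorted(pairs)), PlantedTruth(modules=modules)


def generate_go_annotation(
    genes,
    n_terms: int = 100,
    enriched: list | None = None,
    seed: int = 0,
    size_range: tuple = (10, 200),
):
    """Simulate a flat GO-style gene-set collection.

    ``enriched`` is a list of ``(gene_set, odds_ratio)`` pairs; for each,
    a planted term is created whose membership probability for the given
    genes is multiplied by the odds ratio (capped at 1). All other terms
    draw members uniformly.

    Returns ``(GeneSetCollection, PlantedTruth)``.
    """
    rng = np.random.default_rng([seed, 4])
    genes = sorted({g.upper() for g in genes})
    n = len(genes)
    lo, hi = size_range
    hi = min(hi, n)
    terms = {}
    truth = PlantedTruth()
    enriched = enriched or []
    for t in range(n_terms):
        tid = f"GO:{t + 1:07d}"
        name = f"synthetic pathway {t + 1}"
        size = int(rng.integers(lo, hi + 1))
        q = size / n
        if t < len(enriched):
            target, odds = enriched[t]
            target = {g.upper() for g in target}
            probs = np.array([min(1.0, q * odds) if g in target else q for g in genes])
            members = [g for g, u, p in zip(genes, rng.random(n), probs) if u < p]
            truth.enriched_terms[tid] = t
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        if len(members) < 2:
            members = list(rng.choice(genes, size=2, replace=False))
        terms[tid] = (name, frozenset(members))
    return GeneSetCollection(terms), truth
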