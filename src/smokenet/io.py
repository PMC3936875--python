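"""Containers and file I/O for every external artifact.

Beta matrices, probe annotation manifests, sample sheets, PPI edge
lists, gene-set collections (GMT), ranked EWAS result tables, and
SIF/attribute network exports. TSV is the canonical dialect; CSV is
accepted via ``sep=','``. Readers validate and fail loudly with
coordinates — no silent coercion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("smokenet")

DETECTION_P_THRESHOLD = 0.05

PLACEMENT_VOCAB = frozenset(
    {"TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"}
)
ISLAND_VOCAB = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "open_sea"}
)


# ---------------------------------------------------------------------------
# containers


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with a missingness mask.

    ``values`` is a float DataFrame indexed by probe id with sample-id
    columns; ``mask`` is a same-shape boolean DataFrame, True where the
    measurement is missing (failed detection p, absent value).
    """

    values: pd.DataFrame
    mask: pd.DataFrame = None

    def __post_init__(self):
        if self.mask is None:
            self.mask = self.values.isna()
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup}")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids in beta matrix")
        v = self.values.to_numpy()
        m = self.mask.to_numpy()
        bad = (~m) & (~np.isnan(v)) & ((v < 0) | (v > 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {v[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def masked_values(self) -> pd.DataFrame:
        """Values with masked entries set to NaN."""
        return self.values.where(~self.mask)

    def drop_high_missingness(self, max_fraction: float = 0.2) -> "BetaMatrix":
        """Drop probes masked in more than ``max_fraction`` of samples."""
        frac = self.mask.mean(axis=1)
        keep = frac <= max_fraction
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("dropping %d probes masked in >%.0f%% of samples", n_drop, 100 * max_fraction)
        return BetaMatrix(self.values.loc[keep], self.mask.loc[keep])


@dataclass
class SampleSheet:
    """Per-sample phenotype and technical covariates."""

    table: pd.DataFrame  # index sample_id; columns smoker, slide, plate

    def __post_init__(self):
        need = {"smoker", "slide", "plate"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample ids in sample sheet")
        smoker = self.table["smoker"]
        if not set(pd.unique(smoker)) <= {0, 1}:
            raise ValueError("smoker column must be coded 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def smoker_flags(self, sample_ids) -> np.ndarray:
        sub = self.table.reindex(sample_ids)
        if sub["smoker"].isna().any():
            missing = list(sub.index[sub["smoker"].isna()])[:5]
            raise ValueError(f"samples absent from sample sheet: {missing}")
        return sub["smoker"].to_numpy(dtype=int)


@dataclass
class ProbeAnnotation:
    """Probe -> gene symbol(s), gene-region placement, island status.

    ``table`` is indexed by probe id with columns ``gene_symbols`` (tuple
    of symbols, possibly empty), ``placement`` and ``island_status``
    drawn from the closed 450K-style vocabularies.
    """

    table: pd.DataFrame

    def __post_init__(self):
        if not self.table.index.is_unique:
            raise ValueError("duplicate probe ids in annotation")
        bad_pl = set(self.table["placement"]) - PLACEMENT_VOCAB
        if bad_pl:
            raise ValueError(f"unknown placement categories: {sorted(bad_pl)}")
        bad_is = set(self.table["island_status"]) - ISLAND_VOCAB
        if bad_is:
            raise ValueError(f"unknown island-status categories: {sorted(bad_is)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class EdgeList:
    """Undirected, deduplicated gene-symbol interaction pairs."""

    edges: list  # list of (a, b) tuples, a < b, uppercase

    def __post_init__(self):
        canon = {tuple(sorted((a.upper(), b.upper()))) for a, b in self.edges if a.upper() != b.upper()}
        self.edges = sorted(canon)

    def __len__(self):
        return len(self.edges)

    def genes(self) -> set:
        return {g for e in self.edges for g in e}


@dataclass
class GeneSetCollection:
    """GO-style gene sets: term id -> (term name, member symbols)."""

    terms: dict = field(default_factory=dict)  # term_id -> (name, frozenset of genes)

    def __post_init__(self):
        self.terms = {
            tid: (name, frozenset(g.upper() for g in members))
            for tid, (name, members) in self.terms.items()
        }

    def __len__(self):
        return len(self.terms)

    def items(self):
        return self.terms.items()


# ---------------------------------------------------------------------------
# readers


def _read_table(path, sep="\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.isna().any():
        raise ValueError(f"{path}: empty/missing id in first column")
    return df


def read_beta_matrix(path, detection_p_path=None, sep="\t") -> BetaMatrix:
    """Read a probes x samples beta table, masking failed detections.

    The optional detection-p table must share shape, probe ids and
    sample ids; entries with detection p strictly greater than 0.05 are
    masked (0.05 itself is kept).
    """
    df = _read_table(path, sep=sep)
    if not df.index.is_unique:
        raise ValueError(f"{path}: duplicate probe id {df.index[df.index.duplicated()][0]!r}")
    try:
        values = df.astype(float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric beta value ({e})") from None
    mask = values.isna()
    v = values.to_numpy()
    bad = (~mask.to_numpy()) & ((v < 0) | (v > 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: beta value out of [0,1] at probe {values.index[i]!r}, "
            f"sample {values.columns[j]!r}: {v[i, j]}"
        )
    if detection_p_path is not None:
        det = _read_table(detection_p_path, sep=sep).astype(float)
        if not det.index.equals(values.index) or not det.columns.equals(values.columns):
            raise ValueError("detection-p table does not align with the beta table")
        mask = mask | (det > DETECTION_P_THRESHOLD)
    return BetaMatrix(values, mask)


def write_beta_matrix(bm: BetaMatrix, path, sep="\t") -> None:
    bm.masked_values().to_csv(path, sep=sep, float_format="%.6g")


def read_sample_sheet(path, sep="\t") -> SampleSheet:
    df = _read_table(path, sep=sep)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, sep="\t") -> None:
    sheet.table.to_csv(path, sep=sep, index_label="sample_id")


def read_probe_annotation(path, sep="\t") -> ProbeAnnotation:
    """Read a manifest-style annotation: probe_id, gene_symbols (';'-delimited,
    may be empty), placement, island_status."""
    df = _read_table(path, sep=sep)
    genes = df["gene_symbols"].fillna("")
    df = df.assign(
        gene_symbols=[tuple(s.upper() for s in g.split(";") if s) for g in genes]
    )
    return ProbeAnnotation(df[["gene_symbols", "placement", "island_status"]])


def write_probe_annotation(ann: ProbeAnnotation, path, sep="\t") -> None:
    out = ann.table.assign(gene_symbols=[";".join(g) for g in ann.table["gene_symbols"]])
    out.to_csv(path, sep=sep, index_label="probe_id")


def read_edge_list(path, sep="\t", columns=(0, 1)) -> EdgeList:
    """Read a two-column (or MITAB-style, via ``columns``) interaction list.

    Symbols are uppercased; duplicates and self-loops are dropped and the
    dropped-record count logged.
    """
    ca, cb = columns
    pairs = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) <= max(ca, cb):
                raise ValueError(f"{path}:{lineno}: expected at least {max(ca, cb) + 1} columns")
            pairs.append((fields[ca], fields[cb]))
            n_lines += 1
    if not pairs:
        raise ValueError(f"{path}: empty edge list")
    el = EdgeList(pairs)
    dropped = n_lines - len(el)
    if dropped:
        log.info("read_edge_list: %d records dropped (duplicates/self-loops)", dropped)
    return el


def write_edge_list(el: EdgeList, path, sep="\t") -> None:
    with open(path, "w") as fh:
        for a, b in el.edges:
            fh.write(f"{a}{sep}{b}\n")


def read_gmt(path) -> GeneSetCollection:
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need term, name, >=1 gene")
            tid, name, members = fields[0], fields[1], fields[2:]
            if tid in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (name, frozenset(members))
    return GeneSetCollection(terms)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(coll.terms):
            name, members = coll.terms[tid]
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# result tables and network exports


def _fmt_p(p: float) -> str:
    return f"{p:.2E}"


def write_ranked_table(results: pd.DataFrame, path, sep="\t") -> None:
    """Write per-probe EWAS results as a ranked TSV.

    Columns: probe_id, gene, placement, island_status, mean_beta_smokers,
    mean_beta_nonsmokers, raw_p, adjusted_p; sorted ascending by raw_p.
    p-values are printed in scientific notation with 3 significant
    digits, betas with 2 decimals.
    """
    cols = [
        "probe_id", "gene", "placement", "island_status",
        "mean_beta_smokers", "mean_beta_nonsmokers", "raw_p", "adjusted_p",
    ]
    out = results.sort_values("raw_p", kind="stable").copy() if len(results) else results
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for _, row in out.iterrows():
            fh.write(sep.join([
                str(row["probe_id"]),
                str(row.get("gene", "")),
                str(row.get("placement", "")),
                str(row.get("island_status", "")),
                f"{row['mean_beta_smokers']:.2f}",
                f"{row['mean_beta_nonsmokers']:.2f}",
                _fmt_p(row["raw_p"]),
                _fmt_p(row["adjusted_p"]),
            ]) + "\n")


def read_ranked_table(path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, keep_default_na=False, na_values=[], dtype={"gene": str}).assign(
        raw_p=lambda d: d["raw_p"].astype(float),
        adjusted_p=lambda d: d["adjusted_p"].astype(float),
    )


def export_network(graph, prefix, interaction="pp") -> None:
    """Export a weighted network as SIF plus node/edge attribute TSVs.

    Writes ``<prefix>.sif``, ``<prefix>.edges.tsv`` (weight per edge,
    line-width semantics) and ``<prefix>.nodes.tsv`` (-log10 adjusted p
    per node, color-gradient semantics), loadable by standard graph
    visualization tools.
    """
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    with open(f"{prefix}.sif", "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{interaction}\t{b}\n")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\t{graph.edges[a, b]['weight']:.6g}\n")
    with open(f"{prefix}.nodes.tsv", "w") as fh:
        fh.write("gene\tneg_log10_adjusted_p\n")
        for n in sorted(graph.nodes()):
            fh.write(f"{n}\t{graph.nodes[n]['neg_log10_p']:.6g}\n")
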