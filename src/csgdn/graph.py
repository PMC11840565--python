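"""Signed bipartite graph data model, file I/O, and initial feature construction.

Gene-phenotype regulatory associations are modelled as a signed bipartite
graph: gene nodes on one side, phenotype nodes on the other, and each edge
labelled +1 (up-regulation) or -1 (down-regulation).  Edge signs typically
come from the sign of a TWAS z-score.  Gene nodes carry an initial feature
vector taken from a row of a gene-gene sequence-similarity matrix (e.g.
percent identity from BLAST); phenotype nodes get one-hot indicator rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignedBipartiteGraph",
    "TwasTable",
    "GeneSimilarity",
    "FeatureMatrix",
    "read_edge_list",
    "write_edge_list",
    "read_blast_similarity",
    "read_similarity_matrix",
    "build_feature_matrix",
    "adjacency",
    "write_predictions",
]


@dataclass
class SignedBipartiteGraph:
    """A signed bipartite graph over gene and phenotype node sets.

    Parameters
    ----------
    gene_ids : list of str
        Ordered gene identifiers; index in this list is the gene node index.
    phenotype_ids : list of str
        Ordered phenotype identifiers.
    edges : list of (int, int, int)
        Triples ``(gene_index, phenotype_index, sign)`` with sign in
        ``{+1, -1}``.  At most one edge per (gene, phenotype) pair.
    """

    gene_ids: list
    phenotype_ids: list
    edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict = {}
        for g, p, s in self.edges:
            if s not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {s!r}")
            if not (0 <= g < len(self.gene_ids)):
                raise ValueError(f"gene index {g} out of range")
            if not (0 <= p < len(self.phenotype_ids)):
                raise ValueError(f"phenotype index {p} out of range")
            if (g, p) in seen:
                raise ValueError(
                    f"duplicate edge for pair ({self.gene_ids[g]}, "
                    f"{self.phenotype_ids[p]})"
                )
            seen[(g, p)] = s

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_ids)

    @property
    def n_nodes(self) -> int:
        """Total node count (genes first, then phenotypes)."""
        return self.n_genes + self.n_phenotypes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_dict(self) -> dict:
        return {(g, p): s for g, p, s in self.edges}

    def with_edges(self, edges) -> "SignedBipartiteGraph":
        """Same node sets, different edge list."""
        return SignedBipartiteGraph(self.gene_ids, self.phenotype_ids, list(edges))

    def same_nodes(self, other: "SignedBipartiteGraph") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.phenotype_ids == other.phenotype_ids
        )


@dataclass
class TwasTable:
    """Raw TWAS rows (gene, phenotype, z-score) retained alongside the graph."""

    rows: list  # (gene_id, phenotype_id, zscore)

    @property
    def twas_gene_set(self) -> set:
        return {g for g, _, _ in self.rows}


@dataclass
class GeneSimilarity:
    """Dense symmetric gene-gene similarity matrix with unit diagonal.

    Row ``i`` supplies the initial feature vector of gene ``i``.
    """

    matrix: np.ndarray
    gene_order: list

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")
        if m.shape[0] != len(self.gene_order):
            raise ValueError("gene_order length does not match matrix")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")
        if m.size and (m.min() < -1e-12 or m.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        self.matrix = m


@dataclass
class FeatureMatrix:
    """Initial node features: gene rows = similarity rows (zero-padded over
    phenotype columns); phenotype rows = one-hot indicators."""

    matrix: np.ndarray
    n_genes: int
    n_phenotypes: int


def read_edge_list(path, sign_column: str = "zscore"):
    """Read a TSV edge list into a graph plus the raw TWAS table.

    The file must have a header with columns ``gene``, ``phenotype`` and
    either ``zscore`` or ``sign``.  Edge sign is the sign of the z-score
    (or the sign column itself).  Rows with z = 0 are rejected with a
    warning; exact duplicate rows are deduplicated; duplicates with
    conflicting signs are a hard error.

    Returns
    -------
    (SignedBipartiteGraph, TwasTable)
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = {c.lower(): c for c in df.columns}
    for need in ("gene", "phenotype"):
        if need not in cols:
            raise ValueError(f"edge list is missing required column {need!r}")
    if sign_column not in ("sign", "zscore"):
        raise ValueError("sign_column must be 'sign' or 'zscore'")
    if sign_column not in cols:
        raise ValueError(f"edge list has no column {sign_column!r}")

    gene_ids: list = []
    phen_ids: list = []
    gidx: dict = {}
    pidx: dict = {}
    edge_sign: dict = {}
    dedup = 0
    rejected = 0
    rows = []
    for gene, phen, val in zip(
        df[cols["gene"]], df[cols["phenotype"]], df[cols[sign_column]]
    ):
        z = float(val)
        if z == 0.0:
            rejected += 1
            continue
        s = 1 if z > 0 else -1
        gene, phen = str(gene), str(phen)
        if gene not in gidx:
            gidx[gene] = len(gene_ids)
            gene_ids.append(gene)
        if phen not in pidx:
            pidx[phen] = len(phen_ids)
            phen_ids.append(phen)
        key = (gidx[gene], pidx[phen])
        if key in edge_sign:
            if edge_sign[key] != s:
                raise ValueError(
                    f"conflicting signs for pair ({gene}, {phen})"
                )
            dedup += 1
            continue
        edge_sign[key] = s
        rows.append((gene, phen, z))
    if rejected:
        warnings.warn(f"rejected {rejected} row(s) with zero z-score")
    if dedup:
        warnings.warn(f"deduplicated {dedup} repeated edge row(s)")
    graph = SignedBipartiteGraph(
        gene_ids, phen_ids, [(g, p, s) for (g, p), s in edge_sign.items()]
    )
    return graph, TwasTable(rows)


def write_edge_list(graph: SignedBipartiteGraph, path, twas: TwasTable = None) -> None:
    """Write the graph back to the TSV edge-list dialect.

    If a :class:`TwasTable` is given its z-scores are written; otherwise the
    sign itself is written in the ``zscore`` column.
    """
    zmap = {}
    if twas is not None:
        zmap = {(g, p): z for g, p, z in twas.rows}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tphenotype\tzscore\n")
        for g, p, s in graph.edges:
            gid, pid = graph.gene_ids[g], graph.phenotype_ids[p]
            z = zmap.get((gid, pid), float(s))
            fh.write(f"{gid}\t{pid}\t{z}\n")


def read_blast_similarity(path, gene_order, score: str = "pident") -> GeneSimilarity:
    """Build a gene similarity matrix from BLAST tabular (outfmt 6) output.

    With ``score="pident"`` (default), entry (i, j) is the best-hit percent
    identity / 100; with ``score="bitscore"`` it is the best bitscore scaled
    by the largest bitscore in the file.  Either way the matrix is
    symmetrized by elementwise max with its transpose, the diagonal is
    forced to 1, and missing pairs are 0.  Hits naming genes outside
    ``gene_order`` are skipped with a warning.
    """
    if score not in ("pident", "bitscore"):
        raise ValueError("score must be 'pident' or 'bitscore'")
    col = 2 if score == "pident" else 11
    idx = {g: i for i, g in enumerate(gene_order)}
    n = len(gene_order)
    m = np.zeros((n, n), dtype=float)
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"malformed BLAST tabular row at line {lineno}: "
                    f"expected 12 columns, got {len(parts)}"
                )
            q, s = parts[0], parts[1]
            try:
                value = float(parts[col])
            except ValueError as exc:
                raise ValueError(
                    f"malformed {score} at line {lineno}: {parts[col]!r}"
                ) from exc
            if q not in idx or s not in idx:
                skipped += 1
                continue
            i, j = idx[q], idx[s]
            m[i, j] = max(m[i, j], value if score == "bitscore" else value / 100.0)
    if skipped:
        warnings.warn(f"skipped {skipped} BLAST hit(s) for genes not in gene_order")
    if score == "bitscore" and m.max() > 0:
        m = m / m.max()
    m = np.maximum(m, m.T)
    np.fill_diagonal(m, 1.0)
    m = np.clip(m, 0.0, 1.0)
    return GeneSimilarity(m, list(gene_order))


def read_similarity_matrix(path) -> GeneSimilarity:
    """Read a dense labelled TSV similarity matrix (row/column gene labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("similarity matrix row and column labels differ")
    return GeneSimilarity(df.to_numpy(dtype=float), [str(g) for g in df.index])


def write_similarity_matrix(sim: GeneSimilarity, path) -> None:
    pd.DataFrame(sim.matrix, index=sim.gene_order, columns=sim.gene_order).to_csv(
        path, sep="\t"
    )


def build_feature_matrix(sim: GeneSimilarity, graph: SignedBipartiteGraph) -> FeatureMatrix:
    """Assemble the N x N initial node-feature matrix.

    Gene block rows are the similarity rows padded with zeros over the
    phenotype columns; phenotype rows are one-hot indicators over the
    phenotype columns.
    """
    if list(sim.gene_order) != list(graph.gene_ids):
        for a, b in zip(sim.gene_order, graph.gene_ids):
            if a != b:
                raise ValueError(
                    f"gene order mismatch between similarity and graph: "
                    f"{a!r} != {b!r}"
                )
        raise ValueError("gene order length mismatch between similarity and graph")
    ng, np_ = graph.n_genes, graph.n_phenotypes
    out = np.zeros((ng + np_, ng + np_), dtype=float)
    out[:ng, :ng] = sim.matrix
    out[ng:, ng:] = np.eye(np_)
    return FeatureMatrix(out, ng, np_)


def align_to_gene_order(graph: SignedBipartiteGraph, gene_order) -> SignedBipartiteGraph:
    """Re-index the graph onto a canonical gene universe.

    ``gene_order`` (typically the similarity matrix's gene list) may contain
    genes without any edge -- e.g. genes lacking TWAS associations that are
    only reachable through the projection MLP.  Every gene already in the
    graph must appear in ``gene_order``.
    """
    idx = {g: i for i, g in enumerate(gene_order)}
    missing = [g for g in graph.gene_ids if g not in idx]
    if missing:
        raise ValueError(
            f"gene(s) {missing[:5]} from the edge list are absent from the "
            f"given gene order"
        )
    edges = [(idx[graph.gene_ids[g]], p, s) for g, p, s in graph.edges]
    return SignedBipartiteGraph(list(gene_order), list(graph.phenotype_ids), edges)


def adjacency(graph: SignedBipartiteGraph) -> np.ndarray:
    """Symmetric signed adjacency matrix over [genes; phenotypes] ordering."""
    n = graph.n_nodes
    a = np.zeros((n, n), dtype=float)
    off = graph.n_genes
    for g, p, s in graph.edges:
        a[g, off + p] = s
        a[off + p, g] = s
    return a


_CALL_NAMES = ("down", "none", "up")
# tie-break priority on exact ties: none > up > down
_TIE_ORDER = (1, 2, 0)


def _call(p_down: float, p_none: float, p_up: float) -> str:
    probs = (p_down, p_none, p_up)
    best = max(probs)
    for idx in _TIE_ORDER:
        if probs[idx] == best:
            return _CALL_NAMES[idx]
    raise AssertionError("unreachable")


def write_predictions(rows, path) -> None:
    """Write prediction rows (gene, phenotype, P_down, P_none, P_up) as TSV.

    Each probability triple must sum to 1 within 1e-6.  A ``call`` column
    holds the argmax label in {down, none, up}; exact ties resolve with
    priority none > up > down.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tphenotype\tp_down\tp_none\tp_up\tcall\n")
        for gene, phen, pd_, pn, pu in rows:
            total = pd_ + pn + pu
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"probability triple for ({gene}, {phen}) sums to {total}, not 1"
                )
            fh.write(
                f"{gene}\t{phen}\t{pd_:.6g}\t{pn:.6g}\t{pu:.6g}\t{_call(pd_, pn, pu)}\n"
            )
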