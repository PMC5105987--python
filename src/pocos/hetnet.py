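"""Heterogeneous locus-gene network and the network-constrained search.

The network G = (V u U, E u F u Q) has two node types — genotyped loci (U)
and genes (V) — and three undirected edge types:

* F (RoI): locus-gene edges when the locus lies within a window (default
  50 kb) up- and downstream of the gene's coding region;
* Q (eQTL): locus-gene edges from expression association screens;
* E (PPI): gene-gene edges between interacting protein products.

Loci never neighbor loci directly, so every locus-locus path of length <= 3
passes through gene nodes only: shared-gene pairs sit 2 hops apart
(RoI-RoI, RoI-eQTL, eQTL-eQTL through one gene) and pairs bridged by one
PPI edge sit 3 hops apart (RoI-PPI-RoI, RoI-PPI-eQTL, eQTL-PPI-eQTL). Hop
counting is uniform over all edge types. The network-constrained locus-set
search restricts every addition after the first to loci within the hop
bound of the growing set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .config import DEFAULTS
from .errors import EmptyNetworkError
from .genotype_models import BinaryProfileSet
from .gwas_io import GwasDataset
from .poco_search import PoCoCollection, discover_pocos

logger = logging.getLogger(__name__)


@dataclass
class HeterogeneousNetwork:
    """Locus and gene nodes with RoI, eQTL and PPI edge sets (deduplicated)."""

    locus_ids: list[str]  # U: loci incident to at least one RoI/eQTL edge
    gene_ids: list[str]  # V
    roi_edges: list[tuple[str, str]]  # F: (locus, gene)
    eqtl_edges: list[tuple[str, str]]  # Q: (locus, gene)
    ppi_edges: list[tuple[str, str]]  # E: (gene, gene)

    @cached_property
    def _locus_pos(self) -> dict[str, int]:
        return {u: i for i, u in enumerate(self.locus_ids)}

    @cached_property
    def _gene_pos(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.gene_ids)}

    @cached_property
    def locus_gene(self) -> sparse.csr_matrix:
        """|U| x |V| incidence of F u Q."""
        rows, cols = [], []
        for lid, gid in self.roi_edges + self.eqtl_edges:
            rows.append(self._locus_pos[lid])
            cols.append(self._gene_pos[gid])
        data = np.ones(len(rows), dtype=bool)
        mat = sparse.coo_matrix(
            (data, (rows, cols)), shape=(len(self.locus_ids), len(self.gene_ids))
        )
        return mat.tocsr()

    @cached_property
    def gene_gene(self) -> sparse.csr_matrix:
        """|V| x |V| symmetric PPI adjacency."""
        rows, cols = [], []
        for a, b in self.ppi_edges:
            ia, ib = self._gene_pos[a], self._gene_pos[b]
            rows += [ia, ib]
            cols += [ib, ia]
        data = np.ones(len(rows), dtype=bool)
        mat = sparse.coo_matrix(
            (data, (rows, cols)), shape=(len(self.gene_ids),) * 2
        )
        return mat.tocsr()

    @cached_property
    def locus_reachability(self) -> np.ndarray:
        """Boolean |U| x |U| matrix: within ``hop_bound`` (=3) hops, self excluded."""
        B = self.locus_gene.astype(np.int64)
        two_hop = B @ B.T  # locus-gene-locus
        three_hop = B @ self.gene_gene.astype(np.int64) @ B.T  # locus-gene-gene-locus
        reach = ((two_hop + three_hop) > 0).toarray()
        np.fill_diagonal(reach, False)
        return reach

    def genes_adjacent_to(self, locus_id: str) -> set[str]:
        """Genes linked to a locus by an RoI or eQTL edge."""
        i = self._locus_pos.get(locus_id)
        if i is None:
            return set()
        row = self.locus_gene[i].indices
        return {self.gene_ids[j] for j in row}

    def to_networkx(self):
        """The network as a networkx Graph with 'kind' node/edge attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.locus_ids, kind="locus")
        g.add_nodes_from(self.gene_ids, kind="gene")
        g.add_edges_from(self.roi_edges, kind="roi")
        g.add_edges_from(self.eqtl_edges, kind="eqtl")
        g.add_edges_from(self.ppi_edges, kind="ppi")
        return g


def build_network(
    dataset: GwasDataset,
    gene_table: pd.DataFrame,
    eqtl_table: pd.DataFrame | None = None,
    ppi_table: pd.DataFrame | None = None,
    window_bp: int = DEFAULTS.roi_window_bp,
) -> HeterogeneousNetwork:
    """Assemble the heterogeneous network from annotation tables.

    ``gene_table`` columns: gene_id, chrom, start, end (1-based inclusive);
    ``eqtl_table`` columns: locus_id, gene_id; ``ppi_table`` columns:
    gene_id_a, gene_id_b. A locus gets an RoI edge to every gene whose
    window ``[start - window_bp, end + window_bp]`` contains its position.
    eQTL rows naming unknown loci or genes are dropped (count logged); PPI
    self-loops are dropped. U contains exactly the genotyped loci with at
    least one RoI or eQTL edge; an empty U raises.
    """
    gene_table = gene_table.reset_index(drop=True)
    gene_ids = [str(g) for g in gene_table["gene_id"]]
    known_genes = set(gene_ids)
    known_loci = set(dataset.locus_ids)

    roi: set[tuple[str, str]] = set()
    chroms = np.array([str(c) for c in gene_table["chrom"]])
    starts = gene_table["start"].to_numpy(dtype=np.int64)
    ends = gene_table["end"].to_numpy(dtype=np.int64)
    for locus in dataset.loci:
        on_chrom = np.flatnonzero(chroms == str(locus.chrom))
        if on_chrom.size == 0:
            continue
        hit = on_chrom[
            (starts[on_chrom] - window_bp <= locus.pos)
            & (locus.pos <= ends[on_chrom] + window_bp)
        ]
        for j in hit:
            roi.add((locus.id, gene_ids[j]))

    eqtl: set[tuple[str, str]] = set()
    dropped = 0
    if eqtl_table is not None:
        for lid, gid in zip(eqtl_table["locus_id"], eqtl_table["gene_id"]):
            lid, gid = str(lid), str(gid)
            if lid in known_loci and gid in known_genes:
                eqtl.add((lid, gid))
            else:
                dropped += 1
    if dropped:
        logger.info("dropped %d eQTL pairs referencing unknown loci/genes", dropped)

    ppi: set[tuple[str, str]] = set()
    if ppi_table is not None:
        cols = list(ppi_table.columns[:2])
        for a, b in zip(ppi_table[cols[0]], ppi_table[cols[1]]):
            a, b = str(a), str(b)
            if a == b or a not in known_genes or b not in known_genes:
                continue
            ppi.add((min(a, b), max(a, b)))

    connected = {lid for lid, _ in roi} | {lid for lid, _ in eqtl}
    locus_ids = [lid for lid in dataset.locus_ids if lid in connected]
    if not locus_ids:
        raise EmptyNetworkError(
            "no genotyped locus is connected to any gene; "
            "network-constrained search is impossible"
        )
    return HeterogeneousNetwork(
        locus_ids=locus_ids,
        gene_ids=gene_ids,
        roi_edges=sorted(roi),
        eqtl_edges=sorted(eqtl),
        ppi_edges=sorted(ppi),
    )


def candidate_frontier(
    network: HeterogeneousNetwork, current_loci: Iterable[str]
) -> set[str]:
    """Loci (outside the current set) within the hop bound of the set."""
    current = set(current_loci)
    pos = network._locus_pos
    reach = network.locus_reachability
    out: set[str] = set()
    for lid in current:
        if lid not in pos:
            raise KeyError(f"locus {lid!r} is not a network node")
        out.update(
            network.locus_ids[j] for j in np.flatnonzero(reach[pos[lid]])
        )
    return out - current


def reachability_for(
    network: HeterogeneousNetwork, locus_ids: Sequence[str]
) -> np.ndarray:
    """Reachability matrix re-indexed to an arbitrary locus ordering.

    Loci absent from the network get empty rows/columns (they can never be
    added after the first pick).
    """
    n = len(locus_ids)
    out = np.zeros((n, n), dtype=bool)
    pos = network._locus_pos
    present = [(i, pos[lid]) for i, lid in enumerate(locus_ids) if lid in pos]
    if not present:
        return out
    di, ni = map(np.array, zip(*present))
    out[np.ix_(di, di)] = network.locus_reachability[np.ix_(ni, ni)]
    return out


def discover_netpocos(
    dataset: GwasDataset,
    profiles: BinaryProfileSet,
    network: HeterogeneousNetwork,
    coverage_fraction: float = DEFAULTS.coverage_fraction,
    emit_partial: bool = False,
) -> PoCoCollection:
    """Network-constrained locus-set discovery.

    Identical to the network-free search except that the candidate pool is
    restricted to network loci U, the first locus of each set is free, and
    every later addition must lie within the hop bound of a locus already
    in the set. Consumed loci leave the candidate pool but remain as graph
    nodes (irrelevant for paths, which never traverse loci).
    """
    in_network = set(network.locus_ids)
    pool = [lid for lid in profiles.locus_ids if lid in in_network]
    reach = reachability_for(network, profiles.locus_ids)
    return discover_pocos(
        dataset,
        profiles,
        coverage_fraction=coverage_fraction,
        emit_partial=emit_partial,
        reach=reach,
        candidate_pool=pool,
    )


def gene_frequency_report(
    collection: PoCoCollection,
    network: HeterogeneousNetwork,
    selected_pocos: Iterable[int] | None = None,
    top_k: int = DEFAULTS.gene_report_top_k,
) -> pd.DataFrame:
    """Most frequent genes across selected locus sets.

    A gene counts once per selected set containing at least one locus
    adjacent to it (RoI or eQTL edge). Returns up to ``top_k`` genes sorted
    by count descending, ties by gene id; ``top_k=None`` returns all.
    """
    indices = range(len(collection)) if selected_pocos is None else selected_pocos
    counts: dict[str, int] = {}
    for i in indices:
        genes: set[str] = set()
        for lid in collection[i].loci:
            genes |= network.genes_adjacent_to(lid)
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ranked = ranked[:top_k]
    return pd.DataFrame(ranked, columns=["gene_id", "count"])
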