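"""Domain types and I/O for interactomes, gene tables and disruption tables.

The central object is :class:`PPINetwork`, an immutable undirected simple
graph over gene identifiers.  :func:`prune_network` turns a genome's set of
disrupted genes into an "evolved" network by deleting the matching nodes and
all incident edges.

All tabular formats are plain UTF-8 TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MUTATION_CLASSES",
    "PPINetwork",
    "GeneTable",
    "DisruptionTable",
    "FormatError",
    "read_edge_list",
    "write_edge_list",
    "read_gene_table",
    "write_gene_table",
    "read_disruptions",
    "write_disruptions",
    "prune_network",
    "degree",
]

#: Mutation classes treated as loss-of-function gene disruptions.
MUTATION_CLASSES = frozenset(
    {"nonsense_snp", "small_indel", "mob_insertion", "large_deletion"}
)


class FormatError(ValueError):
    """Raised when an input file does not match the expected TSV layout."""


def _normalize_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple graph: nodes are gene ids, edges are interactions.

    Invariants enforced on construction: no self-loops, edges stored as
    sorted pairs (so reversed duplicates collapse), every edge endpoint is a
    node.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    name: str = "network"

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a > b:
                raise ValueError(f"edge {(a, b)!r} not normalized (a <= b)")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)!r} has endpoint outside node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        name: str = "network",
    ) -> "PPINetwork":
        """Build a network from raw edge pairs.

        Self-loops are dropped entirely (neither endpoint is added); plain
        and reversed duplicates collapse.  ``extra_nodes`` adds isolated
        nodes (used by the synthetic generator; file readers never pass it).
        """
        node_set: set[str] = set(extra_nodes)
        edge_set: set[tuple[str, str]] = set()
        n_self_loops = 0
        n_dupes = 0
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                n_self_loops += 1
                continue
            e = _normalize_edge(a, b)
            if e in edge_set:
                n_dupes += 1
                continue
            edge_set.add(e)
            node_set.add(a)
            node_set.add(b)
        if n_self_loops or n_dupes:
            logger.info(
                "network %s: dropped %d self-loop and %d duplicate edge records",
                name,
                n_self_loops,
                n_dupes,
            )
        return cls(frozenset(node_set), frozenset(edge_set), name=name)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def _degree_map(self) -> dict[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def degree(self, gene: str) -> int:
        """Number of incident edges; 0 for genes absent from the network."""
        return self._degree_map.get(gene, 0)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)


@dataclass(frozen=True)
class GeneTable:
    """Per-gene coordinates on a circular chromosome plus essentiality flags.

    Coordinates are 1-based inclusive; a gene with ``start > end`` wraps
    around the origin.  ``frame`` is indexed by gene id with columns
    ``start, end, strand, essential, length``.
    """

    frame: pd.DataFrame
    chromosome_length: int

    def __post_init__(self) -> None:
        df = self.frame
        L = self.chromosome_length
        if L <= 0:
            raise ValueError("chromosome length must be positive")
        if not df.index.is_unique:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes}")
        for col in ("start", "end", "strand", "essential", "length"):
            if col not in df.columns:
                raise ValueError(f"gene table missing column {col!r}")
        bad = df[(df["start"] < 1) | (df["start"] > L) | (df["end"] < 1) | (df["end"] > L)]
        if len(bad):
            raise ValueError(
                f"gene coordinates outside [1, {L}]: {sorted(bad.index)}"
            )
        if (df["length"] <= 0).any():
            raise ValueError("non-positive gene length")

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        chromosome_length: int | None = None,
    ) -> "GeneTable":
        """Build from a frame with columns gene, start, end, strand, essential.

        Lengths are recomputed wrap-aware; if ``chromosome_length`` is not
        given it defaults to the maximum observed coordinate.
        """
        df = records.copy()
        if "gene" in df.columns:
            df = df.set_index("gene")
        df.index = df.index.astype(str)
        L = int(chromosome_length) if chromosome_length else int(
            max(df["start"].max(), df["end"].max())
        )
        start = df["start"].astype(int)
        end = df["end"].astype(int)
        length = end - start + 1
        wrapped = end < start
        length[wrapped] = L - start[wrapped] + 1 + end[wrapped]
        df["start"] = start
        df["end"] = end
        df["length"] = length
        df["essential"] = df["essential"].map(_parse_bool)
        return cls(df[["start", "end", "strand", "essential", "length"]], L)

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.frame.index)

    def length(self, gene: str) -> int:
        return int(self.frame.at[gene, "length"])

    def is_essential(self, gene: str) -> bool:
        return bool(self.frame.at[gene, "essential"])

    @property
    def essential_genes(self) -> frozenset[str]:
        return frozenset(self.frame.index[self.frame["essential"]])

    def midpoint(self, gene: str) -> float:
        """Gene midpoint in bp, wrap-aware on the circular chromosome."""
        if gene not in self:
            raise KeyError(f"unknown gene {gene!r}")
        start = int(self.frame.at[gene, "start"])
        half = (self.length(gene) - 1) / 2.0
        return (start - 1 + half) % self.chromosome_length + 1


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no"}:
        return False
    raise ValueError(f"cannot parse boolean flag {value!r}")


@dataclass(frozen=True)
class DisruptionTable:
    """Per-clone gene disruptions.

    ``frame`` columns: population, generation, clone, gene, mutation_class,
    deletion_block (nullable).  A clone's rows list every gene disrupted in
    that genome, so records are cumulative along a lineage.
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("population", "generation", "clone", "gene", "mutation_class", "deletion_block")

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("population", "generation", "clone", "gene", "mutation_class"):
            if col not in df.columns:
                raise ValueError(f"disruption table missing column {col!r}")
        bad_class = sorted(set(df["mutation_class"]) - MUTATION_CLASSES)
        if bad_class:
            raise ValueError(f"unknown mutation_class values: {bad_class}")
        if (df["generation"] < 0).any():
            raise ValueError("negative generation")
        key = df[["population", "generation", "clone", "gene"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].head(5).to_dict("records")
            raise ValueError(f"duplicate disruption records, e.g. {dupes}")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, genes: GeneTable | None = None
    ) -> "DisruptionTable":
        df = frame.copy()
        if "deletion_block" not in df.columns:
            df["deletion_block"] = pd.NA
        df["gene"] = df["gene"].astype(str)
        df["generation"] = df["generation"].astype(int)
        if genes is not None:
            unknown = sorted(set(df["gene"]) - set(genes.frame.index))
            if unknown:
                raise ValueError(
                    f"disrupted genes absent from gene table: {unknown}"
                )
        return cls(df[list(cls.COLUMNS)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population"].unique())

    @property
    def generations(self) -> list[int]:
        return sorted(self.frame["generation"].unique())

    def genes_by_clone(self) -> dict[str, frozenset[str]]:
        """Distinct disrupted genes per clone label."""
        out: dict[str, frozenset[str]] = {}
        for clone, grp in self.frame.groupby("clone"):
            out[str(clone)] = frozenset(grp["gene"])
        return out

    def clone_index(self) -> pd.DataFrame:
        """One row per clone: population, generation, clone, n_disrupted."""
        grp = self.frame.groupby(["population", "generation", "clone"], sort=True)
        out = grp["gene"].nunique().rename("n_disrupted").reset_index()
        return out

    def at_generation(self, generation: int) -> "DisruptionTable":
        return DisruptionTable(
            self.frame[self.frame["generation"] == generation].reset_index(drop=True)
        )

    def multigene_deletion_genes(self) -> frozenset[str]:
        """Genes hit by a deletion block spanning >= 2 distinct genes."""
        df = self.frame[self.frame["deletion_block"].notna()]
        if df.empty:
            return frozenset()
        sizes = df.groupby("deletion_block")["gene"].nunique()
        blocks = set(sizes.index[sizes >= 2])
        return frozenset(df.loc[df["deletion_block"].isin(blocks), "gene"])

    def single_disruption_genes(self) -> frozenset[str]:
        """Genes with at least one record outside multi-gene deletion blocks."""
        multi_blocks = set()
        blocked = self.frame[self.frame["deletion_block"].notna()]
        if len(blocked):
            sizes = blocked.groupby("deletion_block")["gene"].nunique()
            multi_blocks = set(sizes.index[sizes >= 2])
        mask = self.frame["deletion_block"].isna() | ~self.frame["deletion_block"].isin(
            multi_blocks
        )
        return frozenset(self.frame.loc[mask, "gene"])


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, header: bool) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except Exception as exc:  # pragma: no cover - parser-specific messages
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc


def read_edge_list(path: str | Path, header: bool = True, name: str | None = None) -> PPINetwork:
    """Read an undirected edge list (two gene-id columns, TSV).

    Header presence is an explicit flag (default True), never guessed.
    Self-loops are dropped and duplicate/reversed edges collapsed, with
    counts logged.
    """
    df = _read_tsv(path, header)
    if df.empty:
        if df.shape[1] not in (0, 2) and df.shape[1] < 2:
            raise FormatError(f"edge list {path} has fewer than 2 columns")
        return PPINetwork(frozenset(), frozenset(), name=name or Path(path).stem)
    if df.shape[1] < 2:
        raise FormatError(f"edge list {path} has fewer than 2 columns")
    pairs = zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))
    return PPINetwork.from_edges(pairs, name=name or Path(path).stem)


def write_edge_list(network: PPINetwork, path: str | Path, header: bool = True) -> None:
    df = pd.DataFrame(sorted(network.edges), columns=["gene_a", "gene_b"])
    df.to_csv(path, sep="\t", index=False, header=header)


def read_gene_table(
    path: str | Path, chromosome_length: int | None = None, header: bool = True
) -> GeneTable:
    """Read a gene table TSV: gene, start, end, strand, essential[, length].

    If ``chromosome_length`` is omitted it is inferred as the maximum
    observed coordinate; pass it explicitly when wrap-around genes are
    present.
    """
    df = _read_tsv(path, header)
    required = {"gene", "start", "end", "strand", "essential"}
    if not header:
        cols = ["gene", "start", "end", "strand", "essential"][: df.shape[1]]
        df.columns = cols + [f"extra_{i}" for i in range(df.shape[1] - len(cols))]
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene table {path} missing columns {sorted(missing)}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return GeneTable.from_records(df, chromosome_length=chromosome_length)


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    out = genes.frame.reset_index(names="gene")
    out.to_csv(path, sep="\t", index=False)


def read_disruptions(
    path: str | Path, genes: GeneTable, header: bool = True
) -> DisruptionTable:
    """Read a disruption table TSV and validate it against the gene table."""
    df = _read_tsv(path, header)
    if df.empty:
        return DisruptionTable.from_frame(
            pd.DataFrame(columns=list(DisruptionTable.COLUMNS))
        )
    if not header:
        cols = ["population", "generation", "clone", "gene", "mutation_class", "deletion_block"]
        df.columns = cols[: df.shape[1]]
    missing = {"population", "generation", "clone", "gene", "mutation_class"} - set(df.columns)
    if missing:
        raise FormatError(f"disruption table {path} missing columns {sorted(missing)}")
    return DisruptionTable.from_frame(df, genes=genes)


def write_disruptions(disruptions: DisruptionTable, path: str | Path) -> None:
    disruptions.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def prune_network(ancestor: PPINetwork, disrupted: Iterable[str]) -> PPINetwork:
    """Remove disrupted genes and all incident edges; ancestor is unmodified.

    Disrupted genes not present in the network are tolerated (their count is
    logged) — published disruption sets routinely include genes outside the
    interactome.
    """
    disrupted = set(disrupted)
    hit = disrupted & ancestor.nodes
    outside = len(disrupted) - len(hit)
    if outside:
        logger.debug(
            "prune %s: %d disrupted genes not in the network", ancestor.name, outside
        )
    if not hit:
        return PPINetwork(ancestor.nodes, ancestor.edges, name=ancestor.name)
    nodes = ancestor.nodes - hit
    edges = frozenset(e for e in ancestor.edges if e[0] not in hit and e[1] not in hit)
    return PPINetwork(nodes, edges, name=ancestor.name)


def degree(network: PPINetwork, gene: str) -> int:
    """Degree of ``gene`` in ``network``; 0 if absent."""
    return network.degree(gene)


def degrees(network: PPINetwork, genes: Iterable[str]) -> Mapping[str, int]:
    return {g: network.degree(g) for g in genes}
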