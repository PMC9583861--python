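"""Per-cancer anti-correlation regulatory networks and pan-cancer summaries.

For every putative isomiR→target pair (from the harmonized targetomes) we
compute Spearman's correlation between the isomiR and gene log-expression
profiles across the cohort's samples.  An interaction is significant when
rho < -0.3 (strict) and the Benjamini-Hochberg adjusted p-value is < 0.05
(strict).  Two FDR flavors are kept side by side:

* ``fdr_global`` — BH over the p-values of *all* putative interactions of
  the cohort (used for whole-network views);
* ``fdr_local`` — BH within the narrow per-isomiR query list (used when a
  single isomiR's targets, or a single gene's regulators, are inspected
  out of the context of other interactions).

The out-degree of an isomiR in the significant-edge network is its
*isomiR targeting activity* (ITA).  Co-expression modules are maximal
cliques of the isomiR graph whose edges require |rho| > 0.5, and the
pan-cancer "universal" network keeps abundantly expressed isomiRs
together with edges significant in at least half of the cohorts where the
isomiR is highly expressed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import parse_isomir_name
from .targetome import Targetome

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineThresholds:
    """All scalar cut-offs of the pipeline, serialized with every run.

    All comparisons are strict (<, >) unless noted: rho below ``rho_max``,
    FDR below ``fdr_max``, miRDB score >= ``mirdb_min`` (inclusive),
    co-expression edges at |rho| > ``clique_abs_rho``.
    """

    rho_max: float = -0.3
    fdr_max: float = 0.05
    mirdb_min: float = 80.0
    highly_expr_fraction: float = 0.95
    clique_abs_rho: float = 0.5
    len_min: int = 17
    len_max: int = 29
    abundant_min_cancers: int = 10
    universal_min_fraction: float = 0.5
    ora_fdr: float = 0.05

    def __post_init__(self) -> None:
        checks = [
            (-1.0 <= self.rho_max <= 1.0, "rho_max must lie in [-1, 1]"),
            (0.0 < self.fdr_max <= 1.0, "fdr_max must lie in (0, 1]"),
            (0.0 <= self.mirdb_min <= 100.0, "mirdb_min must lie in [0, 100]"),
            (0.0 < self.highly_expr_fraction <= 1.0, "highly_expr_fraction must lie in (0, 1]"),
            (0.0 <= self.clique_abs_rho <= 1.0, "clique_abs_rho must lie in [0, 1]"),
            (1 <= self.len_min <= self.len_max, "need 1 <= len_min <= len_max"),
            (self.abundant_min_cancers >= 1, "abundant_min_cancers must be >= 1"),
            (0.0 < self.universal_min_fraction <= 1.0, "universal_min_fraction in (0, 1]"),
            (0.0 < self.ora_fdr <= 1.0, "ora_fdr must lie in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise NetworkError(f"invalid thresholds: {msg}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegulatoryNetwork:
    """Per-cohort directed bipartite isomiR→gene network.

    ``edges`` holds every *tested* putative pair with its statistics and
    significance flag; ``graph`` contains only the significant edges.
    """

    cohort_id: str | None
    edges: pd.DataFrame  # isomir, gene, rho, p_raw, fdr_global, fdr_local, significant
    graph: nx.DiGraph
    fdr_mode: str = "global"
    n_dropped_genes: int = 0
    n_skipped_constant: int = 0

    @property
    def isomirs(self) -> list[str]:
        return sorted(self.edges["isomir"].unique())


def spearman_rho(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman correlation with mid-ranks for ties.

    ``method="t"`` uses the large-sample t approximation for the p-value;
    ``method="exact"`` enumerates all rank permutations (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NetworkError("spearman_rho needs two equal-length vectors")
    if x.size < 3:
        raise NetworkError("spearman_rho needs at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise NetworkError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p)
    if method != "exact":
        raise NetworkError(f"unknown p-value method {method!r}")
    n = x.size
    if n > 10:
        raise NetworkError("exact permutation p-value limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
            count += 1
    return float(rho), count / total


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise NetworkError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_interaction_network(
    isomir_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    targetomes: Mapping[str, Targetome],
    thresholds: PipelineThresholds | None = None,
    fdr_mode: str = "global",
    cohort_id: str | None = None,
    isomir_subset: Iterable[str] | None = None,
) -> RegulatoryNetwork:
    """Anti-correlation network over all putative isomiR→target pairs.

    Both matrices are log-normalized (features × samples); correlation is
    computed on the shared samples.  ``isomir_subset`` (typically the
    cohort's highly-expressed set) restricts which isomiRs are tested.
    Putative target genes absent from ``gene_expr`` are dropped with a
    logged count; isomiRs/genes with constant profiles are skipped.
    """
    if fdr_mode not in {"global", "local"}:
        raise NetworkError(f"fdr_mode must be 'global' or 'local', got {fdr_mode!r}")
    thresholds = thresholds or PipelineThresholds()
    shared = [s for s in isomir_expr.columns if s in set(gene_expr.columns)]
    if len(shared) < 3:
        raise NetworkError(
            f"need at least 3 shared samples, found {len(shared)}"
        )
    iso_m = isomir_expr[shared]
    gene_m = gene_expr[shared]

    names = [n for n in iso_m.index if n in targetomes]
    if isomir_subset is not None:
        keep = set(isomir_subset)
        names = [n for n in names if n in keep]

    rows: list[tuple[str, str, float, float]] = []
    n_dropped = 0
    n_constant = 0
    gene_index = set(gene_m.index)
    for name in names:
        x = iso_m.loc[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            n_constant += 1
            logger.warning("isomiR %s has a constant profile; skipped", name)
            continue
        for gene in sorted(targetomes[name].genes):
            if gene not in gene_index:
                n_dropped += 1
                continue
            y = gene_m.loc[gene].to_numpy(dtype=float)
            if np.all(y == y[0]):
                n_constant += 1
                continue
            rho, p = spearman_rho(x, y)
            rows.append((name, gene, rho, p))
    if n_dropped:
        logger.info("dropped %d putative targets absent from the expression matrix", n_dropped)

    edges = pd.DataFrame(rows, columns=["isomir", "gene", "rho", "p_raw"])
    if len(edges):
        edges["fdr_global"] = bh_adjust(edges["p_raw"].to_numpy())
        edges["fdr_local"] = (
            edges.groupby("isomir")["p_raw"].transform(lambda p: bh_adjust(p.to_numpy()))
        )
        chosen = edges["fdr_global"] if fdr_mode == "global" else edges["fdr_local"]
        edges["significant"] = (edges["rho"] < thresholds.rho_max) & (chosen < thresholds.fdr_max)
    else:
        edges["fdr_global"] = pd.Series(dtype=float)
        edges["fdr_local"] = pd.Series(dtype=float)
        edges["significant"] = pd.Series(dtype=bool)
    edges = edges.sort_values(["isomir", "gene"], kind="mergesort").reset_index(drop=True)

    graph = nx.DiGraph()
    medians = iso_m.median(axis=1)
    for name in names:
        try:
            _, shift = parse_isomir_name(name)
            canonical = shift == 0
        except ValueError:
            canonical = None
        graph.add_node(
            name,
            kind="isomir",
            canonical=canonical,
            median_expr=float(medians.get(name, np.nan)),
        )
    for row in edges[edges["significant"]].itertuples():
        if row.gene not in graph:
            graph.add_node(row.gene, kind="gene")
        graph.add_edge(row.isomir, row.gene, rho=float(row.rho), p_raw=float(row.p_raw))

    return RegulatoryNetwork(
        cohort_id=cohort_id,
        edges=edges,
        graph=graph,
        fdr_mode=fdr_mode,
        n_dropped_genes=n_dropped,
        n_skipped_constant=n_constant,
    )


def ita(network: RegulatoryNetwork) -> dict[str, int]:
    """isomiR targeting activity: significant out-degree per tested isomiR."""
    out = {name: 0 for name in network.isomirs}
    for name in out:
        if name in network.graph:
            out[name] = network.graph.out_degree(name)
    return out


def isomir_coexpression_graph(
    isomir_expr: pd.DataFrame, clique_abs_rho: float = 0.5
) -> nx.Graph:
    """Undirected isomiR graph with edges at |Spearman rho| strictly > threshold.

    Constant isomiR rows are excluded with a warning (their correlation is
    undefined).
    """
    if isomir_expr.shape[1] < 3:
        raise NetworkError("co-expression graph needs at least 3 samples")
    values = isomir_expr.to_numpy(dtype=float)
    keep = ~np.all(values == values[:, :1], axis=1)
    if not keep.all():
        for name in isomir_expr.index[~keep]:
            logger.warning("isomiR %s has a constant profile; excluded from co-expression", name)
    names = list(isomir_expr.index[keep])
    graph = nx.Graph()
    graph.add_nodes_from(names)
    if len(names) >= 2:
        rho = stats.spearmanr(values[keep].T).statistic
        rho = np.atleast_2d(rho)
        for i, j in itertools.combinations(range(len(names)), 2):
            if abs(rho[i, j]) > clique_abs_rho:
                graph.add_edge(names[i], names[j], rho=float(rho[i, j]))
    return graph


def find_modules(graph: nx.Graph) -> list[frozenset[str]]:
    """All maximal cliques (isolated nodes yield singleton modules)."""
    cliques = [frozenset(c) for c in nx.find_cliques(graph)]
    return sorted(cliques, key=lambda c: (-len(c), tuple(sorted(c))))


def module_representatives(
    modules: Iterable[frozenset[str]], isomir_expr: pd.DataFrame
) -> set[str]:
    """Highest-median-expression member of each module, deduplicated.

    Median ties are broken by lexicographically smallest name.
    """
    medians = isomir_expr.median(axis=1)
    reps: set[str] = set()
    for module in modules:
        missing = [m for m in module if m not in medians.index]
        if missing:
            raise NetworkError(f"module members without expression rows: {missing}")
        reps.add(min(module, key=lambda m: (-medians[m], m)))
    return reps


def universal_interactions(
    per_cancer_networks: Mapping[str, RegulatoryNetwork],
    highly_expressed_map: Mapping[str, Iterable[str]],
    thresholds: PipelineThresholds | None = None,
    rounding: str = "ceil",
) -> nx.DiGraph:
    """Pan-cancer network of abundantly expressed isomiRs.

    Keeps isomiRs highly expressed in >= ``abundant_min_cancers`` cohorts;
    an edge survives iff it is significant in at least
    ``universal_min_fraction`` of the cohorts where its isomiR is highly
    expressed ("at least half" uses the ceiling by default).  Edge weight
    ``support`` is the number of supporting cohorts.
    """
    if not per_cancer_networks:
        raise NetworkError("universal network needs at least one cohort")
    if rounding not in {"ceil", "floor"}:
        raise NetworkError("rounding must be 'ceil' or 'floor'")
    thresholds = thresholds or PipelineThresholds()
    he_map = {c: set(v) for c, v in highly_expressed_map.items()}

    he_counts: dict[str, int] = {}
    for cohort, isomirs in he_map.items():
        for name in isomirs:
            he_counts[name] = he_counts.get(name, 0) + 1
    abundant = {n for n, k in he_counts.items() if k >= thresholds.abundant_min_cancers}

    support: dict[tuple[str, str], int] = {}
    for cohort in sorted(per_cancer_networks):
        net = per_cancer_networks[cohort]
        sig = net.edges[net.edges["significant"]]
        for row in sig.itertuples():
            if row.isomir in abundant and row.isomir in he_map.get(cohort, set()):
                key = (row.isomir, row.gene)
                support[key] = support.get(key, 0) + 1

    rounder = math.ceil if rounding == "ceil" else math.floor
    graph = nx.DiGraph()
    for name in sorted(abundant):
        graph.add_node(name, kind="isomir", n_highly_expressed=he_counts[name])
    for (isomir, gene), count in sorted(support.items()):
        need = max(1, rounder(thresholds.universal_min_fraction * he_counts[isomir]))
        if count >= need:
            if gene not in graph:
                graph.add_node(gene, kind="gene")
            graph.add_edge(isomir, gene, support=count)
    return graph


def ora_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    ora_fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in annotated sets.

    Gene sets are intersected with the background universe; per set a
    one-sided hypergeometric tail P(X >= overlap) is computed, followed by
    BH adjustment across sets.
    """
    query = set(query_genes)
    universe = set(background)
    if not query <= universe:
        raise NetworkError("query genes must be contained in the background universe")
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        overlap = len(members & query)
        if members:
            p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        else:
            p = 1.0
        rows.append((set_id, overlap, len(members), min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size", "p"])
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["fdr"] < ora_fdr
    else:
        table["fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
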