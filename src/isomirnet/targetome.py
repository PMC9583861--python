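"""Harmonization of two target-prediction dialects into per-isomiR targetomes.

Two score tables are consumed as inputs: one in the miRDB dialect (target
score in [0, 100], higher = more confident; 80 is the conventional
high-confidence cut-off) and one in the TargetScan dialect (cumulative
weighted context++ score, CWCS; more negative = stronger predicted
repression).  Because CWCS has no conventional cut-off, the two sources
are equalized per isomiR: keep miRDB predictions with score >= 80, then
take the same number n of best-ranked (lowest-CWCS) TargetScan
predictions, and use the union.  Target prediction is attempted only for
isomiRs whose sequence length lies in [17, 29] nt.

Targetomes are sequence-derived and therefore cancer-agnostic; they are
computed once per isomiR and reused across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .catalog import AdjacentPair, IsomiR

logger = logging.getLogger(__name__)

MIRDB_DIALECT = "mirdb_score"
TARGETSCAN_DIALECT = "targetscan_cwcs"
_DIALECTS = (MIRDB_DIALECT, TARGETSCAN_DIALECT)


class TargetomeError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionTable:
    """Rows of (isomir, gene, score) in one prediction dialect."""

    table: pd.DataFrame  # columns: isomir, gene, score
    dialect: str

    def __post_init__(self) -> None:
        if self.dialect not in _DIALECTS:
            raise TargetomeError(f"unknown dialect {self.dialect!r}; expected one of {_DIALECTS}")
        required = {"isomir", "gene", "score"}
        if not required.issubset(self.table.columns):
            raise TargetomeError(f"prediction table needs columns {sorted(required)}")
        if self.table.duplicated(subset=["isomir", "gene"]).any():
            raise TargetomeError("duplicate (isomir, gene) rows in prediction table")
        if self.dialect == MIRDB_DIALECT and len(self.table):
            s = self.table["score"]
            if (s < 0).any() or (s > 100).any():
                raise TargetomeError("miRDB scores must lie in [0, 100]")


@dataclass(frozen=True)
class Targetome:
    """Predicted target-gene set of one isomiR with per-gene provenance."""

    isomir: str
    provenance: Mapping[str, str]  # gene -> {"mirdb", "targetscan", "both"}

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)


def length_gate(isomir: IsomiR | str, min_len: int = 17, max_len: int = 29) -> bool:
    """Eligibility for target prediction: sequence length within [17, 29] nt."""
    seq = isomir.sequence if isinstance(isomir, IsomiR) else isomir
    return min_len <= len(seq) <= max_len


def filter_mirdb(table: PredictionTable, min_score: float = 80.0) -> dict[str, set[str]]:
    """Per-isomiR gene sets surviving the miRDB score cut-off (inclusive)."""
    if table.dialect != MIRDB_DIALECT:
        raise TargetomeError(f"filter_mirdb needs the {MIRDB_DIALECT} dialect, got {table.dialect}")
    kept = table.table[table.table["score"] >= min_score]
    out: dict[str, set[str]] = {}
    for isomir, group in kept.groupby("isomir"):
        out[str(isomir)] = set(group["gene"])
    return out


def select_targetscan_topn(table: PredictionTable, isomir: str, n: int) -> set[str]:
    """The ``n`` genes with smallest (most negative) CWCS for one isomiR.

    Ties are broken lexicographically by gene id; if fewer than ``n``
    predictions exist, all are returned.
    """
    if table.dialect != TARGETSCAN_DIALECT:
        raise TargetomeError(
            f"select_targetscan_topn needs the {TARGETSCAN_DIALECT} dialect, got {table.dialect}"
        )
    if n < 0:
        raise TargetomeError("n must be >= 0")
    rows = table.table[table.table["isomir"] == isomir]
    ranked = rows.sort_values(["score", "gene"], kind="mergesort")
    return set(ranked["gene"].head(n))


def harmonize_targetome(
    mirdb_set: set[str], ts_table: PredictionTable, isomir: str
) -> Targetome:
    """Union of filtered miRDB targets and the equal-sized TargetScan top-n."""
    n = len(mirdb_set)
    ts_set = select_targetscan_topn(ts_table, isomir, n)
    provenance: dict[str, str] = {}
    for gene in mirdb_set | ts_set:
        if gene in mirdb_set and gene in ts_set:
            provenance[gene] = "both"
        elif gene in mirdb_set:
            provenance[gene] = "mirdb"
        else:
            provenance[gene] = "targetscan"
    return Targetome(isomir=isomir, provenance=provenance)


def build_targetomes(
    mirdb_table: PredictionTable,
    ts_table: PredictionTable,
    isomirs: Iterable[IsomiR],
    min_score: float = 80.0,
    min_len: int = 17,
    max_len: int = 29,
) -> dict[str, Targetome]:
    """Harmonized targetomes for every length-eligible isomiR."""
    mirdb_sets = filter_mirdb(mirdb_table, min_score=min_score)
    out: dict[str, Targetome] = {}
    n_gated = 0
    for iso in isomirs:
        if not length_gate(iso, min_len=min_len, max_len=max_len):
            n_gated += 1
            continue
        out[iso.name] = harmonize_targetome(mirdb_sets.get(iso.name, set()), ts_table, iso.name)
    if n_gated:
        logger.info("length gate excluded %d isomiRs from target prediction", n_gated)
    return out


def jaccard_index(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B|; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise TargetomeError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def containment_fraction(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Percentage of A contained in B: 100 * |A ∩ B| / |A|."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise TargetomeError("containment undefined for an empty reference set")
    return 100.0 * len(a & b) / len(a)


def adjacent_jaccard_profile(
    pairs: Iterable[AdjacentPair],
    targetomes: Mapping[str, Targetome],
) -> list[tuple[AdjacentPair, float]]:
    """Jaccard index of the two targetomes for every adjacent isomiR pair.

    Pairs where either member lacks a targetome (length-gated) or where
    both targetomes are empty are skipped with a logged warning.
    """
    profile: list[tuple[AdjacentPair, float]] = []
    for pair in pairs:
        name_a, name_b = pair.names
        if name_a not in targetomes or name_b not in targetomes:
            logger.warning("skipping pair (%s, %s): missing targetome", name_a, name_b)
            continue
        genes_a = targetomes[name_a].genes
        genes_b = targetomes[name_b].genes
        if not genes_a and not genes_b:
            logger.warning("skipping pair (%s, %s): both targetomes empty", name_a, name_b)
            continue
        profile.append((pair, jaccard_index(genes_a, genes_b)))
    return profile
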