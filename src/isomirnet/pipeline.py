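"""Per-cohort and pan-cancer orchestration.

``run_cohort`` executes the full per-cohort chain: aggregate isoform
records to 5'-isomiR counts → low-expression filter → TMM → RPM/FPKM →
log2 → highly-expressed calling → targetome harmonization → interaction
network (both FDR columns) → ITA table → co-expression modules → optional
over-representation analysis.  ``run_pancancer`` combines the per-cohort
outputs into the binarized highly-expressed matrix, the pan-cancer ITA
table, the universal interaction network and the adjacent-pair Jaccard /
merged-seed analysis.

Every output file carries the hash of the *scientific* configuration
(thresholds, seed, cohort ids, fdr mode — not file paths) so reruns are
traceable; run reports record the input/output cardinality of every
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import expression, networks, quantio, synthetic, targetome as tg
from .catalog import (
    HairpinRecord,
    IsomiR,
    MatureAnnotation,
    compute_5p_shift,
    dedup_merged_seeds,
    enumerate_adjacent_pairs,
    format_isomir_name,
    merge_seed_regions,
    uracil_start_test,
)
from .networks import PipelineThresholds
from .quantio import FormatError, IsoformQuantRecord, mature_genomic_interval

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


class PipelineError(RuntimeError):
    pass


@dataclass
class CohortInputs:
    quantification: Path
    gene_counts: Path


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_config`` for the YAML layout)."""

    cohorts: dict[str, CohortInputs]
    hairpin_fasta: Path
    mirna_gff3: Path
    gene_lengths: Path
    mirdb_table: Path
    targetscan_table: Path
    output_dir: Path
    gmt: Path | None = None
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    fdr_mode: str = "global"
    seed: int = 0
    max_abs_shift: int = 5
    top_pairs: int = 50
    uracil_null_freq: float = 0.25

    def __post_init__(self) -> None:
        if self.fdr_mode not in {"global", "local"}:
            raise PipelineError(f"fdr_mode must be 'global' or 'local', got {self.fdr_mode!r}")
        if not 0 < self.uracil_null_freq < 1:
            raise PipelineError("uracil_null_freq must lie in (0, 1)")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so a run is
        reproducible wherever its inputs live)."""
        payload = {
            "cohorts": sorted(self.cohorts),
            "thresholds": self.thresholds.to_dict(),
            "fdr_mode": self.fdr_mode,
            "seed": self.seed,
            "max_abs_shift": self.max_abs_shift,
            "top_pairs": self.top_pairs,
            "uracil_null_freq": self.uracil_null_freq,
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
        return digest[:16]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def _p(value: str) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    try:
        cohorts = {
            cid: CohortInputs(
                quantification=_p(spec["quantification"]),
                gene_counts=_p(spec["gene_counts"]),
            )
            for cid, spec in raw["cohorts"].items()
        }
        thresholds = PipelineThresholds(**raw.get("thresholds", {}))
        config = RunConfig(
            cohorts=cohorts,
            hairpin_fasta=_p(raw["hairpin_fasta"]),
            mirna_gff3=_p(raw["mirna_gff3"]),
            gene_lengths=_p(raw["gene_lengths"]),
            mirdb_table=_p(raw["mirdb_table"]),
            targetscan_table=_p(raw["targetscan_table"]),
            gmt=_p(raw["gmt"]) if raw.get("gmt") else None,
            output_dir=_p(raw["output_dir"]),
            thresholds=thresholds,
            fdr_mode=raw.get("fdr_mode", "global"),
            seed=int(raw.get("seed", 0)),
            max_abs_shift=int(raw.get("max_abs_shift", 5)),
            top_pairs=int(raw.get("top_pairs", 50)),
            uracil_null_freq=float(raw.get("uracil_null_freq", 0.25)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PipelineError(f"invalid configuration {path}: {exc}") from exc
    for cid, inputs in config.cohorts.items():
        for p in (inputs.quantification, inputs.gene_counts):
            if not p.exists():
                raise PipelineError(f"cohort {cid}: missing input {p}")
    for p in (
        config.hairpin_fasta,
        config.mirna_gff3,
        config.gene_lengths,
        config.mirdb_table,
        config.targetscan_table,
    ):
        if not p.exists():
            raise PipelineError(f"missing input {p}")
    return config


def load_annotation(config: RunConfig) -> tuple[list[HairpinRecord], list[MatureAnnotation]]:
    sequences = quantio.read_hairpin_fasta(config.hairpin_fasta)
    return quantio.read_mirna_gff3(config.mirna_gff3, sequences)


def aggregate_isomir_counts(
    records: list[IsoformQuantRecord],
    hairpins: list[HairpinRecord],
    matures: list[MatureAnnotation],
    max_abs_shift: int = 5,
) -> tuple[pd.DataFrame, int]:
    """Collapse isoform records onto 5'-isomiR names and sum read counts.

    Each record is keyed by (mature arm, 5' shift) via its genomic 5' end;
    records sharing a key within a sample (3'-end variants) are summed.
    Records matching no mature arm within ``max_abs_shift`` land in an
    "unassigned" bucket that is reported, not raised.
    """
    hp_by_id = {hp.hairpin_id: hp for hp in hairpins}
    matures_by_hp: dict[str, list[MatureAnnotation]] = {}
    for mat in matures:
        matures_by_hp.setdefault(mat.hairpin_id, []).append(mat)

    totals: dict[tuple[str, str], int] = {}
    samples: list[str] = []
    seen_samples: set[str] = set()
    n_unassigned = 0
    for rec in records:
        if rec.sample_id not in seen_samples:
            seen_samples.add(rec.sample_id)
            samples.append(rec.sample_id)
        hp = hp_by_id.get(rec.mirna_id)
        if hp is None:
            raise PipelineError(f"record references unknown hairpin {rec.mirna_id!r}")
        best: tuple[int, str] | None = None
        for mat in matures_by_hp.get(hp.hairpin_id, []):
            interval = mature_genomic_interval(hp, mat)
            shift = compute_5p_shift((rec.chrom, rec.start, rec.end), interval, hp.strand)
            if abs(shift) <= max_abs_shift and (best is None or abs(shift) < abs(best[0])):
                best = (shift, mat.mature_id)
        if best is None:
            n_unassigned += rec.read_count
            logger.warning(
                "record %s:%d-%d on %s matched no mature arm; counted as unassigned",
                rec.chrom, rec.start, rec.end, rec.mirna_id,
            )
            continue
        name = format_isomir_name(best[1], best[0])
        key = (name, rec.sample_id)
        totals[key] = totals.get(key, 0) + rec.read_count

    names = sorted({k[0] for k in totals})
    matrix = pd.DataFrame(0, index=names, columns=samples, dtype=int)
    for (name, sample), count in totals.items():
        matrix.loc[name, sample] = count
    return matrix, n_unassigned


def build_catalog_isomirs(
    hairpins: list[HairpinRecord],
    matures: list[MatureAnnotation],
    names: list[str],
) -> list[IsomiR]:
    """Materialize IsomiR objects (with sequences) for observed isomiR names."""
    from .catalog import build_isomir, parse_isomir_name

    hp_by_id = {hp.hairpin_id: hp for hp in hairpins}
    mat_by_id = {m.mature_id: m for m in matures}
    out = []
    for name in names:
        mature_id, shift = parse_isomir_name(name)
        mat = mat_by_id.get(mature_id)
        if mat is None:
            raise PipelineError(f"no annotation for mature arm {mature_id!r}")
        out.append(build_isomir(hp_by_id[mat.hairpin_id], mat, shift))
    return out


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_cohort(config: RunConfig, cohort_id: str) -> dict:
    """Execute the full per-cohort pipeline and persist its outputs."""
    if cohort_id not in config.cohorts:
        raise PipelineError(f"unknown cohort {cohort_id!r}")
    thr = config.thresholds
    chash = config.config_hash()
    outdir = config.output_dir / cohort_id
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"cohort_id": cohort_id, "config_hash": chash, "stages": {}}

    def stage(name: str, **counts) -> None:
        report["stages"][name] = counts
        logger.info("[%s] %s: %s", cohort_id, name, counts)

    try:
        hairpins, matures = load_annotation(config)
        records = quantio.read_isoform_quantification(config.cohorts[cohort_id].quantification)
        iso_counts, n_unassigned = aggregate_isomir_counts(
            records, hairpins, matures, config.max_abs_shift
        )
        assigned = int(iso_counts.to_numpy().sum())
        stage(
            "aggregate",
            records_in=len(records),
            reads_assigned=assigned,
            reads_unassigned=n_unassigned,
            isomirs=iso_counts.shape[0],
            samples=iso_counts.shape[1],
        )

        filtered = expression.filter_low_expressed(iso_counts)
        stage("filter_isomirs", features_in=iso_counts.shape[0], kept=filtered.shape[0],
              filtered=iso_counts.shape[0] - filtered.shape[0])

        factors = expression.tmm_factors(filtered)
        iso_log = expression.log2_transform(expression.normalize(filtered, factors))
        quantio.write_matrix_tsv(iso_log, outdir / "isomir_log2_tmm_rpm.tsv", chash)

        he = expression.call_highly_expressed(
            filtered, fraction=thr.highly_expr_fraction, cohort_id=cohort_id
        )
        stage("highly_expressed", n=len(he.isomirs), coverage=round(he.coverage_fraction, 6))
        (outdir / "highly_expressed.txt").write_text(
            f"# config_hash: {chash}\n" + "".join(f"{n}\n" for n in he.isomirs)
        )

        gene_counts = quantio.read_counts_tsv(config.cohorts[cohort_id].gene_counts)
        lengths = quantio.read_lengths_tsv(config.gene_lengths)
        gene_filtered = expression.filter_low_expressed(gene_counts)
        stage("filter_genes", features_in=gene_counts.shape[0], kept=gene_filtered.shape[0],
              filtered=gene_counts.shape[0] - gene_filtered.shape[0])
        gene_factors = expression.tmm_factors(gene_filtered)
        gene_log = expression.log2_transform(
            expression.normalize(gene_filtered, gene_factors, lengths)
        )
        quantio.write_matrix_tsv(gene_log, outdir / "gene_log2_tmm_fpkm.tsv", chash)

        catalog = build_catalog_isomirs(hairpins, matures, list(filtered.index))
        mirdb = quantio.read_prediction_table(config.mirdb_table)
        ts = quantio.read_prediction_table(config.targetscan_table)
        targetomes = tg.build_targetomes(
            mirdb, ts, catalog, min_score=thr.mirdb_min,
            min_len=thr.len_min, max_len=thr.len_max,
        )
        quantio.write_targetomes_tsv(targetomes, outdir / "targetomes.tsv", chash)
        stage("targetomes", isomirs=len(targetomes),
              genes=len({g for t in targetomes.values() for g in t.genes}))

        network = networks.build_interaction_network(
            iso_log, gene_log, targetomes,
            thresholds=thr, fdr_mode=config.fdr_mode,
            cohort_id=cohort_id, isomir_subset=set(he.isomirs),
        )
        edges = network.edges.copy()
        edges.insert(0, "cohort", cohort_id)
        quantio.write_matrix_tsv(
            edges.set_index("cohort"), outdir / "interactions.tsv", chash
        )
        stage("network", pairs_tested=len(network.edges),
              significant=int(network.edges["significant"].sum()),
              dropped_targets=network.n_dropped_genes,
              skipped_constant=network.n_skipped_constant)

        ita_map = networks.ita(network)
        ita_table = pd.DataFrame(
            {"isomir": sorted(ita_map), "ita": [ita_map[k] for k in sorted(ita_map)]}
        ).set_index("isomir")
        quantio.write_matrix_tsv(ita_table, outdir / "ita.tsv", chash)

        he_log = iso_log.loc[[n for n in iso_log.index if n in set(he.isomirs)]]
        cograph = networks.isomir_coexpression_graph(he_log, thr.clique_abs_rho)
        modules = networks.find_modules(cograph)
        reps = networks.module_representatives(modules, he_log)
        _write_json(
            {
                "config_hash": chash,
                "modules": [sorted(m) for m in modules],
                "representatives": sorted(reps),
            },
            outdir / "modules.json",
        )
        stage("modules", n_modules=len(modules), n_representatives=len(reps))

        if config.gmt is not None:
            gene_sets = quantio.read_gmt(config.gmt)
            background = set(gene_log.index)
            ora_rows = []
            for isomir in sorted(ita_map):
                if ita_map[isomir] == 0 or isomir not in network.graph:
                    continue
                query = set(network.graph.successors(isomir)) & background
                if not query:
                    continue
                table = networks.ora_enrichment(query, gene_sets, background, thr.ora_fdr)
                table.insert(0, "isomir", isomir)
                ora_rows.append(table)
            ora = (
                pd.concat(ora_rows, ignore_index=True)
                if ora_rows
                else pd.DataFrame(columns=["isomir", "set_id", "overlap", "set_size", "p", "fdr", "significant"])
            )
            quantio.write_matrix_tsv(ora.set_index("isomir") if len(ora) else ora,
                                     outdir / "ora.tsv", chash)
            stage("ora", queries=len(ora_rows), rows=len(ora))

        _write_json(report, outdir / "run_report.json")
    except Exception as exc:
        done = list(report["stages"])
        raise PipelineError(
            f"cohort {cohort_id} failed after stages {done}: {exc}"
        ) from exc
    return {
        "report": report,
        "network": network,
        "highly_expressed": he,
        "ita": ita_map,
        "targetomes": targetomes,
        "isomir_log": iso_log,
    }


def run_pancancer(config: RunConfig, cohort_bundles: Mapping[str, dict] | None = None) -> dict:
    """Combine per-cohort results into the pan-cancer summaries."""
    if not config.cohorts:
        raise PipelineError("no cohorts configured")
    chash = config.config_hash()
    thr = config.thresholds
    outdir = config.output_dir / "pancancer"
    outdir.mkdir(parents=True, exist_ok=True)

    if cohort_bundles is None:
        missing = [
            cid for cid in config.cohorts
            if not (config.output_dir / cid / "run_report.json").exists()
        ]
        if missing:
            raise PipelineError(f"missing cohort outputs for {missing}; run them first")
        cohort_bundles = {cid: run_cohort(config, cid) for cid in config.cohorts}

    he_map = {cid: set(b["highly_expressed"].isomirs) for cid, b in cohort_bundles.items()}
    nets = {cid: b["network"] for cid, b in cohort_bundles.items()}

    all_he = sorted(set().union(*he_map.values())) if he_map else []
    binarized = pd.DataFrame(
        {cid: [name in he_map[cid] for name in all_he] for cid in sorted(he_map)},
        index=all_he,
    ).astype(int)
    quantio.write_matrix_tsv(binarized, outdir / "highly_expressed_matrix.tsv", chash)

    ita_frame = pd.DataFrame(
        {cid: pd.Series(cohort_bundles[cid]["ita"]) for cid in sorted(cohort_bundles)}
    )
    quantio.write_matrix_tsv(ita_frame.astype("Int64"), outdir / "pancancer_ita.tsv", chash)

    universal = networks.universal_interactions(nets, he_map, thr)
    node_link = {
        "config_hash": chash,
        "nodes": [
            {"id": n, **{k: v for k, v in universal.nodes[n].items()}}
            for n in sorted(universal.nodes)
        ],
        "edges": [
            {"source": u, "target": v, "support": int(d["support"])}
            for u, v, d in sorted(universal.edges(data=True))
        ],
    }
    _write_json(node_link, outdir / "universal_network.json")

    # adjacent-pair targetome comparison on the shared (cancer-agnostic) catalog
    any_bundle = next(iter(cohort_bundles.values()))
    targetomes = any_bundle["targetomes"]
    hairpins, matures = load_annotation(config)
    names = sorted({n for b in cohort_bundles.values() for n in b["ita"]})
    catalog = build_catalog_isomirs(hairpins, matures, names)
    pairs = enumerate_adjacent_pairs(catalog)
    profile = tg.adjacent_jaccard_profile(pairs, targetomes)
    ji_rows = [
        {
            "isomir_a": pair.isomir_a.name,
            "isomir_b": pair.isomir_b.name,
            "merged_seed7": merge_seed_regions(pair),
            "jaccard": ji,
        }
        for pair, ji in profile
    ]
    ji_table = pd.DataFrame(ji_rows, columns=["isomir_a", "isomir_b", "merged_seed7", "jaccard"])
    quantio.write_matrix_tsv(
        ji_table.set_index("isomir_a") if len(ji_table) else ji_table,
        outdir / "adjacent_jaccard.tsv", chash,
    )

    deduped = dedup_merged_seeds([(pair, ji) for pair, ji in profile])
    top = sorted(deduped, key=lambda e: (-e[1], e[0].names))[: config.top_pairs]
    uracil_result = None
    if top:
        n_uracil = sum(1 for pair, _ in top if merge_seed_regions(pair).startswith("U"))
        stat, p = uracil_start_test(n_uracil, len(top), config.uracil_null_freq)
        uracil_result = {
            "n_uracil_start": n_uracil,
            "n_top_pairs": len(top),
            "null_freq": config.uracil_null_freq,
            "chi2": stat,
            "p_value": p,
        }
    _write_json(
        {
            "config_hash": chash,
            "n_adjacent_pairs": len(profile),
            "median_jaccard": float(np.median([ji for _, ji in profile])) if profile else None,
            "uracil_start_test": uracil_result,
        },
        outdir / "adjacent_summary.json",
    )

    report = {
        "config_hash": chash,
        "cohorts": sorted(cohort_bundles),
        "n_abundant_isomirs": sum(
            1 for _, d in universal.nodes(data=True) if d.get("kind") == "isomir"
        ),
        "n_universal_edges": universal.number_of_edges(),
        "n_adjacent_pairs": len(profile),
    }
    _write_json(report, outdir / "pancancer_report.json")
    return {
        "binarized": binarized,
        "ita": ita_frame,
        "universal": universal,
        "adjacent_profile": profile,
        "uracil": uracil_result,
        "report": report,
    }


def make_fixtures(
    outdir: str | Path,
    seed: int = 20220,
    n_cohorts: int = 3,
    n_samples: int = 60,
    n_hairpins: int = 20,
    shifts_per_hairpin: int = 2,
    n_genes: int = 300,
    n_planted: int = 50,
) -> Path:
    """Write a complete synthetic multi-cohort input bundle + config.yaml.

    The truth (hairpins, isomiRs, planted regulation, prediction tables)
    is shared across cohorts — targetomes are sequence-derived and hence
    cancer-agnostic — while counts and expression are drawn per cohort
    from cohort-specific sub-seeds.  Returns the path of the config file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beta = synthetic.beta_for_spearman(-0.6, noise_sd=1.0)
    truth = synthetic.generate_truth(
        n_hairpins=n_hairpins,
        shifts_per_hairpin=shifts_per_hairpin,
        n_genes=n_genes,
        n_planted=n_planted,
        beta_range=(beta, beta),
        seed=seed,
    )
    quantio.write_hairpin_fasta(truth.hairpins, outdir / "hairpins.fa")
    quantio.write_mirna_gff3(truth.hairpins, truth.matures, outdir / "mirna.gff3")
    quantio.write_lengths_tsv(truth.gene_lengths, outdir / "gene_lengths.tsv")
    mirdb, ts = synthetic.generate_prediction_tables(truth, seed=seed + 1)
    quantio.write_prediction_table(mirdb, outdir / "mirdb_predictions.tsv")
    quantio.write_prediction_table(ts, outdir / "targetscan_predictions.tsv")

    # small gene-set collection: one set per busy regulator (its planted
    # targets, enrichable by construction) plus random background sets
    import numpy as np

    rng = np.random.default_rng(seed + 2)
    planted_by_isomir: dict[str, set[str]] = {}
    for isomir, gene, _ in truth.planted_interactions:
        planted_by_isomir.setdefault(isomir, set()).add(gene)
    busiest = sorted(planted_by_isomir, key=lambda k: -len(planted_by_isomir[k]))[:2]
    with open(outdir / "gene_sets.gmt", "w") as fh:
        for k, isomir in enumerate(busiest):
            genes = sorted(planted_by_isomir[isomir])
            fh.write(f"PLANTED_SET_{k + 1}\tplanted targets\t" + "\t".join(genes) + "\n")
        for k in range(4):
            genes = sorted(rng.choice(truth.genes, size=20, replace=False))
            fh.write(f"RANDOM_SET_{k + 1}\trandom genes\t" + "\t".join(genes) + "\n")

    cohort_cfg = {}
    for c in range(n_cohorts):
        cid = f"COHORT{c + 1}"
        sub = seed + 100 * (c + 1)
        counts = synthetic.simulate_isomir_counts(truth, n_samples, seed=sub)
        iso_log = expression.log2_transform(
            expression.normalize(counts, pd.Series(1.0, index=counts.columns))
        )
        gene_log = synthetic.simulate_gene_expression(truth, iso_log, seed=sub + 1)
        gene_counts = synthetic.simulate_gene_counts(truth, gene_log, seed=sub + 2)
        records = quantification_records(truth, counts, sample_prefix=f"{cid}-")
        quantio.write_isoform_quantification(records, outdir / f"{cid}_isoform_quant.tsv")
        gene_counts.columns = [f"{cid}-{s}" for s in gene_counts.columns]
        gene_counts.index.name = "gene"
        gene_counts.to_csv(outdir / f"{cid}_gene_counts.tsv", sep="\t")
        cohort_cfg[cid] = {
            "quantification": f"{cid}_isoform_quant.tsv",
            "gene_counts": f"{cid}_gene_counts.tsv",
        }

    truth_json = {
        "isomirs": list(truth.isomir_names),
        "planted_interactions": [list(t) for t in truth.planted_interactions],
        "planted_abundance": truth.planted_abundance,
        "seed": seed,
    }
    _write_json(truth_json, outdir / "truth.json")

    config = {
        "gmt": "gene_sets.gmt",
        "cohorts": cohort_cfg,
        "hairpin_fasta": "hairpins.fa",
        "mirna_gff3": "mirna.gff3",
        "gene_lengths": "gene_lengths.tsv",
        "mirdb_table": "mirdb_predictions.tsv",
        "targetscan_table": "targetscan_predictions.tsv",
        "output_dir": "results",
        "seed": seed,
        "fdr_mode": "global",
        "thresholds": {"abundant_min_cancers": 2},
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path


def quantification_records(
    truth: synthetic.SyntheticTruth,
    counts: pd.DataFrame,
    sample_prefix: str = "",
    assembly: str = "synth1",
) -> list[IsoformQuantRecord]:
    """Render a simulated count matrix as GDC-style isoform records.

    Each isomiR's per-sample count is split across two records with
    different 3' ends (where the count allows) to exercise the 5'-keyed
    aggregation; both share the isomiR's genomic 5' end.
    """
    hp_by_id = {hp.hairpin_id: hp for hp in truth.hairpins}
    mat_by_id = {m.mature_id: m for m in truth.matures}
    iso_by_name = {iso.name: iso for iso in truth.isomirs}
    records: list[IsoformQuantRecord] = []
    for name in counts.index:
        iso = iso_by_name[name]
        mat = mat_by_id[iso.mature_id]
        hp = hp_by_id[mat.hairpin_id]
        local_start = mat.start + iso.shift5
        length = len(iso.sequence)
        if hp.strand == "+":
            g_start = hp.start + local_start - 1
            spans = [(g_start, g_start + length - 1), (g_start, g_start + length - 2)]
        else:
            g_end = hp.end - local_start + 1
            spans = [(g_end - length + 1, g_end), (g_end - length + 2, g_end)]
        for sample in counts.columns:
            total = int(counts.loc[name, sample])
            if total <= 0:
                continue
            first = total - total // 3
            parts = [(spans[0], first)]
            if total - first > 0:
                parts.append((spans[1], total - first))
            for (g_s, g_e), part in parts:
                records.append(
                    IsoformQuantRecord(
                        sample_id=f"{sample_prefix}{sample}",
                        mirna_id=hp.hairpin_id,
                        assembly=assembly,
                        chrom=hp.chrom,
                        start=g_s,
                        end=g_e,
                        strand=hp.strand,
                        read_count=part,
                        region=mat.mature_id,
                    )
                )
    return records
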