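"""Readers and writers for the pipeline's external file formats.

Formats handled here:

* hairpin FASTA (via Biopython; T is converted to U on read),
* miRBase-style GFF3 with ``miRNA_primary_transcript`` and ``miRNA``
  features (genomic coordinates, 1-based inclusive; mature coordinates
  are converted to hairpin-local on read),
* GDC-style isoform quantification TSV with coordinate strings of the
  form ``assembly:chrom:start-end:strand``,
* count / length / prediction / targetome TSV tables,
* GMT gene-set files (standard tab layout: id, description, genes...).

Prediction tables carry a ``# dialect: <mirdb_score|targetscan_cwcs>``
comment on their first line; the reader requires it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import AnnotationError, HairpinRecord, IsomiR, MatureAnnotation
from .targetome import PredictionTable, Targetome

_COORD_RE = re.compile(
    r"^(?P<assembly>[^:]+):(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$"
)


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class IsoformQuantRecord:
    """One row of a GDC-style isoform quantification table."""

    sample_id: str
    mirna_id: str  # hairpin id
    assembly: str
    chrom: str
    start: int
    end: int
    strand: str
    read_count: int
    region: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"coordinate start {self.start} > end {self.end}")
        if self.read_count < 0:
            raise FormatError(f"negative read count {self.read_count}")


def parse_coordinate_string(coords: str) -> tuple[str, str, int, int, str]:
    m = _COORD_RE.match(coords)
    if m is None:
        raise FormatError(
            f"malformed coordinate string {coords!r}; expected assembly:chrom:start-end:strand"
        )
    return (
        m.group("assembly"),
        m.group("chrom"),
        int(m.group("start")),
        int(m.group("end")),
        m.group("strand"),
    )


def read_isoform_quantification(path: str | Path) -> list[IsoformQuantRecord]:
    """Parse an isoform quantification TSV into structured records.

    Required columns: sample_id, mirna_id, isoform_coords, read_count;
    an optional miRNA_region column is preserved.  Errors carry the
    1-based line number of the offending row.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "mirna_id", "isoform_coords", "read_count"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[IsoformQuantRecord] = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        try:
            assembly, chrom, start, end, strand = parse_coordinate_string(row.isoform_coords)
            count = int(row.read_count)
            records.append(
                IsoformQuantRecord(
                    sample_id=row.sample_id,
                    mirna_id=row.mirna_id,
                    assembly=assembly,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    read_count=count,
                    region=getattr(row, "miRNA_region", "") or "",
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return records


def write_isoform_quantification(records: Iterable[IsoformQuantRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "mirna_id": r.mirna_id,
            "isoform_coords": f"{r.assembly}:{r.chrom}:{r.start}-{r.end}:{r.strand}",
            "read_count": r.read_count,
            "miRNA_region": r.region,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hairpin_fasta(path: str | Path) -> dict[str, str]:
    """Hairpin id -> RNA sequence (DNA input is transcribed to RNA)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("T", "U")
    return out


def write_hairpin_fasta(hairpins: Iterable[HairpinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(hp.sequence), id=hp.hairpin_id, description="")
        for hp in hairpins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mirna_gff3(
    path: str | Path, sequences: Mapping[str, str]
) -> tuple[list[HairpinRecord], list[MatureAnnotation]]:
    """miRBase-convention GFF3: hairpins + matures, matures made hairpin-local.

    ``sequences`` maps hairpin ids (GFF ``Name`` or ``ID``) to RNA
    sequences from the companion FASTA.  Mature genomic coordinates are
    converted to 1-based local coordinates in the hairpin's 5'→3' sense
    (reversed on the minus strand).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", id_spec=["ID"],
    )

    def _name(feature) -> str:
        values = feature.attributes.get("Name") or feature.attributes.get("ID")
        if not values:
            raise FormatError(f"{path}: feature without ID/Name at {feature.start}")
        return values[0]

    hairpins: dict[str, HairpinRecord] = {}
    for feature in db.features_of_type("miRNA_primary_transcript"):
        name = _name(feature)
        if name not in sequences:
            raise FormatError(f"{path}: no FASTA sequence for hairpin {name!r}")
        hairpins[name] = HairpinRecord(
            hairpin_id=name,
            sequence=sequences[name],
            chrom=feature.seqid,
            start=feature.start,
            end=feature.end,
            strand=feature.strand,
        )
    pending_matures: list[tuple[str, str, int, int]] = []
    for feature in db.features_of_type("miRNA"):
        parents = feature.attributes.get("Derives_from")
        if not parents:
            raise FormatError(f"{path}: miRNA {_name(feature)!r} without Derives_from")
        pending_matures.append((_name(feature), parents[0], feature.start, feature.end))
    matures: list[MatureAnnotation] = []
    for name, parent, g_start, g_end in pending_matures:
        if parent not in hairpins:
            raise FormatError(f"mature {name!r} derives from unknown hairpin {parent!r}")
        hp = hairpins[parent]
        if hp.strand == "+":
            local_start = g_start - hp.start + 1
            local_end = g_end - hp.start + 1
        else:
            local_start = hp.end - g_end + 1
            local_end = hp.end - g_start + 1
        matures.append(
            MatureAnnotation(
                mature_id=name, hairpin_id=parent, start=local_start, end=local_end
            )
        )
    return list(hairpins.values()), matures


def mature_genomic_interval(
    hairpin: HairpinRecord, mature: MatureAnnotation
) -> tuple[str, int, int]:
    """Genomic (chrom, start, end) of a hairpin-local mature interval."""
    if mature.hairpin_id != hairpin.hairpin_id:
        raise AnnotationError("mature annotated on a different hairpin")
    if hairpin.strand == "+":
        return (
            hairpin.chrom,
            hairpin.start + mature.start - 1,
            hairpin.start + mature.end - 1,
        )
    return (
        hairpin.chrom,
        hairpin.end - mature.end + 1,
        hairpin.end - mature.start + 1,
    )


def write_mirna_gff3(
    hairpins: Iterable[HairpinRecord], matures: Iterable[MatureAnnotation], path: str | Path
) -> None:
    by_id = {hp.hairpin_id: hp for hp in hairpins}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for hp in by_id.values():
            fh.write(
                f"{hp.chrom}\t.\tmiRNA_primary_transcript\t{hp.start}\t{hp.end}\t.\t"
                f"{hp.strand}\t.\tID={hp.hairpin_id};Name={hp.hairpin_id}\n"
            )
        for mat in matures:
            hp = by_id[mat.hairpin_id]
            chrom, g_start, g_end = mature_genomic_interval(hp, mat)
            fh.write(
                f"{chrom}\t.\tmiRNA\t{g_start}\t{g_end}\t.\t{hp.strand}\t.\t"
                f"ID={mat.mature_id};Name={mat.mature_id};Derives_from={mat.hairpin_id}\n"
            )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Feature × sample count matrix; comment lines (config hash) skipped."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_tsv(
    matrix: pd.DataFrame, path: str | Path, config_hash: str | None = None, digits: int = 6
) -> None:
    # %g keeps tiny p-values legible while bounding file size
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        matrix.to_csv(fh, sep="\t", float_format=f"%.{digits}g")


def read_lengths_tsv(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", comment="#")
    if table.shape[1] != 2:
        raise FormatError(f"{path}: expected a 2-column gene/length table")
    series = table.set_index(table.columns[0])[table.columns[1]]
    if (series < 1).any():
        raise FormatError(f"{path}: transcript lengths must be >= 1")
    return series


def write_lengths_tsv(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(lengths), "length": [lengths[g] for g in lengths]}
    ).to_csv(path, sep="\t", index=False)


def read_prediction_table(path: str | Path) -> PredictionTable:
    """Prediction TSV with a mandatory ``# dialect: ...`` first line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    m = re.match(r"^#\s*dialect:\s*(\S+)$", first)
    if m is None:
        raise FormatError(f"{path}: missing '# dialect: <name>' header line")
    table = pd.read_csv(path, sep="\t", comment="#")
    return PredictionTable(table=table, dialect=m.group(1))


def write_prediction_table(table: PredictionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dialect: {table.dialect}\n")
        table.table.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_targetomes_tsv(
    targetomes: Mapping[str, Targetome], path: str | Path, config_hash: str | None = None
) -> None:
    rows = []
    for name in sorted(targetomes):
        tg = targetomes[name]
        for gene in sorted(tg.genes):
            rows.append({"isomir": name, "gene": gene, "provenance": tg.provenance[gene]})
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        pd.DataFrame(rows, columns=["isomir", "gene", "provenance"]).to_csv(
            fh, sep="\t", index=False
        )


def read_targetomes_tsv(path: str | Path) -> dict[str, Targetome]:
    table = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, Targetome] = {}
    for isomir, group in table.groupby("isomir"):
        provenance = dict(zip(group["gene"], group["provenance"]))
        out[str(isomir)] = Targetome(isomir=str(isomir), provenance=provenance)
    return out


def write_isomir_catalog_tsv(isomirs: Iterable[IsomiR], path: str | Path) -> None:
    rows = [
        {
            "name": iso.name,
            "mature_id": iso.mature_id,
            "shift5": iso.shift5,
            "sequence": iso.sequence,
            "seed6": iso.seed6,
        }
        for iso in isomirs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Standard GMT: one gene set per line (id, description, genes...)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}, line {lineno}: GMT needs id, description, >=1 gene")
            out[fields[0]] = [g for g in fields[2:] if g]
    return out
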