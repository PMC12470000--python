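"""Read/write the canonical TSV dialects and expose the packaged cohort.

The interchange format is plain UTF-8, LF-terminated, tab-separated text
with a fixed header and no quoting. Empty cells are *absent* values, never
zero — an observed frequency of 0 is an observation and round-trips as
``0``. Three sentinel prevalence strings occur in hand-curated tables and
are mapped at read time: ``common`` -> 1.0, ``just<0.0001`` -> 9.9e-5,
``0.00%`` -> 0.0.

The packaged cohort (``load_paper_fixture``) is a transcription of a
published trio-WGS autism study: 151 de novo coding variants across 100
subjects plus one inherited same-gene companion variant (KDM5B), the gene
annotation ladder for every referenced symbol, and a per-subject phenotype
table. The phenotype table is a deterministic reconstruction from the
published aggregate counts (the source reports only aggregates); it is
synthetic at the per-subject level and documented as such.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from .model import (
    ClassLabel,
    ClassTally,
    GeneAnnotation,
    GeneCategory,
    Genome,
    Inheritance,
    LabReportStatus,
    ManualConservation,
    SfariScore,
    SubjectPhenotype,
    TriState,
    VariantClass,
    VariantRecord,
)

VARIANT_COLUMNS = [
    "subject_id", "label", "gene_symbols", "variant_class", "genome",
    "chromosome", "inheritance", "af1", "af2", "phylop", "phastcons",
    "manual_conservation", "splice_rf", "splice_ada", "het_subject",
    "het_mother", "verified_real", "known_pathogenic_cnv", "companion_flag",
    "lab_report_status", "possible_mosaic",
]

GENE_COLUMNS = ["symbol", "category", "sfari_score", "ar_only", "coding"]

PHENOTYPE_COLUMNS = [
    "subject_id", "sex", "age_years", "id_moderate_or_worse", "nonverbal",
    "epilepsy", "regression", "tics",
]

#: Curated-table prevalence sentinels.
FREQ_SENTINELS = {"common": 1.0, "just<0.0001": 9.9e-5, "just <0.0001": 9.9e-5}


class TableFormatError(ValueError):
    """Malformed row or header; the message names line and column."""


def _parse_freq(cell: str, line: int, col: str) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", "N/A", "NA"):
        return None
    key = cell.lower().replace(" ", "")
    if key in FREQ_SENTINELS:
        return FREQ_SENTINELS[key]
    if cell.endswith("%"):
        try:
            return float(cell[:-1]) / 100.0
        except ValueError:
            raise TableFormatError(f"line {line}, column {col}: bad percent {cell!r}")
    try:
        return float(cell)
    except ValueError:
        raise TableFormatError(f"line {line}, column {col}: bad number {cell!r}")


def _parse_float(cell: str, line: int, col: str) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", "N/A", "NA"):
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableFormatError(f"line {line}, column {col}: bad number {cell!r}")


def _parse_bool(cell: str, line: int, col: str) -> bool:
    token = cell.strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no", ""):
        return False
    raise TableFormatError(f"line {line}, column {col}: bad boolean {cell!r}")


def _parse_enum(enum_cls, cell: str, line: int, col: str, default=None):
    token = cell.strip()
    if not token and default is not None:
        return default
    try:
        return enum_cls(token)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise TableFormatError(
            f"line {line}, column {col}: unknown token {cell!r} "
            f"(allowed: {allowed})"
        )


def read_variant_table(source: Union[str, Path, TextIO]) -> list[VariantRecord]:
    """Parse a variants.tsv into :class:`VariantRecord` objects.

    Absent numeric cells map to ``None``, never zero.
    """
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source, encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != VARIANT_COLUMNS:
            raise TableFormatError(
                f"bad header: expected {VARIANT_COLUMNS}, got {header}"
            )
        records = []
        for lineno, rowv in enumerate(reader, start=2):
            if not rowv or all(not c for c in rowv):
                continue
            if len(rowv) != len(VARIANT_COLUMNS):
                raise TableFormatError(
                    f"line {lineno}: expected {len(VARIANT_COLUMNS)} fields, "
                    f"got {len(rowv)}"
                )
            row = dict(zip(VARIANT_COLUMNS, rowv))
            genes = tuple(g for g in row["gene_symbols"].split(";") if g)
            if not genes:
                raise TableFormatError(
                    f"line {lineno}, column gene_symbols: empty"
                )
            records.append(VariantRecord(
                subject_id=row["subject_id"],
                label=row["label"],
                gene_symbols=genes,
                variant_class=_parse_enum(VariantClass, row["variant_class"],
                                          lineno, "variant_class"),
                genome=_parse_enum(Genome, row["genome"], lineno, "genome",
                                   default=Genome.NUCLEAR),
                chromosome=row["chromosome"],
                inheritance=_parse_enum(Inheritance, row["inheritance"],
                                        lineno, "inheritance",
                                        default=Inheritance.DE_NOVO),
                allele_freq_1=_parse_freq(row["af1"], lineno, "af1"),
                allele_freq_2=_parse_freq(row["af2"], lineno, "af2"),
                phylop=_parse_float(row["phylop"], lineno, "phylop"),
                phastcons=_parse_float(row["phastcons"], lineno, "phastcons"),
                manual_conservation=_parse_enum(
                    ManualConservation, row["manual_conservation"], lineno,
                    "manual_conservation", default=ManualConservation.NONE),
                splice_rf=_parse_float(row["splice_rf"], lineno, "splice_rf"),
                splice_ada=_parse_float(row["splice_ada"], lineno,
                                        "splice_ada"),
                heteroplasmy_subject_pct=_parse_float(
                    row["het_subject"], lineno, "het_subject"),
                heteroplasmy_mother_pct=_parse_float(
                    row["het_mother"], lineno, "het_mother"),
                verified_real=_parse_bool(row["verified_real"], lineno,
                                          "verified_real"),
                known_pathogenic_cnv=_parse_bool(
                    row["known_pathogenic_cnv"], lineno,
                    "known_pathogenic_cnv"),
                companion_rare_conserved_variant=_parse_bool(
                    row["companion_flag"], lineno, "companion_flag"),
                lab_report_status=_parse_enum(
                    LabReportStatus, row["lab_report_status"], lineno,
                    "lab_report_status", default=LabReportStatus.NOT_LISTED),
                possible_mosaic=_parse_bool(row["possible_mosaic"], lineno,
                                            "possible_mosaic"),
            ))
        return records
    finally:
        if close:
            fh.close()


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    if x == int(x) and abs(x) < 1e6:
        return repr(x)
    return repr(x)


def write_variant_table(records: Iterable[VariantRecord],
                        path: Union[str, Path]) -> None:
    """Write records in the canonical dialect (round-trips with the reader)."""
    lines = ["\t".join(VARIANT_COLUMNS)]
    for r in records:
        lines.append("\t".join([
            r.subject_id,
            r.label,
            ";".join(r.gene_symbols),
            r.variant_class.value,
            r.genome.value,
            r.chromosome,
            r.inheritance.value,
            _fmt_num(r.allele_freq_1),
            _fmt_num(r.allele_freq_2),
            _fmt_num(r.phylop),
            _fmt_num(r.phastcons),
            r.manual_conservation.value,
            _fmt_num(r.splice_rf),
            _fmt_num(r.splice_ada),
            _fmt_num(r.heteroplasmy_subject_pct),
            _fmt_num(r.heteroplasmy_mother_pct),
            "true" if r.verified_real else "false",
            "true" if r.known_pathogenic_cnv else "false",
            "true" if r.companion_rare_conserved_variant else "false",
            r.lab_report_status.value,
            "true" if r.possible_mosaic else "false",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gene_config(source: Union[str, Path, TextIO]) -> dict[str, GeneAnnotation]:
    """Load the gene annotation config: symbol -> category/SFARI/AR flags."""
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source, encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != GENE_COLUMNS:
            raise TableFormatError(
                f"bad header: expected {GENE_COLUMNS}, got {header}")
        genes: dict[str, GeneAnnotation] = {}
        for lineno, rowv in enumerate(reader, start=2):
            if not rowv or all(not c for c in rowv):
                continue
            row = dict(zip(GENE_COLUMNS, rowv))
            sym = row["symbol"]
            if sym in genes:
                raise TableFormatError(
                    f"line {lineno}: duplicate gene symbol {sym!r}")
            genes[sym] = GeneAnnotation(
                symbol=sym,
                category=_parse_enum(GeneCategory, row["category"], lineno,
                                     "category"),
                sfari_score=_parse_enum(SfariScore, row["sfari_score"],
                                        lineno, "sfari_score",
                                        default=SfariScore.NONE),
                ar_only=_parse_bool(row["ar_only"], lineno, "ar_only"),
                coding=_parse_bool(row["coding"], lineno, "coding"),
            )
        return genes
    finally:
        if close:
            fh.close()


def write_gene_config(genes: dict[str, GeneAnnotation],
                      path: Union[str, Path]) -> None:
    lines = ["\t".join(GENE_COLUMNS)]
    for sym in sorted(genes):
        g = genes[sym]
        lines.append("\t".join([
            g.symbol, g.category.value, g.sfari_score.value,
            "true" if g.ar_only else "false",
            "true" if g.coding else "false",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_phenotype_table(source: Union[str, Path, TextIO]) -> list[SubjectPhenotype]:
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source, encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != PHENOTYPE_COLUMNS:
            raise TableFormatError(
                f"bad header: expected {PHENOTYPE_COLUMNS}, got {header}")
        out = []
        seen = set()
        for lineno, rowv in enumerate(reader, start=2):
            if not rowv or all(not c for c in rowv):
                continue
            row = dict(zip(PHENOTYPE_COLUMNS, rowv))
            sid = row["subject_id"]
            if sid in seen:
                raise TableFormatError(
                    f"line {lineno}: duplicate subject_id {sid!r}")
            seen.add(sid)
            out.append(SubjectPhenotype(
                subject_id=sid,
                sex=row["sex"] or "unknown",
                age_years=_parse_float(row["age_years"], lineno, "age_years"),
                id_moderate_or_worse=_parse_enum(
                    TriState, row["id_moderate_or_worse"], lineno,
                    "id_moderate_or_worse", default=TriState.UNKNOWN),
                nonverbal=_parse_enum(TriState, row["nonverbal"], lineno,
                                      "nonverbal", default=TriState.UNKNOWN),
                epilepsy=_parse_enum(TriState, row["epilepsy"], lineno,
                                     "epilepsy", default=TriState.UNKNOWN),
                regression=_parse_enum(TriState, row["regression"], lineno,
                                       "regression",
                                       default=TriState.UNKNOWN),
                tics=_parse_enum(TriState, row["tics"], lineno, "tics",
                                 default=TriState.UNKNOWN),
            ))
        return out
    finally:
        if close:
            fh.close()


def write_phenotype_table(phenotypes: Iterable[SubjectPhenotype],
                          path: Union[str, Path]) -> None:
    lines = ["\t".join(PHENOTYPE_COLUMNS)]
    for p in phenotypes:
        lines.append("\t".join([
            p.subject_id, p.sex, _fmt_num(p.age_years),
            p.id_moderate_or_worse.value, p.nonverbal.value,
            p.epilepsy.value, p.regression.value, p.tics.value,
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class CohortBundle:
    """A cohort's variants, gene annotations and phenotype roster."""

    variants: list[VariantRecord]
    genes: dict[str, GeneAnnotation]
    phenotypes: list[SubjectPhenotype] = field(default_factory=list)
    provenance: str = ""

    @property
    def de_novo(self) -> list[VariantRecord]:
        return [v for v in self.variants if v.is_de_novo]

    @property
    def subject_ids(self) -> list[str]:
        """Cohort roster: phenotype table if present, else variant subjects."""
        if self.phenotypes:
            return [p.subject_id for p in self.phenotypes]
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.subject_id, None)
        return list(seen)

    def unresolved_symbols(self) -> set[str]:
        missing = set()
        for v in self.variants:
            for g in v.gene_symbols:
                if g not in self.genes:
                    missing.add(g)
        return missing

    def write(self, directory: Union[str, Path]) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.variants, d / "variants.tsv")
        write_gene_config(self.genes, d / "genes.tsv")
        write_phenotype_table(self.phenotypes, d / "phenotypes.tsv")

    @classmethod
    def read(cls, directory: Union[str, Path],
             provenance: str = "") -> "CohortBundle":
        d = Path(directory)
        return cls(
            variants=read_variant_table(d / "variants.tsv"),
            genes=read_gene_config(d / "genes.tsv"),
            phenotypes=read_phenotype_table(d / "phenotypes.tsv"),
            provenance=provenance,
        )


def _data_path(name: str):
    return resources.files("pdvkit.data").joinpath(name)


def load_paper_fixture() -> CohortBundle:
    """The packaged 100-subject trio-WGS cohort.

    151 de novo coding variants plus the inherited KDM5B companion variant,
    with gene annotations and the (reconstructed, synthetic at subject
    level) phenotype roster.
    """
    with _data_path("variants.tsv").open(encoding="utf-8") as fh:
        variants = read_variant_table(fh)
    with _data_path("genes.tsv").open(encoding="utf-8") as fh:
        genes = read_gene_config(fh)
    with _data_path("phenotypes.tsv").open(encoding="utf-8") as fh:
        phenotypes = read_phenotype_table(fh)
    return CohortBundle(
        variants=variants, genes=genes, phenotypes=phenotypes,
        provenance="packaged 100-subject ASD trio-WGS cohort transcription",
    )


def read_table3_tallies() -> list[ClassTally]:
    """The packaged genome-wide per-class variant/SFARI tallies.

    Six classes: de novo missense PDV, de novo silent PDV (100 subjects
    each, CNV and mtDNA variants excluded), and inherited missense / silent /
    UTR / up+downstream counted genome-wide in randomised subject subsets
    (50/50/50/25 subjects).
    """
    with _data_path("class_tallies.tsv").open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            ClassTally(
                class_label=ClassLabel(row["class_label"]),
                n_subjects=int(row["n_subjects"]),
                n_variants=int(row["n_variants"]),
                n_sfari=int(row["n_sfari"]),
            )
            for row in reader
        ]


__all__ = [
    "CohortBundle", "TableFormatError", "VARIANT_COLUMNS", "GENE_COLUMNS",
    "PHENOTYPE_COLUMNS", "read_variant_table", "write_variant_table",
    "read_gene_config", "write_gene_config", "read_phenotype_table",
    "write_phenotype_table", "load_paper_fixture", "read_table3_tallies",
]
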