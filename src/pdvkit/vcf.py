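"""Minimal VCF ingestion.

The canonical interchange format is the TSV dialect in :mod:`pdvkit.io`;
this reader exists for pipelines whose annotation step emits VCF. It maps
a small set of INFO keys onto :class:`~pdvkit.model.VariantRecord` fields:

======== ==========================================
INFO key field
======== ==========================================
GENE     gene symbol(s), comma-separated
VCLASS   variant class token (missense, silent, ...)
INH      inheritance token (default de_novo)
AF_G     allele_freq_1 (genomes)
AF_E     allele_freq_2 (exomes)
PHYLOP   phylop
PHASTCONS phastcons
======== ==========================================

Everything else (manual conservation verdicts, heteroplasmy, laboratory
status) stays at its defaults — the TSV remains authoritative for the full
record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pysam

from .model import Genome, Inheritance, VariantClass, VariantRecord

_MITO_NAMES = {"MT", "chrM", "chrMT", "M"}


def _info_float(rec, key):
    val = rec.info.get(key)
    if val is None:
        return None
    if isinstance(val, tuple):
        val = val[0]
    return float(val)


def read_variant_vcf(path: Union[str, Path],
                     subject_id: str) -> list[VariantRecord]:
    """Read one subject's annotated variants from a VCF file."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gene = rec.info.get("GENE")
            vclass = rec.info.get("VCLASS")
            if gene is None or vclass is None:
                continue  # unannotated site
            if isinstance(gene, tuple):
                genes = tuple(gene)
            else:
                genes = tuple(str(gene).split(","))
            if isinstance(vclass, tuple):
                vclass = vclass[0]
            inh = rec.info.get("INH", "de_novo")
            if isinstance(inh, tuple):
                inh = inh[0]
            chrom = rec.chrom
            records.append(VariantRecord(
                subject_id=subject_id,
                label=f"{rec.chrom}:{rec.pos}:{rec.ref}>{','.join(rec.alts or ('.',))}",
                gene_symbols=genes,
                variant_class=VariantClass(str(vclass)),
                genome=(Genome.MITO if chrom.lstrip("chr") in {"M", "MT"}
                        or chrom in _MITO_NAMES else Genome.NUCLEAR),
                chromosome=chrom.removeprefix("chr"),
                inheritance=Inheritance(str(inh)),
                allele_freq_1=_info_float(rec, "AF_G"),
                allele_freq_2=_info_float(rec, "AF_E"),
                phylop=_info_float(rec, "PHYLOP"),
                phastcons=_info_float(rec, "PHASTCONS"),
            ))
    return records


__all__ = ["read_variant_vcf"]
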