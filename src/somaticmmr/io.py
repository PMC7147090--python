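"""Readers and writers for the pipeline's tabular formats.

The native dialect is UTF-8 TSV with '#'-prefixed comment lines and fixed
column names; it round-trips bit-identically. VCF 4.2 input (paired
tumor/normal samples with AD-style allele depths) is converted to the same
in-memory records on read. The signature-matrix TSV has the channel label in
column 1 and one column per signature; rows are canonicalized to the
conventional channel order on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np

from .channels import CHANNEL_INDEX, CHANNELS
from .types import (
    MSI_MARKERS,
    Consequence,
    GeneCategory,
    GenePanel,
    GermlineKind,
    Group,
    IhcResult,
    MmrGene,
    MsiResult,
    SignatureMatrix,
    SomaticVariant,
    TumorSample,
)

VARIANT_COLUMNS = (
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "consequence",
    "t_ref", "t_alt", "n_ref", "n_alt", "context3", "somatic_p",
)

_MISSING = "."


class ParseError(ValueError):
    pass


def _read_rows(path: str, expected_columns: Sequence[str]) -> list[tuple[int, dict[str, str]]]:
    rows = []
    header: Optional[list[str]] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(expected_columns) - set(header)
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: malformed header, missing columns {sorted(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append((lineno, dict(zip(header, fields))))
    if header is None:
        raise ParseError(f"{path}: empty file, no header")
    return rows


def read_variants(path: str, format: str = "maf_tsv", **kwargs) -> list[SomaticVariant]:
    """Read somatic variant records from the TSV dialect or from VCF 4.2."""
    if format == "maf_tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path, **kwargs)
    raise ValueError(f"unknown variant format {format!r}")


def _read_variants_tsv(path: str) -> list[SomaticVariant]:
    variants = []
    for lineno, row in _read_rows(path, VARIANT_COLUMNS):
        try:
            variants.append(
                SomaticVariant(
                    sample_id=row["sample_id"],
                    gene=row["gene"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    consequence=Consequence(row["consequence"]),
                    tumor_ref_reads=int(row["t_ref"]),
                    tumor_alt_reads=int(row["t_alt"]),
                    normal_ref_reads=int(row["n_ref"]),
                    normal_alt_reads=int(row["n_alt"]),
                    context3=None if row["context3"] == _MISSING else row["context3"],
                    somatic_p=None if row["somatic_p"] == _MISSING else float(row["somatic_p"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return variants


def _read_variants_vcf(
    path: str,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
    sample_id: Optional[str] = None,
) -> list[SomaticVariant]:
    """Read paired tumor/normal VCF records using per-sample AD allele depths.

    Gene, consequence and trinucleotide context are taken from the INFO keys
    GENE, CONSEQUENCE and CONTEXT when present. Positions stay 1-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise ParseError(f"{path}: sample {name!r} not in VCF (has {samples})")
    it, inorm = samples.index(tumor_sample), samples.index(normal_sample)
    variants = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} lacks AD allele depths")
        t_ref, t_alt = int(ad[it][0]), int(ad[it][1])
        n_ref, n_alt = int(ad[inorm][0]), int(ad[inorm][1])
        if n_ref < 0 or n_alt < 0:
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} missing normal counts")
        info = dict(rec.INFO)
        variants.append(
            SomaticVariant(
                sample_id=sample_id or tumor_sample,
                gene=str(info.get("GENE", _MISSING)),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                consequence=Consequence(info.get("CONSEQUENCE", "other")),
                tumor_ref_reads=t_ref,
                tumor_alt_reads=t_alt,
                normal_ref_reads=n_ref,
                normal_alt_reads=n_alt,
                context3=info.get("CONTEXT"),
            )
        )
    return variants


def write_variants(variants: Iterable[SomaticVariant], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.sample_id, v.gene, v.chrom, str(v.pos), v.ref_allele, v.alt_allele,
                        v.consequence.value, str(v.tumor_ref_reads), str(v.tumor_alt_reads),
                        str(v.normal_ref_reads), str(v.normal_alt_reads),
                        v.context3 if v.context3 is not None else _MISSING,
                        repr(v.somatic_p) if v.somatic_p is not None else _MISSING,
                    ]
                )
                + "\n"
            )


COHORT_COLUMNS = (
    "sample_id", "group", "predisposing_gene", "germline_variant_kind",
    "ihc_MLH1", "ihc_MSH2", "ihc_MSH6", "ihc_PMS2",
    "msi_BAT25", "msi_BAT26", "mlpa_dosage", "methylation_dosage",
    "pole_pold1_screened", "age_at_diagnosis",
)
_IHC_PROTEINS = ("MLH1", "MSH2", "MSH6", "PMS2")


def read_cohort(path: str) -> list[TumorSample]:
    samples = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, COHORT_COLUMNS):
        sid = row["sample_id"]
        if sid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            mlpa = None
            if row["mlpa_dosage"] != _MISSING:
                mlpa = {}
                for item in row["mlpa_dosage"].split(";"):
                    probe, ratio = item.split("=")
                    mlpa[probe] = float(ratio)
            samples.append(
                TumorSample(
                    sample_id=sid,
                    group=Group(row["group"]),
                    predisposing_gene=MmrGene(row["predisposing_gene"]),
                    germline_variant_kind=GermlineKind(row["germline_variant_kind"]),
                    ihc={p: IhcResult(row[f"ihc_{p}"]) for p in _IHC_PROTEINS},
                    msi_markers={m: MsiResult(row[f"msi_{m}"]) for m in MSI_MARKERS},
                    mlpa_dosage=mlpa,
                    methylation_dosage=(
                        None if row["methylation_dosage"] == _MISSING
                        else float(row["methylation_dosage"])
                    ),
                    pole_pold1_screened=(
                        None if row["pole_pold1_screened"] == _MISSING
                        else row["pole_pold1_screened"] == "true"
                    ),
                    age_at_diagnosis=(
                        None if row["age_at_diagnosis"] == _MISSING
                        else float(row["age_at_diagnosis"])
                    ),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return samples


def write_cohort(samples: Iterable[TumorSample], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COHORT_COLUMNS) + "\n")
        for s in samples:
            mlpa = _MISSING
            if s.mlpa_dosage is not None:
                mlpa = ";".join(f"{k}={v!r}" for k, v in sorted(s.mlpa_dosage.items()))
            fh.write(
                "\t".join(
                    [
                        s.sample_id, s.group.value, s.predisposing_gene.value,
                        s.germline_variant_kind.value,
                        *[s.ihc.get(p, IhcResult.not_done).value for p in _IHC_PROTEINS],
                        *[s.msi_markers[m].value for m in MSI_MARKERS],
                        mlpa,
                        repr(s.methylation_dosage) if s.methylation_dosage is not None else _MISSING,
                        (_MISSING if s.pole_pold1_screened is None
                         else ("true" if s.pole_pold1_screened else "false")),
                        repr(s.age_at_diagnosis) if s.age_at_diagnosis is not None else _MISSING,
                    ]
                )
                + "\n"
            )


def read_signature_matrix(path: str) -> SignatureMatrix:
    """Signature TSV: column 1 the channel label, one column per signature.

    Rows may appear in any order; the result is canonicalized. Missing or
    misspelled channel labels are reported by name.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sig_ids = header[1:]
    if not sig_ids:
        raise ParseError(f"{path}: no signature columns")
    probs = np.zeros((len(sig_ids), 96))
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        label = fields[0]
        if label not in CHANNEL_INDEX:
            raise ParseError(f"{path}:{lineno}: unknown channel label {label!r}")
        if label in seen:
            raise ParseError(f"{path}:{lineno}: duplicate channel {label!r}")
        seen.add(label)
        if len(fields) != len(sig_ids) + 1:
            raise ParseError(f"{path}:{lineno}: expected {len(sig_ids) + 1} fields")
        probs[:, CHANNEL_INDEX[label]] = [float(x) for x in fields[1:]]
    missing = [c for c in CHANNELS if c not in seen]
    if missing:
        raise ParseError(f"{path}: missing channels {missing[:5]}" + ("..." if len(missing) > 5 else ""))
    return SignatureMatrix(signature_ids=tuple(sig_ids), probs=probs)


def write_signature_matrix(matrix: SignatureMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("channel\t" + "\t".join(matrix.signature_ids) + "\n")
        for i, channel in enumerate(CHANNELS):
            fh.write(channel + "\t" + "\t".join(repr(float(x)) for x in matrix.probs[:, i]) + "\n")


def read_panel(path: str) -> GenePanel:
    """Panel TSV: columns gene, categories (comma list, may be empty).

    The footprint is declared in a comment line ``#footprint_mb=<value>``.
    """
    footprint = None
    genes: list[str] = []
    category: dict[str, set[GeneCategory]] = {}
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#footprint_mb="):
                footprint = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[:2] != ["gene", "categories"]:
                    raise ParseError(f"{path}:{lineno}: malformed header {header}")
                continue
            fields = line.split("\t")
            gene = fields[0]
            genes.append(gene)
            cats = fields[1] if len(fields) > 1 else ""
            if cats:
                category[gene] = {GeneCategory(c) for c in cats.split(",")}
    if footprint is None:
        raise ParseError(f"{path}: missing '#footprint_mb=' declaration")
    return GenePanel(genes=frozenset(genes), footprint_mb=footprint, category=category)


def write_panel(panel: GenePanel, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#footprint_mb={panel.footprint_mb!r}\n")
        fh.write("gene\tcategories\n")
        for gene in sorted(panel.genes):
            cats = ",".join(sorted(c.value for c in panel.category.get(gene, ())))
            fh.write(f"{gene}\t{cats}\n")
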