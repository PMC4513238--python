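"""Readers and writers for every file the pipeline touches.

Formats:

* variant calls — VCF 4.2 (read via :mod:`pysam`); only the per-sample
  ``GT``/``DP``/``AD``/``MQ`` keys are consumed.  Functional annotations live
  in a sidecar TSV keyed by (chrom, pos, ref, alt) and are joined onto the
  calls with :func:`attach_annotations`, which decouples the analysis from
  any particular annotation engine.
* gene annotations, participants, variant annotations, result tables — TSV
  with a header row (pandas).
* panels — one gene symbol per line, ``#`` comments.
* filter configuration and match lexicon — YAML.

All writers emit UTF-8 with Unix newlines.
"""
from __future__ import annotations

import csv
import os
from typing import Iterable, Mapping

import pandas as pd
import pysam
import yaml

from .types import (
    INDEL,
    SNV,
    FilterConfig,
    GeneAnnotation,
    PanelDefinition,
    Participant,
    ScoredVariant,
    TieredVariant,
    VariantCall,
)

__all__ = [
    "read_vcf",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_variant_annotations",
    "write_variant_annotations",
    "attach_annotations",
    "read_participants",
    "write_participants",
    "read_panel",
    "write_panel",
    "write_result_table",
    "read_result_table",
    "read_filter_config",
    "write_filter_config",
    "read_pathogenicity",
    "write_pathogenicity",
]

CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y"]


class VcfFormatError(ValueError):
    """Malformed VCF header or record."""


def _zygosity_from_gt(gt: tuple, allele_index: int, chrom: str) -> str | None:
    """Map a pysam GT tuple to a zygosity for one ALT allele.

    Returns ``None`` when the sample does not carry the allele.  Haploid
    genotypes (single-allele GT, as written for male X/Y calls) map to
    hemizygous.
    """
    called = [a for a in gt if a is not None]
    if allele_index not in called:
        return None
    if len(called) == 1:
        if chrom.removeprefix("chr") not in ("X", "Y"):
            raise VcfFormatError(f"haploid genotype on autosome {chrom}")
        return "hemizygous"
    if all(a == allele_index for a in called):
        return "homozygous_alt"
    return "heterozygous"


def _calls_from_record(rec, sample) -> list[VariantCall]:
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        return []
    for a in gt:
        if a is not None and not (0 <= a <= len(rec.alts or ())):
            raise VcfFormatError(
                f"unknown GT allele index {a} at {rec.chrom}:{rec.pos}")
    dp = sample.get("DP")
    ad = sample.get("AD")
    mq = sample.get("MQ")
    calls: list[VariantCall] = []
    for i, alt in enumerate(rec.alts or (), start=1):
        zyg = _zygosity_from_gt(gt, i, rec.chrom)
        if zyg is None:
            continue
        alt_depth = None
        if ad is not None and len(ad) > i and ad[i] is not None:
            alt_depth = int(ad[i])
        calls.append(VariantCall(
            sample_id=sample.name,
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=alt,
            vclass=SNV if len(rec.ref) == 1 and len(alt) == 1 else INDEL,
            zygosity=zyg,
            map_quality=float(mq) if mq is not None else None,
            depth=int(dp) if dp is not None else None,
            alt_depth=alt_depth,
        ))
    return calls


def read_vcf(path: str | os.PathLike, sample_id: str) -> list[VariantCall]:
    """Read one sample's calls from a VCF; one call per carried ALT allele.

    Multi-allelic records are split per ALT; a het ``1/2`` genotype yields two
    heterozygous calls.  Raises :class:`VcfFormatError` on malformed input and
    ``KeyError`` naming a missing mandatory per-sample key.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if sample_id not in list(vf.header.samples):
            raise KeyError(f"sample {sample_id!r} not in VCF {path}")
        if "GT" not in vf.header.formats:
            raise KeyError("mandatory per-sample key 'GT' missing from VCF header")
        calls: list[VariantCall] = []
        for rec in vf:
            calls.extend(_calls_from_record(rec, rec.samples[sample_id]))
    return calls


def read_cohort_vcf(path: str | os.PathLike) -> list[VariantCall]:
    """Read calls for every sample in a multi-sample VCF."""
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise KeyError("mandatory per-sample key 'GT' missing from VCF header")
        calls: list[VariantCall] = []
        for rec in vf:
            for sample in rec.samples.values():
                calls.extend(_calls_from_record(rec, sample))
    return calls


def write_cohort_vcf(variants: Iterable[VariantCall],
                     participants: Iterable[Participant],
                     path: str | os.PathLike) -> None:
    """Write a multi-sample VCF 4.2 with GT:DP:AD:MQ per-sample fields.

    Calls sharing an allele key are merged into one record; non-carrier
    samples are emitted as ``./.``.  Hemizygous genotypes are written haploid.
    """
    sample_ids = [p.sample_id for p in participants]
    by_key: dict[tuple, dict[str, VariantCall]] = {}
    for v in variants:
        by_key.setdefault(v.key, {})[v.sample_id] = v
    chrom_rank = {c: i for i, c in enumerate(CHROMS)}

    def _rank(key):
        chrom, pos, ref, alt = key
        return (chrom_rank.get(chrom.removeprefix("chr"), 99), pos, ref, alt)

    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in CHROMS]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">',
        '##FORMAT=<ID=MQ,Number=1,Type=Integer,Description="PHRED mapping quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    gt_repr = {"heterozygous": "0/1", "homozygous_alt": "1/1", "hemizygous": "1"}
    for key in sorted(by_key, key=_rank):
        chrom, pos, ref, alt = key
        carriers = by_key[key]
        fields = [chrom, str(pos), ".", ref, alt, ".", ".", ".", "GT:DP:AD:MQ"]
        for s in sample_ids:
            v = carriers.get(s)
            if v is None:
                fields.append("./.")
                continue
            dp = "." if v.depth is None else str(v.depth)
            if v.alt_depth is None or v.depth is None:
                ad = "."
            else:
                ad = f"{v.depth - v.alt_depth},{v.alt_depth}"
            mq = "." if v.map_quality is None else str(int(round(v.map_quality)))
            fields.append(f"{gt_repr[v.zygosity]}:{dp}:{ad}:{mq}")
        lines.append("\t".join(fields))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene annotation table

_GENE_COLUMNS = ["gene", "phenotypes", "has_hgmd_omim_phenotype",
                 "is_non_disease_trait_only", "inheritance", "protective_only",
                 "sex_limited", "observable_in_emr", "gwas_exact_positions"]


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValueError(f"cannot parse boolean {x!r}")


def read_gene_annotation(path: str | os.PathLike) -> dict[str, GeneAnnotation]:
    """Read the gene-level HGMD/OMIM-style annotation TSV.

    Phenotypes are pipe-delimited; order is preserved and whitespace trimmed.
    Duplicate gene symbols are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene annotation table missing columns: {missing}")
    out: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.gene in out:
            raise ValueError(f"duplicate gene symbol {row.gene!r}")
        phenos = [p.strip() for p in row.phenotypes.split("|") if p.strip()]
        gwas = set()
        if row.gwas_exact_positions:
            for tok in row.gwas_exact_positions.split(","):
                chrom, pos, ref, alt = tok.strip().split(":")
                gwas.add((chrom, int(pos), ref, alt))
        out[row.gene] = GeneAnnotation(
            gene=row.gene,
            phenotypes=phenos,
            has_hgmd_omim_phenotype=_parse_bool(row.has_hgmd_omim_phenotype),
            is_non_disease_trait_only=_parse_bool(row.is_non_disease_trait_only),
            inheritance=row.inheritance,
            protective_only=_parse_bool(row.protective_only),
            sex_limited=row.sex_limited or "none",
            observable_in_emr=_parse_bool(row.observable_in_emr),
            gwas_exact_positions=gwas,
        )
    return out


def write_gene_annotation(anns: Mapping[str, GeneAnnotation],
                          path: str | os.PathLike) -> None:
    rows = []
    for gene in sorted(anns):
        a = anns[gene]
        rows.append({
            "gene": a.gene,
            "phenotypes": "|".join(a.phenotypes),
            "has_hgmd_omim_phenotype": a.has_hgmd_omim_phenotype,
            "is_non_disease_trait_only": a.is_non_disease_trait_only,
            "inheritance": a.inheritance,
            "protective_only": a.protective_only,
            "sex_limited": a.sex_limited,
            "observable_in_emr": a.observable_in_emr,
            "gwas_exact_positions": ",".join(
                f"{c}:{p}:{r}:{t}" for c, p, r, t in sorted(a.gwas_exact_positions)),
        })
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# variant annotation sidecar

_VANN_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence",
                 "sift", "polyphen", "pop_af"]


def write_variant_annotations(variants: Iterable[VariantCall],
                              path: str | os.PathLike) -> None:
    """Write the per-allele annotation sidecar (one row per allele key)."""
    seen = set()
    rows = []
    for v in variants:
        if v.key in seen:
            continue
        seen.add(v.key)
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "consequence": v.consequence,
            "sift": v.sift, "polyphen": v.polyphen,
            "pop_af": ";".join(f"{k}={v.pop_af[k]:.6g}" for k in sorted(v.pop_af)),
        })
    pd.DataFrame(rows, columns=_VANN_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_variant_annotations(path: str | os.PathLike) -> dict[tuple, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _VANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant annotation table missing columns: {missing}")
    out: dict[tuple, dict] = {}
    for row in df.itertuples(index=False):
        pop_af = {}
        if row.pop_af:
            for tok in row.pop_af.split(";"):
                panel, af = tok.split("=")
                pop_af[panel] = float(af)
        out[(row.chrom, int(row.pos), row.ref, row.alt)] = {
            "gene": row.gene, "consequence": row.consequence,
            "sift": row.sift, "polyphen": row.polyphen, "pop_af": pop_af,
        }
    return out


def attach_annotations(calls: Iterable[VariantCall],
                       annotations: Mapping[tuple, dict]) -> list[VariantCall]:
    """Join sidecar annotations onto calls by allele key (in place)."""
    calls = list(calls)
    for v in calls:
        ann = annotations.get(v.key)
        if ann is None:
            continue
        v.gene = ann["gene"]
        v.consequence = ann["consequence"]
        v.sift = ann["sift"]
        v.polyphen = ann["polyphen"]
        v.pop_af = dict(ann["pop_af"])
    return calls


# ---------------------------------------------------------------------------
# participants

def read_participants(path: str | os.PathLike,
                      diagnosis_sep: str = ";") -> list[Participant]:
    """Read the participant table; diagnoses are ``diagnosis_sep``-delimited."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "sex", "diagnoses"):
        if col not in df.columns:
            raise ValueError(f"participant table missing column {col!r}")
    out: list[Participant] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.sample_id in seen:
            raise ValueError(f"duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        sex = row.sex.strip().upper()[:1]
        if sex not in ("M", "F"):
            raise ValueError(f"unparseable sex {row.sex!r} for {row.sample_id}")
        out.append(Participant(
            sample_id=row.sample_id,
            sex=sex,
            diagnoses=[d.strip() for d in row.diagnoses.split(diagnosis_sep) if d.strip()],
            has_invasive_cancer=_parse_bool(getattr(row, "has_invasive_cancer", False)),
            group=int(getattr(row, "group", 1)),
        ))
    return out


def write_participants(participants: Iterable[Participant],
                       path: str | os.PathLike,
                       diagnosis_sep: str = ";") -> None:
    rows = [{
        "sample_id": p.sample_id,
        "sex": p.sex,
        "diagnoses": diagnosis_sep.join(p.diagnoses),
        "has_invasive_cancer": p.has_invasive_cancer,
        "group": p.group,
    } for p in participants]
    pd.DataFrame(rows, columns=["sample_id", "sex", "diagnoses",
                                "has_invasive_cancer", "group"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# panels

def read_panel(path: str | os.PathLike, name: str | None = None) -> PanelDefinition:
    """Read a panel file: one gene symbol per line, ``#`` comments allowed."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    if len(genes) != len(set(genes)):
        raise ValueError(f"panel file {path} contains duplicate symbols")
    return PanelDefinition(name=name or os.path.splitext(os.path.basename(path))[0],
                           genes=frozenset(genes))


def write_panel(panel: PanelDefinition, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# panel: {panel.name} ({len(panel.genes)} genes)\n")
        fh.writelines(g + "\n" for g in sorted(panel.genes))


# ---------------------------------------------------------------------------
# scored result table

_RESULT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vclass",
                   "zygosity", "map_quality", "depth", "alt_depth", "gene",
                   "consequence", "sift", "polyphen", "tier", "tier_basis",
                   "inh_class", "score", "reason"]


def write_result_table(records: list[ScoredVariant], path: str | os.PathLike) -> None:
    """Write scored variants as TSV, sorted by (sample_id, chrom, pos, alt).

    Embedded tabs/newlines in free-text fields are quoted (csv quoting) so the
    table round-trips losslessly through :func:`read_result_table`.
    """
    chrom_rank = {c: i for i, c in enumerate(CHROMS)}

    def _rank(s: ScoredVariant):
        v = s.variant
        return (v.sample_id, chrom_rank.get(v.chrom.removeprefix("chr"), 99),
                v.pos, v.alt)

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, dialect="excel-tab", lineterminator="\n")
        w.writerow(_RESULT_COLUMNS)
        for s in sorted(records, key=_rank):
            v = s.variant
            w.writerow([v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.vclass,
                        v.zygosity, v.map_quality, v.depth, v.alt_depth,
                        v.gene, v.consequence, v.sift, v.polyphen,
                        s.tiered.tier, s.tiered.tier_basis, s.inh_class,
                        s.score, s.reason])


def read_result_table(path: str | os.PathLike) -> list[ScoredVariant]:
    out: list[ScoredVariant] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, dialect="excel-tab")
        if reader.fieldnames != _RESULT_COLUMNS:
            raise ValueError(f"unexpected result-table columns in {path}")
        for row in reader:
            v = VariantCall(
                sample_id=row["sample_id"], chrom=row["chrom"],
                pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                vclass=row["vclass"], zygosity=row["zygosity"],
                map_quality=float(row["map_quality"]) if row["map_quality"] else None,
                depth=int(row["depth"]) if row["depth"] else None,
                alt_depth=int(row["alt_depth"]) if row["alt_depth"] else None,
                gene=row["gene"], consequence=row["consequence"],
                sift=row["sift"], polyphen=row["polyphen"],
            )
            out.append(ScoredVariant(
                tiered=TieredVariant(variant=v, tier=int(row["tier"]),
                                     tier_basis=row["tier_basis"]),
                inh_class=row["inh_class"], score=row["score"],
                reason=row["reason"]))
    return out


# ---------------------------------------------------------------------------
# config / pathogenicity

def read_filter_config(path: str | os.PathLike) -> FilterConfig:
    with open(path, encoding="utf-8") as fh:
        return FilterConfig.from_dict(yaml.safe_load(fh) or {})


def write_filter_config(cfg: FilterConfig, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def read_pathogenicity(path: str | os.PathLike) -> dict[tuple, int]:
    """Read manual pathogenicity scores (1–5) keyed by allele."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[tuple, int] = {}
    for row in df.itertuples(index=False):
        score = int(row.score)
        if not 1 <= score <= 5:
            raise ValueError(f"pathogenicity score {score} outside 1..5")
        out[(row.chrom, int(row.pos), row.ref, row.alt)] = score
    return out


def write_pathogenicity(scores: Mapping[tuple, int], path: str | os.PathLike) -> None:
    rows = [{"chrom": c, "pos": p, "ref": r, "alt": a, "score": s}
            for (c, p, r, a), s in sorted(scores.items(), key=lambda kv: str(kv[0]))]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "score"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
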