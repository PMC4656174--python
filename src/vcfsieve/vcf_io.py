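"""Read VCF/TSV cohorts and write tabular filter reports.

Reading goes through pysam; plain and bgzipped VCF 4.x both work.  All
records are read by default (the FILTER column is ignored) — ``pass_only``
restricts to PASS/'.' records and ``min_qual`` applies a QUAL floor, both
off by default.  If one sample's VCF contains the same (chrom, pos, ref,
alt) twice, the last record wins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
import yaml

from .model import (
    FilterResult,
    MalformedRecordError,
    ResultLevel,
    Role,
    RoleError,
    SampleVariantSet,
    Variant,
    Zygosity,
    chrom_sort_key,
    decompose_record,
    normalize_chrom,
)


def read_vcf_samples(
    path: str,
    wanted_samples: Sequence[str] = (),
    *,
    role: Role = Role.CASE,
    pass_only: bool = False,
    min_qual: Optional[float] = None,
    lenient_ploidy: bool = False,
    harmonize_chr: Optional[str] = None,
) -> List[SampleVariantSet]:
    """Read one SampleVariantSet per requested sample (empty = all samples).

    Every record is decomposed into per-alt observations; reference-only
    and fully missing genotypes store nothing.  The assigned ``role``
    applies to all returned sets (cohort manifests assign per-sample roles).
    """
    with pysam.VariantFile(path) as vcf:
        available = list(vcf.header.samples)
        if not available:
            raise MalformedRecordError(f"{path}: VCF has no sample columns")
        wanted = list(wanted_samples) if wanted_samples else available
        missing = [s for s in wanted if s not in available]
        if missing:
            raise MalformedRecordError(
                f"{path}: sample(s) {missing} not in VCF; available: {available}"
            )
        sets = {s: SampleVariantSet(s, role) for s in wanted}
        for rec in vcf:
            if pass_only:
                keys = list(rec.filter.keys())
                if keys and keys != ["PASS"]:
                    continue
            if min_qual is not None and (rec.qual is None or rec.qual < min_qual):
                continue
            alts = [a for a in (rec.alts or ())]
            if not alts:
                continue
            chrom = normalize_chrom(rec.chrom, harmonize_chr)
            for s in wanted:
                gt = rec.samples[s].get("GT")
                if gt is None:
                    continue
                for v, z in decompose_record(
                    chrom, rec.pos, rec.ref, alts, gt, lenient_ploidy=lenient_ploidy
                ):
                    sets[s].observations[v] = z
    return [sets[s] for s in wanted]


def read_tsv_variants(
    path: str,
    column_map: Mapping[str, str],
    zygosity_map: Mapping[str, Zygosity],
    *,
    sample_id: Optional[str] = None,
    role: Role = Role.CASE,
) -> SampleVariantSet:
    """Read one sample's variants from a generic TSV export.

    ``column_map`` names the columns holding "chrom", "pos", "ref", "alt"
    and "zygosity"; ``zygosity_map`` translates the file's zygosity labels
    (e.g. {"Homozygous": Zygosity.HOM_ALT, "Heterozygous": Zygosity.HET}).
    """
    required = {"chrom", "pos", "ref", "alt", "zygosity"}
    missing_keys = required - set(column_map)
    if missing_keys:
        raise ValueError(f"column_map lacks keys: {sorted(missing_keys)}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in required:
        col = column_map[key]
        if col not in df.columns:
            raise MalformedRecordError(
                f"{path}: mapped column {col!r} (for {key}) not in header "
                f"{list(df.columns)}"
            )
    out = SampleVariantSet(sample_id or Path(path).stem, role)
    for i, row in df.iterrows():
        label = row[column_map["zygosity"]]
        if label not in zygosity_map:
            raise MalformedRecordError(
                f"{path}: row {i + 2}: unmapped zygosity label {label!r}"
            )
        v = Variant(
            str(row[column_map["chrom"]]),
            int(row[column_map["pos"]]),
            str(row[column_map["ref"]]),
            str(row[column_map["alt"]]),
        )
        out.observations[v] = zygosity_map[label]
    return out


def write_result(result: FilterResult, path: str) -> None:
    """Write a filter result as a deterministic TSV report.

    Columns: chrom, pos, ref, alt, case_count, control_count (plus
    source/unit_id at UNIT level); rows in natural coordinate order, so
    identical results give byte-identical files.
    """
    unit_level = result.level is ResultLevel.UNIT
    header = ["chrom", "pos", "ref", "alt", "case_count", "control_count"]
    if unit_level:
        header += ["source", "unit_id"]
    rows = sorted(
        result.rows,
        key=lambda r: (
            chrom_sort_key(r.variant.chrom),
            r.variant.pos,
            r.variant.ref,
            r.variant.alt,
            r.unit_id or ("", ""),
        ),
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for r in rows:
            line = [
                r.variant.chrom,
                r.variant.pos,
                r.variant.ref,
                r.variant.alt,
                r.case_count,
                r.control_count,
            ]
            if unit_level:
                src, uid = r.unit_id if r.unit_id else ("", "")
                line += [src, uid]
            w.writerow(line)


# ------------------------------------------------------------------ manifest

@dataclass
class ManifestEntry:
    path: str
    role: Role
    sample: Optional[str] = None  # sample name within a multi-sample VCF


@dataclass
class CohortManifest:
    """Which file/sample plays which role; family mode is a trio-only layout."""

    entries: List[ManifestEntry]
    family_mode: bool = False

    def __post_init__(self) -> None:
        roles = [e.role for e in self.entries]
        if self.family_mode:
            if roles.count(Role.CHILD) != 1:
                raise RoleError("family mode requires exactly one CHILD entry")
            if roles.count(Role.MOTHER) > 1 or roles.count(Role.FATHER) > 1:
                raise RoleError("family mode allows at most one MOTHER and one FATHER")
            if any(r in (Role.CASE, Role.CONTROL) for r in roles):
                raise RoleError(
                    "unrelated cases/controls must not appear in a family "
                    "manifest (they would be treated as parents)"
                )
        else:
            if any(r in (Role.CHILD, Role.MOTHER, Role.FATHER) for r in roles):
                raise RoleError(
                    "CHILD/MOTHER/FATHER roles require family_mode: true"
                )
            if Role.CASE not in roles:
                raise RoleError("a cohort manifest needs at least one CASE entry")


def load_manifest(path: str) -> CohortManifest:
    """Load a YAML manifest: ``samples: [{path, role, sample?}, ...]`` plus
    an optional ``family: true`` flag."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise MalformedRecordError(f"{path}: manifest needs a 'samples' list")
    base = Path(path).parent
    entries = []
    for item in doc["samples"]:
        try:
            role = Role(item["role"].lower())
        except (KeyError, ValueError) as exc:
            raise MalformedRecordError(
                f"{path}: each sample needs a role in "
                f"{[r.value for r in Role]}: {item}"
            ) from exc
        p = Path(item["path"])
        if not p.is_absolute():
            p = base / p
        entries.append(ManifestEntry(str(p), role, item.get("sample")))
    return CohortManifest(entries, family_mode=bool(doc.get("family", False)))


def load_samples(
    manifest: CohortManifest, **read_kwargs
) -> Dict[Role, List[SampleVariantSet]]:
    """Read every manifest entry, grouped by role."""
    out: Dict[Role, List[SampleVariantSet]] = {}
    for e in manifest.entries:
        wanted = [e.sample] if e.sample else ()
        sets = read_vcf_samples(e.path, wanted, role=e.role, **read_kwargs)
        if e.sample is None and len(sets) > 1:
            raise RoleError(
                f"{e.path}: multi-sample VCF needs an explicit 'sample' field "
                f"per manifest entry (found {[s.sample_id for s in sets]})"
            )
        out.setdefault(e.role, []).extend(sets)
    return out
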