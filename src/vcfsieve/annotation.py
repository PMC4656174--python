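"""Assign variants to genomic units (genes, exons or custom intervals).

Units come from BED (0-based half-open, converted to the package's 1-based
inclusive internal coordinates) or GTF (1-based inclusive, used as-is).
Membership is tested at the variant's POS anchor only — the span of a long
deletion is not considered, a documented limitation for indels.  A variant
may belong to several units (and several sources, e.g. "ensembl" and
"refseq") simultaneously; sources are kept separate so unit-level filters
count each (source, unit) pair on its own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .model import MalformedRecordError, Variant, Zygosity


@dataclass
class AnnotationUnit:
    """A named unit as a set of 1-based inclusive intervals on one chromosome."""

    unit_id: str
    chrom: str
    intervals: List[Tuple[int, int]]
    source: str = "custom"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"unit {self.unit_id!r} has no intervals")
        for start, end in self.intervals:
            if start > end or start < 1:
                raise ValueError(
                    f"unit {self.unit_id!r}: bad interval ({start}, {end})"
                )

    @property
    def key(self) -> Tuple[str, str]:
        return (self.source, self.unit_id)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(s <= pos <= e for s, e in self.intervals)


@dataclass
class AnnotatedVariant:
    variant: Variant
    zygosity: Zygosity
    unit_ids: Set[Tuple[str, str]] = field(default_factory=set)


def read_bed_units(
    path: str, name_policy: str = "column4", source: str = "custom"
) -> List[AnnotationUnit]:
    """Read units from a BED file (>= 3 columns, 0-based half-open).

    ``name_policy`` is "column4" (use the BED name column, rows sharing a
    name merge into one multi-interval unit; falls back to coordinates when
    the column is absent) or "auto" (every row named by its coordinates).
    """
    if name_policy not in ("column4", "auto"):
        raise ValueError(f"unknown name_policy {name_policy!r}")
    grouped: Dict[str, AnnotationUnit] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedRecordError(
                    f"{path}:{lineno}: BED needs >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MalformedRecordError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            if start0 >= end0 or start0 < 0:
                raise MalformedRecordError(
                    f"{path}:{lineno}: malformed interval [{start0}, {end0}) "
                    "(start must be >= 0 and < end)"
                )
            start, end = start0 + 1, end0  # to 1-based inclusive
            if name_policy == "column4" and len(fields) >= 4 and fields[3]:
                name = fields[3]
            else:
                name = f"{chrom}:{start}-{end}"
            if name in grouped:
                if grouped[name].chrom != chrom:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: unit {name!r} spans chromosomes "
                        f"{grouped[name].chrom} and {chrom}"
                    )
                grouped[name].intervals.append((start, end))
            else:
                grouped[name] = AnnotationUnit(name, chrom, [(start, end)], source)
                order.append(name)
    return [grouped[n] for n in order]


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_units(
    path: str,
    level: str = "gene",
    id_attribute: str = "gene_id",
    source: str = "custom",
) -> List[AnnotationUnit]:
    """Read units from a GTF file (1-based inclusive coordinates).

    ``level`` selects the feature type (column 3, e.g. "gene", "exon",
    "transcript", or "*" for all features); features sharing the
    ``id_attribute`` value merge into one unit, so e.g. level="exon" grouped
    by gene_id yields one unit per gene whose intervals are its exons.
    """
    grouped: Dict[str, AnnotationUnit] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise MalformedRecordError(
                    f"{path}:{lineno}: GTF needs 9 tab-separated columns"
                )
            chrom, _, feature, start_s, end_s = fields[0], fields[1], fields[2], fields[3], fields[4]
            if level != "*" and feature != level:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise MalformedRecordError(
                    f"{path}:{lineno}: non-integer GTF coordinates"
                ) from exc
            if start < 1 or start > end:
                raise MalformedRecordError(
                    f"{path}:{lineno}: malformed interval [{start}, {end}]"
                )
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            if id_attribute not in attrs:
                raise MalformedRecordError(
                    f"{path}:{lineno}: feature lacks attribute {id_attribute!r}"
                )
            name = attrs[id_attribute]
            if name in grouped:
                if grouped[name].chrom != chrom:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: unit {name!r} spans chromosomes "
                        f"{grouped[name].chrom} and {chrom}"
                    )
                grouped[name].intervals.append((start, end))
            else:
                grouped[name] = AnnotationUnit(name, chrom, [(start, end)], source)
                order.append(name)
    return [grouped[n] for n in order]


class UnitIndex:
    """Interval index over units; point queries are O(log n + hits)."""

    def __init__(self, units: Iterable[AnnotationUnit]):
        self.units = list(units)
        self._trees: Dict[str, IntervalTree] = {}
        for unit in self.units:
            tree = self._trees.setdefault(unit.chrom, IntervalTree())
            for start, end in unit.intervals:
                tree.addi(start, end + 1, unit.key)  # half-open query space

    def lookup(self, chrom: str, pos: int) -> Set[Tuple[str, str]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}


def annotate(
    observations: Sequence[Tuple[Variant, Zygosity]],
    units: Iterable[AnnotationUnit] | UnitIndex,
) -> List[AnnotatedVariant]:
    """Assign each observation to every unit whose intervals contain its POS."""
    index = units if isinstance(units, UnitIndex) else UnitIndex(units)
    return [
        AnnotatedVariant(v, z, index.lookup(v.chrom, v.pos)) for v, z in observations
    ]


def keep_annotated(
    annotated: Sequence[AnnotatedVariant], source_filter: Optional[str] = None
) -> List[AnnotatedVariant]:
    """Retain variants assigned to >= 1 unit (optionally from one source only).

    Order is preserved; with a ``source_filter`` the surviving variants'
    unit sets are restricted to that source.
    """
    out: List[AnnotatedVariant] = []
    for av in annotated:
        keys = av.unit_ids
        if source_filter is not None:
            keys = {k for k in keys if k[0] == source_filter}
        if keys:
            out.append(AnnotatedVariant(av.variant, av.zygosity, set(keys)))
    return out


def merge_report(annotated: Sequence[AnnotatedVariant]) -> List[Tuple[Variant, List[Tuple[str, str]]]]:
    """List variants annotated by more than one source: candidates for the
    same underlying unit reported under different annotation databases."""
    out = []
    for av in annotated:
        sources = {s for s, _ in av.unit_ids}
        if len(sources) > 1:
            out.append((av.variant, sorted(av.unit_ids)))
    return out
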