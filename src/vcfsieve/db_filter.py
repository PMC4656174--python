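"""Filter called variants against a database VCF (dbSNP-style), optionally
restricted by minor allele frequency.

With ``maf_threshold == 0`` every database variant is usable for filtering
(pure membership test).  With a positive threshold only database variants
whose folded minor allele frequency is at least the threshold — i.e. the
known-common variants — are removed; rare database variants stay in the
candidate set.  Database zygosity is irrelevant: matching is by allele
identity (or, optionally, by position alone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import pysam

from .model import (
    MalformedRecordError,
    SampleVariantSet,
    Variant,
    normalize_chrom,
)


@dataclass
class VariantDatabase:
    """Known variants keyed by exact identity, each with an optional MAF."""

    entries: Dict[Variant, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, maf in self.entries.items():
            if maf is not None and not 0 <= maf <= 1:
                raise ValueError(f"MAF for {v} out of [0, 1]: {maf}")
        self._positions: Set[Tuple[str, int]] = {
            (v.chrom, v.pos) for v in self.entries
        }

    def __contains__(self, v: Variant) -> bool:
        return v in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def has_position(self, v: Variant) -> bool:
        return (v.chrom, v.pos) in self._positions


def fold_maf(af: float) -> float:
    """Fold an allele frequency to the minor-allele scale: min(af, 1 - af)."""
    if not 0 <= af <= 1:
        raise ValueError(f"allele frequency out of [0, 1]: {af}")
    return min(af, 1.0 - af)


def load_database(
    path: str,
    af_field: Optional[str] = None,
    *,
    harmonize_chr: Optional[str] = None,
) -> VariantDatabase:
    """Load a database VCF; multi-allelic records are decomposed and, when
    ``af_field`` names a per-alt INFO key (Number=A), each alt is paired with
    its own folded frequency.  Records (or alts) without the key get no MAF.
    """
    entries: Dict[Variant, Optional[float]] = {}
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            afs: Tuple[Optional[float], ...] = (None,) * len(alts)
            if af_field is not None and af_field in rec.info:
                raw = rec.info[af_field]
                if not isinstance(raw, tuple):
                    raw = (raw,)
                try:
                    parsed = tuple(None if x is None else float(x) for x in raw)
                except (TypeError, ValueError) as exc:
                    raise MalformedRecordError(
                        f"{path}: non-numeric {af_field} at {rec.chrom}:{rec.pos}"
                    ) from exc
                # tolerate a single scalar annotating a multi-allelic record
                if len(parsed) == len(alts):
                    afs = parsed
                elif len(parsed) == 1:
                    afs = parsed * len(alts)
                else:
                    raise MalformedRecordError(
                        f"{path}: {af_field} has {len(parsed)} values for "
                        f"{len(alts)} alt allele(s) at {rec.chrom}:{rec.pos}"
                    )
            chrom = normalize_chrom(rec.chrom, harmonize_chr)
            for alt, af in zip(alts, afs):
                if alt is None or alt in ("*", "<NON_REF>"):
                    continue
                v = Variant(chrom, rec.pos, rec.ref, alt)
                entries[v] = None if af is None else fold_maf(af)
    return VariantDatabase(entries)


def filter_against_db(
    sample: SampleVariantSet,
    db: VariantDatabase,
    maf_threshold: float = 0.0,
    *,
    treat_missing_af_as_common: bool = False,
    match_position_only: bool = False,
) -> SampleVariantSet:
    """Remove a sample's observations that match usable database variants.

    An observation is removed iff its variant is in the database AND either
    the threshold is 0 (every database variant usable) or the database MAF
    is known and >= threshold.  Database entries lacking a MAF are, under a
    positive threshold, NOT used for filtering unless
    ``treat_missing_af_as_common`` is set.  ``match_position_only`` relaxes
    the match from (chrom, pos, ref, alt) to (chrom, pos).
    """
    if not 0 <= maf_threshold <= 1:
        raise ValueError(f"maf_threshold out of [0, 1]: {maf_threshold}")

    def usable(v: Variant) -> bool:
        if match_position_only:
            if not db.has_position(v):
                return False
            if maf_threshold == 0:
                return True
            mafs = [
                m
                for dv, m in db.entries.items()
                if (dv.chrom, dv.pos) == (v.chrom, v.pos)
            ]
            return any(
                (m is None and treat_missing_af_as_common)
                or (m is not None and m >= maf_threshold)
                for m in mafs
            )
        if v not in db:
            return False
        if maf_threshold == 0:
            return True
        maf = db.entries[v]
        if maf is None:
            return treat_missing_af_as_common
        return maf >= maf_threshold

    kept = {v: z for v, z in sample.observations.items() if not usable(v)}
    return sample.replace_observations(kept)
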