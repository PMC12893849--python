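"""Directional amino-acid mismatch counting (the AMS stage).

The comparison joins the two samples' variant sites on ``(chrom, pos, ref)``,
cleans genotypes with user-configurable quality filters, reduces each
``(site, transcript, protein position)`` to the set of amino acids encoded by
a sample's two alleles, and counts the directional set differences:

* ``SOT``  — amino acids present in the donor but absent in the recipient
  (host-versus-graft relevance after solid organ transplantation);
* ``HCT``  — amino acids present in the recipient but absent in the donor
  (graft-versus-host relevance after haematopoietic cell transplantation).

Sites with a missing (or quality-rejected) genotype in either sample are
either masked (``STRINGENT``, default) or imputed as homozygous reference
(``IMPUTE``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .vcf_io import Consequence, GenotypeCall, VariantRecord

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    """Which sample is the mismatch *source*."""

    SOT = "sot"  # source = donor, target = recipient
    HCT = "hct"  # source = recipient, target = donor


class MissingMode(str, Enum):
    STRINGENT = "stringent"  # mask sites with any missing genotype
    IMPUTE = "impute"  # treat missing genotypes as homozygous reference


class TranscriptScope(str, Enum):
    CANONICAL = "canonical"  # one representative transcript per site
    ALL = "all"  # count every annotated transcript


@dataclass(frozen=True)
class FilterConfig:
    """Data-cleaning thresholds; all user-settable.

    ``min_gnomad_af`` defaults to 0.01 (1%); the quality
    thresholds are repository defaults.
    """

    require_pass: bool = True
    min_depth: int = 10
    min_gq: int = 20
    het_ab_low: float = 0.2
    het_ab_high: float = 0.8
    min_gnomad_af: float = 0.01
    drop_af_absent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_gnomad_af <= 1.0:
            raise ValueError("min_gnomad_af must be in [0, 1]")
        if self.het_ab_low > self.het_ab_high:
            raise ValueError("het_ab_low must be <= het_ab_high")


@dataclass(frozen=True)
class CountConfig:
    """Counting rule knobs: the score is a count of directional mismatches,
    and these preserve the plausible counting conventions."""

    transcript_scope: TranscriptScope = TranscriptScope.CANONICAL
    binary_site: bool = False  # cap each (site, transcript) contribution at 1
    include_stop_gained: bool = False


@dataclass(frozen=True)
class MismatchRecord:
    """One row of the AMS table: a directional amino-acid mismatch."""

    chrom: str
    pos: int
    rsid: Optional[str]
    gene_id: str
    transcript_id: str
    protein_position: int
    ref_aa: str
    source_aas: frozenset[str]
    target_aas: frozenset[str]
    mismatch_aas: frozenset[str]
    direction: Direction
    contribution: int

    def to_row(self) -> dict[str, object]:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "rsid": self.rsid,
            "gene_id": self.gene_id,
            "transcript_id": self.transcript_id,
            "protein_position": self.protein_position,
            "ref_aa": self.ref_aa,
            "source_aas": ",".join(sorted(self.source_aas)),
            "target_aas": ",".join(sorted(self.target_aas)),
            "mismatch_aas": ",".join(sorted(self.mismatch_aas)),
            "direction": self.direction.value,
            "contribution": self.contribution,
        }

    @classmethod
    def from_row(cls, row: dict[str, str]) -> "MismatchRecord":
        return cls(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            rsid=row["rsid"] or None,
            gene_id=row["gene_id"],
            transcript_id=row["transcript_id"],
            protein_position=int(row["protein_position"]),
            ref_aa=row["ref_aa"],
            source_aas=frozenset(row["source_aas"].split(",")) - {""},
            target_aas=frozenset(row["target_aas"].split(",")) - {""},
            mismatch_aas=frozenset(row["mismatch_aas"].split(",")) - {""},
            direction=Direction(row["direction"]),
            contribution=int(row["contribution"]),
        )


AMS_TABLE_COLUMNS = [
    "chrom", "pos", "rsid", "gene_id", "transcript_id", "protein_position",
    "ref_aa", "source_aas", "target_aas", "mismatch_aas", "direction",
    "contribution",
]


@dataclass
class AMSResult:
    ams: int
    table: list[MismatchRecord]
    masked_sites: int
    rejected_by_filter: dict[str, int]
    config: dict[str, object] = field(default_factory=dict)

    def table_rows(self) -> list[dict[str, object]]:
        return [m.to_row() for m in self.table]


class RestrictionError(ValueError):
    """Malformed restriction file (e.g. a bad BED line)."""


class InputMismatchError(ValueError):
    """The two inputs are not comparable (e.g. disjoint contig names)."""


# ---------------------------------------------------------------------------
# Filters

_PASS_OK = frozenset({"PASS", "."})

_AF_REASONS = ("af_below_min", "af_absent")


def apply_filters(
    record: VariantRecord, sample: str, cfg: FilterConfig
) -> tuple[bool, Optional[str]]:
    """Per-(sample, site) cleaning verdict.

    Returns ``(True, None)`` for a kept site, else ``(False, reason)`` with
    reason one of ``non_pass``, ``low_depth``, ``low_gq``,
    ``allelic_imbalance``, ``af_below_min``, ``af_absent``. The allelic
    balance check applies only to heterozygous calls. A call with a missing
    quality field fails the corresponding enabled check. Fully missing
    genotypes are not rejected here; they are handled by ``MissingMode``.
    """
    if cfg.require_pass and record.filter_status and not (record.filter_status <= _PASS_OK):
        return False, "non_pass"

    call = record.calls.get(sample)
    if call is not None and not call.is_missing:
        reason = _quality_reason(call, cfg)
        if reason is not None:
            return False, reason

    reason = af_gate_reason(record, cfg)
    if reason is not None:
        return False, reason
    return True, None


def _quality_reason(call: GenotypeCall, cfg: FilterConfig) -> Optional[str]:
    if cfg.min_depth > 0:
        if call.depth is None or call.depth < cfg.min_depth:
            return "low_depth"
    if cfg.min_gq > 0:
        if call.genotype_quality is None or call.genotype_quality < cfg.min_gq:
            return "low_gq"
    if call.is_het and (cfg.het_ab_low > 0.0 or cfg.het_ab_high < 1.0):
        if call.allele_depths is None or sum(call.allele_depths) == 0:
            return "allelic_imbalance"
        a, b = call.allele_indices
        total = sum(call.allele_depths)
        # balance of the non-reference (or second) allele of the het pair
        alt_idx = b if b != 0 else a
        if alt_idx is None or alt_idx >= len(call.allele_depths):
            return "allelic_imbalance"
        ab = call.allele_depths[alt_idx] / total
        if not (cfg.het_ab_low <= ab <= cfg.het_ab_high):
            return "allelic_imbalance"
    return None


def af_gate_reason(record: VariantRecord, cfg: FilterConfig) -> Optional[str]:
    """Population-frequency gate, evaluated on the coding consequences.

    The site passes when at least one coding consequence passes: AF present
    and >= ``min_gnomad_af``, or AF absent while ``drop_af_absent`` is off
    (absence is distinct from 0: informative variants may be missing from
    the population database entirely).
    """
    if cfg.min_gnomad_af <= 0.0 and not cfg.drop_af_absent:
        return None
    coding = [c for c in record.consequences if c.amino_acids and c.protein_position]
    if not coding:
        return None
    saw_af = False
    for c in coding:
        if c.gnomad_af is None:
            if not cfg.drop_af_absent:
                return None
        else:
            saw_af = True
            if c.gnomad_af >= cfg.min_gnomad_af:
                return None
    return "af_below_min" if saw_af else "af_absent"


# ---------------------------------------------------------------------------
# Amino-acid set construction


def aa_set(
    record: VariantRecord,
    consequence_group: Sequence[Consequence],
    call: GenotypeCall,
) -> set[str]:
    """Amino acids encoded by a sample's two alleles at one
    (transcript, protein position).

    VCF allele index 0 contributes the reference amino acid; ALT index
    ``j >= 1`` contributes the alternate amino acid of the consequence with
    ``allele_index == j - 1``. An allele with no matching consequence (at a
    site annotated for other alleles) falls back to the reference amino acid.
    Homozygous calls yield singletons (set semantics).
    """
    if call.is_missing:
        raise ValueError("aa_set requires a non-missing genotype")
    ref_aa = consequence_group[0].ref_aa
    by_alt = {c.allele_index: c for c in consequence_group}
    out: set[str] = set()
    for j in call.allele_indices:
        if j == 0:
            out.add(ref_aa)
        else:
            cons = by_alt.get(j - 1)
            if cons is None:
                logger.debug(
                    "no consequence for ALT %d at %s:%d (%s); treating as reference",
                    j, record.chrom, record.pos, consequence_group[0].transcript_id,
                )
                out.add(ref_aa)
            else:
                out.add(cons.alt_aa)
    return out


def directional_mismatch(source: set[str], target: set[str]) -> set[str]:
    """Amino acids present in the source sample but absent from the target."""
    return source - target


# ---------------------------------------------------------------------------
# Restriction


def load_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Parse a BED file (0-based half-open) into per-chrom interval lists."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise RestrictionError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise RestrictionError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end < start:
                raise RestrictionError(f"{path}:{lineno}: end < start")
            intervals.setdefault(parts[0], []).append((start, end))
    for ivs in intervals.values():
        ivs.sort()
    return intervals


def load_id_list(path: str | Path) -> set[str]:
    with Path(path).open() as fh:
        return {line.strip() for line in fh if line.strip()}


def restrict(
    records: Iterable[VariantRecord],
    bed: Optional[dict[str, list[tuple[int, int]]] | str | Path] = None,
    rsids: Optional[set[str] | str | Path] = None,
    transcripts: Optional[set[str] | str | Path] = None,
) -> list[VariantRecord]:
    """Restrict records to BED intervals, an rsID list and/or a transcript list.

    A record survives iff (no BED OR ``pos - 1`` falls in some interval on its
    chrom) AND (no rsID list OR its id is listed). Transcript restriction
    removes consequences for unlisted transcripts, keeping the site only if
    consequences remain.
    """
    if isinstance(bed, (str, Path)):
        bed = load_bed(bed)
    if isinstance(rsids, (str, Path)):
        rsids = load_id_list(rsids)
    if isinstance(transcripts, (str, Path)):
        transcripts = load_id_list(transcripts)

    out: list[VariantRecord] = []
    for rec in records:
        if bed is not None:
            ivs = bed.get(rec.chrom, ())
            p0 = rec.pos - 1
            if not any(lo <= p0 < hi for lo, hi in ivs):
                continue
        if rsids is not None and (rec.id is None or rec.id not in rsids):
            continue
        if transcripts is not None:
            kept = [c for c in rec.consequences if c.transcript_id in transcripts]
            if not kept:
                continue
            rec = VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=rec.alts,
                id=rec.id, filter_status=rec.filter_status, calls=rec.calls,
                consequences=kept,
            )
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Site merging (single-sample inputs with potentially different ALT sets)


def _merge_sites(a: VariantRecord, b: VariantRecord) -> VariantRecord:
    """Merge two records at the same (chrom, pos, ref): union ALTs and remap
    the second record's allele indices (consequences and genotypes)."""
    if a.alts == b.alts:
        calls = dict(a.calls)
        calls.update(b.calls)
        seen = {(c.transcript_id, c.allele_index, c.amino_acids) for c in a.consequences}
        cons = list(a.consequences)
        cons += [c for c in b.consequences
                 if (c.transcript_id, c.allele_index, c.amino_acids) not in seen]
        return VariantRecord(
            chrom=a.chrom, pos=a.pos, ref=a.ref, alts=a.alts, id=a.id or b.id,
            filter_status=a.filter_status | b.filter_status, calls=calls,
            consequences=cons,
        )
    merged_alts = list(a.alts)
    for alt in b.alts:
        if alt not in merged_alts:
            merged_alts.append(alt)
    alt_map = {j: merged_alts.index(alt) for j, alt in enumerate(b.alts)}

    def remap_call(call: GenotypeCall) -> GenotypeCall:
        if call.is_missing:
            return call
        idx = tuple(0 if j == 0 else alt_map[j - 1] + 1 for j in call.allele_indices)
        return GenotypeCall(
            allele_indices=idx, phased=call.phased, depth=call.depth,
            genotype_quality=call.genotype_quality, allele_depths=call.allele_depths,
        )

    calls = dict(a.calls)
    calls.update({s: remap_call(c) for s, c in b.calls.items()})
    cons = list(a.consequences)
    seen = {(c.transcript_id, c.allele_index, c.amino_acids) for c in a.consequences}
    for c in b.consequences:
        remapped = Consequence(
            transcript_id=c.transcript_id, gene_id=c.gene_id,
            consequence_terms=c.consequence_terms,
            protein_position=c.protein_position, amino_acids=c.amino_acids,
            allele_index=alt_map[c.allele_index], gnomad_af=c.gnomad_af,
            existing_variation=c.existing_variation, is_canonical=c.is_canonical,
        )
        key = (remapped.transcript_id, remapped.allele_index, remapped.amino_acids)
        if key not in seen:
            cons.append(remapped)
            seen.add(key)
    return VariantRecord(
        chrom=a.chrom, pos=a.pos, ref=a.ref, alts=tuple(merged_alts),
        id=a.id or b.id, filter_status=a.filter_status | b.filter_status,
        calls=calls, consequences=cons,
    )


def _index_sites(records: Iterable[VariantRecord]) -> dict[tuple[str, int, str], VariantRecord]:
    index: dict[tuple[str, int, str], VariantRecord] = {}
    for rec in records:
        key = rec.site_key
        if key in index:
            logger.warning("duplicate site %s:%d ref=%s; keeping first", *key)
            continue
        index[key] = rec
    return index


# ---------------------------------------------------------------------------
# Grouping of coding consequences, cached per record instance


def _coding_groups(
    record: VariantRecord, count: CountConfig
) -> list[tuple[tuple[str, int], list[Consequence]]]:
    cache_key = (count.transcript_scope, count.include_stop_gained)
    cache = getattr(record, "_group_cache", None)
    if cache is not None and cache[0] == cache_key:
        return cache[1]

    groups: dict[tuple[str, int], list[Consequence]] = {}
    for c in record.consequences:
        if c.amino_acids is None or c.protein_position is None:
            continue
        if not count.include_stop_gained and "*" in c.amino_acids:
            continue
        groups.setdefault((c.transcript_id, c.protein_position), []).append(c)

    items = sorted(groups.items())
    if count.transcript_scope is TranscriptScope.CANONICAL and items:
        canonical = [g for g in items if any(c.is_canonical for c in g[1])]
        if canonical:
            items = [canonical[0]]
        else:
            # no CANONICAL flag at this site: fall back to the first
            # transcript (deterministic) to avoid isoform multi-counting
            items = [items[0]]
    record._group_cache = (cache_key, items)  # type: ignore[attr-defined]
    return items


_HOM_REF = GenotypeCall(allele_indices=(0, 0))


def compute_ams(
    donor: Iterable[VariantRecord],
    recipient: Iterable[VariantRecord],
    direction: Direction = Direction.SOT,
    missing: MissingMode = MissingMode.STRINGENT,
    cfg: FilterConfig = FilterConfig(),
    count: CountConfig = CountConfig(),
    donor_sample: Optional[str] = None,
    recipient_sample: Optional[str] = None,
    bed: Optional[dict[str, list[tuple[int, int]]] | str | Path] = None,
    rsids: Optional[set[str] | str | Path] = None,
    transcripts: Optional[set[str] | str | Path] = None,
) -> AMSResult:
    """Join, clean and compare the two samples; return the AMS and its table.

    ``donor`` and ``recipient`` may be the same joint record collection, in
    which case ``donor_sample``/``recipient_sample`` select the columns.
    A site present in only one input is genotype-missing in the other and
    resolved by ``missing``. Sites are joined on ``(chrom, pos, ref)``; ALT
    sets are unioned with per-sample allele-index remapping.
    """
    donor_list = donor if isinstance(donor, list) else list(donor)
    joint = donor is recipient
    recipient_list = donor_list if joint else (
        recipient if isinstance(recipient, list) else list(recipient)
    )

    if bed is not None or rsids is not None or transcripts is not None:
        donor_list = restrict(donor_list, bed=bed, rsids=rsids, transcripts=transcripts)
        recipient_list = donor_list if joint else restrict(
            recipient_list, bed=bed, rsids=rsids, transcripts=transcripts)

    donor_sample = _resolve_sample(donor_list, donor_sample, "donor")
    recipient_sample = _resolve_sample(recipient_list, recipient_sample, "recipient")

    if not joint and donor_list and recipient_list:
        dc = {r.chrom for r in donor_list}
        rc = {r.chrom for r in recipient_list}
        if not dc & rc:
            raise InputMismatchError(
                f"no contig names in common between inputs (donor: {sorted(dc)[:5]}, "
                f"recipient: {sorted(rc)[:5]}); check reference builds")

    if joint:
        merged = donor_list
    else:
        d_index = _index_sites(donor_list)
        r_index = _index_sites(recipient_list)
        merged = []
        for key in d_index.keys() | r_index.keys():
            if key in d_index and key in r_index:
                merged.append(_merge_sites(d_index[key], r_index[key]))
            else:
                merged.append(d_index.get(key) or r_index[key])
        merged.sort(key=lambda r: (r.chrom, r.pos, r.ref))

    table: list[MismatchRecord] = []
    masked = 0
    rejected: dict[str, int] = {}
    stringent = missing is MissingMode.STRINGENT
    ams = 0

    for rec in merged:
        af_reason = af_gate_reason(rec, cfg)
        if af_reason is not None:
            rejected[af_reason] = rejected.get(af_reason, 0) + 1
            continue
        groups = _coding_groups(rec, count)
        if not groups:
            continue

        d_call = _effective_call(rec, donor_sample, cfg, rejected)
        r_call = _effective_call(rec, recipient_sample, cfg, rejected)
        if d_call is None or r_call is None:
            if stringent:
                masked += 1
                continue
            d_call = d_call or _HOM_REF
            r_call = r_call or _HOM_REF

        for (transcript_id, ppos), group in groups:
            d_aas = aa_set(rec, group, d_call)
            r_aas = aa_set(rec, group, r_call)
            if direction is Direction.SOT:
                source, target = d_aas, r_aas
            else:
                source, target = r_aas, d_aas
            mm = source - target
            if not mm:
                continue
            contribution = 1 if count.binary_site else len(mm)
            ams += contribution
            table.append(MismatchRecord(
                chrom=rec.chrom, pos=rec.pos, rsid=rec.id,
                gene_id=group[0].gene_id, transcript_id=transcript_id,
                protein_position=ppos, ref_aa=group[0].ref_aa,
                source_aas=frozenset(source), target_aas=frozenset(target),
                mismatch_aas=frozenset(mm), direction=direction,
                contribution=contribution,
            ))

    table.sort(key=lambda m: (m.chrom, m.pos, m.transcript_id))
    return AMSResult(
        ams=ams, table=table, masked_sites=masked, rejected_by_filter=rejected,
        config={
            "direction": direction.value,
            "missing": missing.value,
            "donor_sample": donor_sample,
            "recipient_sample": recipient_sample,
            "filters": asdict(cfg),
            "counting": {
                "transcript_scope": count.transcript_scope.value,
                "binary_site": count.binary_site,
                "include_stop_gained": count.include_stop_gained,
            },
        },
    )


def _resolve_sample(
    records: list[VariantRecord], sample: Optional[str], role: str
) -> Optional[str]:
    if sample is not None or not records:
        return sample
    names = sorted({s for r in records[:50] for s in r.calls})
    if len(names) == 1:
        return names[0]
    raise InputMismatchError(
        f"{role} input has samples {names}; name the {role} sample explicitly")


def _effective_call(
    rec: VariantRecord, sample: Optional[str], cfg: FilterConfig,
    rejected: dict[str, int],
) -> Optional[GenotypeCall]:
    """The genotype used in the comparison, or None when missing/rejected.

    Quality-rejected genotypes are treated like missing ones (and resolved
    by MissingMode); the rejection reason is tallied.
    """
    call = rec.calls.get(sample) if sample is not None else None
    if call is None or call.is_missing:
        return None
    reason = _quality_reason(call, cfg)
    if reason is not None:
        rejected[reason] = rejected.get(reason, 0) + 1
        return None
    if cfg.require_pass and rec.filter_status and not (rec.filter_status <= _PASS_OK):
        rejected["non_pass"] = rejected.get("non_pass", 0) + 1
        return None
    return call
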