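"""VCF input and tabular output.

All format-dialect handling lives here: VEP ``CSQ`` strings are parsed
strictly from the header-declared subfield order, genotypes accept both
``/`` and ``|`` separators, and multi-allelic sites are kept as single
records with per-ALT consequences (decomposition happens downstream).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

#: Sentinel used for missing allele indices in a genotype call.
MISSING: Optional[int] = None


class VcfFormatError(ValueError):
    """Raised for structural problems in an input VCF (header or records)."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site, with the quality fields the
    cleaning filters consume.

    ``allele_indices`` are indices into ``[ref] + alts`` (0 = REF); a fully
    missing genotype is represented as ``(None, None)``.
    """

    allele_indices: tuple[Optional[int], Optional[int]]
    phased: bool = False
    depth: Optional[int] = None
    genotype_quality: Optional[int] = None
    allele_depths: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        a, b = self.allele_indices
        if (a is None) != (b is None):
            raise ValueError(f"half-missing genotype not supported: {self.allele_indices}")

    @property
    def is_missing(self) -> bool:
        return self.allele_indices[0] is None

    @property
    def is_het(self) -> bool:
        a, b = self.allele_indices
        return a is not None and a != b

    def ad_consistent(self) -> bool:
        """True unless both DP and AD are present and AD sums above DP.

        Some caller dialects emit sum(AD) > DP; we flag rather than reject.
        """
        if self.depth is None or self.allele_depths is None:
            return True
        return sum(self.allele_depths) <= self.depth


@dataclass(frozen=True)
class Consequence:
    """One VEP consequence entry (one transcript x one ALT allele)."""

    transcript_id: str
    gene_id: str = ""
    consequence_terms: frozenset[str] = frozenset()
    protein_position: Optional[int] = None
    amino_acids: Optional[str] = None  # "A/V" ref/alt pair
    allele_index: int = 0  # 0-based index into the site's ALT list
    gnomad_af: Optional[float] = None  # absence is distinct from 0.0
    existing_variation: Optional[str] = None
    is_canonical: bool = False

    @property
    def ref_aa(self) -> Optional[str]:
        if self.amino_acids is None:
            return None
        return self.amino_acids.split("/")[0]

    @property
    def alt_aa(self) -> Optional[str]:
        if self.amino_acids is None:
            return None
        parts = self.amino_acids.split("/")
        return parts[1] if len(parts) > 1 else parts[0]


@dataclass
class VariantRecord:
    """One VCF site with per-sample calls and parsed consequences."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    id: Optional[str] = None
    filter_status: frozenset[str] = frozenset()
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    consequences: list[Consequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError(f"empty REF/ALT at {self.chrom}:{self.pos}")
        for c in self.consequences:
            if c.allele_index >= len(self.alts):
                raise ValueError(
                    f"consequence allele_index {c.allele_index} out of range at "
                    f"{self.chrom}:{self.pos} ({len(self.alts)} ALTs)"
                )

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.ref)


def _parse_csq_format(header: pysam.VariantHeader, csq_key: str) -> list[str]:
    if csq_key not in header.info:
        raise VcfFormatError(
            f"INFO field {csq_key!r} not declared in the VCF header; "
            f"annotate with VEP or pass the correct --csq-key"
        )
    desc = header.info[csq_key].description or ""
    marker = "Format:"
    if marker not in desc:
        raise VcfFormatError(
            f"INFO {csq_key!r} header description lacks a 'Format:' subfield list: {desc!r}"
        )
    fmt = desc.split(marker, 1)[1].strip().strip('"')
    fields = [f.strip() for f in fmt.split("|")]
    if not fields or fields == [""]:
        raise VcfFormatError(f"empty {csq_key} subfield list in header")
    return fields


def _to_int(value: str) -> Optional[int]:
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def _parse_protein_position(value: str) -> Optional[int]:
    # VEP writes e.g. "42", "42-43", or "42/301"
    if not value:
        return None
    value = value.split("/")[0].split("-")[0]
    return _to_int(value)


def _consequence_from_entry(
    entry: Mapping[str, str], alts: Sequence[str], af_field: str
) -> Optional[Consequence]:
    allele_num = entry.get("ALLELE_NUM", "")
    if allele_num:
        idx = _to_int(allele_num)
        allele_index = idx - 1 if idx is not None and idx >= 1 else None
    else:
        allele = entry.get("Allele", "")
        allele_index = None
        if allele in alts:
            allele_index = list(alts).index(allele)
        elif len(alts) == 1:
            allele_index = 0
    if allele_index is None or allele_index >= len(alts):
        return None

    af_raw = entry.get(af_field, "")
    gnomad_af: Optional[float]
    try:
        gnomad_af = float(af_raw) if af_raw not in ("", ".", None) else None
    except ValueError:
        gnomad_af = None

    amino_acids = entry.get("Amino_acids") or None
    return Consequence(
        transcript_id=entry.get("Feature", "") or entry.get("Transcript", ""),
        gene_id=entry.get("Gene", ""),
        consequence_terms=frozenset((entry.get("Consequence") or "").split("&")) - {""},
        protein_position=_parse_protein_position(entry.get("Protein_position", "")),
        amino_acids=amino_acids,
        allele_index=allele_index,
        gnomad_af=gnomad_af,
        existing_variation=(entry.get("Existing_variation") or None),
        is_canonical=entry.get("CANONICAL", "") == "YES",
    )


def _call_from_sample(sample: "pysam.libcbcf.VariantRecordSample") -> GenotypeCall:
    gt = sample.get("GT", (None, None))
    if gt is None:
        gt = (None, None)
    gt = tuple(gt)
    if len(gt) == 1:  # haploid dialects: duplicate the single allele
        gt = (gt[0], gt[0])
    if any(a is None for a in gt):
        gt = (None, None)
    ad = sample.get("AD")
    return GenotypeCall(
        allele_indices=(gt[0], gt[1]),
        phased=bool(getattr(sample, "phased", False)),
        depth=sample.get("DP"),
        genotype_quality=sample.get("GQ"),
        allele_depths=tuple(ad) if ad is not None else None,
    )


def read_vep_vcf(
    path: str | Path,
    samples: Optional[Sequence[str]] = None,
    csq_key: str = "CSQ",
    af_field: str = "gnomADe_AF",
) -> Iterator[VariantRecord]:
    """Read a VEP-annotated VCF (plain or bgzipped) into ``VariantRecord``s.

    Parameters
    ----------
    path:
        VCF 4.x file with a ``csq_key`` INFO header line declaring
        pipe-delimited subfields.
    samples:
        Restrict parsing to these sample names (all samples by default).
        Missing samples are a hard error listing the available names.
    csq_key:
        Name of the consequence INFO field (default ``CSQ``).
    af_field:
        CSQ subfield holding the population allele frequency
        (default ``gnomADe_AF``); absence is kept distinct from 0.

    Yields records in file order. Multi-allelic sites stay single records,
    with consequences attached to their ALT via ``allele_index``. The CSQ
    subfield order is taken from the header, never assumed.
    """
    with pysam.VariantFile(str(path)) as vf:
        csq_fields = _parse_csq_format(vf.header, csq_key)
        available = list(vf.header.samples)
        if samples is None:
            wanted = available
        else:
            missing = [s for s in samples if s not in available]
            if missing:
                raise VcfFormatError(
                    f"sample(s) {missing} not in {path}; available samples: {available}"
                )
            wanted = list(samples)

        for i, rec in enumerate(vf):
            try:
                yield _convert_record(rec, wanted, csq_key, csq_fields, af_field)
            except VcfFormatError:
                raise
            except Exception as exc:  # pragma: no cover - defensive wrap
                raise VcfFormatError(f"{path}: malformed record #{i + 1} at "
                                     f"{rec.chrom}:{rec.pos}: {exc}") from exc


def _convert_record(
    rec: "pysam.VariantRecord",
    wanted: Sequence[str],
    csq_key: str,
    csq_fields: Sequence[str],
    af_field: str,
) -> VariantRecord:
    alts = tuple(rec.alts or ())
    consequences: list[Consequence] = []
    raw_csq = rec.info.get(csq_key)
    if raw_csq:
        if isinstance(raw_csq, str):
            raw_csq = (raw_csq,)
        for entry_str in raw_csq:
            values = entry_str.split("|")
            entry = dict(zip(csq_fields, values))
            cons = _consequence_from_entry(entry, alts, af_field)
            if cons is not None:
                consequences.append(cons)
    calls = {name: _call_from_sample(rec.samples[name]) for name in wanted}
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alts=alts,
        id=rec.id,
        filter_status=frozenset(rec.filter.keys()),
        calls=calls,
        consequences=consequences,
    )


def contig_names(records: Iterable[VariantRecord]) -> set[str]:
    return {r.chrom for r in records}


# ---------------------------------------------------------------------------
# Tabular output


def write_tsv(
    rows: Sequence[Mapping[str, object]],
    columns: Sequence[str],
    path: str | Path,
    sort_by: Optional[Sequence[str]] = None,
) -> None:
    """Write homogeneous dict rows as a UTF-8 TSV with one header line.

    Row order is deterministic: rows are sorted by ``sort_by`` columns
    (stringified comparison on numeric-aware keys) when given, else kept
    as provided. ``None`` serialises to the empty string.
    """
    rows = list(rows)
    if sort_by:
        def key(row: Mapping[str, object]):
            return tuple(_sort_token(row.get(c)) for c in sort_by)
        rows = sorted(rows, key=key)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow(["" if row.get(c) is None else str(row.get(c)) for c in columns])


def _sort_token(value: object) -> tuple[int, float | str]:
    # numbers sort before strings so "chr2" vs pos columns behave sanely
    if value is None:
        return (2, "")
    if isinstance(value, (int, float)):
        return (0, float(value))
    return (1, str(value))


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_tsv` back into string-valued rows."""
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [dict(row) for row in reader]
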