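"""Peptide reconstruction around mismatches and affinity-filtered scoring.

From each AMS-table row this stage rebuilds the source sample's protein,
enumerates every window of the requested lengths covering the mismatched
residue, removes windows whose exact sequence also occurs in the target
sample's protein, scores the survivors against HLA class I alleles through a
pluggable predictor adapter, and counts the binders (the af-AMS).

External predictors (NetMHCpan 4.1, MixMHCpred, NetChop) are wrapped, never
re-implemented; a deterministic built-in mock predictor makes the pipeline
runnable and testable offline.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
import subprocess
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .allo_count import MismatchRecord

logger = logging.getLogger(__name__)

STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ReconstructionError(ValueError):
    """Annotation/FASTA disagreement while rebuilding a protein."""


class PredictorError(RuntimeError):
    """External predictor unavailable or returned unusable output."""


@dataclass(frozen=True)
class PeptideRecord:
    """One reconstructed window covering a mismatched residue."""

    sequence: str
    transcript_id: str
    protein_position_of_mismatch: int  # 1-based in the protein
    offset_in_peptide: int  # 1-based position of the mismatched residue
    source_allele_aa: str
    origin: str = ""  # provenance label (sample / direction)

    def __post_init__(self) -> None:
        if not 1 <= self.offset_in_peptide <= len(self.sequence):
            raise ValueError("offset_in_peptide out of range")
        if self.sequence[self.offset_in_peptide - 1] != self.source_allele_aa:
            raise ValueError(
                f"peptide {self.sequence} does not carry {self.source_allele_aa} "
                f"at offset {self.offset_in_peptide}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def c_terminal_protein_position(self) -> int:
        start = self.protein_position_of_mismatch - self.offset_in_peptide + 1
        return start + self.length - 1


@dataclass(frozen=True)
class AffinityRecord:
    peptide: PeptideRecord
    hla_allele: str
    percent_rank: float
    affinity_nm: Optional[float]
    binder: bool


@dataclass(frozen=True)
class CleavageProfile:
    """Per-residue proteasomal cleavage scores for one reconstructed protein."""

    transcript_id: str
    scores: tuple[float, ...]  # one score in [0,1] per residue


@dataclass
class AfAMSResult:
    af_ams: int
    table: list[AffinityRecord]
    rank_threshold: Optional[float]
    nm_threshold: Optional[float]
    count_pairs: bool
    predictor: str
    extra: dict[str, object] = field(default_factory=dict)


AF_AMS_TABLE_COLUMNS = [
    "peptide", "length", "transcript_id", "protein_position",
    "offset_in_peptide", "source_aa", "origin", "hla_allele",
    "percent_rank", "affinity_nm", "binder",
]


def affinity_table_rows(records: Sequence[AffinityRecord]) -> list[dict[str, object]]:
    rows = []
    for r in records:
        p = r.peptide
        rows.append({
            "peptide": p.sequence, "length": p.length,
            "transcript_id": p.transcript_id,
            "protein_position": p.protein_position_of_mismatch,
            "offset_in_peptide": p.offset_in_peptide,
            "source_aa": p.source_allele_aa, "origin": p.origin,
            "hla_allele": r.hla_allele,
            "percent_rank": f"{r.percent_rank:.6f}",
            "affinity_nm": "" if r.affinity_nm is None else f"{r.affinity_nm:.3f}",
            "binder": r.binder,
        })
    return rows


# ---------------------------------------------------------------------------
# Protein reconstruction and windowing


def load_protein_fasta(path: str | Path) -> dict[str, str]:
    """Load a protein FASTA keyed by the first whitespace-delimited token."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def reconstruct_protein(
    reference: str,
    edits: Sequence[tuple[int, str, str]],
    transcript_id: str = "?",
) -> str:
    """Apply single-residue substitutions ``(position, ref_aa, alt_aa)`` to a
    reference protein (positions 1-based).

    Raises :class:`ReconstructionError` when a position is out of bounds or
    the reference residue disagrees with the stated reference amino acid —
    both indicate an annotation/FASTA build mismatch.
    """
    seq = list(reference)
    for pos, ref_aa, alt_aa in edits:
        if not 1 <= pos <= len(seq):
            raise ReconstructionError(
                f"{transcript_id}: protein position {pos} outside 1..{len(seq)}")
        if seq[pos - 1] != ref_aa:
            raise ReconstructionError(
                f"{transcript_id}: residue at position {pos} is {seq[pos - 1]!r}, "
                f"annotation says {ref_aa!r}")
        seq[pos - 1] = alt_aa
    return "".join(seq)


def window_peptides(
    protein: str,
    p: int,
    k: int,
    transcript_id: str = "",
    origin: str = "",
) -> list[PeptideRecord]:
    """Every length-``k`` window of ``protein`` covering 1-based position ``p``.

    When ``len(protein) >= k`` the count is
    ``min(p, L - k + 1) - max(1, p - k + 1) + 1``; shorter proteins yield
    nothing.
    """
    L = len(protein)
    if not 1 <= p <= L:
        raise ValueError(f"position {p} outside protein of length {L}")
    if k < 1:
        raise ValueError("peptide length must be >= 1")
    if L < k:
        return []
    first = max(1, p - k + 1)
    last = min(p, L - k + 1)
    out = []
    for start in range(first, last + 1):
        seq = protein[start - 1:start - 1 + k]
        out.append(PeptideRecord(
            sequence=seq, transcript_id=transcript_id,
            protein_position_of_mismatch=p,
            offset_in_peptide=p - start + 1,
            source_allele_aa=protein[p - 1],
            origin=origin,
        ))
    return out


def differential_peptides(
    source_peptides: Sequence[PeptideRecord],
    target_sequences: Iterable[str],
) -> list[PeptideRecord]:
    """Source peptides whose exact sequence never occurs in the target set.

    Peptides containing non-standard residues are dropped with a warning.
    """
    target = set(target_sequences)
    out = []
    for p in source_peptides:
        if not set(p.sequence) <= STANDARD_AAS:
            logger.warning("dropping peptide with non-standard residues: %s", p.sequence)
            continue
        if p.sequence not in target:
            out.append(p)
    return out


def kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i:i + k] for i in range(len(sequence) - k + 1)}


# ---------------------------------------------------------------------------
# Predictor adapters


@dataclass(frozen=True)
class Prediction:
    peptide: str
    allele: str
    percent_rank: float
    affinity_nm: Optional[float] = None


class AffinityPredictor(ABC):
    """Adapter contract: peptide list + allele list in, one prediction per
    (peptide, allele) pair out, order-stable."""

    name: str = "base"

    @abstractmethod
    def predict(self, peptides: Sequence[str], alleles: Sequence[str]) -> list[Prediction]:
        ...


class MockPredictor(AffinityPredictor):
    """Deterministic stand-in: hash of (peptide, allele) -> uniform %rank in
    [0, 100] and a monotone pseudo-nM value. Offline, reproducible, and with
    no biological meaning."""

    name = "mock"

    @staticmethod
    def _rank(peptide: str, allele: str) -> float:
        digest = hashlib.blake2b(f"{peptide}|{allele}".encode(), digest_size=8).digest()
        return int.from_bytes(digest, "big") / 2**64 * 100.0

    def predict(self, peptides: Sequence[str], alleles: Sequence[str]) -> list[Prediction]:
        out = []
        for pep in peptides:
            for allele in alleles:
                rank = self._rank(pep, allele)
                nm = 10.0 ** (0.5 + 4.5 * rank / 100.0)  # ~3nM .. 100uM, monotone in rank
                out.append(Prediction(pep, allele, rank, nm))
        return out


class _ExternalPredictor(AffinityPredictor):
    """Shared plumbing for subprocess-backed predictors."""

    def __init__(self, executable: str):
        self.executable = executable
        if shutil.which(executable) is None and not Path(executable).exists():
            raise PredictorError(
                f"{self.name} executable not found at {executable!r}; install it, "
                f"pass --predictor-path, or use the built-in mock predictor")

    def _run(self, args: Sequence[str]) -> str:
        proc = subprocess.run(
            [self.executable, *args], capture_output=True, text=True)
        if proc.returncode != 0:
            raise PredictorError(
                f"{self.name} failed (exit {proc.returncode}): {proc.stderr[-500:]}")
        return proc.stdout


class NetMHCpanPredictor(_ExternalPredictor):
    """Wrapper around a local NetMHCpan-4.1 installation (``-p`` peptide mode)."""

    name = "netmhcpan"

    def predict(self, peptides: Sequence[str], alleles: Sequence[str]) -> list[Prediction]:
        import tempfile

        results: dict[tuple[str, str], Prediction] = {}
        with tempfile.NamedTemporaryFile("w", suffix=".pep", delete=False) as fh:
            fh.write("\n".join(peptides) + "\n")
            pepfile = fh.name
        for allele in alleles:
            stdout = self._run(["-p", pepfile, "-a", allele.replace("*", ""), "-BA"])
            for line in stdout.splitlines():
                parts = line.split()
                # data lines: pos allele peptide ... score_el %rank_el ... aff(nM) %rank_ba
                if len(parts) < 13 or not parts[0].isdigit():
                    continue
                pep = parts[2]
                try:
                    rank = float(parts[12])
                    nm = float(parts[15]) if len(parts) > 15 else None
                except (ValueError, IndexError):
                    continue
                results[(pep, allele)] = Prediction(pep, allele, rank, nm)
        out = []
        for pep in peptides:
            for allele in alleles:
                pred = results.get((pep, allele))
                if pred is None:
                    raise PredictorError(
                        f"{self.name} output missing peptide {pep} / allele {allele}")
                out.append(pred)
        return out


class MixMHCpredPredictor(_ExternalPredictor):
    """Wrapper around a local MixMHCpred installation."""

    name = "mixmhcpred"

    def predict(self, peptides: Sequence[str], alleles: Sequence[str]) -> list[Prediction]:
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".pep", delete=False) as fh:
            fh.write("\n".join(peptides) + "\n")
            pepfile = fh.name
        with tempfile.NamedTemporaryFile(suffix=".out", delete=False) as out_fh:
            outfile = out_fh.name
        # MixMHCpred allele syntax drops the "HLA-" prefix and '*'
        allele_arg = ",".join(a.replace("HLA-", "").replace("*", "") for a in alleles)
        self._run(["-i", pepfile, "-o", outfile, "-a", allele_arg])
        header: list[str] = []
        results: dict[tuple[str, str], Prediction] = {}
        for line in Path(outfile).read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split("\t")
            if not header:
                header = parts
                continue
            row = dict(zip(header, parts))
            pep = row.get("Peptide", "")
            for allele in alleles:
                short = allele.replace("HLA-", "").replace("*", "")
                col = f"%Rank_{short}"
                if col not in row:
                    raise PredictorError(f"{self.name}: column {col!r} missing")
                results[(pep, allele)] = Prediction(pep, allele, float(row[col]), None)
        out = []
        for pep in peptides:
            for allele in alleles:
                pred = results.get((pep, allele))
                if pred is None:
                    raise PredictorError(
                        f"{self.name} output missing peptide {pep} / allele {allele}")
                out.append(pred)
        return out


def get_predictor(name: str, path: Optional[str] = None) -> AffinityPredictor:
    name = name.lower()
    if name == "mock":
        return MockPredictor()
    if name == "netmhcpan":
        return NetMHCpanPredictor(path or "netMHCpan")
    if name == "mixmhcpred":
        return MixMHCpredPredictor(path or "MixMHCpred")
    raise ValueError(f"unknown predictor {name!r}")


def predict_affinity(
    peptides: Sequence[PeptideRecord],
    hla_alleles: Sequence[str],
    predictor: AffinityPredictor,
    rank_threshold: Optional[float] = 2.0,
    nm_threshold: Optional[float] = None,
) -> list[AffinityRecord]:
    """Score every (peptide, allele) pair; exactly one binder criterion is
    active (%rank by default, inclusive boundary)."""
    if (rank_threshold is None) == (nm_threshold is None):
        raise ValueError("exactly one of rank_threshold/nm_threshold must be set")
    if not peptides:
        return []
    seqs = [p.sequence for p in peptides]
    unique_seqs = list(dict.fromkeys(seqs))
    preds = {(pr.peptide, pr.allele): pr
             for pr in predictor.predict(unique_seqs, list(hla_alleles))}
    out: list[AffinityRecord] = []
    for pep in peptides:
        for allele in hla_alleles:
            pr = preds.get((pep.sequence, allele))
            if pr is None:
                raise PredictorError(
                    f"{predictor.name} returned no prediction for "
                    f"{pep.sequence} / {allele}")
            if nm_threshold is not None:
                binder = pr.affinity_nm is not None and pr.affinity_nm <= nm_threshold
            else:
                binder = pr.percent_rank <= rank_threshold
            out.append(AffinityRecord(
                peptide=pep, hla_allele=allele, percent_rank=pr.percent_rank,
                affinity_nm=pr.affinity_nm, binder=binder,
            ))
    return out


# ---------------------------------------------------------------------------
# Cleavage


def mock_cleavage_profile(transcript_id: str, protein: str) -> CleavageProfile:
    """Deterministic per-residue pseudo-cleavage scores in [0, 1]."""
    scores = []
    for i in range(len(protein)):
        digest = hashlib.blake2b(
            f"{transcript_id}|{i}|{protein[i]}".encode(), digest_size=8).digest()
        scores.append(int.from_bytes(digest, "big") / 2**64)
    return CleavageProfile(transcript_id=transcript_id, scores=tuple(scores))


def netchop_profile(transcript_id: str, protein: str,
                    executable: str = "netchop") -> CleavageProfile:
    """Run an external NetChop binary on the reconstructed protein."""
    import tempfile

    if shutil.which(executable) is None and not Path(executable).exists():
        raise PredictorError(
            f"netchop executable not found at {executable!r}; use the mock profile")
    with tempfile.NamedTemporaryFile("w", suffix=".fsa", delete=False) as fh:
        fh.write(f">{transcript_id}\n{protein}\n")
        fasta = fh.name
    proc = subprocess.run([executable, fasta], capture_output=True, text=True)
    if proc.returncode != 0:
        raise PredictorError(f"netchop failed: {proc.stderr[-500:]}")
    scores = [0.0] * len(protein)
    for line in proc.stdout.splitlines():
        parts = line.split()
        # data lines: pos AA C score ident
        if len(parts) >= 4 and parts[0].isdigit():
            idx = int(parts[0]) - 1
            if 0 <= idx < len(protein):
                try:
                    scores[idx] = float(parts[3])
                except ValueError:
                    continue
    return CleavageProfile(transcript_id=transcript_id, scores=tuple(scores))


def cleavage_filter(
    peptides: Sequence[PeptideRecord],
    profile: CleavageProfile,
    threshold: float = 0.5,
) -> list[PeptideRecord]:
    """Keep peptides whose C-terminus coincides with a predicted cleavage
    site (score >= threshold) in the reconstructed protein."""
    out = []
    for p in peptides:
        c_pos = p.c_terminal_protein_position
        if c_pos > len(profile.scores):
            raise ValueError(
                f"cleavage profile for {profile.transcript_id} shorter than "
                f"peptide C-terminus position {c_pos}")
        if profile.scores[c_pos - 1] >= threshold:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# af-AMS


def compute_af_ams(
    records: Sequence[AffinityRecord],
    rank_threshold: Optional[float] = 2.0,
    nm_threshold: Optional[float] = None,
    count_pairs: bool = False,
    predictor_name: str = "",
) -> AfAMSResult:
    """Count binders: by default the number of distinct binder peptide
    sequences (a peptide binding several alleles counts once);
    ``count_pairs`` counts (peptide, allele) binder pairs instead."""
    if (rank_threshold is None) == (nm_threshold is None):
        raise ValueError("exactly one of rank_threshold/nm_threshold must be set")
    rescored = []
    binder_peptides: set[str] = set()
    pair_count = 0
    for r in records:
        if nm_threshold is not None:
            binder = r.affinity_nm is not None and r.affinity_nm <= nm_threshold
        else:
            binder = r.percent_rank <= rank_threshold
        rescored.append(AffinityRecord(
            peptide=r.peptide, hla_allele=r.hla_allele,
            percent_rank=r.percent_rank, affinity_nm=r.affinity_nm, binder=binder))
        if binder:
            binder_peptides.add(r.peptide.sequence)
            pair_count += 1
    af_ams = pair_count if count_pairs else len(binder_peptides)
    return AfAMSResult(
        af_ams=af_ams, table=rescored, rank_threshold=rank_threshold,
        nm_threshold=nm_threshold, count_pairs=count_pairs,
        predictor=predictor_name,
    )


# ---------------------------------------------------------------------------
# Orchestration over an AMS table


def mismatch_peptides(
    mismatches: Sequence[MismatchRecord],
    proteins: Mapping[str, str],
    lengths: Sequence[int] = (8, 9, 10, 11),
    cleavage_profile_fn: Optional[Callable[[str, str], CleavageProfile]] = None,
    cleavage_threshold: float = 0.5,
) -> list[PeptideRecord]:
    """Reconstruct the differential peptides for every AMS-table row.

    For each row, the source protein is the reference protein from the FASTA
    with the focal mismatch amino acid applied on a background of the source
    sample's homozygous co-variants on the same transcript (rows whose
    source amino-acid set is a non-reference singleton). The comparison set
    is every k-mer of the target proteins built the same way, one per target
    allele; exact sequence matching removes shared windows.
    """
    by_transcript: dict[str, list[MismatchRecord]] = {}
    for m in mismatches:
        by_transcript.setdefault(m.transcript_id, []).append(m)

    out: list[PeptideRecord] = []
    for transcript_id in sorted(by_transcript):
        rows = by_transcript[transcript_id]
        if transcript_id not in proteins:
            raise ReconstructionError(
                f"transcript {transcript_id!r} absent from the protein FASTA")
        reference = proteins[transcript_id]

        background = []
        for m in rows:
            if len(m.source_aas) == 1:
                (aa,) = m.source_aas
                if aa != m.ref_aa:
                    background.append((m.protein_position, m.ref_aa, aa))

        for m in sorted(rows, key=lambda r: r.protein_position):
            bg = [e for e in background if e[0] != m.protein_position]
            for source_aa in sorted(m.mismatch_aas):
                src_protein = reconstruct_protein(
                    reference, bg + [(m.protein_position, m.ref_aa, source_aa)],
                    transcript_id)
                target_proteins = [
                    reconstruct_protein(
                        reference, bg + [(m.protein_position, m.ref_aa, t_aa)],
                        transcript_id)
                    for t_aa in sorted(m.target_aas)
                ]
                profile = (cleavage_profile_fn(transcript_id, src_protein)
                           if cleavage_profile_fn else None)
                for k in lengths:
                    windows = window_peptides(
                        src_protein, m.protein_position, k, transcript_id,
                        origin=f"{m.direction.value}:{m.chrom}:{m.pos}")
                    target_kmers: set[str] = set()
                    for tp in target_proteins:
                        target_kmers |= kmers(tp, k)
                    diff = differential_peptides(windows, target_kmers)
                    if profile is not None:
                        diff = cleavage_filter(diff, profile, cleavage_threshold)
                    out.extend(diff)
    # deterministic order; drop duplicate (sequence, transcript, position) entries
    seen: set[tuple[str, str, int, int]] = set()
    unique = []
    for p in sorted(out, key=lambda p: (p.transcript_id, p.protein_position_of_mismatch,
                                        p.length, p.sequence)):
        key = (p.sequence, p.transcript_id, p.protein_position_of_mismatch,
               p.offset_in_peptide)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def run_affinity(
    mismatches: Sequence[MismatchRecord],
    proteins: Mapping[str, str],
    hla_alleles: Sequence[str],
    lengths: Sequence[int] = (8, 9, 10, 11),
    predictor: Optional[AffinityPredictor] = None,
    rank_threshold: Optional[float] = 2.0,
    nm_threshold: Optional[float] = None,
    count_pairs: bool = False,
    cleavage_profile_fn: Optional[Callable[[str, str], CleavageProfile]] = None,
    cleavage_threshold: float = 0.5,
) -> tuple[AfAMSResult, list[PeptideRecord]]:
    """End-to-end second stage: peptides -> affinity -> af-AMS."""
    predictor = predictor or MockPredictor()
    peptides = mismatch_peptides(
        mismatches, proteins, lengths, cleavage_profile_fn, cleavage_threshold)
    records = predict_affinity(
        peptides, hla_alleles, predictor, rank_threshold, nm_threshold)
    result = compute_af_ams(
        records, rank_threshold, nm_threshold, count_pairs, predictor.name)
    return result, peptides
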