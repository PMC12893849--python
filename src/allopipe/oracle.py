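"""Naive reference evaluator for the mismatch score.

Deliberately independent of :mod:`allopipe.allo_count`: it works on plain
per-site genotype tuples with nested loops and explicit set construction,
and is used only to validate the optimised implementation and to produce
ground truth for simulations. Keep it slow and obvious.

A *site* here is any mapping with keys ``ref_aa``, ``alt_aa`` and
``gnomad_af`` (biallelic missense by construction). A *genotype* is a tuple
of two allele indices in {0, 1}, or ``None`` when missing.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

Genotype = Optional[tuple[int, int]]


def amino_acids_of(site: Mapping[str, object], genotype: tuple[int, int]) -> set[str]:
    """The set of amino acids encoded by the two alleles of one genotype."""
    aas = set()
    for allele in genotype:
        if allele == 0:
            aas.add(site["ref_aa"])
        else:
            aas.add(site["alt_aa"])
    return aas


def oracle_mismatches(
    sites: Sequence[Mapping[str, object]],
    donor_genotypes: Sequence[Genotype],
    recipient_genotypes: Sequence[Genotype],
    direction: str,
    mode: str = "stringent",
    min_af: float = 0.0,
) -> list[tuple[int, set[str]]]:
    """Per-site directional mismatch sets, brute force.

    direction: "sot" (donor is source) or "hct" (recipient is source).
    mode: "stringent" (mask sites with a missing genotype) or "impute"
    (missing genotype becomes homozygous reference).
    """
    if direction not in ("sot", "hct"):
        raise ValueError(direction)
    if mode not in ("stringent", "impute"):
        raise ValueError(mode)
    out: list[tuple[int, set[str]]] = []
    for i in range(len(sites)):
        site = sites[i]
        af = site.get("gnomad_af")
        if min_af > 0.0 and af is not None and af < min_af:
            continue
        d = donor_genotypes[i]
        r = recipient_genotypes[i]
        if d is None or r is None:
            if mode == "stringent":
                continue
            if d is None:
                d = (0, 0)
            if r is None:
                r = (0, 0)
        donor_aas = amino_acids_of(site, d)
        recipient_aas = amino_acids_of(site, r)
        if direction == "sot":
            mismatch = {aa for aa in donor_aas if aa not in recipient_aas}
        else:
            mismatch = {aa for aa in recipient_aas if aa not in donor_aas}
        if mismatch:
            out.append((i, mismatch))
    return out


def oracle_ams(
    sites: Sequence[Mapping[str, object]],
    donor_genotypes: Sequence[Genotype],
    recipient_genotypes: Sequence[Genotype],
    direction: str,
    mode: str = "stringent",
    min_af: float = 0.0,
) -> int:
    """Total mismatch score: sum of per-site mismatch-set sizes."""
    total = 0
    for _, mismatch in oracle_mismatches(
        sites, donor_genotypes, recipient_genotypes, direction, mode, min_af
    ):
        total += len(mismatch)
    return total
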