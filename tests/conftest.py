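"""Shared fixtures: hand-written VCF text builders and toy pairs."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pytest

CSQ_SUBFIELDS = [
    "Allele", "Consequence", "Gene", "Feature", "Protein_position",
    "Amino_acids", "Existing_variation", "CANONICAL", "gnomADe_AF",
]

_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length=100000>
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=q10,Description="low quality">
##INFO=<ID={csq_key},Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: {csq_format}">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf_text(
    path: Path,
    rows: Sequence[Mapping[str, object]],
    samples: Sequence[str] = ("S1",),
    csq_subfields: Sequence[str] = CSQ_SUBFIELDS,
    csq_key: str = "CSQ",
    contig: str = "chr1",
) -> Path:
    """Write a minimal VEP-annotated VCF by hand.

    Each row: chrom, pos, id, ref, alts (list), filter, csq (list of
    subfield->value mappings), gts (one "GT:DP:GQ:AD" string per sample).
    """
    out = _HEADER_TEMPLATE.format(
        contig=contig, csq_key=csq_key, csq_format="|".join(csq_subfields),
        samples="\t".join(samples))
    for row in rows:
        csq_entries = [
            "|".join(str(entry.get(f, "")) for f in csq_subfields)
            for entry in row.get("csq", [])
        ]
        info = f"{csq_key}=" + ",".join(csq_entries) if csq_entries else "."
        fields = [
            str(row.get("chrom", contig)), str(row["pos"]),
            str(row.get("id", ".")), str(row["ref"]),
            ",".join(row["alts"]), "100", str(row.get("filter", "PASS")),
            info, "GT:DP:GQ:AD", *[str(g) for g in row["gts"]],
        ]
        out += "\t".join(fields) + "\n"
    path.write_text(out)
    return path


def missense_csq(allele: str, transcript: str, ppos: int, aas: str,
                 gene: str = "GENE1", rsid: str = "", canonical: str = "YES",
                 af: object = "") -> dict[str, object]:
    return {
        "Allele": allele, "Consequence": "missense_variant", "Gene": gene,
        "Feature": transcript, "Protein_position": ppos, "Amino_acids": aas,
        "Existing_variation": rsid, "CANONICAL": canonical, "gnomADe_AF": af,
    }


#: The three-site toy pair: expected scores frozen from hand evaluation of
#: the per-site amino-acid set differences (site1 donor {A,V} vs {A};
#: site2 donor {R} vs {G,R}; site3 donor missing vs {L,P}).
THREE_SITE_EXPECTED = {
    ("sot", "stringent"): 1,
    ("hct", "stringent"): 1,
    ("sot", "impute"): 1,
    ("hct", "impute"): 2,
}


@pytest.fixture
def three_site_pair(tmp_path: Path) -> tuple[Path, Path]:
    common = [
        dict(pos=100, id="rs1", ref="C", alts=["T"],
             csq=[missense_csq("T", "TR1", 10, "A/V", af=0.3)]),
        dict(pos=200, id="rs2", ref="G", alts=["A"],
             csq=[missense_csq("A", "TR2", 5, "G/R", af=0.4)]),
        dict(pos=300, id="rs3", ref="T", alts=["C"],
             csq=[missense_csq("C", "TR3", 7, "L/P", af=0.25)]),
    ]
    donor_gts = ["0/1:30:99:15,15", "1/1:30:99:0,30", "./."]
    recipient_gts = ["0/0:30:99:30,0", "0/1:30:99:14,16", "0/1:30:99:15,15"]
    donor = write_vcf_text(
        tmp_path / "donor.vcf",
        [dict(r, gts=[g]) for r, g in zip(common, donor_gts)], samples=["DON"])
    recipient = write_vcf_text(
        tmp_path / "recipient.vcf",
        [dict(r, gts=[g]) for r, g in zip(common, recipient_gts)], samples=["REC"])
    return donor, recipient
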