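"""Synthetic data with the statistical structure the scorer assumes.

Generates a toy proteome, biallelic missense sites with population allele
frequencies, Mendelian families (two parents, N siblings, Poisson-distributed
crossovers), per-genotype error and missingness models, and serialises any
sample pair as VEP-style annotated VCFs that round-trip through
:mod:`allopipe.vcf_io`. Ground-truth scores come from the independent
brute-force :mod:`allopipe.oracle`, never from the optimised implementation.

Read-level simulation, alignment and genotyping are deliberately replaced by
the per-genotype error model: the validation target is the counting, not a
variant caller.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import oracle
from .vcf_io import Consequence, GenotypeCall, VariantRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CHROM = "chrS"

_NUCS = "ACGT"

CSQ_FORMAT = ("Allele|Consequence|Gene|Feature|Protein_position|Amino_acids|"
              "Existing_variation|CANONICAL|gnomADe_AF")


@dataclass(frozen=True)
class SimConfig:
    """Family-simulation parameters. ``seed`` is mandatory: no hidden
    global randomness."""

    n_sites: int = 1000
    n_children: int = 2
    beta_a: float = 0.5
    beta_b: float = 0.5
    af_min: float = 0.01
    af_max: float = 0.5
    rare_fraction: float = 0.0  # fraction of sites with AF drawn below af_min
    rare_af_range: tuple[float, float] = (0.001, 0.009)
    recomb_rate: float = 1.5  # expected crossovers per transmitted haplotype
    error_rate: float = 0.0  # per-site, per-sample genotype error probability
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("rare_fraction", "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.af_min <= self.af_max <= 1.0:
            raise ValueError("need 0 < af_min <= af_max <= 1")


@dataclass(frozen=True)
class SimSite:
    """Metadata of one simulated biallelic missense site."""

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    gene_id: str
    transcript_id: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    gnomad_af: float

    def as_oracle_site(self) -> dict[str, object]:
        return {"ref_aa": self.ref_aa, "alt_aa": self.alt_aa,
                "gnomad_af": self.gnomad_af}


def make_toy_proteome(
    n_transcripts: int,
    length_range: tuple[int, int] = (30, 60),
    seed: int = 0,
) -> dict[str, str]:
    """Random amino-acid sequences keyed ``TR000001`` ...; deterministic per
    seed."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    out = {}
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AA_ALPHABET[j] for j in rng.integers(0, len(AA_ALPHABET), length))
        out[f"TR{i + 1:06d}"] = seq
    return out


def write_fasta(proteome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name in proteome:
            fh.write(f">{name}\n")
            seq = proteome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing
_CODE_TO_PAIR: dict[int, Optional[tuple[int, int]]] = {
    0: (0, 0), 1: (0, 1), 2: (1, 1), -1: None,
}

_CODE_TO_CALL: dict[int, GenotypeCall] = {
    0: GenotypeCall((0, 0), depth=50, genotype_quality=99, allele_depths=(50, 0)),
    1: GenotypeCall((0, 1), depth=50, genotype_quality=99, allele_depths=(25, 25)),
    2: GenotypeCall((1, 1), depth=50, genotype_quality=99, allele_depths=(0, 50)),
    -1: GenotypeCall((None, None)),
}

_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_CODE_TO_AD = {0: "50,0", 1: "25,25", 2: "0,50", -1: ".,."}


@dataclass
class FamilySim:
    """Simulated family: phased parental haplotypes, derived siblings, and
    observed genotypes after error/missingness injection."""

    cfg: SimConfig
    sites: list[SimSite]
    proteome: dict[str, str]
    sample_names: list[str]  # ["mother", "father", "sib01", ...]
    haplotypes: dict[str, np.ndarray]  # sample -> (2, n_sites) int8
    true_codes: np.ndarray  # (n_samples, n_sites) int8
    observed_codes: np.ndarray  # (n_samples, n_sites) int8, -1 = missing
    _truth_cache: dict[tuple, int] = field(default_factory=dict, repr=False)

    @property
    def children(self) -> list[str]:
        return [s for s in self.sample_names if s.startswith("sib")]

    def genotypes(self, sample: str, observed: bool = True) -> list[oracle.Genotype]:
        codes = self.observed_codes if observed else self.true_codes
        row = codes[self.sample_names.index(sample)]
        return [_CODE_TO_PAIR[int(c)] for c in row]

    def oracle_sites(self) -> list[dict[str, object]]:
        return [s.as_oracle_site() for s in self.sites]

    def truth_ams(self, pair: tuple[str, str], direction: str = "sot",
                  mode: str = "stringent", min_af: float = 0.0) -> int:
        """Ground-truth score on TRUE genotypes, via the brute-force oracle."""
        key = (pair, direction, mode, min_af)
        if key not in self._truth_cache:
            donor, recipient = pair
            self._truth_cache[key] = oracle.oracle_ams(
                self.oracle_sites(),
                self.genotypes(donor, observed=False),
                self.genotypes(recipient, observed=False),
                direction, mode, min_af,
            )
        return self._truth_cache[key]

    # -- conversion to the pipeline's variant model ------------------------

    def variant_records(
        self, samples: Optional[Sequence[str]] = None, observed: bool = True,
    ) -> list[VariantRecord]:
        samples = list(samples) if samples is not None else list(self.sample_names)
        idx = [self.sample_names.index(s) for s in samples]
        codes = self.observed_codes if observed else self.true_codes
        records = []
        for j, site in enumerate(self.sites):
            calls = {s: _CODE_TO_CALL[int(codes[i, j])] for s, i in zip(samples, idx)}
            records.append(VariantRecord(
                chrom=site.chrom, pos=site.pos, ref=site.ref, alts=(site.alt,),
                id=site.rsid, filter_status=frozenset({"PASS"}), calls=calls,
                consequences=[Consequence(
                    transcript_id=site.transcript_id, gene_id=site.gene_id,
                    consequence_terms=frozenset({"missense_variant"}),
                    protein_position=site.protein_position,
                    amino_acids=f"{site.ref_aa}/{site.alt_aa}", allele_index=0,
                    gnomad_af=site.gnomad_af, existing_variation=site.rsid,
                    is_canonical=True,
                )],
            ))
        return records


def _draw_afs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    afs = np.empty(cfg.n_sites)
    todo = np.arange(cfg.n_sites)
    while todo.size:  # rejection-sample the truncated Beta
        draw = rng.beta(cfg.beta_a, cfg.beta_b, todo.size)
        ok = (draw >= cfg.af_min) & (draw <= cfg.af_max)
        afs[todo[ok]] = draw[ok]
        todo = todo[~ok]
    if cfg.rare_fraction > 0.0:
        n_rare = int(round(cfg.rare_fraction * cfg.n_sites))
        rare_idx = rng.choice(cfg.n_sites, size=n_rare, replace=False)
        lo, hi = cfg.rare_af_range
        afs[rare_idx] = rng.uniform(lo, hi, n_rare)
    return afs


def make_sites(cfg: SimConfig, seed: Optional[int] = None) -> tuple[list[SimSite], dict[str, str]]:
    """Site metadata plus a consistent toy proteome (one transcript per block
    of up to 50 sites; the consequence's reference amino acid always equals
    the FASTA residue)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sites_per_tr = 50
    n_tr = -(-cfg.n_sites // sites_per_tr)
    # transcripts long enough to host 50 distinct protein positions + margin
    proteome = make_toy_proteome(n_tr, (sites_per_tr + 14, sites_per_tr + 14),
                                 seed=int(rng.integers(2**31)))
    tr_names = list(proteome)
    afs = _draw_afs(cfg, rng)
    sites = []
    for i in range(cfg.n_sites):
        tr = tr_names[i // sites_per_tr]
        ppos = (i % sites_per_tr) + 8  # keep away from the N-terminus
        ref_aa = proteome[tr][ppos - 1]
        alt_aa = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
        while alt_aa == ref_aa:
            alt_aa = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
        ref = _NUCS[int(rng.integers(4))]
        alt = _NUCS[int(rng.integers(4))]
        while alt == ref:
            alt = _NUCS[int(rng.integers(4))]
        sites.append(SimSite(
            chrom=CHROM, pos=1000 + 100 * i, rsid=f"rs{900000 + i}",
            ref=ref, alt=alt, gene_id=f"GENE{(i // sites_per_tr) + 1:04d}",
            transcript_id=tr, protein_position=ppos, ref_aa=ref_aa,
            alt_aa=alt_aa, gnomad_af=float(afs[i]),
        ))
    return sites, proteome


def _transmit(parent_haps: np.ndarray, rng: np.random.Generator,
              recomb_rate: float) -> np.ndarray:
    """One recombined gamete from a parent's (2, n_sites) haplotypes."""
    n_sites = parent_haps.shape[1]
    n_cross = rng.poisson(recomb_rate)
    cuts = np.sort(rng.integers(1, n_sites, size=n_cross)) if n_cross else np.array([], int)
    current = int(rng.integers(2))
    gamete = np.empty(n_sites, dtype=np.int8)
    start = 0
    for cut in list(cuts) + [n_sites]:
        gamete[start:cut] = parent_haps[current, start:cut]
        current = 1 - current
        start = cut
    return gamete


def simulate_family(
    cfg: SimConfig,
    sites: Optional[list[SimSite]] = None,
    proteome: Optional[dict[str, str]] = None,
) -> FamilySim:
    """Simulate parents and ``cfg.n_children`` siblings.

    Parents' haplotype alleles are Bernoulli draws from each site's allele
    frequency; each child receives one recombined haplotype per parent
    (crossover count ~ Poisson(recomb_rate), cut positions uniform). Errors
    then flip a genotype to a uniformly random *different* genotype with
    probability ``error_rate``; missingness masks genotypes with probability
    ``missing_rate``. Truth tables always refer to the pre-error,
    pre-missingness genotypes.

    Passing ``sites``/``proteome`` reuses existing site metadata so that
    independent families remain comparable.
    """
    rng = np.random.default_rng(cfg.seed)
    if sites is None:
        sites, proteome = make_sites(cfg, seed=int(rng.integers(2**31)))
    assert proteome is not None
    afs = np.array([s.gnomad_af for s in sites])
    n_sites = len(sites)

    sample_names = ["mother", "father"] + [f"sib{i + 1:02d}" for i in range(cfg.n_children)]
    haplotypes: dict[str, np.ndarray] = {}
    for parent in ("mother", "father"):
        haplotypes[parent] = (rng.random((2, n_sites)) < afs).astype(np.int8)
    for child in sample_names[2:]:
        maternal = _transmit(haplotypes["mother"], rng, cfg.recomb_rate)
        paternal = _transmit(haplotypes["father"], rng, cfg.recomb_rate)
        haplotypes[child] = np.stack([maternal, paternal])

    true_codes = np.stack([haplotypes[s].sum(axis=0) for s in sample_names]).astype(np.int8)

    observed = true_codes.copy()
    if cfg.error_rate > 0.0:
        err_mask = rng.random(observed.shape) < cfg.error_rate
        # flip to a uniformly random different genotype among {0, 1, 2}
        shift = rng.integers(1, 3, size=observed.shape)
        observed = np.where(err_mask, (observed + shift) % 3, observed).astype(np.int8)
    if cfg.missing_rate > 0.0:
        miss_mask = rng.random(observed.shape) < cfg.missing_rate
        observed = np.where(miss_mask, np.int8(-1), observed)

    return FamilySim(
        cfg=cfg, sites=list(sites), proteome=dict(proteome),
        sample_names=sample_names, haplotypes=haplotypes,
        true_codes=true_codes, observed_codes=observed,
    )


# ---------------------------------------------------------------------------
# VCF serialisation


def _vcf_header(samples: Sequence[str], contig_length: int) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM},length={contig_length}>",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        ('##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
         f'annotations from Ensembl VEP. Format: {CSQ_FORMAT}">'),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def write_vcf(
    sim: FamilySim,
    path: str | Path,
    samples: Sequence[str],
    observed: bool = True,
    drop_hom_ref: bool = False,
) -> Path:
    """Write the given samples as one VEP-style annotated VCF (plain text).

    ``drop_hom_ref`` omits sites where every written sample is homozygous
    reference, mimicking separately-genotyped single-sample files (the
    joint-genotype missing-site behaviour is then exercised downstream).
    """
    path = Path(path)
    codes = sim.observed_codes if observed else sim.true_codes
    idx = [sim.sample_names.index(s) for s in samples]
    contig_length = sim.sites[-1].pos + 1000
    with path.open("w") as fh:
        fh.write(_vcf_header(samples, contig_length))
        for j, site in enumerate(sim.sites):
            if drop_hom_ref and all(int(codes[i, j]) == 0 for i in idx):
                continue
            csq = "|".join([
                site.alt, "missense_variant", site.gene_id, site.transcript_id,
                str(site.protein_position), f"{site.ref_aa}/{site.alt_aa}",
                site.rsid, "YES", f"{site.gnomad_af:.6g}",
            ])
            fields = [
                site.chrom, str(site.pos), site.rsid, site.ref, site.alt,
                "100", "PASS", f"CSQ={csq}", "GT:DP:GQ:AD",
            ]
            for i in idx:
                code = int(codes[i, j])
                if code == -1:
                    fields.append("./.")
                else:
                    fields.append(f"{_CODE_TO_GT[code]}:50:99:{_CODE_TO_AD[code]}")
            fh.write("\t".join(fields) + "\n")
    return path


def write_pair_vcfs(
    sim: FamilySim,
    pair: tuple[str, str],
    out_dir: str | Path,
    joint: bool = False,
    observed: bool = True,
    drop_hom_ref: bool = False,
) -> tuple[Path, ...]:
    """Serialise one (donor, recipient) pair as two single-sample VCFs, or as
    one joint two-sample VCF when ``joint`` is set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    donor, recipient = pair
    for name in pair:
        if name not in sim.sample_names:
            raise ValueError(f"unknown sample {name!r}; have {sim.sample_names}")
    if joint:
        return (write_vcf(sim, out_dir / "joint.vcf", [donor, recipient],
                          observed, drop_hom_ref),)
    return (
        write_vcf(sim, out_dir / f"{donor}.vcf", [donor], observed, drop_hom_ref),
        write_vcf(sim, out_dir / f"{recipient}.vcf", [recipient], observed, drop_hom_ref),
    )


def write_truth_table(sim: FamilySim, path: str | Path) -> None:
    """Oracle scores for every sibling pair, all directions and modes."""
    from itertools import combinations

    from .vcf_io import write_tsv

    rows = []
    for a, b in combinations(sim.children, 2):
        for direction in ("sot", "hct"):
            for mode in ("stringent", "impute"):
                rows.append({
                    "donor": a, "recipient": b, "direction": direction,
                    "mode": mode,
                    "truth_ams": sim.truth_ams((a, b), direction, mode),
                })
    write_tsv(rows, ["donor", "recipient", "direction", "mode", "truth_ams"],
              path, sort_by=["donor", "recipient", "direction", "mode"])


def config_dict(cfg: SimConfig) -> dict[str, object]:
    return dataclasses.asdict(cfg)
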