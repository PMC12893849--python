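import itertools

import pytest

from allopipe import oracle
from allopipe.allo_count import (
    CountConfig, Direction, FilterConfig, MissingMode, RestrictionError,
    aa_set, apply_filters, compute_ams, directional_mismatch, load_bed, restrict,
)
from allopipe.synthetic import SimConfig, simulate_family
from allopipe.vcf_io import Consequence, GenotypeCall, VariantRecord, read_vep_vcf

from conftest import THREE_SITE_EXPECTED, missense_csq, write_vcf_text

NO_AF = FilterConfig(min_gnomad_af=0.0)


def _record(gt, aas="A/V", alts=("T",), consequences=None, dp=30, gq=99,
            ad=None, filt=("PASS",), af=0.3):
    if consequences is None:
        consequences = [Consequence(
            transcript_id="TR1", protein_position=10, amino_acids=aas,
            allele_index=0, gnomad_af=af, is_canonical=True,
            consequence_terms=frozenset({"missense_variant"}))]
    if ad is None and gt != (None, None) and dp is not None:
        ad = (dp // 2, dp - dp // 2) if gt[0] != gt[1] else (
            (dp, 0) if gt == (0, 0) else (0, dp))
    call = GenotypeCall(allele_indices=gt, depth=dp, genotype_quality=gq,
                        allele_depths=ad)
    return VariantRecord(chrom="chr1", pos=100, ref="C", alts=alts,
                         filter_status=frozenset(filt), calls={"S": call},
                         consequences=consequences)


# ---------------------------------------------------------------------------
# apply_filters


def test_low_depth_rejected():
    rec = _record((0, 1), dp=5)
    assert apply_filters(rec, "S", FilterConfig()) == (False, "low_depth")


def test_low_gq_rejected():
    rec = _record((0, 1), gq=10)
    assert apply_filters(rec, "S", FilterConfig()) == (False, "low_gq")


def test_allelic_imbalance_rejected():
    rec = _record((0, 1), ad=(28, 2))  # AB = 0.067
    assert apply_filters(rec, "S", FilterConfig()) == (False, "allelic_imbalance")


def test_hom_call_skips_balance_check():
    rec = _record((1, 1), ad=(0, 30))
    assert apply_filters(rec, "S", FilterConfig(min_gnomad_af=0.0)) == (True, None)


def test_non_pass_rejected():
    rec = _record((0, 1), filt=("q10",))
    assert apply_filters(rec, "S", FilterConfig()) == (False, "non_pass")
    assert apply_filters(rec, "S", FilterConfig(require_pass=False,
                                                min_gnomad_af=0.0)) == (True, None)


def test_af_gate_default_and_zero():
    # gnomad_af=0.005 rejected at the 1% default, kept at 0%
    rec = _record((0, 1), af=0.005)
    assert apply_filters(rec, "S", FilterConfig()) == (False, "af_below_min")
    assert apply_filters(rec, "S", FilterConfig(min_gnomad_af=0.0)) == (True, None)


def test_af_absent_kept_unless_dropped():
    rec = _record((0, 1), af=None)
    assert apply_filters(rec, "S", FilterConfig()) == (True, None)
    assert apply_filters(rec, "S", FilterConfig(drop_af_absent=True)) == (
        False, "af_absent")


def test_missing_quality_field_rejected():
    rec = _record((0, 1), dp=None)
    assert apply_filters(rec, "S", FilterConfig()) == (False, "low_depth")


# ---------------------------------------------------------------------------
# aa_set / directional_mismatch


def test_aa_set_het():
    rec = _record((0, 1))
    assert aa_set(rec, rec.consequences, rec.calls["S"]) == {"A", "V"}


def test_aa_set_hom_alt_singleton():
    rec = _record((1, 1))
    assert aa_set(rec, rec.consequences, rec.calls["S"]) == {"V"}


def test_aa_set_two_alt_het():
    """GT=1/2 with per-ALT consequences; independently enumerated: allele 1
    -> R, allele 2 -> W."""
    cons = [
        Consequence(transcript_id="TR1", protein_position=10, amino_acids="G/R",
                    allele_index=0, is_canonical=True),
        Consequence(transcript_id="TR1", protein_position=10, amino_acids="G/W",
                    allele_index=1, is_canonical=True),
    ]
    rec = _record((1, 2), alts=("T", "G"), consequences=cons, ad=(0, 15, 15))
    expected = set()
    for allele in (1, 2):  # independent enumeration over allele indices
        expected.add(cons[allele - 1].amino_acids.split("/")[1])
    assert aa_set(rec, cons, rec.calls["S"]) == expected == {"R", "W"}


def test_aa_set_unannotated_alt_falls_back_to_reference():
    cons = [Consequence(transcript_id="TR1", protein_position=10,
                        amino_acids="G/R", allele_index=0, is_canonical=True)]
    rec = _record((0, 2), alts=("T", "G"), consequences=cons, ad=(15, 0, 15))
    assert aa_set(rec, cons, rec.calls["S"]) == {"G"}


@pytest.mark.parametrize("source,target,expected", [
    ({"A", "V"}, {"A"}, {"V"}),
    ({"A"}, {"A"}, set()),
    ({"R"}, {"G", "R"}, set()),
    ({"G", "R"}, {"R"}, {"G"}),  # the reference allele can be the mismatch
])
def test_directional_mismatch(source, target, expected):
    assert directional_mismatch(source, target) == expected


# ---------------------------------------------------------------------------
# compute_ams on the three-site toy


@pytest.mark.parametrize("direction,missing", list(itertools.product(
    ["sot", "hct"], ["stringent", "impute"])))
def test_three_site_toy(three_site_pair, direction, missing):
    donor, recipient = three_site_pair
    res = compute_ams(
        list(read_vep_vcf(donor)), list(read_vep_vcf(recipient)),
        Direction(direction), MissingMode(missing), NO_AF)
    assert res.ams == THREE_SITE_EXPECTED[(direction, missing)]
    assert res.ams == sum(m.contribution for m in res.table)


def test_three_site_toy_mismatch_identities(three_site_pair):
    donor, recipient = three_site_pair
    d, r = list(read_vep_vcf(donor)), list(read_vep_vcf(recipient))
    sot = compute_ams(d, r, Direction.SOT, MissingMode.STRINGENT, NO_AF)
    assert [set(m.mismatch_aas) for m in sot.table] == [{"V"}]
    assert sot.masked_sites == 1  # the ./. site
    hct = compute_ams(d, r, Direction.HCT, MissingMode.IMPUTE, NO_AF)
    assert sorted(sorted(m.mismatch_aas) for m in hct.table) == [["G"], ["P"]]


def test_self_comparison_is_zero(three_site_pair):
    donor, _ = three_site_pair
    d = list(read_vep_vcf(donor))
    for direction in Direction:
        for mode in MissingMode:
            res = compute_ams(d, d, direction, mode, NO_AF)
            assert res.ams == 0 and res.table == []


# ---------------------------------------------------------------------------
# properties on random family fixtures


def _sim_pair(seed, n_sites=40, **kw):
    cfg = SimConfig(n_sites=n_sites, n_children=2, seed=seed,
                    error_rate=kw.pop("error_rate", 0.05),
                    missing_rate=kw.pop("missing_rate", 0.1), **kw)
    sim = simulate_family(cfg)
    return sim, sim.variant_records()


@pytest.mark.parametrize("seed", range(12))
def test_direction_duality(seed):
    sim, recs = _sim_pair(seed)
    for mode in MissingMode:
        a = compute_ams(recs, recs, Direction.SOT, mode, NO_AF,
                        donor_sample="sib01", recipient_sample="sib02")
        b = compute_ams(recs, recs, Direction.HCT, mode, NO_AF,
                        donor_sample="sib02", recipient_sample="sib01")
        assert a.ams == b.ams
        assert [(m.pos, m.mismatch_aas) for m in a.table] == \
               [(m.pos, m.mismatch_aas) for m in b.table]


@pytest.mark.parametrize("seed", range(8))
def test_oracle_equivalence(seed):
    sim, recs = _sim_pair(seed, n_sites=50)
    for direction in ("sot", "hct"):
        for mode in ("stringent", "impute"):
            got = compute_ams(recs, recs, Direction(direction), MissingMode(mode),
                              NO_AF, donor_sample="sib01",
                              recipient_sample="sib02").ams
            want = oracle.oracle_ams(
                sim.oracle_sites(), sim.genotypes("sib01"),
                sim.genotypes("sib02"), direction, mode)
            assert got == want


def test_stringent_le_impute():
    for seed in range(6):
        sim, recs = _sim_pair(seed, missing_rate=0.15)
        s = compute_ams(recs, recs, Direction.SOT, MissingMode.STRINGENT, NO_AF,
                        donor_sample="sib01", recipient_sample="sib02").ams
        i = compute_ams(recs, recs, Direction.SOT, MissingMode.IMPUTE, NO_AF,
                        donor_sample="sib01", recipient_sample="sib02").ams
        assert s <= i


def test_af_threshold_monotonicity():
    for seed in range(6):
        cfg = SimConfig(n_sites=60, n_children=2, seed=seed, rare_fraction=0.2)
        sim = simulate_family(cfg)
        recs = sim.variant_records()
        scores = []
        for min_af in (0.05, 0.01, 0.0):
            scores.append(compute_ams(
                recs, recs, Direction.SOT, MissingMode.STRINGENT,
                FilterConfig(min_gnomad_af=min_af),
                donor_sample="sib01", recipient_sample="sib02").ams)
        # lowering the threshold never decreases the score
        assert scores[0] <= scores[1] <= scores[2]


def test_binary_site_caps_contribution():
    # donor het A/V vs recipient hom-ref in HCT gives no mismatch; craft a
    # two-mismatch site instead: donor {A,V}, recipient {W} via 1/1 on alt2
    cons = [
        Consequence(transcript_id="TR1", protein_position=10, amino_acids="A/V",
                    allele_index=0, gnomad_af=0.3, is_canonical=True),
        Consequence(transcript_id="TR1", protein_position=10, amino_acids="A/W",
                    allele_index=1, gnomad_af=0.3, is_canonical=True),
    ]
    donor_call = GenotypeCall((0, 1), depth=30, genotype_quality=99,
                              allele_depths=(15, 15, 0))
    recip_call = GenotypeCall((2, 2), depth=30, genotype_quality=99,
                              allele_depths=(0, 0, 30))
    rec = VariantRecord(chrom="chr1", pos=100, ref="C", alts=("T", "G"),
                        filter_status=frozenset({"PASS"}),
                        calls={"D": donor_call, "R": recip_call},
                        consequences=cons)
    plain = compute_ams([rec], [rec], Direction.SOT, MissingMode.STRINGENT,
                        NO_AF, donor_sample="D", recipient_sample="R")
    assert plain.ams == 2  # {A, V} both absent from {W}
    capped = compute_ams([rec], [rec], Direction.SOT, MissingMode.STRINGENT,
                         NO_AF, CountConfig(binary_site=True),
                         donor_sample="D", recipient_sample="R")
    assert capped.ams == 1


def test_site_missing_from_one_file(tmp_path):
    """A site absent from the recipient VCF is genotype-missing there."""
    donor = write_vcf_text(tmp_path / "d.vcf", [
        dict(pos=100, ref="C", alts=["T"],
             csq=[missense_csq("T", "TR1", 10, "A/V", af=0.3)],
             gts=["1/1:30:99:0,30"]),
    ], samples=["D"])
    recipient = write_vcf_text(tmp_path / "r.vcf", [
        dict(pos=500, ref="G", alts=["A"],
             csq=[missense_csq("A", "TR2", 4, "G/R", af=0.3)],
             gts=["0/0:30:99:30,0"]),
    ], samples=["R"])
    d, r = list(read_vep_vcf(donor)), list(read_vep_vcf(recipient))
    stringent = compute_ams(d, r, Direction.SOT, MissingMode.STRINGENT, NO_AF)
    assert stringent.ams == 0 and stringent.masked_sites == 2
    impute = compute_ams(d, r, Direction.SOT, MissingMode.IMPUTE, NO_AF)
    assert impute.ams == 1  # donor V vs imputed {A}


# ---------------------------------------------------------------------------
# restriction


def test_bed_half_open(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("chr1\t99\t200\n")
    kept = _record((0, 1))  # pos 100 -> 0-based 99, inside [99, 200)
    dropped = VariantRecord(chrom="chr1", pos=99, ref="C", alts=("T",),
                            calls=kept.calls, consequences=kept.consequences)
    out = restrict([kept, dropped], bed=bed)
    assert [r.pos for r in out] == [100]


def test_empty_rsid_list_drops_everything(tmp_path):
    ids = tmp_path / "ids.txt"
    ids.write_text("")
    assert restrict([_record((0, 1))], rsids=ids) == []


def test_transcript_restriction_keeps_surviving_consequences():
    cons = [
        Consequence(transcript_id="TR1", protein_position=10, amino_acids="A/V",
                    allele_index=0, is_canonical=True),
        Consequence(transcript_id="TR2", protein_position=22, amino_acids="A/L",
                    allele_index=0),
    ]
    rec = _record((0, 1), consequences=cons)
    (kept,) = restrict([rec], transcripts={"TR2"})
    assert [c.transcript_id for c in kept.consequences] == ["TR2"]
    assert restrict([rec], transcripts={"TRX"}) == []


def test_malformed_bed_reports_line(tmp_path):
    bed = tmp_path / "bad.bed"
    bed.write_text("chr1\t0\t10\nchr1\toops\t20\n")
    with pytest.raises(RestrictionError, match=":2"):
        load_bed(bed)


def test_restricted_ams_le_unrestricted(tmp_path):
    sim, recs = _sim_pair(3, n_sites=50)
    bed = tmp_path / "half.bed"
    # first half of the simulated chromosome
    mid = sim.sites[len(sim.sites) // 2].pos
    bed.write_text(f"chrS\t0\t{mid}\n")
    full = compute_ams(recs, recs, Direction.SOT, MissingMode.STRINGENT, NO_AF,
                       donor_sample="sib01", recipient_sample="sib02").ams
    part = compute_ams(recs, recs, Direction.SOT, MissingMode.STRINGENT, NO_AF,
                       donor_sample="sib01", recipient_sample="sib02",
                       bed=bed).ams
    assert part <= full
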