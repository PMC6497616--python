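"""Reading, allele alignment, orientation and proxy substitution."""

import math

import pytest

from bwmr.summary_data import (
    AlleleMismatchError,
    HarmonisedInstrument,
    NullInstrumentError,
    ProxyMap,
    SummaryAssociation,
    align_alleles,
    harmonise,
    orient_to_exposure_increasing,
    read_instruments,
    read_summary_table,
    substitute_proxies,
    write_instruments,
)


def _assoc(snp="rs1", ea="A", oa="G", beta=0.02, se=0.01, p=0.05, eaf=0.3):
    return SummaryAssociation(snp, ea, oa, beta, se, p, eaf=eaf)


class TestReadSummaryTable:
    def test_well_formed_table_gives_one_record_per_row(self, tmp_path):
        path = tmp_path / "sum.tsv"
        path.write_text(
            "snp\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\tA\tG\t0.3\t0.02\t0.01\t0.046\t1000\n"
            "rs2\tC\tT\t0.5\t-0.01\t0.02\t0.62\t1000\n"
            "rs3\tG\tA\t0.1\t0.05\t0.012\t3e-5\t1000\n"
        )
        records = read_summary_table(path)
        assert len(records) == 3
        assert records[0].snp_id == "rs1"
        assert records[1].beta == -0.01

    def test_row_with_na_se_is_dropped(self, tmp_path, caplog):
        path = tmp_path / "sum.tsv"
        path.write_text(
            "snp\teffect_allele\tother_allele\tbeta\tse\tpvalue\n"
            "rs1\tA\tG\t0.02\tNA\t0.05\n"
            "rs2\tC\tT\t0.01\t0.02\t0.5\n"
        )
        with caplog.at_level("WARNING"):
            records = read_summary_table(path)
        assert [r.snp_id for r in records] == ["rs2"]
        assert any("dropped 1" in m for m in caplog.messages)

    def test_column_order_and_aliases_are_irrelevant(self, tmp_path):
        canonical = tmp_path / "a.tsv"
        canonical.write_text(
            "snp\teffect_allele\tother_allele\tbeta\tse\tpvalue\nrs1\tA\tG\t0.02\t0.01\t0.046\n"
        )
        shuffled = tmp_path / "b.tsv"
        shuffled.write_text(
            "P\tSE\tMarkerName\tA2\tEffect\tA1\n0.046\t0.01\trs1\tG\t0.02\tA\n"
        )
        assert read_summary_table(canonical) == read_summary_table(shuffled)

    def test_missing_required_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp\teffect_allele\tbeta\tse\tpvalue\nrs1\tA\t0.02\t0.01\t0.05\n")
        with pytest.raises(ValueError, match="other_allele"):
            read_summary_table(path)

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(OSError):
            read_summary_table(tmp_path / "missing.tsv")


class TestAlignAlleles:
    def test_already_aligned_is_unchanged(self):
        exp = _assoc(beta=0.02)
        out = _assoc(beta=-0.01)
        assert align_alleles(exp, out) == out

    def test_swapped_alleles_flip_beta_and_complement_eaf(self):
        exp = _assoc(ea="A", oa="G", beta=0.02)
        out = _assoc(ea="G", oa="A", beta=-0.01, eaf=0.3)
        aligned = align_alleles(exp, out)
        assert aligned.effect_allele == "A" and aligned.other_allele == "G"
        assert aligned.beta == pytest.approx(0.01)
        assert aligned.eaf == pytest.approx(0.7)

    def test_irreconcilable_alleles_raise(self):
        with pytest.raises(AlleleMismatchError):
            align_alleles(_assoc(ea="A", oa="G"), _assoc(ea="C", oa="T"))

    def test_alignment_is_idempotent(self):
        exp = _assoc(ea="A", oa="G", beta=0.02)
        out = _assoc(ea="G", oa="A", beta=-0.01, eaf=0.3)
        once = align_alleles(exp, out)
        assert align_alleles(exp, once) == once


class TestOrientation:
    def _record(self, bx, by):
        return HarmonisedInstrument(
            "rs1", bx, 0.01, by, 0.02, eaf=0.3, covariate_betas={"height": (0.05, 0.01)}
        )

    def test_negative_exposure_beta_flips_all_betas_jointly(self):
        rec = orient_to_exposure_increasing(self._record(-0.03, 0.01))
        assert rec.beta_exposure == pytest.approx(0.03)
        assert rec.beta_outcome == pytest.approx(-0.01)
        assert rec.covariate_betas["height"][0] == pytest.approx(-0.05)
        assert rec.eaf == pytest.approx(0.7)

    def test_positive_exposure_beta_is_identity(self):
        rec = self._record(0.03, 0.01)
        assert orient_to_exposure_increasing(rec) is rec

    @pytest.mark.parametrize("bx,by", [(-0.03, 0.01), (0.04, -0.02), (-0.1, -0.05)])
    def test_wald_ratio_is_invariant(self, bx, by):
        rec = self._record(bx, by)
        assert orient_to_exposure_increasing(rec).wald_ratio == pytest.approx(rec.wald_ratio)

    def test_zero_exposure_beta_is_excluded(self):
        with pytest.raises(NullInstrumentError, match="null_instrument"):
            orient_to_exposure_increasing(self._record(0.0, 0.01))


class TestProxySubstitution:
    def test_qualifying_proxy_is_used(self):
        pm = ProxyMap({"rs1": ("rs9", 0.9)})
        available = {"rs9": _assoc(snp="rs9")}
        resolved, unmatched = substitute_proxies(["rs1"], available, pm, min_r2=0.8)
        assert unmatched == []
        record, proxy_id, r2 = resolved["rs1"]
        assert proxy_id == "rs9" and r2 == 0.9

    def test_proxy_below_threshold_leaves_lead_unmatched(self):
        pm = ProxyMap({"rs1": ("rs9", 0.7)})
        resolved, unmatched = substitute_proxies(["rs1"], {"rs9": _assoc(snp="rs9")}, pm, min_r2=0.8)
        assert resolved == {} and unmatched == ["rs1"]

    def test_direct_record_beats_proxy(self):
        pm = ProxyMap({"rs1": ("rs9", 0.95)})
        available = {"rs1": _assoc(), "rs9": _assoc(snp="rs9")}
        resolved, _ = substitute_proxies(["rs1"], available, pm)
        assert resolved["rs1"][1] is None

    def test_r2_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ProxyMap({"rs1": ("rs9", 1.2)})


class TestHarmonise:
    def test_round_trip_through_tsv(self, tmp_path):
        exp = [_assoc(snp="rs1", beta=0.02), _assoc(snp="rs2", ea="T", oa="C", beta=-0.03)]
        out = [
            _assoc(snp="rs1", beta=-0.01, se=0.02),
            _assoc(snp="rs2", ea="C", oa="T", beta=0.02, se=0.03, eaf=0.4),
        ]
        instruments, exclusions = harmonise(exp, out)
        assert exclusions == []
        assert all(i.beta_exposure > 0 for i in instruments)
        path = tmp_path / "instr.tsv"
        write_instruments(instruments, path)
        back = read_instruments(path)
        for a, b in zip(instruments, back):
            assert a.snp_id == b.snp_id
            assert a.beta_exposure == pytest.approx(b.beta_exposure, rel=1e-12)
            assert a.beta_outcome == pytest.approx(b.beta_outcome, rel=1e-12)
            assert a.wald_ratio == pytest.approx(b.wald_ratio, rel=1e-12)

    def test_allele_mismatch_is_logged_not_fatal(self):
        exp = [_assoc(snp="rs1"), _assoc(snp="rs2")]
        out = [_assoc(snp="rs1", ea="C", oa="T"), _assoc(snp="rs2")]
        instruments, exclusions = harmonise(exp, out)
        assert ("rs1", "allele_mismatch") in exclusions
        assert [i.snp_id for i in instruments] == ["rs2"]

    def test_strict_mode_drops_ambiguous_palindromes(self):
        exp = [_assoc(snp="rs1", ea="A", oa="T", eaf=0.5), _assoc(snp="rs2")]
        out = [_assoc(snp="rs1", ea="A", oa="T", eaf=0.5), _assoc(snp="rs2")]
        lax, _ = harmonise(exp, out)
        strict, excl = harmonise(exp, out, strict_palindromic=True)
        assert len(lax) == 2
        assert [i.snp_id for i in strict] == ["rs2"]
        assert ("rs1", "palindromic_ambiguous") in excl

    def test_missing_outcome_without_proxy_is_excluded(self):
        instruments, exclusions = harmonise([_assoc(snp="rs1")], [])
        assert instruments == []
        assert exclusions == [("rs1", "missing_outcome")]

    def test_pvalue_consistency_check(self):
        ok = _assoc(beta=0.02, se=0.01, p=2 * 0.02275)  # z = 2
        assert ok.pvalue_consistent()
        bad = _assoc(beta=0.02, se=0.01, p=0.9)
        assert not bad.pvalue_consistent()
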