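"""Reading, validation and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrkit.summary_io import (DiagnosticUnavailable, FormatError, ProxyMap,
                              ProxyRecord, SnpAssociation, ValidationError,
                              eaf_concordance, harmonize, harmonized_frame,
                              instrument_strength, read_association_table,
                              read_harmonized, write_harmonized)


def write_table(path, rows, columns=("snp", "effect_allele", "other_allele",
                                     "eaf", "beta", "se")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
    return path


def assoc(snp, ea, oa, beta, se=0.01, eaf=None):
    return SnpAssociation(snp_id=snp, effect_allele=ea, other_allele=oa,
                          beta=beta, se=se, eaf=eaf)


class TestReadAssociationTable:
    def test_identity_read(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [
            ("rs1", "A", "G", 0.25, 0.031, 0.004),
            ("rs2", "C", "T", 0.60, -0.020, 0.003),
            ("rs3", "G", "C", 0.50, 0.011, 0.005),
        ])
        recs = read_association_table(p, "exposure")
        assert [r.snp_id for r in recs] == ["rs1", "rs2", "rs3"]
        assert recs[0].beta == 0.031 and recs[0].se == 0.004
        assert recs[1].effect_allele == "C" and recs[1].eaf == 0.60

    def test_zero_se_names_row(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [
            ("rs1", "A", "G", 0.25, 0.031, 0.004),
            ("rs2", "C", "T", 0.60, -0.020, 0.0),
        ])
        with pytest.raises(ValidationError, match="rs2"):
            read_association_table(p, "exposure")

    def test_missing_column_named(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [("rs1", "A", "G", 0.03)],
                        columns=("snp", "effect_allele", "other_allele", "beta"))
        with pytest.raises(FormatError, match="se"):
            read_association_table(p, "exposure")

    def test_non_numeric_beta(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [("rs1", "A", "G", 0.2, "xx", 0.004)])
        with pytest.raises(ValidationError, match="non-numeric"):
            read_association_table(p, "outcome")

    def test_duplicates_listed(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [
            ("rs1", "A", "G", 0.2, 0.03, 0.004),
            ("rs1", "A", "G", 0.2, 0.03, 0.004),
        ])
        with pytest.raises(FormatError, match="rs1"):
            read_association_table(p, "exposure")

    def test_synonym_headers(self, tmp_path):
        p = write_table(tmp_path / "t.tsv", [("rs1", "A", "G", 0.2, 0.03, 0.004)],
                        columns=("MarkerName", "A1", "A2", "FRQ", "b", "SE"))
        recs = read_association_table(p, "exposure")
        assert recs[0].snp_id == "rs1" and recs[0].eaf == 0.2


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        expo = [assoc("rs1", "A", "G", 0.03, eaf=0.3)]
        outc = [assoc("rs1", "G", "A", -0.10, eaf=0.7)]
        harm = harmonize(expo, outc)
        assert len(harm) == 1
        inst = harm[0]
        assert inst.Gamma == pytest.approx(0.10)
        assert inst.eaf_outcome == pytest.approx(0.3)

    def test_strand_complement(self):
        expo = [assoc("rs1", "A", "G", 0.03)]
        outc = [assoc("rs1", "T", "C", 0.10)]   # same variant, other strand
        harm = harmonize(expo, outc)
        assert harm[0].Gamma == pytest.approx(0.10)

    def test_complement_and_swap(self):
        expo = [assoc("rs1", "A", "G", 0.03)]
        outc = [assoc("rs1", "C", "T", 0.10)]
        assert harmonize(expo, outc)[0].Gamma == pytest.approx(-0.10)

    def test_allele_mismatch_excluded_with_reason(self):
        expo = [assoc("rs1", "A", "G", 0.03)]
        outc = [assoc("rs1", "A", "C", 0.10)]
        harm = harmonize(expo, outc)
        assert len(harm) == 0
        assert harm.excluded == [("rs1", "allele mismatch")]

    def test_absent_excluded_and_proxy_substitution(self):
        expo = [assoc("rs1", "A", "G", 0.03), assoc("rs2", "C", "T", 0.02)]
        outc = [assoc("rs1", "A", "G", 0.08), assoc("rs99", "C", "T", 0.05)]
        proxies = ProxyMap([ProxyRecord("rs2", "rs99", 0.95, 1000)])
        harm = harmonize(expo, outc, proxies)
        assert len(harm) == 2
        by_id = {i.snp_id: i for i in harm}
        assert by_id["rs99"].proxy_of == "rs2"
        assert by_id["rs99"].Gamma == pytest.approx(0.05)
        # without the proxy map rs2 is excluded with a reason
        harm2 = harmonize(expo, outc)
        assert harm2.excluded == [("rs2", "absent from outcome table")]

    def test_palindromic_eaf_discordant_flips(self):
        expo = [assoc("rs1", "A", "T", 0.03, eaf=0.2)]
        outc = [assoc("rs1", "A", "T", 0.10, eaf=0.8)]  # other strand coding
        harm = harmonize(expo, outc)
        assert harm[0].Gamma == pytest.approx(-0.10)
        assert harm[0].eaf_outcome == pytest.approx(0.2)

    def test_palindromic_uninformative_warns(self):
        expo = [assoc("rs1", "C", "G", 0.03, eaf=0.52)]
        outc = [assoc("rs1", "C", "G", 0.10, eaf=0.49)]
        harm = harmonize(expo, outc)
        assert harm[0].Gamma == pytest.approx(0.10)
        assert any("palindromic" in w for w in harm.warnings)

    def test_double_swap_is_involution(self, rng):
        expo = [assoc(f"rs{j}", "A", "G", float(b), eaf=0.3)
                for j, b in enumerate(rng.uniform(0.01, 0.05, 8))]
        outc = [assoc(f"rs{j}", "A", "G", float(b), eaf=0.3)
                for j, b in enumerate(rng.normal(0, 0.05, 8))]
        once = harmonize(expo, outc)
        twice = harmonize(expo, [o.flipped().flipped() for o in outc])
        assert [i.Gamma for i in once] == [i.Gamma for i in twice]

    @given(beta=st.floats(-0.5, 0.5, allow_nan=False),
           eaf=st.floats(0.05, 0.95))
    def test_reexpressing_outcome_on_other_allele_is_neutral(self, beta, eaf):
        """Flipping (alleles, beta, eaf) of a non-palindromic outcome row
        must leave the harmonized pair unchanged."""
        expo = [assoc("rs1", "A", "G", 0.03, eaf=0.3)]
        outc = [assoc("rs1", "A", "G", beta, eaf=eaf)]
        h1 = harmonize(expo, outc)
        h2 = harmonize(expo, [outc[0].flipped()])
        assert h1[0].gamma == h2[0].gamma
        assert h1[0].Gamma == pytest.approx(h2[0].Gamma)

    def test_counts_and_exclusion_accounting(self, rng):
        expo = [assoc(f"rs{j}", "A", "G", 0.03) for j in range(10)]
        outc = [assoc(f"rs{j}", "A", "G", 0.05) for j in range(7)]
        harm = harmonize(expo, outc)
        assert len(harm) + len(harm.excluded) == len(expo)
        assert all(reason for _, reason in harm.excluded)


class TestProxyMap:
    def test_threshold_validation(self):
        with pytest.raises(ValidationError, match="r2"):
            ProxyMap([ProxyRecord("rs1", "rs2", 0.5, 100)])
        with pytest.raises(ValidationError, match="distance"):
            ProxyMap([ProxyRecord("rs1", "rs2", 0.9, 600_000)])

    def test_highest_r2_wins(self):
        pm = ProxyMap([ProxyRecord("rs1", "rsA", 0.85, 100),
                       ProxyRecord("rs1", "rsB", 0.95, 200)])
        assert pm.best_proxy("rs1").proxy_snp == "rsB"


class TestDiagnostics:
    def test_perfect_concordance(self):
        expo = [assoc(f"rs{j}", "A", "G", 0.03, eaf=e)
                for j, e in enumerate((0.2, 0.5, 0.8, 0.35))]
        outc = [assoc(f"rs{j}", "A", "G", 0.05, eaf=e)
                for j, e in enumerate((0.2, 0.5, 0.8, 0.35))]
        conc = eaf_concordance(harmonize(expo, outc).instruments)
        assert conc.r == pytest.approx(1.0)
        assert conc.n_pairs == 4

    def test_too_few_pairs_flagged(self):
        expo = [assoc("rs1", "A", "G", 0.03, eaf=0.2),
                assoc("rs2", "A", "G", 0.03, eaf=0.3)]
        outc = [assoc("rs1", "A", "G", 0.05, eaf=0.2),
                assoc("rs2", "A", "G", 0.05, eaf=0.3)]
        with pytest.raises(DiagnosticUnavailable):
            eaf_concordance(harmonize(expo, outc).instruments)

    def test_f_statistics(self, instruments):
        s = instrument_strength(instruments)
        f = np.array([(i.gamma / i.se_gamma) ** 2 for i in instruments])
        assert s.f_stats.to_numpy() == pytest.approx(f)
        assert s.mean == pytest.approx(f.mean())
        assert s.median == pytest.approx(np.median(f))

    def test_zero_gamma_zero_f(self):
        from mrkit.summary_io import HarmonizedInstrument
        inst = [HarmonizedInstrument("rs1", 0.0, 0.01, 0.1, 0.02)]
        assert instrument_strength(inst).f_stats["rs1"] == 0.0

    def test_rescaling_and_errors(self, instruments):
        s = instrument_strength(instruments, target_n=16_731, source_n=322_154)
        ratio = 16_731 / 322_154
        assert s.rescaled.mean == pytest.approx(s.mean * ratio)
        with pytest.raises(ValueError):
            instrument_strength(instruments, target_n=100.0)

    def test_f_invariant_to_orientation(self, instruments):
        from dataclasses import replace
        flipped = [replace(i, gamma=-i.gamma, Gamma=-i.Gamma) for i in instruments]
        assert instrument_strength(flipped).mean == \
            pytest.approx(instrument_strength(instruments).mean)


def test_harmonized_roundtrip(tmp_path, instruments):
    path = tmp_path / "h.tsv"
    write_harmonized(instruments, path)
    back = read_harmonized(path)
    assert [i.snp_id for i in back] == [i.snp_id for i in instruments]
    assert [i.Gamma for i in back] == pytest.approx([i.Gamma for i in instruments])
    cols = list(harmonized_frame(instruments).columns)
    assert cols[:4] == ["snp_id", "proxy_of", "gamma", "se_gamma"]
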