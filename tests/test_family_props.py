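import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famevo import family_props as fp
from famevo.family_props import DomainHit, ProteinRecord
from famevo.io_formats import DomTblRow

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


def _row(ev, sc):
    return DomTblRow("p", "PF00110", ev, sc, ev, 1, 100)


class TestFilterHits:
    @pytest.mark.parametrize(
        "ev,sc,kept",
        [
            (1e-6, 50.0, True),
            (1e-4, 50.0, False),
            (1e-5, 0.0, True),  # both thresholds inclusive
            (1e-6, -0.1, False),
        ],
    )
    def test_thresholds(self, ev, sc, kept):
        assert bool(fp.filter_hits([_row(ev, sc)])) is kept

    def test_idempotent(self):
        rows = [_row(10.0 ** -k, float(k)) for k in range(12)]
        once = fp.filter_hits(rows)
        assert fp.filter_hits(once) == once

    def test_domain_evalue_switch(self):
        row = DomTblRow("p", "PF00778", 1e-9, 50.0, 1e-3, 1, 70)
        assert fp.filter_hits([row]) == [row]
        assert fp.filter_hits([row], use_domain_evalue=True) == []


class TestDeduplicate:
    def test_longest_isoform_kept(self, random_protein):
        prots = [
            ProteinRecord("p_short", "geneA", "mouse", random_protein(350)),
            ProteinRecord("p_long", "geneA", "mouse", random_protein(400)),
        ]
        assert [p.protein_id for p in fp.deduplicate(prots)] == ["p_long"]

    def test_tie_breaks_lexicographically(self, random_protein):
        seq = random_protein(120)
        prots = [
            ProteinRecord("iso_b", "geneA", "mouse", seq),
            ProteinRecord("iso_a", "geneA", "mouse", seq),
        ]
        assert [p.protein_id for p in fp.deduplicate(prots)] == ["iso_a"]

    def test_representative_count_equals_gene_count(self, rng, random_protein):
        # a 30-isoform set drawn from 19 genes yields 19 representatives
        genes = [f"Wnt{k}" for k in range(1, 20)]
        prots = [
            ProteinRecord(f"iso{i}", genes[i % 19], "mouse",
                          random_protein(int(rng.integers(300, 420))))
            for i in range(30)
        ]
        assert len(fp.deduplicate(prots)) == 19

    def test_missing_gene_id_rejected(self, random_protein):
        with pytest.raises(ValueError, match="gene_id"):
            fp.deduplicate([ProteinRecord("p", "", "mouse", random_protein(10))])


class TestMolecularWeight:
    def test_glycine(self):
        assert fp.molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        assert fp.molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    @given(sequences)
    @settings(max_examples=50, derandomize=True)
    def test_appending_residue_increases_mass(self, seq):
        assert fp.molecular_weight(seq + "A") > fp.molecular_weight(seq)

    def test_x_uses_average_mass(self):
        expected = fp.WATER_MASS + fp.X_MASS
        assert fp.molecular_weight("X") == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            fp.molecular_weight("")
        with pytest.raises(ValueError, match="non-canonical"):
            fp.molecular_weight("GZ")


class TestIsoelectricPoint:
    def test_terminal_groups_only(self):
        # only the termini ionize: pI = midpoint of their pK values
        assert fp.isoelectric_point("GGGG") == pytest.approx(5.52, abs=0.05)

    def test_monotone_in_basic_and_acidic_residues(self):
        base = fp.isoelectric_point("GGGG")
        assert fp.isoelectric_point("GGGGK") > base
        assert fp.isoelectric_point("GGGGD") < base

    @given(sequences)
    @settings(max_examples=30, derandomize=True)
    def test_charge_at_pi_is_zero(self, seq):
        pi = fp.isoelectric_point(seq, tol=1e-5)
        assert abs(fp.net_charge(seq, pi)) < 0.01

    @given(sequences, st.randoms(use_true_random=False))
    @settings(max_examples=30, derandomize=True)
    def test_composition_only(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert fp.isoelectric_point("".join(shuffled)) == pytest.approx(
            fp.isoelectric_point(seq), abs=1e-9
        )


class TestDomainArchitecture:
    def test_dvl_like_n_terminal_dix(self):
        hits = [
            DomainHit("p", "DIX", 1, 80, 95.0, 1e-20),
            DomainHit("p", "PDZ", 250, 330, 80.0, 1e-15),
            DomainHit("p", "DEP", 400, 470, 85.0, 1e-17),
        ]
        assert fp.domain_architecture(hits) == "DIX-PDZ-DEP"

    def test_axin_like_c_terminal_dix(self):
        hits = [
            DomainHit("p", "RGS", 80, 200, 90.0, 1e-18),
            DomainHit("p", "DIX", 760, 830, 70.0, 1e-12),
        ]
        assert fp.domain_architecture(hits) == "RGS-DIX"

    def test_overlap_keeps_higher_score(self):
        hits = [
            DomainHit("p", "DIX", 1, 80, 90.0, 1e-20),
            DomainHit("p", "DIX", 40, 110, 30.0, 1e-5),
        ]
        assert fp.domain_architecture(hits) == "DIX"

    def test_no_hits_empty_string(self):
        assert fp.domain_architecture([]) == ""

    def test_mixed_proteins_rejected(self):
        hits = [
            DomainHit("p1", "DIX", 1, 80, 90.0, 1e-20),
            DomainHit("p2", "DIX", 1, 80, 90.0, 1e-20),
        ]
        with pytest.raises(ValueError):
            fp.domain_architecture(hits)


class TestCensus:
    def test_counts_and_group_means(self):
        genes = {
            "sp1": {"Wnt": [f"g{i}" for i in range(10)]},
            "sp2": {"Wnt": [f"g{i}" for i in range(10)]},
            "sp3": {"Wnt": [f"g{i}" for i in range(10)]},
        }
        c = fp.census(genes, {"vert": ["sp1", "sp2", "sp3"]})
        assert c.group_means("Wnt") == {"vert": 10.0}

    def test_species_without_hits_counts_zero(self):
        genes = {"sp1": {"Wnt": ["a", "b"]}}
        c = fp.census(genes, {"vert": ["sp1", "sp2"]})
        assert c.counts.loc["sp2", "Wnt"] == 0
        assert c.group_means("Wnt") == {"vert": 1.0}

    def test_species_in_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            fp.census({}, {"vert": ["sp1"], "invert": ["sp1"]})


class TestAnova:
    def test_identical_groups(self):
        res = fp.compare_groups_anova({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_well_separated_groups(self, rng):
        res = fp.compare_groups_anova(
            {"a": rng.normal(0, 1, 20), "b": rng.normal(10, 1, 20)}
        )
        assert res.p_value < 1e-6
        assert res.dunnett_p["b"] < 1e-6

    def test_shift_invariance(self, rng):
        groups = {k: rng.normal(m, 1, 10) for k, m in zip("abc", (0, 1, 2))}
        shifted = {k: np.asarray(v) + 100.0 for k, v in groups.items()}
        res1 = fp.compare_groups_anova(groups)
        res2 = fp.compare_groups_anova(shifted)
        assert res1.f_statistic == pytest.approx(res2.f_statistic, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fp.compare_groups_anova({"a": [1.0], "b": [1.0, 2.0]})


def test_orf_length_includes_stop():
    assert fp.orf_length_bp(349) == 1050
    assert fp.orf_length_bp(417) == 1254
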