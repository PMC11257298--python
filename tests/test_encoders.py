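"""Encoder correctness against independently written brute-force oracles,
plus schema bookkeeping and purity properties."""

import math

import numpy as np
import pytest

import oracles
from encap.encoders import (
    EncoderError,
    FeatureSchema,
    default_registry,
    encode_all,
    encode_peptide,
    make_encoder,
    rebuild_registry,
)
from encap.encoders.physicochem import net_charge
from encap.peptides import LabeledPeptideSet, Peptide
from encap.tables import OVPC_CLASSES

from Bio.SeqUtils.ProtParam import ProteinAnalysis


# (encoder factory kwargs, oracle callable) pairs covering every family
ORACLE_CASES = [
    (("AAC", {}), oracles.aac),
    (("DPC", {}), oracles.dpc),
    (("GAAC", {}), oracles.gaac),
    (("GDPC", {}), oracles.gdpc),
    (("CTriad", {}), oracles.ctriad),
    (("DDE", {}), oracles.dde),
    (("CKSAAP", {"gap": 0}), lambda s: oracles.cksaap(s, 0)),
    (("CKSAAP", {"gap": 3}), lambda s: oracles.cksaap(s, 3)),
    (("CKSAAP", {"gap": 5}), lambda s: oracles.cksaap(s, 5)),
    (("CKSAAGP", {"gap": 2}), lambda s: oracles.cksaagp(s, 2)),
    (("CTDC", {}), oracles.ctdc),
    (("CTDT", {}), oracles.ctdt),
    (("CTDD", {}), oracles.ctdd),
    (("APAAC", {"lam": 3}), lambda s: oracles.apaac(s, 3)),
    (("QSO", {"nlag": 3}), lambda s: oracles.qso(s, 3)),
    (("DDR", {}), oracles.ddr),
    (("RRI", {}), oracles.rri),
    (("SER", {}), oracles.ser),
    (("SEP", {}), oracles.sep),
    (("MSW", {}), lambda s: oracles.scale_descriptor(s, "MSW", 10)),
    (("Z3", {}), lambda s: oracles.scale_descriptor(s, "Z3", 10)),
    (("Z5", {}), lambda s: oracles.scale_descriptor(s, "Z5", 15)),
    (("Ez", {}), lambda s: oracles.scale_descriptor(s, "Ez", 10)),
    (("Cougar", {}), lambda s: oracles.scale_descriptor(s, "Cougar", 10)),
    (("ABHPRK", {}), oracles.abhprk),
    (("global_aliphatic_index", {}), lambda s: [oracles.aliphatic_index(s)]),
    (("global_boman_index", {}), lambda s: [oracles.boman(s)]),
]


@pytest.mark.parametrize(
    "factory,oracle", ORACLE_CASES, ids=[c[0][0] + str(c[0][1]) for c in ORACLE_CASES]
)
def test_encoder_matches_bruteforce_oracle(factory, oracle, random_peptides):
    name, params = factory
    spec = make_encoder(name, **params)
    for seq in random_peptides:
        got = spec.encode(seq)
        want = np.asarray(oracle(seq), dtype=float)
        np.testing.assert_allclose(got, want, atol=1e-10, err_msg=f"{name} on {seq}")


class TestWorkedExamples:
    def test_aac_uniform_composition(self):
        v = make_encoder("AAC").encode("FATP")
        idx = {a: i for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        for a in "FATP":
            assert v[idx[a]] == pytest.approx(0.25)
        assert v.sum() == pytest.approx(1.0)

    def test_dpc_single_dipeptide_type(self):
        v = make_encoder("DPC").encode("AAA")
        assert v[0] == pytest.approx(1.0)  # AA is the first dipeptide
        assert v.sum() == pytest.approx(1.0)

    def test_dde_closed_form_on_ww(self):
        # single WW window: Dc=1, Tm=(1/61)^2, Tv=Tm(1-Tm)/1
        v = make_encoder("DDE").encode("WW")
        tm = (1 / 61) ** 2
        expected = (1 - tm) / math.sqrt(tm * (1 - tm))
        ww = 20 * 18 + 18  # W is residue index 18
        assert v[ww] == pytest.approx(expected)

    def test_ctd_transitions_zero_on_homopeptide(self):
        assert np.all(make_encoder("CTDT").encode("AAAAA") == 0)

    def test_ctd_composition_single_class_occupancy(self):
        v = make_encoder("CTDC").encode("AAAAA")
        per_property = v.reshape(13, 3)
        assert np.all(per_property.sum(axis=1) == pytest.approx(1.0))
        assert set(np.unique(v)) == {0.0, 1.0}

    def test_ctdd_first_occurrence_percent_position(self):
        # under the secondary-structure partition G and A fall in different
        # classes, so the first A of GAAAA sits at position 2 of 5 -> 40%
        from encap.tables import CTD_PROPERTIES

        props = list(CTD_PROPERTIES)
        pi = props.index("secondarystruct")
        groups = CTD_PROPERTIES["secondarystruct"]
        a_group = next(i for i, g in enumerate(groups) if "A" in g)
        v = make_encoder("CTDD").encode("GAAAA")
        assert v[pi * 15 + a_group * 5 + 0] == pytest.approx(40.0)

    def test_apaac_lambda_zero_reduces_to_aac(self):
        v = make_encoder("APAAC", lam=0).encode("FATPLLD")
        np.testing.assert_allclose(v, make_encoder("AAC").encode("FATPLLD"))

    def test_qso_size_is_46_at_nlag_3(self):
        assert make_encoder("QSO", nlag=3).size == 46

    def test_aromaticity_all_and_none(self):
        spec = make_encoder("global_aromaticity")
        assert spec.encode("FWY")[0] == pytest.approx(1.0)
        assert spec.encode("AAAA")[0] == pytest.approx(0.0)

    def test_aliphatic_index_hand_value(self):
        v = make_encoder("global_aliphatic_index").encode("AVIL")
        assert v[0] == pytest.approx(25 + 2.9 * 25 + 3.9 * 50)

    def test_isoelectric_point_near_bisection_root(self):
        spec = make_encoder("global_isoelectric_point")
        for seq in ("KKKK", "DDEE", "FATPLLD", "ACDEFGHIK"):
            assert spec.encode(seq)[0] == pytest.approx(
                oracles.pi_bisection(seq), abs=0.1
            )

    def test_ovpc_aromatic_fraction(self):
        spec = make_encoder("OVPC_Aromatic")
        assert spec.encode("FWYA")[0] == pytest.approx(0.75)

    def test_scale_descriptor_constant_profile(self):
        # homopeptide: mean == first == last == the residue's scale value
        from encap.tables.scales_synthetic import SCALE_TABLES

        v = make_encoder("Z3").encode("AAAAA")
        z_a = SCALE_TABLES["Z3"]["A"]
        for d in range(3):
            assert v[d * 10 + 0] == pytest.approx(z_a[d])  # mean
            assert v[d * 10 + 1] == pytest.approx(0.0)     # std

    def test_ser_entropy_limits(self):
        ser = make_encoder("SER")
        assert ser.encode("AAAA")[0] == 0.0
        assert ser.encode("ACDE")[0] == pytest.approx(2.0)

    def test_charge_sign_conventions(self):
        assert net_charge("KKKK") > 0
        assert net_charge("DDEE") < 0


class TestLengthGuards:
    @pytest.mark.parametrize(
        "name,params,too_short",
        [
            ("CKSAAP", {"gap": 5}, "ACDEFG"),
            ("APAAC", {"lam": 3}, "ACD"),
            ("QSO", {"nlag": 3}, "ACD"),
            ("CTriad", {}, "AC"),
        ],
    )
    def test_short_peptides_raise_named_error(self, name, params, too_short):
        with pytest.raises(EncoderError, match="length"):
            make_encoder(name, **params).encode(too_short)


class TestSchemaBookkeeping:
    def test_default_registry_is_57_types_4349_features(self):
        reg = default_registry()
        schema = FeatureSchema(reg)
        assert len(reg) == 57
        assert len(schema) == 4349
        assert len(schema.names) == 4349
        assert len(set(schema.names)) == 4349

    def test_declared_sizes_match_emitted_lengths(self, rng):
        from conftest import random_sequence

        seq = random_sequence(rng)
        for spec in default_registry():
            assert len(spec.encode(seq)) == spec.size

    def test_printed_family_sizes(self):
        sizes = {s.name: s.size for s in default_registry()}
        assert sizes["DDE"] == 400
        assert sizes["QSO"] == 46
        assert sizes["CTDC"] == 39
        assert sizes["CTDD"] == 195
        assert sizes["MSW"] == 30
        assert sizes["Ez"] == 30
        assert sizes["Cougar"] == 30
        assert sizes["Z5"] == 75

    def test_encode_all_shape_and_order(self, rng):
        reg = [make_encoder("AAC")]
        peps = [Peptide(f"p{i}", "FATPLLDK") for i in range(3)]
        data = LabeledPeptideSet(peps, [1, 0, 1])
        m = encode_all(data, reg)
        assert m.values.shape == (3, 20)
        assert m.row_ids == ["p0", "p1", "p2"]

    def test_registry_permutation_permutes_blocks(self):
        a = make_encoder("AAC")
        g = make_encoder("GAAC")
        v1 = encode_peptide("FATPLLDK", [a, g])
        v2 = encode_peptide("FATPLLDK", [g, a])
        np.testing.assert_allclose(v1, np.concatenate([v2[5:], v2[:5]]))

    def test_encoder_purity(self, random_peptides):
        spec = make_encoder("APAAC", lam=3)
        for seq in random_peptides[:10]:
            np.testing.assert_array_equal(spec.encode(seq), spec.encode(seq))

    def test_compositional_blocks_sum_to_one(self, random_peptides):
        specs = [make_encoder(n) for n in ("AAC", "DPC", "GAAC", "GDPC", "CTriad")]
        specs += [make_encoder("CKSAAP", gap=g) for g in (0, 2, 5)]
        for seq in random_peptides:
            for spec in specs:
                assert spec.encode(seq).sum() == pytest.approx(1.0)

    def test_encode_all_failure_names_peptide_and_encoder(self):
        data = LabeledPeptideSet([Peptide("tiny", "ACDE")], [1])
        with pytest.raises(EncoderError, match="tiny.*CKSAAP_gap5"):
            encode_all(data, [make_encoder("CKSAAP", gap=5)])

    def test_rebuild_registry_round_trip(self):
        reg = default_registry()
        config = [{"name": s.name, "params": s.params} for s in reg]
        rebuilt = rebuild_registry(config)
        assert FeatureSchema(rebuilt).names == FeatureSchema(reg).names
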