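"""Core free-energy model: configuration tiling, encoding, energies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotercalc.energy_model import (
    FEATURE_NAMES,
    NUMERIC_FEATURES,
    CompiledModel,
    EnergyModelParams,
    FeatureVector,
    InsufficientContextError,
    OccupancySystem,
    delta_g_total,
    default_normalizers,
    encode_features,
    occupancy,
    parse_configuration,
    reverse_complement,
    tx_from_energy,
)

from .conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=82, max_size=120)


class TestParseConfiguration:
    def test_tiling_coordinates_hand_checked(self, rng):
        # 82-nt parent, TSS at 62, spacer 17, disc 7: upstream context is
        # 20+6+17+6+7 = 56 nt, so the UP element starts at 62-56 = 6
        seq = random_dna(rng, 82)
        cfg = parse_configuration(seq, 62, spacer_length=17, disc_length=7)
        assert cfg.coords["up_distal"] == (6, 16)
        assert cfg.coords["hex35"] == (26, 32)
        assert cfg.coords["hex10"] == (49, 55)
        assert cfg.coords["disc"] == (55, 62)
        assert cfg.coords["itr"] == (62, 82)
        assert cfg.hex35 == seq[26:32]
        assert cfg.itr == seq[62:82]

    @pytest.mark.parametrize("spacer,disc", [(14, 6), (21, 6), (17, 4), (17, 11)])
    def test_out_of_range_geometry_rejected(self, rng, spacer, disc):
        seq = random_dna(rng, 100)
        with pytest.raises(ValueError):
            parse_configuration(seq, 70, spacer_length=spacer, disc_length=disc)

    def test_linear_edge_raises(self, rng):
        seq = random_dna(rng, 82)
        with pytest.raises(InsufficientContextError):
            parse_configuration(seq, 30, spacer_length=17, disc_length=7)

    def test_circular_wraps_upstream_context(self, rng):
        seq = random_dna(rng, 82)
        cfg = parse_configuration(seq, 5, spacer_length=17, disc_length=7, circular=True)
        doubled = seq + seq
        assert cfg.itr == doubled[5:25]
        # upstream wraps around the origin
        assert cfg.disc == doubled[82 + 5 - 7 : 82 + 5]

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            parse_configuration("ACGTN" * 20, 70)

    def test_reverse_strand_is_forward_on_revcomp(self, rng):
        seq = random_dna(rng, 120)
        rc = reverse_complement(seq)
        fwd = parse_configuration(rc, 119 - 40, spacer_length=16, disc_length=8)
        rev = parse_configuration(seq, 40, strand="reverse", spacer_length=16, disc_length=8)
        assert rev.hex10 == fwd.hex10
        assert rev.itr == fwd.itr
        assert rev.sequence_window == fwd.sequence_window

    @settings(max_examples=30, derandomize=True)
    @given(seq=dna, spacer=st.integers(15, 20), disc=st.integers(5, 10))
    def test_tiles_are_contiguous_and_end_at_tss(self, seq, spacer, disc):
        tss = 32 + spacer + disc
        if len(seq) < tss + 20:
            return
        cfg = parse_configuration(seq, tss, spacer_length=spacer, disc_length=disc)
        upstream = cfg.up_distal + cfg.up_proximal + cfg.hex35 + cfg.spacer + cfg.hex10 + cfg.disc
        assert upstream == seq[:tss]
        assert cfg.ext10 == cfg.spacer[-4:]
        assert len(upstream) == 32 + spacer + disc


class TestEncodeFeatures:
    def test_consensus_bits_and_cardinality(self, tables, rng):
        up = random_dna(rng, 20)
        spacer = random_dna(rng, 15) + "TG"  # 17-nt spacer ending in TG
        seq = up + "TTGACA" + spacer + "TATAAT" + random_dna(rng, 6) + random_dna(rng, 20)
        cfg = parse_configuration(seq, 55, spacer_length=17, disc_length=6)
        fv = encode_features(cfg, tables, default_normalizers(tables))
        assert len(fv) == 346
        active = fv.active()
        categorical = [n for n in active if n not in NUMERIC_FEATURES]
        assert len(categorical) == 7
        for expected in ("hex35_1_TTG", "hex35_2_ACA", "hex10_1_TAT", "hex10_2_AAT",
                         "ext10_TG", "spacer_len_17"):
            assert fv[expected] == 1.0

    def test_numeric_features_normalized_to_unit_interval(self, tables, rng):
        norm = default_normalizers(tables)
        for _ in range(20):
            seq = random_dna(rng, 100)
            cfg = parse_configuration(seq, 70, spacer_length=18, disc_length=8)
            fv = encode_features(cfg, tables, norm)
            # MGW and rigidity are positive quantities bounded by their maxima
            assert 0.0 < fv["up_distal_mgw"] <= 1.0
            assert 0.0 < fv["up_proximal_mgw"] <= 1.0
            assert 0.0 < fv["spacer_rigidity"] <= 1.0
            assert abs(fv["itr_rloop"]) <= 1.0  # R-loop stability can be negative

    def test_feature_space_blocks(self):
        by_prefix = {
            "hex35_": 128, "hex10_": 128, "disc_": 64, "ext10_": 16, "spacer_len_": 6,
        }
        for prefix, size in by_prefix.items():
            assert sum(n.startswith(prefix) for n in FEATURE_NAMES) == size
        assert len(FEATURE_NAMES) == 346


class TestDeltaG:
    def test_zero_coefficients_zero_energy(self, zero_params, tables, rng):
        cfg = parse_configuration(random_dna(rng, 100), 70)
        fv = encode_features(cfg, tables, zero_params.normalizers)
        bd = delta_g_total(fv, zero_params)
        assert bd.dg_total == 0.0
        assert all(v == 0.0 for v in bd.terms().values())

    def test_single_coefficient_isolated_to_its_term(self, zero_params, tables, rng):
        params = zero_params.replace_coefficients({"spacer_len_17": -1.0})
        cfg = parse_configuration(random_dna(rng, 100), 70, spacer_length=17)
        fv = encode_features(cfg, tables, params.normalizers)
        bd = delta_g_total(fv, params)
        assert bd.dg_spacer == -1.0
        assert bd.dg_total == -1.0

    def test_matches_dot_product_oracle(self, truth_params, tables, rng):
        w = truth_params.weights
        for _ in range(50):
            cfg = parse_configuration(
                random_dna(rng, 120), 80,
                spacer_length=int(rng.integers(15, 21)),
                disc_length=int(rng.integers(5, 11)),
            )
            fv = encode_features(cfg, tables, truth_params.normalizers)
            bd = delta_g_total(fv, truth_params)
            assert bd.dg_total == pytest.approx(float(w @ fv.values), abs=1e-9)
            assert bd.dg_total == pytest.approx(sum(bd.terms().values()), abs=1e-9)

    def test_compiled_path_equals_encode_path(self, truth_params, tables, rng):
        compiled = CompiledModel(truth_params, tables)
        for _ in range(30):
            cfg = parse_configuration(
                random_dna(rng, 120), 80,
                spacer_length=int(rng.integers(15, 21)),
                disc_length=int(rng.integers(5, 11)),
            )
            fv = encode_features(cfg, tables, truth_params.normalizers)
            slow = delta_g_total(fv, truth_params)
            fast = compiled.breakdown(cfg)
            assert fast.dg_total == pytest.approx(slow.dg_total, abs=1e-12)
            assert fast.terms() == pytest.approx(slow.terms(), abs=1e-12)


class TestTxFromEnergy:
    def test_reference_identity_and_doubling(self, zero_params):
        p = zero_params
        assert tx_from_energy(p.dg_total_ref, p) == p.tx_ref
        assert tx_from_energy(-math.log(2.0), p) == pytest.approx(2.0 * p.tx_ref)

    def test_strictly_decreasing(self, zero_params, rng):
        dgs = rng.normal(0, 3, size=(1000, 2))
        for a, b in dgs:
            lo, hi = min(a, b), max(a, b)
            if lo == hi:
                continue
            assert tx_from_energy(lo, zero_params) > tx_from_energy(hi, zero_params)

    def test_composed_with_delta_g_matches_closed_form(self, truth_params, tables, rng):
        # independent oracle: exp(-beta*(w.x - dg_ref)) * tx_ref
        w = truth_params.weights
        for _ in range(100):
            cfg = parse_configuration(random_dna(rng, 100), 70)
            fv = encode_features(cfg, tables, truth_params.normalizers)
            dg = delta_g_total(fv, truth_params).dg_total
            expected = truth_params.tx_ref * math.exp(
                -truth_params.beta * (float(w @ fv.values) - truth_params.dg_total_ref)
            )
            assert tx_from_energy(dg, truth_params) == pytest.approx(expected, rel=1e-12)


class TestOccupancy:
    def test_single_site_closed_form(self):
        bound, free = occupancy(OccupancySystem(sites=((1.0, 0.0),), r_total=1.0))
        assert bound[0] == pytest.approx(0.5)
        assert free == pytest.approx(0.5)

    def test_two_identical_sites_split_evenly(self):
        bound, free = occupancy(OccupancySystem(sites=((1.0, 0.0), (1.0, 0.0)), r_total=3.0))
        assert bound == pytest.approx([1.0, 1.0])
        assert free == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        sites=st.lists(
            st.tuples(st.floats(0.1, 50), st.floats(-5, 5)), min_size=1, max_size=8
        ),
        r_total=st.floats(0, 100),
    )
    def test_conserves_total_holoenzyme(self, sites, r_total):
        bound, free = occupancy(OccupancySystem(sites=tuple(sites), r_total=r_total))
        total = sum(bound) + free
        assert total == pytest.approx(r_total, rel=1e-12, abs=1e-12)
        assert all(0 <= c <= r_total + 1e-12 for c in bound)

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValueError):
            OccupancySystem(sites=((-1.0, 0.0),), r_total=1.0)


class TestParamsSerialization:
    def test_json_round_trip(self, truth_params, tmp_path):
        path = tmp_path / "params.json"
        truth_params.to_json(path)
        loaded = EnergyModelParams.from_json(path)
        assert loaded.coefficients == truth_params.coefficients
        assert loaded.normalizers == truth_params.normalizers
        assert loaded.tables_checksum == truth_params.tables_checksum

    def test_csv_export_covers_all_features(self, truth_params, tmp_path):
        path = tmp_path / "energies.csv"
        truth_params.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 347  # header + 346 energies

    def test_incomplete_coefficients_rejected(self, tables):
        with pytest.raises(ValueError):
            EnergyModelParams(
                coefficients={"hex35_1_AAA": 0.0},
                normalizers=default_normalizers(tables),
            )

    def test_feature_vector_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(np.zeros(10))
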