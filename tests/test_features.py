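"""Feature schema composition, positional read-off, negative controls,
and model-variant schemas."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from readthru.catalog import MrnaRecord
from readthru.features import (
    NA_LEVEL,
    attach_negative_controls,
    default_schema,
    derive_variant_schema,
    encode_feature_matrix,
    extract_feature_table,
    extract_features,
)
from readthru.simulate import SimConfig, simulate_catalog


def record_from_parts(utr5, cds, stop, tail, tid="T1"):
    return MrnaRecord(tid, utr5 + cds + stop + tail, len(utr5), len(cds), 3 + len(tail))


class TestSchemaComposition:
    def test_full_schema_accounting(self, full_schema):
        # 21 context + 10 tunnel + 44 other = 75, plus 2 negative controls
        assert len(full_schema.feature_names) == 77
        assert len(full_schema.biological_features) == 75
        assert full_schema.count("context") == 21
        assert full_schema.count("tunnel") == 10
        assert full_schema.count("other") == 44
        assert full_schema.count("negative_control") == 2

    def test_duplicate_feature_names_rejected(self):
        from readthru.features import FeatureSchema

        with pytest.raises(ValueError, match="duplicate"):
            FeatureSchema("x", ("a", "a"), {"a": "context"})


class TestExtraction:
    def test_positional_read_off(self, full_schema):
        rec = record_from_parts("", "AUGAAG", "UGA", "CUAGAAAAAAAA")
        vec = extract_features(rec, full_schema)
        assert vec.values["psite_codon"] == "AAG"
        assert vec.values["psite_aa"] == "K"
        assert vec.values["nt_p4"] == "C"
        assert vec.values["nt_m1"] == "G"
        assert vec.values["nt_m2"] == "A"
        assert vec.values["nt_m3"] == "A"
        assert vec.values["esite_codon"] == "AUG"
        assert vec.values["esite_aa"] == "M"
        assert vec.values["utr3_len"] == 15

    def test_window_reconstruction_roundtrip(self, small_sim, full_schema):
        # features -9..+12 reassemble the original window around the stop
        for rec in small_sim["records"][:100]:
            vec = extract_features(rec, full_schema)
            window = (
                "".join(vec.values[f"nt_m{k}"] for k in range(9, 0, -1))
                + vec.values["stop_codon"]
                + "".join(vec.values[f"nt_p{m}"] for m in range(4, 13))
            )
            s = rec.stop_offset
            assert window == rec.sequence[s - 9:s + 12]

    def test_short_regions_yield_explicit_missing_level(self, full_schema):
        rec = record_from_parts("AC", "AUGAAG", "UGA", "C")
        vec = extract_features(rec, full_schema)
        assert vec.values["nt_m7"] == NA_LEVEL  # would precede the start codon
        assert vec.values["nt_p5"] == NA_LEVEL  # past the transcript end
        assert vec.values["nt_p4"] == "C"
        assert vec.values["esite_codon"] == "AUG"
        assert vec.valid

    def test_n_in_window_invalidates_record(self, full_schema):
        rec = record_from_parts("", "AUGAAG", "UGA", "NUAGAAAA")
        vec = extract_features(rec, full_schema)
        assert not vec.valid
        table, excluded = extract_feature_table([rec], full_schema)
        assert excluded == ["T1"]
        assert table.empty

    def test_tunnel_aggregates_from_known_peptide(self, full_schema):
        # MKKDE -> 2 positive (K,K), 2 negative (D,E), C-terminal E negative
        rec = record_from_parts("", "AUGAAAAAGGAUGAA", "UAA", "A" * 30)
        vec = extract_features(rec, full_schema)
        assert vec.values["tunnel_frac_positive"] == pytest.approx(2 / 5)
        assert vec.values["tunnel_frac_negative"] == pytest.approx(2 / 5)
        assert vec.values["tunnel_net_charge"] == 0
        assert vec.values["tunnel_cterm_charge"] == "negative"

    def test_assay_features_depend_only_on_context_window(self, full_schema):
        assay = derive_variant_schema("assay")
        utr5, cds, stop = "ACGUAC", "AUG" + "GCU" * 20, "UGA"
        tail = "C" + "A" * 50
        rec1 = record_from_parts(utr5, cds, stop, tail)
        # mutate far upstream (5'-UTR) and far downstream (nt +20 onwards)
        rec2 = record_from_parts("GGGGGG", cds, stop, tail[:16] + "G" * 34)
        v1 = extract_features(rec1, assay)
        v2 = extract_features(rec2, assay)
        assert v1.values == v2.values


class TestNegativeControls:
    def test_reproducible_given_seed(self, small_sim):
        t1 = attach_negative_controls(small_sim["features"].drop(
            columns=["nc_number", "nc_letter"]), seed=9)
        t2 = attach_negative_controls(small_sim["features"].drop(
            columns=["nc_number", "nc_letter"]), seed=9)
        assert (t1["nc_number"] == t2["nc_number"]).all()
        assert (t1["nc_letter"] == t2["nc_letter"]).all()

    def test_letter_frequencies_are_uniform(self):
        df = pd.DataFrame({"transcript_id": [f"T{i}" for i in range(10_000)]})
        out = attach_negative_controls(df, seed=3)
        freqs = out["nc_letter"].value_counts(normalize=True)
        assert set(freqs.index) == {"A", "C", "G", "U"}
        assert ((freqs - 0.25).abs() < 0.02).all()
        assert out["nc_number"].between(1, 100).all()

    def test_independent_of_readthrough_efficiency(self):
        hits = 0
        for seed in range(20):
            config = SimConfig(n_transcripts=5000, seed=seed)
            _, truth = simulate_catalog(config)
            nc = attach_negative_controls(truth[["transcript_id"]], seed=seed + 1000)
            rho, _ = spearmanr(nc["nc_number"], truth["true_log2_re"])
            if abs(rho) < 0.05:
                hits += 1
        assert hits >= 19


class TestVariantSchemas:
    @staticmethod
    @pytest.fixture(scope="class")
    def importance(full_schema):
        # a plausible importance table: planted features high, rest low
        rng = np.random.default_rng(0)
        rows = []
        high = {"stop_codon", "nt_p4", "utr3_len", "psite_aa", "nt_m16"}
        for f in full_schema.feature_names:
            if f in ("nc_number", "nc_letter"):
                score = 1.0
            elif f in high:
                score = 20.0 + rng.random()
            else:
                score = rng.normal(0, 0.5)
            rows.append({"feature": f, "importance": score})
        return pd.DataFrame(rows)

    def test_reduced_has_no_tunnel_features(self, importance, full_schema):
        reduced = derive_variant_schema("reduced", importance)
        assert all(full_schema.groups[f] != "tunnel" for f in reduced.feature_names)
        # context features and important non-tunnel features are present
        assert "stop_codon" in reduced.feature_names
        assert "utr3_len" in reduced.feature_names
        assert "nt_m16" in reduced.feature_names

    def test_mock_matches_reduced_size(self, importance):
        reduced = derive_variant_schema("reduced", importance)
        for k in (1, 2, 3):
            mock = derive_variant_schema(f"mock{k}", importance, seed=5)
            assert len(mock.biological_features) == len(reduced.biological_features)

    def test_assay_nests_in_reduced_nests_in_full(self, importance, full_schema):
        reduced = set(derive_variant_schema("reduced", importance).feature_names)
        assay = set(derive_variant_schema("assay", importance).feature_names)
        assert assay < reduced < set(full_schema.feature_names)
        assert "utr3_len" not in assay

    def test_mock_requires_importance_table(self):
        with pytest.raises(ValueError, match="importance"):
            derive_variant_schema("mock1")

    def test_mock_fails_when_too_few_low_importance_features(self, full_schema):
        rows = [{"feature": f, "importance": 50.0}
                for f in full_schema.feature_names]
        for f in ("nc_number", "nc_letter"):
            rows.append({"feature": f, "importance": 1.0})
        imp = pd.DataFrame(rows).drop_duplicates("feature", keep="last")
        with pytest.raises(ValueError, match="low-importance"):
            derive_variant_schema("mock1", imp)


class TestEncoding:
    def test_unseen_level_maps_to_na_bucket_with_warning(self, small_sim, full_schema):
        table = small_sim["features"].copy()
        table.loc[table.index[0], "nt_p4"] = "X"
        matrix, warnings = encode_feature_matrix(table, full_schema)
        assert any("nt_p4" in w for w in warnings)
        j = full_schema.feature_names.index("nt_p4")
        assert matrix[0, j] == 4.0  # NA bucket of the nucleotide registry

    def test_extraction_is_pure(self, small_sim, full_schema):
        rec = small_sim["records"][0]
        v1 = extract_features(rec, full_schema)
        v2 = extract_features(rec, full_schema)
        assert v1.values == v2.values
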