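"""Series classification, orientation, b-value decoding, caching, stats."""

import json

import numpy as np
import pytest

from mammocdm.dicom import (
    GE_BVALUE_OFFSET,
    Orientation,
    SeriesMetadata,
    Technique,
    classify_series,
    fetch_collection_series,
    normalize_tag_key,
    orientation_from_cosines,
    parse_diffusion_bvalue,
    technique_statistics,
)
from mammocdm.fixtures import SeriesComposition, generate_series_metadata


def series(tags, uid="1.2.3", collection="C"):
    return SeriesMetadata(series_uid=uid, collection=collection, tags=tags)


class TestTagNormalization:
    @pytest.mark.parametrize(
        "raw", ["(0020,0105)", "0020,0105", ("0020", "0105"), "00200105", "(0020, 0105)"]
    )
    def test_spelling_dialects(self, raw):
        assert normalize_tag_key(raw) == ("0020", "0105")

    def test_rejects_garbage(self):
        with pytest.raises(ValueError):
            normalize_tag_key("hello")


class TestOrientation:
    @pytest.mark.parametrize(
        "iop,expected",
        [
            ("1\\0\\0\\0\\1\\0", Orientation.AXIAL),
            ("1\\0\\0\\0\\0\\-1", Orientation.CORONAL),
            ("0\\1\\0\\0\\0\\-1", Orientation.SAGITTAL),
            ("0.7071\\0.7071\\0\\0\\0\\-1", Orientation.OBLIQUE),
            (None, Orientation.UNKNOWN),
            ("not numbers at all", Orientation.UNKNOWN),
        ],
    )
    def test_cardinal_and_degenerate_cases(self, iop, expected):
        assert orientation_from_cosines(iop) is expected

    def test_agrees_with_cross_product_oracle_on_random_frames(self):
        rng = np.random.default_rng(42)
        axes = {0: Orientation.SAGITTAL, 1: Orientation.CORONAL, 2: Orientation.AXIAL}
        for _ in range(1000):
            # random orthonormal frame via QR decomposition
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            row, col = q[:, 0], q[:, 1]
            normal = np.cross(row, col)
            k = int(np.argmax(np.abs(normal)))
            expected = axes[k] if abs(normal[k]) >= 0.8 else Orientation.OBLIQUE
            iop = "\\".join(f"{v:.9f}" for v in [*row, *col])
            assert orientation_from_cosines(iop) is expected


class TestDiffusionBValue:
    def test_standard_tag_passthrough(self):
        assert parse_diffusion_bvalue({("0018", "9087"): "1000"}) == 1000

    def test_ge_private_tag_offset(self):
        tags = {("0043", "1039"): [GE_BVALUE_OFFSET + 600, 8, 0, 0]}
        b = parse_diffusion_bvalue(tags)
        assert b == 600
        assert 0 <= b <= 5000  # plausible diffusion-weighting range

    def test_ge_tag_without_offset_kept_as_is(self):
        assert parse_diffusion_bvalue({("0043", "1039"): [800, 8, 0, 0]}) == 800

    def test_standard_tag_preferred_over_private(self):
        tags = {
            ("0018", "9087"): "50",
            ("0043", "1039"): [GE_BVALUE_OFFSET + 600, 8, 0, 0],
        }
        assert parse_diffusion_bvalue(tags) == 50

    def test_absent(self):
        assert parse_diffusion_bvalue({}) is None
        assert parse_diffusion_bvalue({("0043", "1039"): "junk"}) is None


class TestClassification:
    def test_temporal_positions_mean_dce(self):
        label = classify_series(series({"(0020,0105)": "60", "(0018,0020)": "GR"}))
        assert label.technique is Technique.DCE
        assert label.evidence

    def test_dce_fallback_without_temporal_positions(self):
        label = classify_series(series({
            "(0018,0020)": "GR", "(0018,0023)": "3D", "(0018,1314)": "10",
        }))
        assert label.technique is Technique.DCE

    def test_echo_planar_with_bvalue_is_dwi(self):
        label = classify_series(series({"(0018,0020)": "EP", "(0018,9087)": "800"}))
        assert label.technique is Technique.DWI
        assert label.b_values == (800.0,)

    def test_epi_without_diffusion_evidence_is_not_dwi(self):
        label = classify_series(series({"(0018,0020)": "EP"}))
        assert label.technique is not Technique.DWI

    def test_spin_echo_description_keywords(self):
        assert classify_series(
            series({"(0018,0020)": "SE", "(0008,103E)": "ax t2 fs"})
        ).technique is Technique.T2W
        assert classify_series(
            series({"(0018,0020)": "SE", "(0008,103E)": "sag t1"})
        ).technique is Technique.T1W

    def test_empty_tag_map_is_unknown_with_no_evidence(self):
        label = classify_series(series({}))
        assert label.technique is Technique.UNKNOWN
        assert label.orientation is Orientation.UNKNOWN
        assert label.evidence == ()

    def test_unmatched_tags_are_other(self):
        label = classify_series(series({"(0018,0020)": "GR", "(0018,1314)": "70"}))
        assert label.technique is Technique.OTHER

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip_with_generator_including_anonymized(self, seed):
        comp = SeriesComposition(
            counts={"DWI": 2, "DCE": 2, "T1W": 1, "T2W": 1, "OTHER": 1, "UNKNOWN": 1},
            anonymized_fraction=0.5,
            seed=seed,
        )
        for gs in generate_series_metadata(comp):
            label = classify_series(gs.meta)
            assert label.technique is gs.technique
            assert label.orientation is gs.orientation

    @pytest.mark.parametrize("seed", range(20))
    def test_inert_extra_tag_never_changes_label(self, seed):
        comp = SeriesComposition(
            counts={"DWI": 2, "DCE": 2, "T1W": 1, "T2W": 1, "OTHER": 1}, seed=seed
        )
        for gs in generate_series_metadata(comp):
            before = classify_series(gs.meta)
            noisy = SeriesMetadata(
                series_uid=gs.meta.series_uid,
                collection=gs.meta.collection,
                tags={**gs.meta.tags, ("0008", "0070"): "SYNTH MEDICAL"},
            )
            after = classify_series(noisy)
            assert (after.technique, after.orientation) == (
                before.technique, before.orientation,
            )


class TestStatistics:
    def test_composition_recovered(self):
        comp = SeriesComposition(counts={"DWI": 5, "DCE": 7, "T1W": 3}, seed=11)
        metas = [gs.meta for gs in generate_series_metadata(comp)]
        stats = technique_statistics(metas)
        assert stats.counts["DWI"] == 5
        assert stats.counts["DCE"] == 7
        assert stats.counts["T1W"] == 3
        assert stats.total == 15
        assert sum(stats.counts.values()) == stats.total

    def test_empty_and_unknown(self):
        assert technique_statistics([]).total == 0
        blanks = [series({}, uid=f"1.{i}") for i in range(10)]
        assert technique_statistics(blanks).counts["UNKNOWN"] == 10

    def test_mixed_collections_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            technique_statistics(
                [series({}, uid="1.1", collection="A"),
                 series({}, uid="1.2", collection="B")]
            )


class _CountingClient:
    """Serves a fixed listing; counts every request."""

    def __init__(self, n=7):
        self.listing = [
            {"SeriesInstanceUID": f"1.2.3.{i}", "PatientID": f"P{i}"} for i in range(n)
        ]
        self.list_calls = 0
        self.tag_calls = 0

    def list_series(self, collection):
        self.list_calls += 1
        return list(self.listing)

    def get_series_tags(self, series_uid):
        self.tag_calls += 1
        i = int(series_uid.rsplit(".", 1)[1])
        return [
            {"element": "(0018,0020)", "data": "GR"},
            {"element": "(0020,0105)", "data": str(10 + i)},
        ]


class TestFetchAndCache:
    def test_cold_fetch_populates_cache(self, tmp_path):
        client = _CountingClient()
        out = fetch_collection_series("COLL", client, tmp_path)
        assert len(out) == 7
        assert client.tag_calls == 7
        assert len(list((tmp_path / "COLL").glob("1.2.3.*.json"))) == 7

    def test_warm_cache_identical_and_zero_calls(self, tmp_path):
        client = _CountingClient()
        cold = fetch_collection_series("COLL", client, tmp_path)
        warm = fetch_collection_series("COLL", client, tmp_path)
        assert client.list_calls == 1 and client.tag_calls == 7
        assert [(s.series_uid, s.subject_id, s.tags) for s in warm] == [
            (s.series_uid, s.subject_id, s.tags) for s in cold
        ]

    def test_empty_listing_ok(self, tmp_path):
        client = _CountingClient(n=0)
        assert fetch_collection_series("EMPTY", client, tmp_path) == []

    def test_cold_cache_without_client_fails(self, tmp_path):
        with pytest.raises(ConnectionError):
            fetch_collection_series("COLL", None, tmp_path)

    def test_malformed_tag_response_names_series(self, tmp_path):
        class Bad(_CountingClient):
            def get_series_tags(self, series_uid):
                return [{"no-element-key": 1}]

        with pytest.raises(ValueError, match="1.2.3.0"):
            fetch_collection_series("COLL", Bad(n=1), tmp_path)
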