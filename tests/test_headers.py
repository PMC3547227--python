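"""Header parsing, metadata auditing and pixel-codec round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflqc.headers import (
    Dialect,
    HeaderParseError,
    OverflowScheme,
    ScanAxis,
    SpindleSense,
    audit_metadata,
    decode_pixels,
    encode_pixels,
    parse_bruker_header,
    parse_raxis_header,
)


class TestRaxisParsing:
    def test_spindle_scan_fields(self, raxis_header_text):
        md = parse_raxis_header(raxis_header_text)
        assert md.dialect is Dialect.raxis
        assert md.scan_axis is ScanAxis.phi
        assert md.rotation_per_frame == 1.0  # a3fPhi 0.0 0.0 1.0
        assert md.start_angles["phi"] == 0.0

    def test_goniometer_circle_angles(self, raxis_header_text):
        # a3fCircle 0.0 0.0 0.0 carries omega, chi and swing theta in order
        md = parse_raxis_header(raxis_header_text)
        assert md.start_angles["omega"] == 0.0
        assert md.start_angles["chi"] == 0.0
        assert md.start_angles["theta"] == 0.0

    def test_detector_geometry(self, raxis_header_text):
        md = parse_raxis_header(raxis_header_text)
        assert (md.n_fast, md.n_slow) == (3000, 3000)
        assert md.pixel_size == 100.0
        assert md.overflow_scheme is OverflowScheme.raxis_scaled

    def test_gain_defaults_when_absent(self, raxis_header_text):
        md = parse_raxis_header(raxis_header_text)
        assert md.gain == 1.0
        assert "gain" in md.missing_fields

    def test_empty_spindle_field_is_unknown_sense(self, raxis_header_text):
        md = parse_raxis_header(raxis_header_text)
        assert md.spindle_sense is SpindleSense.unknown
        assert "spindle orientation" in md.missing_fields

    def test_malformed_numeric_names_the_key(self, raxis_header_text):
        bad = raxis_header_text.replace("a3fPhi 0.0 0.0 1.0", "a3fPhi 0.0 xx 1.0")
        with pytest.raises(HeaderParseError, match="a3fPhi"):
            parse_raxis_header(bad)

    def test_missing_geometry_is_hard_error(self, raxis_header_text):
        bad = "\n".join(
            line for line in raxis_header_text.splitlines() if not line.startswith("nPixels")
        )
        with pytest.raises(HeaderParseError, match="nPixels"):
            parse_raxis_header(bad)


class TestBrukerParsing:
    def test_euler_angles_in_order(self, bruker_header_text):
        # ANGLES: 0.0 358.75 0.0 0.0 -> (2theta, omega, phi, chi)
        md = parse_bruker_header(bruker_header_text)
        assert md.start_angles == {
            "two_theta": 0.0, "omega": 358.75, "phi": 0.0, "chi": 0.0,
        }

    def test_axis_3_selects_phi(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        assert md.scan_axis is ScanAxis.phi

    def test_gain_from_ccdparm_first_field(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        assert md.gain == 3.83

    def test_detector_geometry_and_baseline(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        assert (md.n_fast, md.n_slow) == (1024, 1024)
        assert md.pixel_size == 89.99
        assert md.beam_center == (512.0, 512.0)
        assert md.baseline_offset == 32
        assert md.overflow_scheme is OverflowScheme.bruker_table

    def test_correction_provenance(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        assert md.correction_refs["flood_field"] == "0138_1024_180s._fl"
        assert md.correction_refs["distortion"] == "0138_1024_180s._ix"
        assert md.correction_refs["dark"] == "0138_01024_00010._dk"

    def test_missing_npixelb_is_hard_error(self, bruker_header_text):
        bad = "\n".join(
            line for line in bruker_header_text.splitlines() if "NPIXELB" not in line
        )
        with pytest.raises(HeaderParseError, match="NPIXELB"):
            parse_bruker_header(bad)

    def test_axis_outside_documented_set(self, bruker_header_text):
        bad = bruker_header_text.replace("AXIS: 3", "AXIS: 7")
        with pytest.raises(HeaderParseError, match="AXIS"):
            parse_bruker_header(bad)


class TestAudit:
    def test_fully_specified_header_is_clean(self, bruker_header_text):
        complete = bruker_header_text + "\nSENSE: ccw\n"
        md = parse_bruker_header(complete)
        assert audit_metadata(md) == []

    def test_raxis_flags_rotation_sense_and_axis_convention(self, raxis_header_text):
        findings = {f.field for f in audit_metadata(parse_raxis_header(raxis_header_text))}
        assert "spindle orientation" in findings
        assert "fast/slow convention" in findings
        assert "gain" in findings

    def test_bruker_missing_flood_field_reference(self, bruker_header_text):
        stripped = "\n".join(
            line for line in bruker_header_text.splitlines() if "CORRECT" not in line
        )
        findings = {f.field for f in audit_metadata(parse_bruker_header(stripped))}
        assert "flood_field reference" in findings

    @pytest.mark.parametrize("key", ["fGain", "CCDPARM", "MACH3", "DARK", "WARFIL"])
    def test_removing_a_field_never_shrinks_findings(
        self, raxis_header_text, bruker_header_text, key
    ):
        if key == "fGain":
            base_text, parser = raxis_header_text + "\nfGain 2.0\n", parse_raxis_header
        else:
            base_text, parser = bruker_header_text, parse_bruker_header
        base = {f.field for f in audit_metadata(parser(base_text))}
        stripped = "\n".join(l for l in base_text.splitlines() if not l.startswith(key))
        reduced = {f.field for f in audit_metadata(parser(stripped))}
        assert base <= reduced


class TestPixelCodecs:
    def test_bruker_identity_below_sentinel(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        x = np.arange(md.n_fast * md.n_slow) % 200 - md.baseline_offset
        enc = encode_pixels(x, md)
        assert enc.overflow_table == []
        np.testing.assert_array_equal(decode_pixels(enc.raw, md, enc.overflow_table), x)

    def test_bruker_sentinel_uses_overflow_table(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        x = np.zeros(md.n_fast * md.n_slow, dtype=np.int64)
        x[12345] = 70000 - md.baseline_offset
        enc = encode_pixels(x, md)
        assert enc.overflow_table == [70000]
        decoded = decode_pixels(enc.raw, md, enc.overflow_table)
        assert decoded[12345] == 70000 - md.baseline_offset

    def test_bruker_too_few_table_entries_errors(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        raw = bytes([255] * (md.n_fast * md.n_slow))
        with pytest.raises(ValueError, match="overflow"):
            decode_pixels(raw, md, [70000])

    def test_raxis_overflow_rule(self, raxis_header_text):
        # stored 32768 -> 0; stored 32769 -> R = 8
        md = parse_raxis_header(raxis_header_text)
        small_md = type(md)(**{**md.__dict__, "n_fast": 2, "n_slow": 1})
        raw = np.array([32768, 32769], dtype="<u2").tobytes()
        np.testing.assert_array_equal(decode_pixels(raw, small_md), [0, 8])

    def test_raxis_odd_byte_count_errors(self, raxis_header_text):
        md = parse_raxis_header(raxis_header_text)
        with pytest.raises(ValueError, match="odd"):
            decode_pixels(b"\x00" * 3, md)

    def test_raxis_off_grid_value_is_lossy(self, raxis_header_text):
        md = parse_raxis_header(raxis_header_text)
        small_md = type(md)(**{**md.__dict__, "n_fast": 1, "n_slow": 1})
        enc = encode_pixels(np.array([32771]), small_md)  # not on the x8 grid
        assert enc.lossy
        decoded = decode_pixels(enc.raw, small_md)
        assert abs(int(decoded[0]) - 32771) <= 4  # nearest grid point

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=64))
    def test_bruker_round_trip_random(self, bruker_header_text, values):
        md = parse_bruker_header(bruker_header_text)
        small_md = type(md)(**{**md.__dict__, "n_fast": len(values), "n_slow": 1})
        x = np.asarray(values)
        enc = encode_pixels(x, small_md)
        np.testing.assert_array_equal(decode_pixels(enc.raw, small_md, enc.overflow_table), x)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=61439), min_size=1, max_size=64),
    )
    def test_raxis_round_trip_on_grid(self, raxis_header_text, values):
        # direct values < 32768 and overflow values on the x8 grid are exact
        md = parse_raxis_header(raxis_header_text)
        small_md = type(md)(**{**md.__dict__, "n_fast": len(values), "n_slow": 1})
        x = np.asarray(values)
        on_grid = np.where(x < 32768, x, 32768 + (x - 32768) * 8)
        enc = encode_pixels(on_grid, small_md)
        assert not enc.lossy
        np.testing.assert_array_equal(decode_pixels(enc.raw, small_md), on_grid)

    def test_all_zero_buffer(self, bruker_header_text):
        md = parse_bruker_header(bruker_header_text)
        small_md = type(md)(**{**md.__dict__, "n_fast": 8, "n_slow": 1, "baseline_offset": 0})
        enc = encode_pixels(np.zeros(8), small_md)
        assert enc.raw == b"\x00" * 8 and enc.overflow_table == []

    def test_out_of_range_errors(self, raxis_header_text):
        md = parse_raxis_header(raxis_header_text)
        small_md = type(md)(**{**md.__dict__, "n_fast": 1, "n_slow": 1})
        with pytest.raises(ValueError, match="range"):
            encode_pixels(np.array([10**9]), small_md)
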