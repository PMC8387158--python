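"""Playframe format: reading, writing, validation, generation, duration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stimbox.errors import (
    ISIValueError,
    MissingColumnError,
    StimulusNameError,
    TriggerValueError,
)
from stimbox.playframe import (
    PlayEntry,
    Playframe,
    generate_playframe,
    read_playframe,
    total_duration_ms,
    validate_playframe,
    write_playframe,
)

entry_strategy = st.builds(
    PlayEntry,
    stimulus_name=st.text(
        alphabet=st.characters(whitelist_categories=("L", "N")), min_size=1, max_size=12
    ).map(lambda s: s + ".wav"),
    trigger_value=st.integers(0, 255),
    isi_ms=st.floats(0, 10_000, allow_nan=False),
)


class TestPlayEntry:
    @pytest.mark.parametrize(
        "kwargs, exc",
        [
            (dict(stimulus_name="", trigger_value=1, isi_ms=0), StimulusNameError),
            (dict(stimulus_name="a.wav", trigger_value=256, isi_ms=0), TriggerValueError),
            (dict(stimulus_name="a.wav", trigger_value=-1, isi_ms=0), TriggerValueError),
            (dict(stimulus_name="a.wav", trigger_value=2.5, isi_ms=0), TriggerValueError),
            (dict(stimulus_name="a.wav", trigger_value=1, isi_ms=-1), ISIValueError),
            (dict(stimulus_name="a.wav", trigger_value=1, isi_ms=float("inf")), ISIValueError),
        ],
    )
    def test_invariants_enforced(self, kwargs, exc):
        with pytest.raises(exc):
            PlayEntry(**kwargs)

    def test_trigger_boundaries_legal(self):
        assert PlayEntry("a.wav", 0, 0.0).trigger_value == 0
        assert PlayEntry("a.wav", 255, 0.0).trigger_value == 255


class TestReadWrite:
    def test_read_preserves_order_and_values(self, tmp_path):
        p = tmp_path / "playframe.csv"
        p.write_text("stim,trigger,isi\nbeep.wav,255,500\nword1.wav,12,1000\n")
        pf = read_playframe(p)
        assert [e.stimulus_name for e in pf] == ["beep.wav", "word1.wav"]
        assert [e.trigger_value for e in pf] == [255, 12]
        assert [e.isi_ms for e in pf] == [500.0, 1000.0]

    def test_header_only_gives_empty_playframe(self, tmp_path):
        p = tmp_path / "playframe.csv"
        p.write_text("stim,trigger,isi\n")
        assert len(read_playframe(p)) == 0

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_playframe(tmp_path / "playframe.csv")

    def test_case_insensitive_headers_and_column_map(self, tmp_path):
        p = tmp_path / "playframe.csv"
        p.write_text("Stim,TRIGGER,Isi\na.wav,1,0\n")
        assert len(read_playframe(p)) == 1
        q = tmp_path / "playframe2.csv"
        q.write_text("file,marker,gap\na.wav,1,0\n")
        with pytest.warns(UserWarning):  # non-canonical stem
            pf = read_playframe(
                q, column_map={"stim": "file", "trigger": "marker", "isi": "gap"}
            )
        assert pf[0].trigger_value == 1

    @pytest.mark.parametrize(
        "rows, exc, fragment",
        [
            ("a.wav,256,0\n", TriggerValueError, "entry 0"),
            ("a.wav,1.5,0\n", TriggerValueError, "entry 0"),
            ("a.wav,notanumber,0\n", TriggerValueError, "entry 0"),
            ("a.wav,1,-5\n", ISIValueError, "entry 0"),
            (",1,0\n", StimulusNameError, "entry 0"),
        ],
    )
    def test_bad_rows_raise_distinct_errors_naming_entry(
        self, tmp_path, rows, exc, fragment
    ):
        p = tmp_path / "playframe.csv"
        p.write_text("stim,trigger,isi\n" + rows)
        with pytest.raises(exc, match=fragment):
            read_playframe(p)

    def test_missing_column_error(self, tmp_path):
        p = tmp_path / "playframe.csv"
        p.write_text("stim,isi\na.wav,0\n")
        with pytest.raises(MissingColumnError):
            read_playframe(p)

    def test_warns_on_nonconventional_stem(self, tmp_path):
        p = tmp_path / "protocol.csv"
        p.write_text("stim,trigger,isi\n")
        with pytest.warns(UserWarning, match="stem"):
            read_playframe(p)

    def test_empty_playframe_roundtrip(self, tmp_path):
        p = tmp_path / "playframe.csv"
        write_playframe(Playframe(), p)
        assert p.read_text().strip() == "stim,trigger,isi"
        assert read_playframe(p) == Playframe()

    def test_two_entry_roundtrip(self, tmp_path, two_entry_playframe):
        p = tmp_path / "playframe.csv"
        write_playframe(two_entry_playframe, p)
        assert read_playframe(p) == two_entry_playframe

    def test_xlsx_roundtrip(self, tmp_path, two_entry_playframe):
        p = tmp_path / "playframe.xlsx"
        write_playframe(two_entry_playframe, p)
        assert read_playframe(p) == two_entry_playframe

    @settings(max_examples=25, derandomize=True)
    @given(entries=st.lists(entry_strategy, max_size=20))
    def test_roundtrip_is_identity_property(self, tmp_path_factory, entries):
        pf = Playframe(entries)
        p = tmp_path_factory.mktemp("rt") / "playframe.csv"
        write_playframe(pf, p)
        assert read_playframe(p) == pf

    def test_roundtrip_100_random_entries(self, tmp_path):
        rng = np.random.default_rng(7)
        entries = [
            PlayEntry(
                f"s{rng.integers(1000)}.wav",
                int(rng.integers(0, 256)),
                float(rng.uniform(0, 5000)),
            )
            for _ in range(100)
        ]
        pf = Playframe(entries)
        p = tmp_path / "playframe.csv"
        write_playframe(pf, p)
        assert read_playframe(p) == pf


class TestValidate:
    def test_valid_protocol_ok(self, stim_dir, two_entry_playframe):
        report = validate_playframe(two_entry_playframe, stim_dir)
        assert report.ok
        assert report.issues == []

    def test_missing_stimulus_flagged(self, stim_dir):
        pf = Playframe([PlayEntry("ghost.wav", 1, 0.0)])
        report = validate_playframe(pf, stim_dir)
        assert not report.ok
        assert report.issues[0][:2] == (0, "missing_file")

    def test_mono_stimulus_flagged(self, stim_dir, mono_wav):
        pf = Playframe([PlayEntry(mono_wav.name, 1, 0.0)])
        report = validate_playframe(pf, stim_dir)
        assert (0, "channels") in [i[:2] for i in report.issues]

    def test_wrong_rate_flagged(self, stim_dir, wrong_rate_wav):
        pf = Playframe([PlayEntry(wrong_rate_wav.name, 1, 0.0)])
        report = validate_playframe(pf, stim_dir)
        assert (0, "sample_rate") in [i[:2] for i in report.issues]

    def test_not_a_wav_flagged(self, stim_dir):
        (stim_dir / "junk.wav").write_text("not audio")
        pf = Playframe([PlayEntry("junk.wav", 1, 0.0)])
        report = validate_playframe(pf, stim_dir)
        assert (0, "not_wav") in [i[:2] for i in report.issues]

    def test_missing_stim_dir_is_report_issue_not_exception(self, tmp_path):
        pf = Playframe([PlayEntry("beep.wav", 1, 0.0)])
        report = validate_playframe(pf, tmp_path / "nowhere")
        assert not report.ok
        assert report.issues[0][0] is None
        assert report.issues[0][1] == "missing_stim_dir"


class TestTotalDuration:
    def test_empty_is_zero(self):
        assert total_duration_ms(Playframe(), []) == 0.0

    def test_final_isi_excluded_by_default(self):
        pf = Playframe([PlayEntry("a.wav", 1, 500.0)])
        assert total_duration_ms(pf, [200.0]) == 200.0
        assert total_duration_ms(pf, [200.0], include_final_isi=True) == 700.0

    def test_hand_arithmetic(self):
        pf = Playframe(
            [PlayEntry("a.wav", 1, 300.0), PlayEntry("b.wav", 2, 900.0)]
        )
        assert total_duration_ms(pf, [200.0, 100.0]) == 600.0  # 200+300+100

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            total_duration_ms(Playframe([PlayEntry("a.wav", 1, 0.0)]), [])

    def test_additive_over_concatenation(self):
        rng = np.random.default_rng(11)
        def random_pf(n):
            return Playframe(
                [
                    PlayEntry("x.wav", 0, float(rng.uniform(0, 100)))
                    for _ in range(n)
                ]
            )
        a, b = random_pf(5), random_pf(3)
        da = list(rng.uniform(10, 50, 5))
        db = list(rng.uniform(10, 50, 3))
        combined = Playframe(a.entries + b.entries)
        assert total_duration_ms(combined, da + db, include_final_isi=True) == (
            pytest.approx(
                total_duration_ms(a, da, include_final_isi=True)
                + total_duration_ms(b, db, include_final_isi=True)
            )
        )


class TestGenerate:
    def test_fixed_isi_as_given(self):
        pf = generate_playframe(["a.wav", "b.wav", "c.wav"], [1, 2, 3], 500.0)
        assert [e.stimulus_name for e in pf] == ["a.wav", "b.wav", "c.wav"]
        assert all(e.isi_ms == 500.0 for e in pf)

    def test_shuffle_is_deterministic_per_seed(self):
        names = [f"s{i}.wav" for i in range(20)]
        trig = list(range(20))
        a = generate_playframe(names, trig, 100.0, order="shuffled", seed=42)
        b = generate_playframe(names, trig, 100.0, order="shuffled", seed=42)
        c = generate_playframe(names, trig, 100.0, order="shuffled", seed=43)
        assert a == b
        assert a != c
        # shuffle permutes (name, trigger) pairs jointly
        assert sorted((e.stimulus_name, e.trigger_value) for e in a) == sorted(
            zip(names, trig)
        )

    def test_isi_range_uniform(self):
        n = 1000
        pf = generate_playframe(
            [f"{i}.wav" for i in range(n)], [0] * n, (500.0, 1000.0), seed=5
        )
        isis = np.array([e.isi_ms for e in pf])
        assert np.all((isis >= 500.0) & (isis <= 1000.0))
        se = (500.0 / np.sqrt(12)) / np.sqrt(n)
        assert abs(isis.mean() - 750.0) < 3 * se

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            generate_playframe(["a.wav"], [1, 2], 100.0)
        with pytest.raises(ISIValueError):
            generate_playframe(["a.wav"], [1], (-5.0, 10.0))
        with pytest.raises(ValueError):
            generate_playframe(["a.wav"], [1], 100.0, order="sideways")
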