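"""JSON mapping fidelity and bulk conversion modes."""

import json
import tarfile
import zipfile

import pytest

from nmrstar import (
    Loop,
    Saveframe,
    StarEntry,
    StarJsonError,
    convert,
    from_json_text,
    parse_text,
    structurally_equal,
    to_json_text,
)
from nmrstar.fixtures import FixtureSpec, generate_corpus, generate_entry


def small_entry():
    entry = StarEntry({"data": "X"})
    entry["A"] = Saveframe({"_T": "v"})
    return entry


def test_entry_maps_one_to_one():
    assert json.loads(to_json_text(small_entry())) == {"data": "X", "A": {"_T": "v"}}


def test_loop_encoded_as_field_list_plus_record_objects():
    entry = StarEntry({"data": "X"})
    entry["A"] = Saveframe(
        {"loop_0": Loop(["_a", "_b"], [{"_a": "1", "_b": "2"}, {"_a": "3", "_b": "4"}])}
    )
    obj = json.loads(to_json_text(entry))
    assert obj["A"]["loop_0"] == [
        ["_a", "_b"],
        [{"_a": "1", "_b": "2"}, {"_a": "3", "_b": "4"}],
    ]


def test_key_order_preserved_through_json():
    text, _ = generate_entry(FixtureSpec(seed=3))
    entry = parse_text(text)
    again = from_json_text(to_json_text(entry))
    assert list(again) == list(entry)
    assert structurally_equal(again, entry)


def test_indent_flag_only_changes_layout():
    entry = small_entry()
    compact = to_json_text(entry)
    pretty = to_json_text(entry, indent=4)
    assert compact != pretty
    assert structurally_equal(from_json_text(pretty), entry)


def test_minimal_object_reconstructs():
    entry = from_json_text('{"data": "X"}')
    assert list(entry) == ["data"]
    assert entry["data"] == "X"


@pytest.mark.parametrize(
    ("text", "needle"),
    [
        ("not json", "malformed JSON"),
        ('["top-level array"]', "must be an object"),
        ('{"data": "X", "A": {"loop_0": [["_a"]]}}', "exactly 2"),
        (
            '{"data": "X", "A": {"loop_0": [["_a"], [{"_b": "1"}]]}}',
            "A/loop_0/record 0",
        ),
        ('{"data": "X", "A": {"_T": 5}}', "A/_T"),
    ],
)
def test_schema_violations_name_the_path(text, needle):
    with pytest.raises(StarJsonError) as err:
        from_json_text(text)
    assert needle in str(err.value)


def test_single_file_conversion_round_trips(tmp_path):
    text, _ = generate_entry(FixtureSpec(seed=9))
    src = tmp_path / "entry.str"
    src.write_text(text, encoding="utf-8")
    dst = tmp_path / "entry.json"
    report = convert(str(src), dst, from_format="nmrstar", to_format="json")
    assert (report.attempted, report.succeeded) == (1, 1)
    assert structurally_equal(from_json_text(dst.read_text()), parse_text(text))

    back = tmp_path / "back.str"
    report = convert(str(dst), back, from_format="json", to_format="nmrstar")
    assert report.ok
    assert structurally_equal(parse_text(back.read_text()), parse_text(text))


def test_directory_conversion_mirrors_nested_layout(tmp_path):
    src = tmp_path / "in"
    (src / "nested").mkdir(parents=True)
    for i, where in enumerate(["a.str", "nested/b.str", "nested/c.str"]):
        text, _ = generate_entry(FixtureSpec(seed=20 + i))
        (src / where).write_text(text, encoding="utf-8")
    out = tmp_path / "out"
    report = convert(str(src), out, from_format="nmrstar", to_format="json")
    assert report.attempted == report.succeeded == 3
    assert (out / "a.json").is_file()
    assert (out / "nested" / "b.json").is_file()
    assert (out / "nested" / "c.json").is_file()


def test_zip_conversion_preserves_member_names_with_swapped_extension(tmp_path):
    archive = tmp_path / "corpus.zip"
    generate_corpus(12, 77, archive)
    out = tmp_path / "converted.zip"
    report = convert(str(archive), out, from_format="nmrstar", to_format="json")
    assert report.attempted == report.succeeded == 12
    with zipfile.ZipFile(out) as z:
        names = z.namelist()
    assert len(names) == 12
    assert all(name.endswith(".json") for name in names)
    assert sorted(n.removesuffix(".json") for n in names) == [
        f"fixture_{i:05d}" for i in range(12)
    ]


def test_targz_conversion_round_trips_members(tmp_path):
    archive = tmp_path / "corpus.tar.gz"
    generate_corpus(8, 42, archive)
    out = tmp_path / "converted.tar.gz"
    report = convert(str(archive), out, from_format="nmrstar", to_format="json")
    assert report.ok and report.attempted == 8
    with tarfile.open(archive) as src_tar, tarfile.open(out) as dst_tar:
        sources = {
            m.name: src_tar.extractfile(m).read().decode() for m in src_tar
        }
        for member in dst_tar:
            converted = from_json_text(dst_tar.extractfile(member).read().decode())
            original = parse_text(sources[member.name.removesuffix(".json") + ".str"])
            assert structurally_equal(converted, original)


def test_unparseable_member_reported_and_skipped(tmp_path):
    src = tmp_path / "in"
    src.mkdir()
    good, _ = generate_entry(FixtureSpec(seed=2))
    (src / "good.str").write_text(good, encoding="utf-8")
    (src / "bad.str").write_text("no data header here\n", encoding="utf-8")
    report = convert(str(src), tmp_path / "out", from_format="nmrstar", to_format="json")
    assert report.attempted == 2
    assert report.succeeded == 1
    assert report.failures[0][0] == "bad.str"


def test_same_format_conversion_rejected(tmp_path):
    with pytest.raises(ValueError):
        convert(str(tmp_path), tmp_path / "out", from_format="json", to_format="json")


def test_triangle_equality_on_sample(parsed_corpus):
    """NMR-STAR parse ≡ JSON round trip ≡ re-written NMR-STAR parse."""
    from nmrstar import star_text

    for name, _, _, entry in parsed_corpus[:40]:
        via_json = from_json_text(to_json_text(entry))
        via_star = parse_text(star_text(entry))
        assert structurally_equal(entry, via_json), name
        assert structurally_equal(via_json, via_star), name
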