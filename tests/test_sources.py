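"""Source-kind inference, lazy resolution, and streaming entry reading."""

import pytest

from nmrstar import (
    SourceKind,
    SourceSpec,
    SourceResolutionError,
    make_spec,
    read_entries,
    resolve,
)
from nmrstar import sources as sources_module
from nmrstar.fixtures import FixtureSpec, generate_corpus, generate_entry


@pytest.fixture()
def fixture_file(tmp_path):
    text, _ = generate_entry(FixtureSpec(seed=4))
    path = tmp_path / "entry.str"
    path.write_text(text, encoding="utf-8")
    return path


def test_kind_inference_precedence(tmp_path, fixture_file):
    assert make_spec(str(fixture_file)).kind is SourceKind.LOCAL_FILE
    assert make_spec(str(tmp_path)).kind is SourceKind.LOCAL_DIR
    archive = tmp_path / "c.zip"
    generate_corpus(2, 1, archive)
    assert make_spec(str(archive)).kind is SourceKind.LOCAL_ARCHIVE
    assert make_spec("http://example.org/x.str").kind is SourceKind.URL_FILE
    assert make_spec("https://example.org/x.tar.gz").kind is SourceKind.URL_ARCHIVE
    assert make_spec("18569").kind is SourceKind.BMRB_ID
    # an existing all-digit file beats the BMRB-id interpretation
    digit_file = tmp_path / "12345"
    digit_file.write_text("data_X\n", encoding="utf-8")
    spec = make_spec(str(digit_file))
    assert spec.kind is SourceKind.LOCAL_FILE
    with pytest.raises(SourceResolutionError):
        make_spec("no/such/path.either")
    with pytest.raises(SourceResolutionError):
        make_spec("")


def test_single_file_resolves_to_one_pair(fixture_file):
    pairs = list(resolve(make_spec(str(fixture_file))))
    assert len(pairs) == 1
    assert pairs[0][0] == str(fixture_file)
    assert pairs[0][1].startswith("data_")


def test_directory_resolution_sorted_recursive_hidden_skipped(tmp_path):
    (tmp_path / "sub").mkdir()
    for i, name in enumerate(["b.str", "a.str", "sub/c.str"]):
        text, _ = generate_entry(FixtureSpec(seed=50 + i))
        (tmp_path / name).write_text(text, encoding="utf-8")
    (tmp_path / ".hidden.str").write_text("data_H\n", encoding="utf-8")
    (tmp_path / "notes.bin").write_text("binary-ish", encoding="utf-8")
    names = [name for name, _ in resolve(make_spec(str(tmp_path)))]
    assert names == ["a.str", "b.str", "sub/c.str"]
    globbed = [name for name, _ in resolve(make_spec(str(tmp_path)), glob="*.bin")]
    assert globbed == ["notes.bin"]


def test_targz_members_stream_in_archive_order(tmp_path):
    archive = tmp_path / "c.tar.gz"
    generate_corpus(20, 5, archive)
    pairs = list(resolve(make_spec(str(archive))))
    assert [name for name, _ in pairs] == [f"fixture_{i:05d}.str" for i in range(20)]
    assert all(text.startswith("data_") for _, text in pairs)


def test_file_url_and_bmrb_id_template(tmp_path, fixture_file):
    url = fixture_file.as_uri()
    pairs = list(resolve(make_spec(url)))
    assert len(pairs) == 1 and pairs[0][1].startswith("data_")

    bmrb_dir = tmp_path / "bmrb"
    bmrb_dir.mkdir()
    text, _ = generate_entry(FixtureSpec(seed=6))
    (bmrb_dir / "bmr18569.str").write_text(text, encoding="utf-8")
    template = bmrb_dir.as_uri() + "/bmr{id}.str"
    pairs = list(resolve(make_spec("18569"), bmrb_template=template))
    assert len(pairs) == 1
    assert pairs[0][1] == text


def test_read_entries_streams_mixed_formats_in_source_order(tmp_path):
    single, _ = generate_entry(FixtureSpec(seed=1))
    single_path = tmp_path / "one.str"
    single_path.write_text(single, encoding="utf-8")

    directory = tmp_path / "dir"
    directory.mkdir()
    for i in range(2):
        star_text, _ = generate_entry(FixtureSpec(seed=30 + i))
        (directory / f"m{i}.str").write_text(star_text, encoding="utf-8")
    json_text, _ = generate_entry(FixtureSpec(seed=33), fmt="json")
    (directory / "m2.json").write_text(json_text, encoding="utf-8")

    archive = tmp_path / "two.zip"
    generate_corpus(2, 8, archive)

    entries = list(
        read_entries([str(single_path), str(directory), str(archive)])
    )
    assert len(entries) == 6
    assert entries[0].source == str(single_path)
    assert entries[3].source.endswith("::m2.json")
    assert entries[4].source == f"{archive}::fixture_00000.str"
    assert all(entry["data"] for entry in entries)


def test_read_entries_empty_directory_yields_nothing(tmp_path):
    assert list(read_entries(str(tmp_path))) == []


def test_read_entries_error_policy(tmp_path):
    (tmp_path / "bad.str").write_text("not star\n", encoding="utf-8")
    good, _ = generate_entry(FixtureSpec(seed=2))
    (tmp_path / "good.str").write_text(good, encoding="utf-8")
    with pytest.raises(Exception):
        list(read_entries(str(tmp_path)))
    survivors = list(read_entries(str(tmp_path), on_error="skip"))
    assert len(survivors) == 1


def test_resolution_is_lazy(tmp_path, monkeypatch):
    for i in range(5):
        text, _ = generate_entry(FixtureSpec(seed=40 + i))
        (tmp_path / f"f{i}.str").write_text(text, encoding="utf-8")
    reads = []
    real = sources_module._read_text_file
    monkeypatch.setattr(
        sources_module, "_read_text_file", lambda p: (reads.append(p), real(p))[1]
    )
    stream = read_entries(str(tmp_path))
    next(stream)
    next(stream)
    assert len(reads) == 2  # consuming k entries reads exactly k documents


def test_format_hint_overrides_detection(tmp_path):
    json_text, _ = generate_entry(FixtureSpec(seed=12), fmt="json")
    path = tmp_path / "entry.dat"
    path.write_text(json_text, encoding="utf-8")
    spec = SourceSpec(str(path), SourceKind.LOCAL_FILE, format_hint="json")
    entries = list(read_entries(spec))
    assert len(entries) == 1
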