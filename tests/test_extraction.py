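"""Whitelist loading, read layout rules, perfect-match extraction, table I/O."""

import gzip
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace import (
    CloneCountTable,
    ExtractionQC,
    ReadLayout,
    SimulationConfig,
    build_library,
    extract_clone_counts,
    generate_reads,
    load_whitelist,
    read_count_table,
    run_stage_plan,
    write_count_table,
)

from conftest import make_read, naive_clone_counts, random_count_table


# ---------------------------------------------------------------------------
# load_whitelist
# ---------------------------------------------------------------------------

class TestLoadWhitelist:
    def _write(self, path, seqs):
        path.write_text("".join(s + "\n" for s in seqs))
        return path

    def test_plain_files(self, tmp_path, small_whitelist):
        b14 = self._write(tmp_path / "bc14.txt", sorted(small_whitelist.bc14_set)[:4])
        b30 = self._write(tmp_path / "bc30.txt", sorted(small_whitelist.bc30_set)[:4])
        wl = load_whitelist(b14, b30)
        assert len(wl.bc14_set) == 4 and len(wl.bc30_set) == 4
        assert wl.valid_pairs is None

    def test_tsv_with_id_column(self, tmp_path, small_whitelist):
        seqs = sorted(small_whitelist.bc14_set)
        b14 = tmp_path / "bc14.tsv"
        b14.write_text("".join(f"BC{i}\t{s}\n" for i, s in enumerate(seqs)))
        b30 = self._write(tmp_path / "bc30.txt", sorted(small_whitelist.bc30_set))
        assert load_whitelist(b14, b30).bc14_set == small_whitelist.bc14_set

    def test_wrong_length_names_line(self, tmp_path, small_whitelist):
        b14 = self._write(tmp_path / "bc14.txt",
                          [sorted(small_whitelist.bc14_set)[0], "ACGTACGTACGTA"])  # 13-mer
        b30 = self._write(tmp_path / "bc30.txt", sorted(small_whitelist.bc30_set))
        with pytest.raises(ValueError, match="bc14.txt:2"):
            load_whitelist(b14, b30)

    def test_bad_alphabet(self, tmp_path, small_whitelist):
        b14 = self._write(tmp_path / "bc14.txt", ["ACGTNCGTACGTAC"])
        b30 = self._write(tmp_path / "bc30.txt", sorted(small_whitelist.bc30_set))
        with pytest.raises(ValueError, match="non-ACGT"):
            load_whitelist(b14, b30)

    def test_empty_file_is_hard_error(self, tmp_path, small_whitelist):
        b14 = tmp_path / "bc14.txt"
        b14.write_text("")
        b30 = self._write(tmp_path / "bc30.txt", sorted(small_whitelist.bc30_set))
        with pytest.raises(ValueError, match="empty"):
            load_whitelist(b14, b30)

    def test_duplicates_deduplicated_with_warning(self, tmp_path, small_whitelist, caplog):
        seqs = sorted(small_whitelist.bc14_set)[:3]
        b14 = self._write(tmp_path / "bc14.txt", seqs + [seqs[0]])
        b30 = self._write(tmp_path / "bc30.txt", sorted(small_whitelist.bc30_set))
        with caplog.at_level(logging.WARNING, logger="clonetrace"):
            wl = load_whitelist(b14, b30)
        assert len(wl.bc14_set) == 3
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_pairs_file(self, tmp_path, small_whitelist):
        b14s = sorted(small_whitelist.bc14_set)
        b30s = sorted(small_whitelist.bc30_set)
        b14 = self._write(tmp_path / "bc14.txt", b14s)
        b30 = self._write(tmp_path / "bc30.txt", b30s)
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text(f"{b14s[0]}\t{b30s[0]}\n{b14s[1]}\t{b30s[1]}\n")
        wl = load_whitelist(b14, b30, pairs)
        assert wl.valid_pairs == {(b14s[0], b30s[0]), (b14s[1], b30s[1])}


# ---------------------------------------------------------------------------
# ReadLayout
# ---------------------------------------------------------------------------

class TestReadLayout:
    def test_defaults_are_consistent(self, layout):
        assert layout.bc14_offset + 14 <= layout.bc30_offset
        assert layout.min_read_length >= layout.bc30_offset + 30

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ReadLayout(bc14_offset=0, bc30_offset=10)

    def test_spacer_must_fill_gap(self):
        with pytest.raises(ValueError, match="spacer length"):
            ReadLayout(bc14_offset=0, spacer="TG", bc30_offset=18)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ReadLayout(bc14_offset=-1, bc30_offset=20)

    def test_barcode_lengths_fixed(self):
        with pytest.raises(ValueError, match="fixed"):
            ReadLayout(bc14_length=10)


# ---------------------------------------------------------------------------
# extract_clone_counts
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_empty_input(self, layout, small_whitelist):
        table = extract_clone_counts([], layout, small_whitelist)
        assert table.counts == {} and table.qc.total_reads == 0

    def test_single_substitution_in_bc30_breaks_match(self, layout, small_whitelist):
        """Three pasted reads, one with a point mutation inside BC30."""
        b14s = sorted(small_whitelist.bc14_set)
        b30s = sorted(small_whitelist.bc30_set)
        good1 = make_read(b14s[0], b30s[0], layout)
        good2 = make_read(b14s[1], b30s[1], layout)
        mutated = list(make_read(b14s[2], b30s[2], layout))
        pos = layout.bc30_offset + 5
        mutated[pos] = "A" if mutated[pos] != "A" else "C"
        reads = [good1, good2, "".join(mutated)]
        table = extract_clone_counts(reads, layout, small_whitelist)
        assert sum(table.counts.values()) == 2
        assert table.qc.both_match == 2
        assert table.qc.bc14_match_only == 1
        assert table.counts == naive_clone_counts(reads, layout, small_whitelist)

    def test_unknown_bc30_is_bc14_match_only(self, layout, small_whitelist):
        b14 = sorted(small_whitelist.bc14_set)[0]
        read = make_read(b14, "A" * 30, layout)
        assert "A" * 30 not in small_whitelist.bc30_set
        table = extract_clone_counts([read], layout, small_whitelist)
        assert table.counts == {} and table.qc.bc14_match_only == 1

    def test_too_short_and_spacer_mismatch(self, layout, small_whitelist):
        b14s = sorted(small_whitelist.bc14_set)
        b30s = sorted(small_whitelist.bc30_set)
        good = make_read(b14s[0], b30s[0], layout)
        short = good[:20]
        bad_spacer = good[:14] + "AAAA" + good[18:]
        assert layout.spacer != "AAAA"
        table = extract_clone_counts([good, short, bad_spacer], layout, small_whitelist)
        assert table.qc.too_short == 1
        assert table.qc.spacer_mismatch == 1
        assert table.qc.both_match == 1

    def test_pair_filtering(self, layout, small_whitelist):
        b14s = sorted(small_whitelist.bc14_set)
        b30s = sorted(small_whitelist.bc30_set)
        wl = type(small_whitelist)(
            bc14_set=small_whitelist.bc14_set,
            bc30_set=small_whitelist.bc30_set,
            valid_pairs=frozenset({(b14s[0], b30s[0])}),
        )
        reads = [make_read(b14s[0], b30s[0], layout),
                 make_read(b14s[1], b30s[1], layout)]
        table = extract_clone_counts(reads, layout, wl)
        assert table.qc.both_match == 1 and table.qc.pair_invalid == 1
        assert sum(table.counts.values()) == table.qc.both_match

    def test_case_insensitive_and_n_never_matches(self, layout, small_whitelist):
        b14 = sorted(small_whitelist.bc14_set)[0]
        b30 = sorted(small_whitelist.bc30_set)[0]
        lower = make_read(b14, b30, layout).lower()
        with_n = make_read(b14, b30, layout)
        with_n = "N" + with_n[1:]  # N inside BC14
        table = extract_clone_counts([lower, with_n], layout, small_whitelist)
        assert table.qc.both_match == 1
        assert table.qc.bc30_match_only == 1

    def test_bc30_only_mode_merges_on_bc30(self, layout, small_whitelist):
        b14s = sorted(small_whitelist.bc14_set)
        b30 = sorted(small_whitelist.bc30_set)[0]
        reads = [make_read(b14s[0], b30, layout), make_read(b14s[1], b30, layout)]
        table = extract_clone_counts(reads, layout, small_whitelist,
                                     clone_key_mode="bc30_only")
        assert table.counts == {b30: 2}

    def test_fastq_file_and_gzip_inputs(self, tmp_path, layout, small_whitelist):
        cfg = SimulationConfig(seed=5, n_bc14=6, n_bc30=8, scale=1.0,
                               n_founder_cells=2_000, per_base_error=0.01,
                               reads_per_cell=3.0, stage_plan=[])
        pop = run_stage_plan(cfg, whitelist=small_whitelist)[0]
        reads, _ = generate_reads(pop, cfg, np.random.default_rng(9))
        fq = tmp_path / "reads.fastq"
        fq.write_text("".join(f"@{n}\n{s}\n+\n{q}\n" for n, s, q in reads))
        fq_gz = tmp_path / "reads.fastq.gz"
        with gzip.open(fq_gz, "wt") as fh:
            fh.write(fq.read_text())
        mem = extract_clone_counts([s for _, s, _ in reads], layout, small_whitelist)
        from_file = extract_clone_counts(fq, layout, small_whitelist)
        from_gz = extract_clone_counts(fq_gz, layout, small_whitelist)
        assert from_file.counts == mem.counts == from_gz.counts
        assert from_file.qc.as_dict() == mem.qc.as_dict()

    def test_truncated_fastq_is_hard_error(self, tmp_path, layout, small_whitelist):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r1\nACGT\n")  # missing plus/quality lines
        with pytest.raises(Exception):
            extract_clone_counts(fq, layout, small_whitelist)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.text(alphabet="ACGTN", min_size=0, max_size=60), max_size=60),
           st.integers(0, 2 ** 31 - 1))
    def test_qc_conservation_property(self, layout, small_whitelist, junk, seed):
        """Every read lands in exactly one bucket: buckets sum to total."""
        rng = np.random.default_rng(seed)
        b14s = sorted(small_whitelist.bc14_set)
        b30s = sorted(small_whitelist.bc30_set)
        good = [make_read(b14s[rng.integers(len(b14s))],
                          b30s[rng.integers(len(b30s))], layout)
                for _ in range(int(rng.integers(0, 10)))]
        reads = junk + good
        table = extract_clone_counts(reads, layout, small_whitelist)
        qc = table.qc
        qc.validate()  # raises if the bucket sum breaks
        assert qc.total_reads == len(reads)
        assert sum(table.counts.values()) == qc.both_match
        assert table.counts == naive_clone_counts(reads, layout, small_whitelist)


# ---------------------------------------------------------------------------
# Count table I/O
# ---------------------------------------------------------------------------

class TestCountTableIO:
    def test_two_clone_file_shape(self, tmp_path, small_whitelist):
        b14s = sorted(small_whitelist.bc14_set)
        b30s = sorted(small_whitelist.bc30_set)
        table = CloneCountTable(
            "s1", {b14s[0] + b30s[0]: 3, b14s[1] + b30s[1]: 1},
            qc=ExtractionQC(total_reads=4, both_match=4),
        )
        path = tmp_path / "t.tsv"
        write_count_table(table, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert lines[0].split("\t") == ["clone_id", "bc14", "bc30", "read_count"]
        assert len(lines) == 3  # header + 2 data rows

    def test_round_trip_identity_1000_clones(self, tmp_path):
        rng = np.random.default_rng(42)
        counts = random_count_table(rng, 1000)
        total = sum(counts.values())
        table = CloneCountTable("big", counts,
                                qc=ExtractionQC(total_reads=total + 7, both_match=total,
                                                no_match=7))
        path = tmp_path / "big.tsv"
        write_count_table(table, path)
        back = read_count_table(path)
        assert back == table

    def test_determinism_byte_identical(self, tmp_path):
        rng = np.random.default_rng(1)
        counts = random_count_table(rng, 50)
        total = sum(counts.values())
        table = CloneCountTable("s", counts, qc=ExtractionQC(total_reads=total, both_match=total))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_count_table(table, p1)
        shuffled = dict(sorted(counts.items(), key=lambda kv: kv[1]))
        write_count_table(CloneCountTable("s", shuffled, qc=table.qc), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("bad", ["0", "-3", "2.5", "x"])
    def test_invalid_counts_rejected(self, tmp_path, small_whitelist, bad):
        b14 = sorted(small_whitelist.bc14_set)[0]
        b30 = sorted(small_whitelist.bc30_set)[0]
        path = tmp_path / "bad.tsv"
        path.write_text("clone_id\tbc14\tbc30\tread_count\n"
                        f"{b14 + b30}\t{b14}\t{b30}\t{bad}\n")
        with pytest.raises(ValueError):
            read_count_table(path)

    def test_bare_deposited_table_accepted(self, tmp_path, small_whitelist):
        """Count tables without QC headers (e.g. downloaded) load fine."""
        b14s = sorted(small_whitelist.bc14_set)
        b30s = sorted(small_whitelist.bc30_set)
        path = tmp_path / "geo.tsv"
        path.write_text("clone_id\tread_count\n"
                        f"{b14s[0] + b30s[0]}\t10\n{b14s[1] + b30s[1]}\t5\n")
        table = read_count_table(path)
        assert table.total_counted() == 15 and len(table.counts) == 2
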