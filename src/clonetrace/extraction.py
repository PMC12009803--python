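"""Positional barcode extraction from amplicon reads.

Reads carry a 14-nt barcode (BC14) and a 30-nt barcode (BC30) at fixed,
configurable offsets.  A read contributes to a clone's count only when both
extracted substrings are *perfect* (exact, case-insensitive) members of the
whitelist, the spacer between them (if one is configured) matches exactly,
and — when an explicit pair list is supplied — the BC14–BC30 combination is
a valid library pair.  No mismatch tolerance, no indel rescue; base
qualities are ignored.

Every read lands in exactly one QC bucket, so the extraction filter is
fully auditable: the bucket counts always sum to the number of reads seen.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

import pysam

logger = logging.getLogger("clonetrace")

DNA_ALPHABET = frozenset("ACGT")
BC14_LENGTH = 14
BC30_LENGTH = 30

ReadsInput = Union[str, Path, Iterable]


def _validate_sequence(seq: str, length: int, where: str) -> str:
    seq = seq.strip().upper()
    if len(seq) != length:
        raise ValueError(f"{where}: expected a {length}-mer, got {len(seq)} nt: {seq!r}")
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"{where}: non-ACGT characters {bad} in {seq!r}")
    return seq


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeWhitelist:
    """The expected BC14 and BC30 sequence sets, optionally with valid pairs.

    Only sequences in these sets count during extraction ("perfect
    matching" against the library's expected barcodes).
    """

    bc14_set: frozenset
    bc30_set: frozenset
    valid_pairs: Optional[frozenset] = None
    source_name: str = ""

    def __post_init__(self):
        if not self.bc14_set or not self.bc30_set:
            raise ValueError("whitelist sets must be non-empty")
        for seq in self.bc14_set:
            _validate_sequence(seq, BC14_LENGTH, "bc14_set")
        for seq in self.bc30_set:
            _validate_sequence(seq, BC30_LENGTH, "bc30_set")
        if self.valid_pairs is not None:
            for b14, b30 in self.valid_pairs:
                if b14 not in self.bc14_set or b30 not in self.bc30_set:
                    raise ValueError(
                        f"valid pair ({b14}, {b30}) has a component outside the whitelist sets"
                    )


@dataclass(frozen=True)
class ReadLayout:
    """Where BC14 and BC30 sit inside a read (0-based offsets).

    The default layout places BC14 at the start of the read, a constant
    spacer, then BC30.  Vendor amplicon designs differ, so every field is
    configurable; the defaults are a documented assumption, not a vendor
    specification.
    """

    bc14_offset: int = 0
    bc14_length: int = BC14_LENGTH
    spacer: Optional[str] = None
    bc30_offset: int = BC14_LENGTH
    bc30_length: int = BC30_LENGTH
    min_read_length: int = 0

    def __post_init__(self):
        if self.bc14_length != BC14_LENGTH or self.bc30_length != BC30_LENGTH:
            raise ValueError("barcode lengths are fixed at 14 and 30 nt")
        if self.bc14_offset < 0 or self.bc30_offset < 0:
            raise ValueError("offsets must be non-negative")
        if self.bc14_offset + self.bc14_length > self.bc30_offset:
            raise ValueError("BC14 field overlaps BC30 field")
        if self.spacer is not None:
            spacer = self.spacer.strip().upper()
            if not set(spacer) <= DNA_ALPHABET:
                raise ValueError(f"spacer contains non-ACGT characters: {self.spacer!r}")
            gap = self.bc30_offset - (self.bc14_offset + self.bc14_length)
            if len(spacer) != gap:
                raise ValueError(
                    f"spacer length {len(spacer)} does not fill the "
                    f"{gap}-nt gap between BC14 and BC30"
                )
            object.__setattr__(self, "spacer", spacer)
        min_len = self.bc30_offset + self.bc30_length
        if self.min_read_length < min_len:
            object.__setattr__(self, "min_read_length", min_len)

    @property
    def spacer_length(self) -> int:
        return len(self.spacer) if self.spacer else 0

    @classmethod
    def with_spacer(cls, spacer: str, bc14_offset: int = 0) -> "ReadLayout":
        """Layout BC14 | spacer | BC30 with no other context."""
        spacer = spacer.strip().upper()
        return cls(
            bc14_offset=bc14_offset,
            spacer=spacer,
            bc30_offset=bc14_offset + BC14_LENGTH + len(spacer),
        )


@dataclass
class ExtractionQC:
    """Exhaustive per-read classification tallies.

    Buckets are mutually exclusive; their sum always equals ``total_reads``.
    Precedence when a read could fall in several: too_short, then
    spacer_mismatch, then barcode membership, then pair validity.
    """

    total_reads: int = 0
    too_short: int = 0
    bc14_match_only: int = 0
    bc30_match_only: int = 0
    both_match: int = 0
    pair_invalid: int = 0
    no_match: int = 0
    spacer_mismatch: int = 0

    _BUCKETS = (
        "too_short", "bc14_match_only", "bc30_match_only",
        "both_match", "pair_invalid", "no_match", "spacer_mismatch",
    )

    def validate(self) -> None:
        if any(getattr(self, f) < 0 for f in ("total_reads",) + self._BUCKETS):
            raise ValueError("QC counts must be non-negative")
        bucket_sum = sum(getattr(self, f) for f in self._BUCKETS)
        if bucket_sum != self.total_reads:
            raise ValueError(
                f"QC buckets sum to {bucket_sum} but total_reads={self.total_reads}"
            )

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in ("total_reads",) + self._BUCKETS}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExtractionQC":
        qc = cls(**{k: int(v) for k, v in d.items()})
        qc.validate()
        return qc


@dataclass
class CloneCountTable:
    """Per-sample clone-barcode -> read count mapping with extraction QC.

    The clone key is the concatenated BC14+BC30 pair by default
    (``clone_key_mode='pair'``), or BC30 alone (``'bc30_only'``).
    """

    sample_id: str
    counts: dict
    qc: ExtractionQC = field(default_factory=ExtractionQC)
    clone_key_mode: str = "pair"

    def __post_init__(self):
        if self.clone_key_mode not in ("pair", "bc30_only"):
            raise ValueError(f"unknown clone_key_mode {self.clone_key_mode!r}")
        clean = {}
        for key, count in self.counts.items():
            if isinstance(count, bool) or int(count) != count or count <= 0:
                raise ValueError(f"clone {key!r}: counts must be strictly positive integers, got {count!r}")
            clean[key] = int(count)
        self.counts = clean

    def total_counted(self) -> int:
        return sum(self.counts.values())

    def clone_keys(self, min_reads: int = 1):
        """Set of clone keys with count >= min_reads."""
        if min_reads <= 1:
            return set(self.counts)
        return {k for k, c in self.counts.items() if c >= min_reads}

    def split_key(self, key: str):
        """Decompose a clone key into (bc14, bc30); bc14 is '' in bc30_only mode."""
        if self.clone_key_mode == "pair":
            return key[:BC14_LENGTH], key[BC14_LENGTH:]
        return "", key

    def __eq__(self, other) -> bool:
        if not isinstance(other, CloneCountTable):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.counts == other.counts
            and self.clone_key_mode == other.clone_key_mode
            and self.qc.as_dict() == other.qc.as_dict()
        )


# ---------------------------------------------------------------------------
# Whitelist I/O
# ---------------------------------------------------------------------------

def _read_sequence_file(path, length: int) -> frozenset:
    """One sequence per line, or 2-column TSV (id<TAB>sequence)."""
    path = Path(path)
    seqs = []
    seen = set()
    n_dup = 0
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            raw = fields[-1] if len(fields) > 1 else fields[0]
            seq = _validate_sequence(raw, length, f"{path}:{lineno}")
            if seq in seen:
                n_dup += 1
                continue
            seen.add(seq)
            seqs.append(seq)
    if not seqs:
        raise ValueError(f"{path}: empty whitelist file")
    if n_dup:
        logger.warning("%s: %d duplicate sequence line(s) deduplicated", path, n_dup)
    return frozenset(seqs)


def load_whitelist(bc14_path, bc30_path, pairs_path=None, source_name: str = "") -> BarcodeWhitelist:
    """Load and validate a BC14/BC30 whitelist from plain-text or TSV files.

    Malformed sequences (wrong length or alphabet) raise with the offending
    line number; duplicated lines are deduplicated with a logged warning.
    ``pairs_path``, if given, is a 2-column TSV of valid (bc14, bc30) pairs.
    """
    bc14_set = _read_sequence_file(bc14_path, BC14_LENGTH)
    bc30_set = _read_sequence_file(bc30_path, BC30_LENGTH)
    valid_pairs = None
    if pairs_path is not None:
        pairs = set()
        with open(pairs_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{pairs_path}:{lineno}: expected bc14<TAB>bc30")
                b14 = _validate_sequence(fields[0], BC14_LENGTH, f"{pairs_path}:{lineno}")
                b30 = _validate_sequence(fields[1], BC30_LENGTH, f"{pairs_path}:{lineno}")
                pairs.add((b14, b30))
        if not pairs:
            raise ValueError(f"{pairs_path}: empty pairs file")
        valid_pairs = frozenset(pairs)
    name = source_name or f"{Path(bc14_path).name}+{Path(bc30_path).name}"
    return BarcodeWhitelist(bc14_set=bc14_set, bc30_set=bc30_set,
                            valid_pairs=valid_pairs, source_name=name)


def write_whitelist(whitelist: BarcodeWhitelist, bc14_path, bc30_path, pairs_path=None) -> None:
    """Write whitelist sets (sorted, one sequence per line) to text files."""
    Path(bc14_path).write_text("".join(s + "\n" for s in sorted(whitelist.bc14_set)))
    Path(bc30_path).write_text("".join(s + "\n" for s in sorted(whitelist.bc30_set)))
    if pairs_path is not None and whitelist.valid_pairs is not None:
        with open(pairs_path, "w") as fh:
            for b14, b30 in sorted(whitelist.valid_pairs):
                fh.write(f"{b14}\t{b30}\n")


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _iter_sequences(reads: ReadsInput) -> Iterator[str]:
    """Yield read sequences from a FASTQ(.gz) path or an in-memory iterable.

    Iterable elements may be plain sequence strings, (name, seq[, qual])
    tuples, or objects with a ``.sequence`` or ``.seq`` attribute.
    """
    if isinstance(reads, (str, Path)):
        path = str(reads)
        try:
            with pysam.FastxFile(path) as fh:
                for i, rec in enumerate(fh):
                    if rec.sequence is None or rec.quality is None:
                        raise ValueError(
                            f"{path}: FASTQ record {i} is truncated or malformed"
                        )
                    yield rec.sequence
        except OSError as exc:
            raise ValueError(f"unreadable or truncated FASTQ {path}: {exc}") from exc
        return
    for item in reads:
        if isinstance(item, str):
            yield item
        elif isinstance(item, (tuple, list)):
            yield item[1]
        elif hasattr(item, "sequence"):
            yield item.sequence
        elif hasattr(item, "seq"):
            yield str(item.seq)
        else:
            raise TypeError(f"cannot interpret read record {item!r}")


def extract_clone_counts(
    reads: ReadsInput,
    layout: ReadLayout,
    whitelist: BarcodeWhitelist,
    clone_key_mode: str = "pair",
    sample_id: str = "sample",
) -> CloneCountTable:
    """Classify every read and accumulate perfect-match clone counts.

    A read increments a clone count iff the substring at the BC14 position
    is in ``bc14_set``, the substring at the BC30 position is in
    ``bc30_set``, the spacer (when configured) matches exactly, and (when
    ``valid_pairs`` is present) the pair is valid.  N bases never match.
    """
    if clone_key_mode not in ("pair", "bc30_only"):
        raise ValueError(f"unknown clone_key_mode {clone_key_mode!r}")
    bc14_set = whitelist.bc14_set
    bc30_set = whitelist.bc30_set
    pairs = whitelist.valid_pairs
    b14_lo, b14_hi = layout.bc14_offset, layout.bc14_offset + layout.bc14_length
    b30_lo, b30_hi = layout.bc30_offset, layout.bc30_offset + layout.bc30_length
    spacer = layout.spacer
    sp_lo, sp_hi = b14_hi, b30_lo
    min_len = layout.min_read_length

    qc = ExtractionQC()
    counts: dict = {}
    for seq in _iter_sequences(reads):
        qc.total_reads += 1
        if len(seq) < min_len:
            qc.too_short += 1
            continue
        seq = seq.upper()
        if spacer is not None and seq[sp_lo:sp_hi] != spacer:
            qc.spacer_mismatch += 1
            continue
        b14 = seq[b14_lo:b14_hi]
        b30 = seq[b30_lo:b30_hi]
        ok14 = b14 in bc14_set
        ok30 = b30 in bc30_set
        if ok14 and ok30:
            if pairs is not None and (b14, b30) not in pairs:
                qc.pair_invalid += 1
                continue
            qc.both_match += 1
            key = b14 + b30 if clone_key_mode == "pair" else b30
            counts[key] = counts.get(key, 0) + 1
        elif ok14:
            qc.bc14_match_only += 1
        elif ok30:
            qc.bc30_match_only += 1
        else:
            qc.no_match += 1
    qc.validate()
    return CloneCountTable(sample_id=sample_id, counts=counts, qc=qc,
                           clone_key_mode=clone_key_mode)


# ---------------------------------------------------------------------------
# Count table I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("clone_id", "bc14", "bc30", "read_count")


def write_count_table(table: CloneCountTable, path) -> None:
    """Serialize a count table as TSV with QC in `#`-prefixed header lines.

    Rows are sorted by clone_id so output is byte-identical across runs.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id={table.sample_id}\n")
        fh.write(f"# clone_key_mode={table.clone_key_mode}\n")
        fh.write(f"# qc={json.dumps(table.qc.as_dict(), sort_keys=True)}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for key in sorted(table.counts):
            b14, b30 = table.split_key(key)
            fh.write(f"{key}\t{b14 or '-'}\t{b30}\t{table.counts[key]}\n")


def read_count_table(path) -> CloneCountTable:
    """Read a TSV count table written by :func:`write_count_table`.

    Also accepts bare TSVs without header comments (e.g. deposited count
    tables) as long as they carry ``clone_id`` and ``read_count`` columns;
    QC is then zero-filled.  Non-positive or non-integer counts are a hard
    error.
    """
    path = Path(path)
    sample_id = path.stem
    clone_key_mode = "pair"
    qc_dict = None
    counts: dict = {}
    header: Optional[list] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sample_id="):
                    sample_id = body.split("=", 1)[1]
                elif body.startswith("clone_key_mode="):
                    clone_key_mode = body.split("=", 1)[1]
                elif body.startswith("qc="):
                    qc_dict = json.loads(body.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "clone_id" not in header or "read_count" not in header:
                    raise ValueError(f"{path}: missing clone_id/read_count columns")
                continue
            row = dict(zip(header, fields))
            raw = row["read_count"]
            try:
                count = int(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer count {raw!r}") from None
            if count <= 0:
                raise ValueError(f"{path}:{lineno}: counts must be strictly positive, got {count}")
            key = row["clone_id"]
            if key in counts:
                raise ValueError(f"{path}:{lineno}: duplicate clone_id {key!r}")
            counts[key] = count
    if header is None:
        raise ValueError(f"{path}: no header row")
    if qc_dict is not None:
        qc = ExtractionQC.from_dict(qc_dict)
    else:
        total = sum(counts.values())
        qc = ExtractionQC(total_reads=total, both_match=total)
    return CloneCountTable(sample_id=sample_id, counts=counts, qc=qc,
                           clone_key_mode=clone_key_mode)
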