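"""Raw 4N-library FASTQ -> clean inserts.

Reads from the 4N protocol are structured 4 random nt + insert + 4 random nt
+ 3' adapter.  Preprocessing finds the adapter, removes it, strips the four
degenerate bases from each end of the insert, and discards adapter dimers,
low-complexity reads and out-of-range insert lengths, with exact read
accounting (every input read lands in exactly one category).

"Low quality" here means low nucleotide complexity -- homopolymers and di-
or tri-nucleotide tandem repeats -- which is the filter the 4N protocol
requires; an optional mean-Phred threshold is available for real data but
off by default.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

STATE_RAW = "raw"
STATE_TRIMMED = "trimmed"
STATE_NO_ADAPTER = "discarded_no_adapter"
STATE_DIMER = "discarded_dimer"
STATE_LOW_COMPLEXITY = "discarded_low_complexity"
STATE_LENGTH = "discarded_length"
STATE_LOW_QUALITY = "discarded_low_quality"

DISCARD_STATES = (STATE_NO_ADAPTER, STATE_DIMER, STATE_LOW_COMPLEXITY,
                  STATE_LENGTH, STATE_LOW_QUALITY)


@dataclass
class ReadRecord:
    read_id: str
    bases: str
    qualities: str
    state: str = STATE_RAW

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.read_id}: bases/qualities length mismatch")


@dataclass
class TrimParams:
    adapter: str
    min_overlap: int = 5
    max_mismatch_rate: float = 0.1
    strip_5p: int = 4
    strip_3p: int = 4
    min_len: int = 15
    max_len: int = 40
    dimer_max_insert: int = 8
    complexity_threshold: float = 0.8
    min_mean_quality: float | None = None

    def __post_init__(self) -> None:
        if len(self.adapter) < self.min_overlap:
            raise ValueError("adapter must be at least min_overlap long")
        if self.min_overlap < 5:
            raise ValueError("min_overlap must be >= 5")
        if not 0.0 <= self.max_mismatch_rate < 1.0:
            raise ValueError("max_mismatch_rate must be in [0, 1)")


@dataclass
class TrimReport:
    raw_count: int = 0
    kept_count: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in DISCARD_STATES})
    insert_length_sum: int = 0

    @property
    def mean_insert_length(self) -> float:
        return self.insert_length_sum / self.kept_count if self.kept_count else 0.0

    @property
    def conserved(self) -> bool:
        return self.raw_count == self.kept_count + sum(self.discarded.values())

    def to_dict(self) -> dict:
        return {"raw_count": self.raw_count, "kept_count": self.kept_count,
                "mean_insert_length": self.mean_insert_length, **self.discarded}

    def write(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text("".join(f"{k}\t{v}\n" for k, v in self.to_dict().items()))


def find_adapter(bases: str, adapter: str, min_overlap: int = 5,
                 max_mismatch_rate: float = 0.1) -> int | None:
    """Leftmost position where a prefix of `adapter` matches within tolerance.

    The overlap at position i is min(len(adapter), len(bases) - i); a match
    requires overlap >= min_overlap and at most floor(overlap *
    max_mismatch_rate) mismatches.  3'-end partial overlaps are allowed.
    Returns None when the adapter is absent (including for empty reads).
    """
    n = len(bases)
    if n < min_overlap:
        return None
    for i in range(n - min_overlap + 1):
        overlap = min(len(adapter), n - i)
        segment = bases[i:i + overlap]
        if segment == adapter[:overlap]:
            return i
        allowed = int(overlap * max_mismatch_rate)
        if allowed == 0:
            continue
        mm = 0
        ok = True
        for a, b in zip(segment, adapter):
            if a != b:
                mm += 1
                if mm > allowed:
                    ok = False
                    break
        if ok:
            return i
    return None


def _verify_at(bases: str, adapter: str, i: int, min_overlap: int,
               max_mismatch_rate: float) -> bool:
    overlap = min(len(adapter), len(bases) - i)
    if overlap < min_overlap:
        return False
    segment = bases[i:i + overlap]
    if segment == adapter[:overlap]:
        return True
    allowed = int(overlap * max_mismatch_rate)
    mm = 0
    for a, b in zip(segment, adapter):
        if a != b:
            mm += 1
            if mm > allowed:
                return False
    return True


def _find_adapter_fast(bases: str, adapter: str, probe: str, min_overlap: int,
                       max_mismatch_rate: float) -> int | None:
    # Anchor on an exact adapter-prefix occurrence; any read whose adapter
    # carries an error in the probe region falls back to the exhaustive scan.
    i = bases.find(probe)
    if i >= 0 and _verify_at(bases, adapter, i, min_overlap, max_mismatch_rate):
        return i
    return find_adapter(bases, adapter, min_overlap, max_mismatch_rate)


def is_low_complexity(bases: str, coverage_threshold: float = 0.8,
                      max_unit: int = 3) -> bool:
    """True iff a tandem repeat of a 1-3 nt unit covers >= threshold of the read.

    A tandem stretch with unit length k consisting of m positions satisfying
    s[i] == s[i-k] covers m + k characters (partial trailing copies count);
    at least two (possibly partial) copies are required.
    """
    n = len(bases)
    if n == 0:
        raise ValueError("empty sequence")
    for k in range(1, max_unit + 1):
        best = 0
        run = 0
        for i in range(k, n):
            if bases[i] == bases[i - k]:
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
        if best and best + k >= coverage_threshold * n:
            return True
    return False


def _classify(bases: str, qualities: str, adapter_pos: int | None,
              params: TrimParams) -> tuple[str, str, str]:
    """Returns (state, insert, insert_qualities)."""
    if adapter_pos is None:
        if bases and is_low_complexity(bases, params.complexity_threshold):
            return STATE_LOW_COMPLEXITY, "", ""
        return STATE_NO_ADAPTER, "", ""
    if adapter_pos <= params.dimer_max_insert:
        return STATE_DIMER, "", ""
    lo, hi = params.strip_5p, adapter_pos - params.strip_3p
    insert = bases[lo:hi]
    quals = qualities[lo:hi]
    if not (params.min_len <= len(insert) <= params.max_len):
        return STATE_LENGTH, insert, quals
    if is_low_complexity(insert, params.complexity_threshold):
        return STATE_LOW_COMPLEXITY, insert, quals
    if params.min_mean_quality is not None and quals:
        mean_q = sum(ord(c) - 33 for c in quals) / len(quals)
        if mean_q < params.min_mean_quality:
            return STATE_LOW_QUALITY, insert, quals
    return STATE_TRIMMED, insert, quals


def trim_read(record: ReadRecord, params: TrimParams) -> ReadRecord:
    """Trim one raw read: adapter removal, 4+4 degenerate-end stripping,
    dimer/length/complexity classification."""
    if record.state != STATE_RAW:
        raise ValueError(f"read {record.read_id} already processed ({record.state})")
    pos = find_adapter(record.bases, params.adapter, params.min_overlap,
                       params.max_mismatch_rate)
    state, insert, quals = _classify(record.bases, record.qualities, pos, params)
    if state == STATE_TRIMMED:
        return ReadRecord(record.read_id, insert, quals, state)
    return ReadRecord(record.read_id, record.bases, record.qualities, state)


def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(handle_or_path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, bases, qualities); abort with the record index on malformed input."""
    if hasattr(handle_or_path, "read"):
        handle = handle_or_path
        close = False
    else:
        handle = _open_text(handle_or_path)
        close = True
    idx = 0
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            if len(seq) != len(qual):
                raise ValueError(
                    f"FASTQ record {idx}: sequence/quality length mismatch")
            yield title.split()[0] if title else "", seq, qual
            idx += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record {idx}: {exc}") from exc
    finally:
        if close:
            handle.close()


def preprocess_stream(reads: Iterable[tuple[str, str, str]], params: TrimParams,
                      report: TrimReport) -> Iterator[tuple[str, str, str]]:
    """Trim and filter a stream of (id, bases, quals); yields clean inserts.

    Accounting accumulates into `report`; conservation (raw = kept + sum of
    discards) holds once the stream is exhausted.
    """
    adapter = params.adapter
    probe = adapter[:min(len(adapter), 10)]
    min_ov, rate = params.min_overlap, params.max_mismatch_rate
    for rid, bases, quals in reads:
        report.raw_count += 1
        pos = _find_adapter_fast(bases, adapter, probe, min_ov, rate)
        state, insert, iq = _classify(bases, quals, pos, params)
        if state == STATE_TRIMMED:
            report.kept_count += 1
            report.insert_length_sum += len(insert)
            yield rid, insert, iq
        else:
            report.discarded[state] += 1


def preprocess_fastq(fastq_in, params: TrimParams,
                     fastq_out=None) -> TrimReport:
    """Preprocess a FASTQ file; optionally write clean inserts as FASTQ."""
    report = TrimReport()
    stream = preprocess_stream(iter_fastq(fastq_in), params, report)
    if fastq_out is None:
        for _ in stream:
            pass
    else:
        with _open_text(fastq_out, "wt") as out:
            for rid, insert, quals in stream:
                out.write(f"@{rid}\n{insert}\n+\n{quals}\n")
    return report
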