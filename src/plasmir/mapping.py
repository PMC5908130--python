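"""Hierarchical read mapping against an ordered reference cascade.

Clean inserts are aligned gap-free (Hamming distance) against a cascade of
databases -- mature miRNA, transcripts, then genome -- at mismatch tiers
0/1/2.  The first database (in rank order) with any hit claims the read and
within that database only the minimum-mismatch hits are kept; ties are
resolved by fractional 1/n weighting so per-read weight always sums to 1.

Seeding uses an exact k-mer index with k capped at floor(len/3): two
mismatches split a read into three clean segments, the longest of which has
length >= floor(len/3), so every hit within two mismatches shares at least
one exact k-mer with the reference and the seeded search is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequtil import hamming, read_fasta, revcomp

DEFAULT_TIERS = (0, 1, 2)
DEFAULT_SEED_K = 10
MIN_INSERT_LEN = 15


@dataclass
class ReferenceDB:
    """One database of the mapping cascade.

    miRNA databases hold stranded mature sequences and are matched on the
    forward strand only; transcript and genome databases are searched on both
    strands (implemented by also querying the read's reverse complement
    against the forward index).
    """

    name: str
    rank: int
    sequences: dict[str, str]
    both_strands: bool = False
    annotation: pd.DataFrame | None = None
    _indexes: dict = field(default_factory=dict, repr=False, compare=False)
    _exact: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"reference database {self.name!r} is empty")

    @classmethod
    def from_fasta(cls, path, name: str, rank: int, both_strands: bool = False,
                   annotation: pd.DataFrame | None = None) -> "ReferenceDB":
        return cls(name=name, rank=rank, sequences=read_fasta(path),
                   both_strands=both_strands, annotation=annotation)

    def index(self, k: int) -> "KmerIndex":
        if k not in self._indexes:
            self._indexes[k] = build_index(self, k)
        return self._indexes[k]

    def exact_lookup(self) -> dict[str, tuple[str, ...]]:
        """sequence -> feature ids with exactly that sequence (forward strand)."""
        if self._exact is None:
            table: dict[str, list[str]] = {}
            for sid, seq in self.sequences.items():
                table.setdefault(seq, []).append(sid)
            self._exact = {s: tuple(ids) for s, ids in table.items()}
        return self._exact


@dataclass
class ReferenceBundle:
    """Ordered database cascade plus the miRNA feature annotation."""

    mirna: ReferenceDB
    transcripts: ReferenceDB
    genome: ReferenceDB
    annotation: pd.DataFrame

    @property
    def cascade(self) -> list[ReferenceDB]:
        dbs = sorted([self.mirna, self.transcripts, self.genome], key=lambda d: d.rank)
        ranks = [d.rank for d in dbs]
        if ranks != list(range(min(ranks), min(ranks) + len(dbs))):
            raise ValueError("cascade ranks must form a contiguous order")
        return dbs

    def write(self, outdir) -> dict[str, Path]:
        from .sequtil import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna": outdir / "mirna.fa",
            "transcripts": outdir / "transcripts.fa",
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.tsv",
        }
        write_fasta(paths["mirna"], self.mirna.sequences)
        write_fasta(paths["transcripts"], self.transcripts.sequences)
        write_fasta(paths["genome"], self.genome.sequences)
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        return paths

    @classmethod
    def read(cls, refdir) -> "ReferenceBundle":
        refdir = Path(refdir)
        annotation = pd.read_csv(refdir / "annotation.tsv", sep="\t")
        return cls(
            mirna=ReferenceDB.from_fasta(refdir / "mirna.fa", "mirna", 0,
                                         both_strands=False, annotation=annotation),
            transcripts=ReferenceDB.from_fasta(refdir / "transcripts.fa", "transcripts", 1,
                                               both_strands=True),
            genome=ReferenceDB.from_fasta(refdir / "genome.fa", "genome", 2,
                                          both_strands=True),
            annotation=annotation,
        )


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    db_name: str
    feature_id: str
    position: int
    strand: str
    mismatches: int
    n_best_hits: int
    weight: float


class KmerIndex:
    """Exact k-mer -> (sequence id, offset) lookup over forward strands."""

    def __init__(self, k: int, table: dict[str, list[tuple[str, int]]]):
        self.k = k
        self.table = table

    def n_seeds(self) -> int:
        return sum(len(v) for v in self.table.values())


def build_index(db: ReferenceDB, k: int = DEFAULT_SEED_K) -> KmerIndex:
    if k < 1:
        raise ValueError("seed length must be >= 1")
    table: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in db.sequences.items():
        for pos in range(len(seq) - k + 1):
            table.setdefault(seq[pos:pos + k], []).append((sid, pos))
    return KmerIndex(k, table)


def _candidates(query: str, index: KmerIndex, db: ReferenceDB) -> set[tuple[str, int]]:
    L = len(query)
    k = index.k
    out: set[tuple[str, int]] = set()
    table = index.table
    for off in range(L - k + 1):
        for sid, pos in table.get(query[off:off + k], ()):
            start = pos - off
            if start >= 0 and start + L <= len(db.sequences[sid]):
                out.add((sid, start))
    return out


def align_read(insert: str, db: ReferenceDB, max_mm: int = 2, k: int = DEFAULT_SEED_K,
               min_len: int = MIN_INSERT_LEN, read_id: str = "") -> list[AlignmentRecord]:
    """Minimum-mismatch gap-free hits of `insert` in `db`, up to `max_mm`.

    Returns only hits at the minimum achieved mismatch count; an empty list
    if no window matches within `max_mm`.
    """
    if max_mm < 0 or max_mm > 2:
        raise ValueError("max_mm must be in {0, 1, 2}")
    L = len(insert)
    if L < min_len:
        return []
    k_eff = min(k, L // 3)
    index = db.index(k_eff)
    queries = [(insert, "+")]
    if db.both_strands:
        queries.append((revcomp(insert), "-"))
    hits: list[tuple[str, int, str, int]] = []
    best = max_mm
    for query, strand in queries:
        for sid, start in _candidates(query, index, db):
            window = db.sequences[sid][start:start + L]
            mm = hamming(query, window, limit=best)
            if mm <= best:
                hits.append((sid, start, strand, mm))
    if not hits:
        return []
    best = min(h[3] for h in hits)
    best_hits = sorted(h for h in hits if h[3] == best)
    n = len(best_hits)
    return [AlignmentRecord(read_id, db.name, sid, start, strand, mm, n, 1.0 / n)
            for sid, start, strand, mm in best_hits]


def map_hierarchical(insert: str, cascade: Sequence[ReferenceDB],
                     tiers: Sequence[int] = DEFAULT_TIERS, order: str = "db-major",
                     k: int = DEFAULT_SEED_K, read_id: str = "") -> list[AlignmentRecord]:
    """Assign a read within the cascade; empty list means unmapped.

    db-major (default): each database in rank order is searched at the full
    mismatch tolerance and the first one with any hit claims the read.
    tier-major: tiers are the outer loop, so a perfect hit in a later
    database beats a mismatched hit in an earlier one.
    """
    dbs = sorted(cascade, key=lambda d: d.rank)
    max_mm = max(tiers)
    if order == "db-major":
        for db in dbs:
            hits = align_read(insert, db, max_mm=max_mm, k=k, read_id=read_id)
            if hits:
                return hits
    elif order == "tier-major":
        for tier in sorted(tiers):
            for db in dbs:
                hits = align_read(insert, db, max_mm=tier, k=k, read_id=read_id)
                if hits:
                    return hits
    else:
        raise ValueError("order must be 'db-major' or 'tier-major'")
    return []


@dataclass
class MappedSample:
    """Weighted per-feature counts and accounting for one sample."""

    sample_id: str
    feature_weights: dict[str, float] = field(default_factory=dict)
    class_weights: dict[str, float] = field(default_factory=dict)
    n_reads: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    alignments: list[AlignmentRecord] | None = None

    def add(self, hits: list[AlignmentRecord], mirna_db_name: str) -> None:
        self.n_reads += 1
        if not hits:
            self.n_unmapped += 1
            return
        self.n_mapped += 1
        if hits[0].db_name == mirna_db_name:
            for h in hits:
                self.feature_weights[h.feature_id] = (
                    self.feature_weights.get(h.feature_id, 0.0) + h.weight)
        else:
            name = hits[0].db_name
            self.class_weights[name] = self.class_weights.get(name, 0.0) + 1.0
        if self.alignments is not None:
            self.alignments.extend(hits)


def map_reads(inserts: Iterable[tuple[str, str]], cascade: Sequence[ReferenceDB],
              order: str = "db-major", k: int = DEFAULT_SEED_K, sample_id: str = "sample",
              multimap: str = "fractional", store_alignments: bool = False) -> MappedSample:
    """Map a stream of (read_id, insert) pairs and accumulate weighted counts.

    An exact-sequence dictionary on the first database short-circuits the
    common case of an error-free read identical to a mature miRNA (a
    0-mismatch hit in the rank-0 database wins under either cascade order).
    """
    dbs = sorted(cascade, key=lambda d: d.rank)
    first = dbs[0]
    exact = first.exact_lookup()
    result = MappedSample(sample_id=sample_id,
                          alignments=[] if store_alignments else None)
    for rid, insert in inserts:
        ids = exact.get(insert)
        if ids is not None and len(insert) >= MIN_INSERT_LEN:
            if multimap == "first":
                ids = ids[:1]
            w = 1.0 / len(ids)
            hits = [AlignmentRecord(rid, first.name, sid, 0, "+", 0, len(ids), w)
                    for sid in ids]
        else:
            hits = map_hierarchical(insert, dbs, order=order, k=k, read_id=rid)
            if multimap == "first" and len(hits) > 1:
                hits = [AlignmentRecord(rid, hits[0].db_name, hits[0].feature_id,
                                        hits[0].position, hits[0].strand,
                                        hits[0].mismatches, 1, 1.0)]
        result.add(hits, first.name)
    return result


@dataclass
class CountMatrix:
    """Features x samples mapped-read counts with sample metadata.

    `features` holds the miRNA-database rows; reads claimed by later
    databases are aggregated per class in `classes` (one row per database).
    Column sums of features plus classes equal mapped reads per sample.
    `units` is "counts" or "rpm".
    """

    features: pd.DataFrame
    classes: pd.DataFrame
    samples: pd.DataFrame
    units: str = "counts"

    def mapped_totals(self) -> pd.Series:
        return self.features.sum(axis=0) + self.classes.sum(axis=0)

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.features[ids], self.classes[ids],
                           self.samples.loc[ids], self.units)

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(f"{prefix}.features.tsv", sep="\t")
        self.classes.to_csv(f"{prefix}.classes.tsv", sep="\t")
        self.samples.to_csv(f"{prefix}.samples.tsv", sep="\t")

    @classmethod
    def read(cls, prefix, units: str = "counts") -> "CountMatrix":
        return cls(
            features=pd.read_csv(f"{prefix}.features.tsv", sep="\t", index_col=0),
            classes=pd.read_csv(f"{prefix}.classes.tsv", sep="\t", index_col=0),
            samples=pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col=0),
            units=units,
        )


def count_features(mapped: dict[str, MappedSample], mirna_db: ReferenceDB,
                   samples: pd.DataFrame | None = None,
                   class_names: Sequence[str] = ("transcripts", "genome")) -> CountMatrix:
    """Assemble per-sample weighted counts into a CountMatrix."""
    if samples is not None:
        missing = set(samples.index) - set(mapped)
        if missing:
            raise ValueError(f"sample sheet ids without alignments: {sorted(missing)}")
        sample_ids = list(samples.index)
    else:
        sample_ids = list(mapped)
        samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    feat_index = pd.Index(list(mirna_db.sequences), name="feature_id")
    features = pd.DataFrame(0.0, index=feat_index, columns=sample_ids)
    classes = pd.DataFrame(0.0, index=pd.Index(class_names, name="class"),
                           columns=sample_ids)
    for sid in sample_ids:
        ms = mapped[sid]
        if ms.feature_weights:
            features[sid] = pd.Series(ms.feature_weights).reindex(feat_index, fill_value=0.0)
        for cname, w in ms.class_weights.items():
            classes.loc[cname, sid] = w
    return CountMatrix(features, classes, samples)


def summarize_mapping(trim_reports: dict[str, "TrimReport"], cm: CountMatrix,
                      mapped: dict[str, MappedSample] | None = None) -> pd.DataFrame:
    """Per-sample mapping statistics (Table-1 style rows per sample).

    observed = number of miRNA features whose summed weight is >= 1
    ("at least one mapped read" after fractional weighting).
    """
    rows = []
    for sid in cm.features.columns:
        rep = trim_reports.get(sid)
        counts = cm.features[sid]
        mirna_mapped = float(counts.sum())
        class_sums = cm.classes[sid]
        n_unmapped = mapped[sid].n_unmapped if mapped else np.nan
        rows.append({
            "sample_id": sid,
            "raw": rep.raw_count if rep else np.nan,
            "trimmed": rep.kept_count if rep else np.nan,
            "mirna_mapped": mirna_mapped,
            **{f"{c}_mapped": float(class_sums[c]) for c in cm.classes.index},
            "unmapped": n_unmapped,
            "observed": int((counts >= 1.0).sum()),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def table1(summary: pd.DataFrame, sheet: pd.DataFrame,
           detectable_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Group-averaged mapping statistics shaped like the study's summary table.

    One column per (compartment, condition) group; rows are raw reads, trimmed
    reads, miRNA-mapped reads, observed miRNAs and (optionally) detectable
    miRNAs, where `detectable_counts` maps group label -> count.
    """
    merged = summary.join(sheet[["condition", "compartment"]], how="inner")
    out = {}
    for (comp, cond), grp in merged.groupby(["compartment", "condition"]):
        label = f"{comp}_{cond}"
        col = {
            "raw_read_count": grp["raw"].mean(),
            "trimmed_read_count": grp["trimmed"].mean(),
            "total_mirna_mapped": grp["mirna_mapped"].mean(),
            "observed_mirna": grp["observed"].mean(),
        }
        if detectable_counts is not None:
            col["detectable_mirna"] = detectable_counts.get(label, np.nan)
        out[label] = col
    return pd.DataFrame(out)
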