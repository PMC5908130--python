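"""Synthetic three-compartment small-RNA-seq cohorts with ground truth.

The generator emulates the study design this package targets: a case/control
plasma cohort (11 subjects per arm by default) profiled in three compartments
-- whole plasma, the extracellular-vesicle (EV) fraction and EV-depleted
plasma -- where the disease effect is a multiplicative decrease concentrated
in two dense miRNA clusters on two chromosomes, and each miRNA partitions
between EV and EV-depleted plasma according to a per-miRNA EV share with
sequence-dependent sorting biases (3'-terminal U and a GGAG motif raise the
EV share).

Reads follow the 4N degenerate-adapter library structure: four i.i.d. random
nucleotides flank the insert on both sides, followed by the 3' adapter,
truncated to the machine read length.  Substitution errors only -- the
mapping stage works in mismatch (Hamming) tiers, and miRNA-length reads make
indels a secondary concern.  Quality strings are constant: the preprocessing
filter is complexity-based, so quality variation is not the generator's job.

Compartment abundances are additive by construction: whole plasma equals EV
plus EV-depleted abundance per miRNA, and sequencing a compartment at nominal
depth D yields ~D * (compartment share of total RNA) reads, so expected EV +
EV-depleted counts equal expected whole-plasma counts at equal nominal depth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mapping import ReferenceBundle, ReferenceDB
from .sequtil import BASES, decode_rows, encode, random_seq, revcomp, to_dna

COMPARTMENTS = ("whole_plasma", "EV", "EV_depleted")
PHRED_CONST = "I"

# Junk categories emitted by the read simulator.
JUNK_HOMOPOLYMER = -1
JUNK_DINUC = -2
JUNK_DIMER = -3


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    cluster_sizes counts precursor loci per disease cluster; each precursor
    yields a 5p and a 3p mature miRNA (52 and 50 precursors by default, i.e.
    104 + 100 mature cluster members).  effect_log2fc is the log2
    case/control ratio applied to an effect_fraction of each cluster's
    members; the default is a decrease.  partition_alpha/beta shape the
    Beta-distributed per-miRNA EV share, shifted up by sorting_u_boost for
    3'-U miRNAs and by motif_boost when sorting_motif occurs in the mature
    sequence (clamped to [0, 1]).
    """

    n_cases: int = 11
    n_controls: int = 11
    n_mirna: int = 600
    cluster_sizes: tuple[int, int] = (52, 50)
    read_depth: int = 1_000_000
    effect_log2fc: float = -1.0
    effect_fraction: float = 0.8
    partition_alpha: float = 2.0
    partition_beta: float = 3.0
    sorting_u_boost: float = 0.15
    sorting_motif: str = "GGAG"
    motif_boost: float = 0.10
    cluster_abundance_scale: float = 0.2
    error_rate: float = 0.001
    junk_fraction: float = 0.05
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 50
    baseline_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        counts = {"n_cases": self.n_cases, "n_controls": self.n_controls,
                  "n_mirna": self.n_mirna, "read_depth": self.read_depth,
                  "read_length": self.read_length}
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0 (got {value})")
        for name in ("effect_fraction", "error_rate", "junk_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {value})")
        if any(c <= 0 for c in self.cluster_sizes):
            raise ValueError("cluster sizes must be > 0")
        if 2 * sum(self.cluster_sizes) > self.n_mirna:
            raise ValueError("cluster mature miRNAs exceed n_mirna")
        if self.n_mirna > 4 ** 19:
            raise ValueError("n_mirna exceeds the number of distinct 19-mers")
        if self.partition_alpha <= 0 or self.partition_beta <= 0:
            raise ValueError("partition shape parameters must be > 0")
        if self.cluster_abundance_scale <= 0:
            raise ValueError("cluster_abundance_scale must be > 0")
        if not set(to_dna(self.sorting_motif)) <= set(BASES):
            raise ValueError("sorting_motif must be a nucleotide string")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cluster_sizes"] = list(d["cluster_sizes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cluster_sizes" in d:
            d["cluster_sizes"] = tuple(d["cluster_sizes"])
        return cls(**d)


def _rng(config: SimulationConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2 ** 31), *tags])


def _unique_mature_seqs(rng: np.random.Generator, n: int) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(19, 25))
        s = random_seq(rng, length)
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def build_reference_bundle(config: SimulationConfig) -> ReferenceBundle:
    """Generate mature-miRNA, decoy-transcript and genome databases.

    The two disease clusters are laid out contiguously (5p/3p mature pairs
    per precursor) on their own chromosomes; background miRNAs are spread
    round-robin across further chromosomes.  Every mature sequence is
    embedded at its genomic locus; decoy transcripts contain no mature
    sequence on either strand.
    """
    config.validate()
    rng = _rng(config, 0)
    n_a, n_b = config.cluster_sizes
    seqs = _unique_mature_seqs(rng, config.n_mirna)

    entries = []  # (feature_id, seq, chrom, cluster_label)
    i = 0
    for p in range(n_a):
        for arm in ("5p", "3p"):
            entries.append((f"syn-miR-c14-{p + 1:02d}-{arm}", seqs[i], "chr14", "clusterA"))
            i += 1
    for p in range(n_b):
        for arm in ("5p", "3p"):
            entries.append((f"syn-miR-c19-{p + 1:02d}-{arm}", seqs[i], "chr19", "clusterB"))
            i += 1
    background_chroms = [f"chr{c}" for c in range(1, 13)]
    for j in range(i, config.n_mirna):
        chrom = background_chroms[(j - i) % len(background_chroms)]
        entries.append((f"syn-miR-bg-{j - i + 1:03d}-5p", seqs[j], chrom, "none"))

    chrom_features: dict[str, list[tuple[str, str, str]]] = {}
    for fid, seq, chrom, label in entries:
        chrom_features.setdefault(chrom, []).append((fid, seq, label))

    genome: dict[str, str] = {}
    ann_rows = []
    for chrom in sorted(chrom_features, key=lambda c: (len(c), c)):
        parts: list[str] = []
        pos = 0
        for fid, seq, label in chrom_features[chrom]:
            spacer = random_seq(rng, int(rng.integers(40, 121)))
            parts.append(spacer)
            pos += len(spacer)
            parts.append(seq)
            ann_rows.append({"feature_id": fid, "chrom": chrom, "start": pos,
                             "end": pos + len(seq), "strand": "+",
                             "cluster_label": label})
            pos += len(seq)
        parts.append(random_seq(rng, int(rng.integers(40, 121))))
        genome[chrom] = "".join(parts)

    mature = {fid: seq for fid, seq, _, _ in entries}
    annotation = pd.DataFrame(ann_rows)

    transcripts: dict[str, str] = {}
    t = 0
    while len(transcripts) < 20:
        cand = random_seq(rng, int(rng.integers(200, 501)))
        rc = revcomp(cand)
        if any(m in cand or m in rc for m in mature.values()):
            t += 1
            if t > 200:
                raise RuntimeError("could not generate clean decoy transcripts")
            continue
        transcripts[f"syn-tx-{len(transcripts) + 1:02d}"] = cand

    return ReferenceBundle(
        mirna=ReferenceDB("mirna", 0, mature, both_strands=False, annotation=annotation),
        transcripts=ReferenceDB("transcripts", 1, transcripts, both_strands=True),
        genome=ReferenceDB("genome", 2, genome, both_strands=True),
        annotation=annotation,
    )


def sample_truth(config: SimulationConfig, bundle: ReferenceBundle) -> pd.DataFrame:
    """Draw the per-miRNA generative truth table.

    baseline_abundance: log-normal relative concentration in whole plasma,
    normalized to sum to 1.  ev_share: Beta(partition_alpha, partition_beta)
    plus the sequence-sorting boosts, clamped to [0, 1].  disease_multiplier:
    2**effect_log2fc for an effect_fraction of each cluster's members, 1
    elsewhere.
    """
    config.validate()
    rng = _rng(config, 1)
    ann = bundle.annotation.set_index("feature_id")
    fids = list(bundle.mirna.sequences)
    n = len(fids)
    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n)
    # Placenta-derived cluster miRNAs are minor species in plasma: scale
    # their baselines down so the clusters stay a small share of the pool
    # (plain RPM fold changes would otherwise be compositionally distorted).
    labels_arr = ann.loc[fids, "cluster_label"].to_numpy()
    baseline[labels_arr != "none"] *= config.cluster_abundance_scale
    baseline /= baseline.sum()
    ev_share = rng.beta(config.partition_alpha, config.partition_beta, size=n)
    motif = to_dna(config.sorting_motif)
    seqs = [bundle.mirna.sequences[f] for f in fids]
    ends_u = np.array([s.endswith("T") for s in seqs])
    has_motif = np.array([motif in s for s in seqs])
    ev_share = np.clip(ev_share + config.sorting_u_boost * ends_u
                       + config.motif_boost * has_motif, 0.0, 1.0)

    multiplier = np.ones(n)
    labels = ann.loc[fids, "cluster_label"].to_numpy()
    for cluster in ("clusterA", "clusterB"):
        members = np.flatnonzero(labels == cluster)
        k = int(round(config.effect_fraction * len(members)))
        chosen = rng.choice(members, size=k, replace=False)
        multiplier[chosen] = 2.0 ** config.effect_log2fc

    return pd.DataFrame({
        "feature_id": fids,
        "sequence": seqs,
        "baseline_abundance": baseline,
        "ev_share": ev_share,
        "disease_multiplier": multiplier,
        "cluster_label": labels,
        "chrom": ann.loc[fids, "chrom"].to_numpy(),
        "start": ann.loc[fids, "start"].to_numpy(),
    }).set_index("feature_id")


def compartment_abundance(truth: pd.DataFrame, compartment: str,
                          condition: str) -> np.ndarray:
    """Unnormalized per-miRNA abundance for one compartment and condition.

    EV = baseline * ev_share * multiplier, EV_depleted = baseline *
    (1 - ev_share) * multiplier, whole plasma = their sum; the multiplier
    applies to case subjects only.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    if condition not in ("case", "control"):
        raise ValueError(f"unknown condition {condition!r}")
    base = truth["baseline_abundance"].to_numpy().copy()
    if condition == "case":
        base = base * truth["disease_multiplier"].to_numpy()
    share = truth["ev_share"].to_numpy()
    if compartment == "EV":
        return base * share
    if compartment == "EV_depleted":
        return base * (1.0 - share)
    return base


def _whole_total(truth: pd.DataFrame, condition: str) -> float:
    return float(compartment_abundance(truth, "whole_plasma", condition).sum())


@dataclass
class SimulatedSample:
    sample_id: str
    fastq_text: str
    true_counts: pd.Series
    n_junk: int
    read_labels: np.ndarray | None = None  # feature index or negative junk code


def simulate_sample_reads(truth: pd.DataFrame, config: SimulationConfig,
                          compartment: str, condition: str, sample_id: str,
                          depth: int | None = None,
                          rng: np.random.Generator | None = None,
                          return_labels: bool = False) -> SimulatedSample:
    """Simulate one sample's raw FASTQ (4N + insert + 4N + adapter reads).

    Reads are drawn multinomially from the compartment's abundance
    distribution; the effective read number for a fractionated compartment is
    binomially thinned by the compartment's share of total plasma RNA.  A
    junk_fraction of reads is replaced by homopolymer / dinucleotide-repeat
    sequences or pure adapter dimers.
    """
    depth = config.read_depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if rng is None:
        rng = _rng(config, 2)
    abundance = compartment_abundance(truth, compartment, condition)
    scale = abundance.sum() / _whole_total(truth, condition)

    n_junk = int(rng.binomial(depth, config.junk_fraction))
    n_real = int(rng.binomial(depth - n_junk, scale))
    counts = rng.multinomial(n_real, abundance / abundance.sum())

    L = config.read_length
    adapter_idx = encode(to_dna(config.adapter))
    n_total = n_real + n_junk
    labels = np.empty(n_total, dtype=np.int64)
    arr = np.zeros((n_total, L), dtype=np.uint8)  # pad base = A

    seq_idx = {f: encode(s) for f, s in zip(truth.index, truth["sequence"])}
    row = 0
    for fi, (fid, c) in enumerate(zip(truth.index, counts)):
        if c == 0:
            continue
        block = arr[row:row + c]
        m = len(seq_idx[fid])
        # Layout 4N | insert | 4N | adapter, truncated at the read length.
        block[:, :min(4, L)] = rng.integers(0, 4, size=(c, min(4, L)), dtype=np.uint8)
        ins_hi = min(4 + m, L)
        if ins_hi > 4:
            block[:, 4:ins_hi] = seq_idx[fid][:ins_hi - 4]
        n2_hi = min(8 + m, L)
        if n2_hi > 4 + m:
            block[:, 4 + m:n2_hi] = rng.integers(0, 4, size=(c, n2_hi - (4 + m)),
                                                 dtype=np.uint8)
        tail = L - (8 + m)
        if tail > 0:
            block[:, 8 + m:8 + m + min(tail, len(adapter_idx))] = \
                adapter_idx[:min(tail, len(adapter_idx))]
        labels[row:row + c] = fi
        row += c

    junk_types = rng.integers(0, 3, size=n_junk)
    dimer = np.resize(adapter_idx, L)
    for j, jt in enumerate(junk_types):
        r = row + j
        if jt == 0:
            arr[r, :] = rng.integers(0, 4)
            labels[r] = JUNK_HOMOPOLYMER
        elif jt == 1:
            pair = rng.integers(0, 4, size=2)
            arr[r, 0::2] = pair[0]
            arr[r, 1::2] = pair[1]
            labels[r] = JUNK_DINUC
        else:
            arr[r, :] = dimer
            labels[r] = JUNK_DIMER

    if config.error_rate > 0:
        mask = rng.random(arr.shape) < config.error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        arr[mask] = (arr[mask] + shifts) % 4

    perm = rng.permutation(n_total)
    arr = arr[perm]
    labels = labels[perm]

    qual = PHRED_CONST * L
    seqs = decode_rows(arr)
    fastq = "".join(f"@{sample_id}:r{i}\n{s}\n+\n{qual}\n"
                    for i, s in enumerate(seqs))
    true_counts = pd.Series(counts, index=truth.index, name=sample_id)
    return SimulatedSample(sample_id, fastq, true_counts, n_junk,
                           labels if return_labels else None)


def _subject_table(config: SimulationConfig) -> pd.DataFrame:
    rows = [{"subject_id": f"case{i + 1:02d}", "condition": "case"}
            for i in range(config.n_cases)]
    rows += [{"subject_id": f"ctrl{i + 1:02d}", "condition": "control"}
             for i in range(config.n_controls)]
    return pd.DataFrame(rows)


def simulate_count_matrix(config: SimulationConfig, truth: pd.DataFrame,
                          compartments: tuple[str, ...] = COMPARTMENTS,
                          depth: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mapped-count-level cohort simulation (no reads, no sequencing errors).

    Draws the same multinomial counts a perfect preprocessing + mapping run
    would recover from the simulated reads.  Returns (counts features x
    samples, sample sheet).  Used for statistical calibration at depths where
    per-read simulation adds nothing but runtime.
    """
    config.validate()
    depth = config.read_depth if depth is None else depth
    subjects = _subject_table(config)
    counts = {}
    sheet_rows = []
    for ci, comp in enumerate(compartments):
        for si, subj in subjects.iterrows():
            rng = _rng(config, 3, ci, si)
            cond = subj["condition"]
            abundance = compartment_abundance(truth, comp, cond)
            scale = abundance.sum() / _whole_total(truth, cond)
            n_assigned = depth - int(rng.binomial(depth, config.junk_fraction))
            n_real = int(rng.binomial(n_assigned, scale))
            sample_id = f"{subj['subject_id']}_{comp}"
            counts[sample_id] = rng.multinomial(n_real, abundance / abundance.sum())
            sheet_rows.append({"sample_id": sample_id,
                               "subject_id": subj["subject_id"],
                               "condition": cond, "compartment": comp})
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    counts_df = pd.DataFrame(counts, index=truth.index)
    return counts_df, sheet


def simulate_cohort(config: SimulationConfig, outdir,
                    compartments: tuple[str, ...] = COMPARTMENTS,
                    overwrite: bool = False, write_reads: bool = True) -> dict:
    """Write a full cohort: references, FASTQ per sample/compartment, sample
    sheet, truth tables and a config echo.  Fully reproducible from the seed.
    """
    config.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {outdir} exists; pass overwrite=True")
    (outdir / "fastq").mkdir(parents=True, exist_ok=True)

    bundle = build_reference_bundle(config)
    ref_paths = bundle.write(outdir / "references")
    truth = sample_truth(config, bundle)
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    config.to_yaml(outdir / "config.yaml")

    subjects = _subject_table(config)
    sheet_rows = []
    true_counts = {}
    junk_counts = {}
    for ci, comp in enumerate(compartments):
        for si, subj in subjects.iterrows():
            sample_id = f"{subj['subject_id']}_{comp}"
            fastq_path = outdir / "fastq" / f"{sample_id}.fastq"
            rng = _rng(config, 3, ci, si)
            sim = simulate_sample_reads(truth, config, comp, subj["condition"],
                                        sample_id, rng=rng)
            if write_reads:
                fastq_path.write_text(sim.fastq_text)
            true_counts[sample_id] = sim.true_counts
            junk_counts[sample_id] = sim.n_junk
            sheet_rows.append({
                "sample_id": sample_id, "subject_id": subj["subject_id"],
                "condition": subj["condition"], "compartment": comp,
                "fastq_path": str(fastq_path),
            })
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t")
    tc = pd.DataFrame(true_counts)
    tc.index.name = "feature_id"
    tc.to_csv(outdir / "true_counts.tsv", sep="\t")
    pd.Series(junk_counts, name="n_junk").rename_axis("sample_id") \
        .to_csv(outdir / "junk_counts.tsv", sep="\t")
    return {"outdir": outdir, "bundle": bundle, "truth": truth, "sheet": sheet,
            "true_counts": tc, "references": ref_paths}


@dataclass
class QPCRResult:
    ct: pd.DataFrame       # tidy: sample_id, feature_id, ct
    sheet: pd.DataFrame    # sample_id -> condition
    normalizer_id: str


def simulate_qpcr(truth: pd.DataFrame, config: SimulationConfig,
                  features: list[str] | None = None,
                  normalizer_id: str | None = None, slope: float = 1.0,
                  intercept: float = 8.0, noise_sd: float = 0.25,
                  censor_ct: float = 40.0) -> QPCRResult:
    """Simulate a qPCR Ct table: Ct = intercept - slope * log2(abundance) + noise.

    The normalizer is an unaffected (multiplier 1, unclustered) miRNA --
    by default the most abundant one -- mirroring the use of a stable
    endogenous control.  Zero abundance is censored at `censor_ct`.
    """
    config.validate()
    rng = _rng(config, 4)
    if normalizer_id is None:
        stable = truth[(truth["disease_multiplier"] == 1.0)
                       & (truth["cluster_label"] == "none")]
        if stable.empty:
            raise ValueError("no unaffected miRNA available as normalizer")
        normalizer_id = stable["baseline_abundance"].idxmax()
    if truth.loc[normalizer_id, "disease_multiplier"] != 1.0:
        raise ValueError("normalizer must have disease_multiplier 1")
    if features is None:
        features = list(truth.index[:8])
    assayed = list(dict.fromkeys(list(features) + [normalizer_id]))

    subjects = _subject_table(config)
    rows = []
    for _, subj in subjects.iterrows():
        abundance = compartment_abundance(truth, "whole_plasma", subj["condition"])
        rel = pd.Series(abundance / abundance.sum(), index=truth.index)
        for fid in assayed:
            a = rel[fid]
            if a <= 0:
                ct = censor_ct
            else:
                ct = intercept - slope * np.log2(a) + rng.normal(0.0, noise_sd)
            rows.append({"sample_id": subj["subject_id"], "feature_id": fid,
                         "ct": ct})
    ct = pd.DataFrame(rows)
    sheet = subjects.rename(columns={"subject_id": "sample_id"}).set_index("sample_id")
    return QPCRResult(ct=ct, sheet=sheet, normalizer_id=normalizer_id)
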