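"""EV / EV-depleted partition and sequence-feature analysis.

Quantifies each miRNA's partition between the extracellular-vesicle fraction
and EV-depleted plasma from matched subjects, and tests whether
EV-enriched and EV-depleted-enriched miRNAs differ in sequence features --
3'-terminal nucleotide, overall composition, or short motifs (e.g. the
exosomal sorting motif GGAG).

Partition estimates need the two compartments on a comparable scale: with
each subject's EV and EV-depleted libraries normalized jointly (a single
per-subject factor), the ratio of means estimates the true EV share, because
both libraries sample the same underlying plasma pool.  Sequences are stored
as DNA internally; motifs and composition are reported in the RNA alphabet.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .sequtil import to_dna, to_rna

_TINY_P = np.finfo(float).tiny

EV_ENRICHED = "EV_enriched"
DEPLETED_ENRICHED = "depleted_enriched"
NEUTRAL = "neutral"


def paired_compartment_counts(counts: pd.DataFrame, sheet: pd.DataFrame,
                              scale_to: float = 1e6
                              ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Jointly normalized EV / EV-depleted matrices for matched subjects.

    Each subject's EV and EV-depleted counts are scaled by one shared factor
    (scale_to / combined total), preserving the within-subject EV:depleted
    ratio that separate per-library RPM would destroy.  Returns (ev, dep)
    matrices indexed by subject plus the subject list.
    """
    ev_sheet = sheet[sheet["compartment"] == "EV"]
    dep_sheet = sheet[sheet["compartment"] == "EV_depleted"]
    ev_by_subj = dict(zip(ev_sheet["subject_id"], ev_sheet.index))
    dep_by_subj = dict(zip(dep_sheet["subject_id"], dep_sheet.index))
    subjects = sorted(set(ev_by_subj) & set(dep_by_subj))
    if not subjects:
        raise ValueError("no subjects with both EV and EV-depleted samples")
    ev = counts[[ev_by_subj[s] for s in subjects]].copy()
    dep = counts[[dep_by_subj[s] for s in subjects]].copy()
    ev.columns = dep.columns = subjects
    total = ev.sum(axis=0) + dep.sum(axis=0)
    factor = scale_to / total
    return ev * factor, dep * factor, subjects


def partition_table(ev: pd.DataFrame, dep: pd.DataFrame,
                    fold_threshold: float = 1.5, alpha: float = 0.05
                    ) -> pd.DataFrame:
    """Per-miRNA EV partition from subject-matched compartment abundances.

    Inputs are features x subjects matrices on a compartment-comparable
    scale (see paired_compartment_counts).  The paired statistic is the
    per-subject log2(x + 1) difference (EV minus depleted) tested against
    zero; ev_share_hat = mean_EV / (mean_EV + mean_depleted).  Enrichment
    classes mirror the differential-abundance rule: |mean difference| >=
    log2(fold_threshold) with p <= alpha, the sign (and the consistent side
    of ev_share_hat = 0.5) choosing the compartment.
    """
    if list(ev.columns) != list(dep.columns):
        raise ValueError("EV and depleted matrices must share subject columns")
    if ev.shape[1] < 2:
        raise ValueError("need at least 2 matched subjects")
    diffs = np.log2(ev.to_numpy(dtype=float) + 1.0) - np.log2(dep.to_numpy(dtype=float) + 1.0)
    mean_diff = diffs.mean(axis=1)
    res = stats.ttest_1samp(diffs, 0.0, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    p[bad & (np.abs(mean_diff) < 1e-12)] = 1.0
    p[bad & (np.abs(mean_diff) >= 1e-12)] = _TINY_P
    p = np.clip(p, _TINY_P, 1.0)
    mean_ev = ev.mean(axis=1).to_numpy()
    mean_dep = dep.mean(axis=1).to_numpy()
    denom = mean_ev + mean_dep
    with np.errstate(invalid="ignore"):
        share = np.where(denom > 0, mean_ev / np.where(denom > 0, denom, 1.0), np.nan)
    thr = np.log2(fold_threshold)
    cls = np.full(len(ev.index), NEUTRAL, dtype=object)
    cls[(mean_diff >= thr) & (p <= alpha) & (share > 0.5)] = EV_ENRICHED
    cls[(mean_diff <= -thr) & (p <= alpha) & (share < 0.5)] = DEPLETED_ENRICHED
    return pd.DataFrame({
        "mean_rpm_ev": mean_ev,
        "mean_rpm_depleted": mean_dep,
        "ev_share_hat": share,
        "log2_ratio": mean_diff,
        "p_value": p,
        "enrichment_class": cls,
    }, index=ev.index.rename("feature_id"))


def terminal_nt_composition(sequences: list[str] | pd.Series) -> pd.DataFrame:
    """Counts and fractions of A/C/G/U at the 3'-terminal position."""
    seqs = [to_dna(s) for s in sequences]
    if not seqs:
        raise ValueError("empty sequence set")
    counts = {b: 0 for b in "ACGT"}
    for s in seqs:
        counts[s[-1]] += 1
    total = len(seqs)
    return pd.DataFrame({
        "base": [to_rna(b) for b in "ACGT"],
        "count": [counts[b] for b in "ACGT"],
        "fraction": [counts[b] / total for b in "ACGT"],
    }).set_index("base")


def terminal_u_test(set_a: list[str], set_b: list[str], base: str = "U",
                    alternative: str = "larger") -> tuple[float, float, float]:
    """Two-proportion test of the 3'-terminal `base` fraction, set A vs B."""
    b = to_dna(base)
    ka = sum(1 for s in set_a if to_dna(s).endswith(b))
    kb = sum(1 for s in set_b if to_dna(s).endswith(b))
    na, nb = len(set_a), len(set_b)
    if na == 0 or nb == 0:
        raise ValueError("both sets must be non-empty")
    stat, p = proportions_ztest([ka, kb], [na, nb], alternative=alternative)
    if not np.isfinite(p):  # degenerate (all-or-none in both sets)
        p = 1.0 if ka / na <= kb / nb else 0.5
    return ka / na, kb / nb, float(p)


def composition_profile(sequences: list[str] | pd.Series
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Overall and positional A/C/G/U fractions (5'-aligned)."""
    seqs = [to_dna(s) for s in sequences]
    if not seqs:
        raise ValueError("empty sequence set")
    max_len = max(len(s) for s in seqs)
    pos_counts = np.zeros((max_len, 4))
    order = {b: i for i, b in enumerate("ACGT")}
    totals = np.zeros(4)
    for s in seqs:
        for i, b in enumerate(s):
            pos_counts[i, order[b]] += 1
            totals[order[b]] += 1
    overall = pd.Series(totals / totals.sum(),
                        index=[to_rna(b) for b in "ACGT"], name="fraction")
    cover = pos_counts.sum(axis=1, keepdims=True)
    positional = pd.DataFrame(pos_counts / np.where(cover > 0, cover, 1.0),
                              columns=[to_rna(b) for b in "ACGT"])
    positional.index.name = "position"
    return overall, positional


def composition_chi2(set_a: list[str], set_b: list[str]) -> float:
    """Chi-square p for overall base-composition difference between two sets."""
    ca = np.zeros(4)
    cb = np.zeros(4)
    order = {b: i for i, b in enumerate("ACGT")}
    for s in set_a:
        for b in to_dna(s):
            ca[order[b]] += 1
    for s in set_b:
        for b in to_dna(s):
            cb[order[b]] += 1
    _, p, _, _ = stats.chi2_contingency(np.vstack([ca, cb]))
    return float(p)


def motif_enrichment(set_a: list[str], set_b: list[str], k: int = 4,
                     fixed_motifs: tuple[str, ...] = ("GGAG",),
                     q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-motif presence/absence enrichment between two sequence sets.

    Motifs are all k-mers occurring in either set plus any fixed motifs;
    containment is counted once per sequence (a 2x2 Fisher design).  A motif
    is flagged enriched when its BH q-value is <= q_threshold.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    a = [to_dna(s) for s in set_a]
    b = [to_dna(s) for s in set_b]
    motifs: set[str] = {to_dna(m) for m in fixed_motifs}
    for s in a + b:
        for i in range(len(s) - k + 1):
            motifs.add(s[i:i + k])
    rows = []
    na, nb = len(a), len(b)
    for m in sorted(motifs):
        ka = sum(1 for s in a if m in s)
        kb = sum(1 for s in b if m in s)
        table = [[ka, na - ka], [kb, nb - kb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"motif": to_rna(m), "count_a": ka, "n_a": na,
                     "count_b": kb, "n_b": nb, "odds_ratio": odds, "p_value": p})
    out = pd.DataFrame(rows).set_index("motif")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["q_value"] <= q_threshold
    return out.sort_values("p_value")
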