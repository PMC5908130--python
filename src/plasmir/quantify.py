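"""Normalization, detectability filtering and differential abundance.

Counts are scaled to reads per million (RPM); a feature is "detectable" in a
group when it has at least `min_reads` mapped reads in at least 70% of that
group's samples, and the differential-abundance universe is the union of the
per-group detectable sets (their intersection and group-unique remainders
reproduce the shared-plus-unique decomposition used when reporting
detectable totals).

The differential test works on x = log2(RPM + 1): the effect estimate is the
difference of group means (log2 fold change, case minus control) and the
p-value comes from a two-sided Welch unequal-variance t-test (the default) or
a label-permutation test.  A feature is flagged significant when |log2FC| >=
log2(fold_threshold) and the raw p-value is at or below the alpha threshold;
Benjamini-Hochberg q-values are reported alongside but do not drive the flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import CountMatrix

_TINY_P = np.finfo(float).tiny


def rpm_normalize(cm: CountMatrix, denominator: str = "all_mapped") -> CountMatrix:
    """Reads-per-million scaling; denominator per sample is either all mapped
    reads (features + classes; their RPMs then sum to 1e6 exactly) or
    miRNA-mapped reads only."""
    if denominator == "all_mapped":
        totals = cm.mapped_totals()
    elif denominator == "mirna_mapped":
        totals = cm.features.sum(axis=0)
    else:
        raise ValueError("denominator must be 'all_mapped' or 'mirna_mapped'")
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    factor = 1e6 / totals
    return CountMatrix(cm.features * factor, cm.classes * factor,
                       cm.samples, units="rpm")


@dataclass
class DetectabilityResult:
    groups: dict[str, set]
    shared: set
    unique: dict[str, set]

    @property
    def universe(self) -> set:
        out: set = set()
        for s in self.groups.values():
            out |= s
        return out

    def counts(self) -> dict[str, int]:
        d = {f"{g}": len(s) for g, s in self.groups.items()}
        d["shared"] = len(self.shared)
        d.update({f"unique_{g}": len(s) for g, s in self.unique.items()})
        d["universe"] = len(self.universe)
        return d


def detectable_features(counts: pd.DataFrame, sheet: pd.DataFrame,
                        min_reads: float = 10, min_fraction: float = 0.7,
                        scope: str = "per_group", group_col: str = "condition",
                        compartment: str | None = None) -> DetectabilityResult:
    """Detectable = count >= min_reads in >= ceil(min_fraction * n) samples.

    The threshold is inclusive (>= 10 reads).  With scope="per_group" the
    rule is applied within each level of `group_col` (case/control by
    default) and the result carries per-group sets plus their shared /
    group-unique decomposition; scope="pooled" applies it across all samples.
    """
    if compartment is not None:
        sheet = sheet[sheet["compartment"] == compartment]
    counts = counts[sheet.index]
    if scope == "pooled":
        groups = {"pooled": _detect_set(counts, min_reads, min_fraction)}
    elif scope == "per_group":
        groups = {}
        for g, sub in sheet.groupby(group_col):
            if len(sub) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
            groups[str(g)] = _detect_set(counts[sub.index], min_reads, min_fraction)
    else:
        raise ValueError("scope must be 'per_group' or 'pooled'")
    names = list(groups)
    shared = set.intersection(*groups.values()) if groups else set()
    unique = {g: groups[g] - set.union(*(groups[h] for h in names if h != g))
              if len(names) > 1 else set() for g in names}
    return DetectabilityResult(groups=groups, shared=shared, unique=unique)


def _detect_set(counts: pd.DataFrame, min_reads: float, min_fraction: float) -> set:
    need = math.ceil(min_fraction * counts.shape[1])
    ok = (counts >= min_reads).sum(axis=1) >= need
    return set(counts.index[ok])


def _welch(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        # degenerate (constant) rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # Zero variance in both groups: p = 1 for equal means, else effectively 0.
    bad = ~np.isfinite(p)
    if bad.any():
        diff = case.mean(axis=1) - ctrl.mean(axis=1)
        p[bad & (np.abs(diff) < 1e-12)] = 1.0
        p[bad & (np.abs(diff) >= 1e-12)] = _TINY_P
    return np.clip(p, _TINY_P, 1.0)


def _permutation(case: np.ndarray, ctrl: np.ndarray, n_permutations: int,
                 rng: np.random.Generator) -> np.ndarray:
    x = np.hstack([case, ctrl])
    n_case = case.shape[1]
    n = x.shape[1]
    obs = np.abs(case.mean(axis=1) - ctrl.mean(axis=1))
    exceed = np.zeros(x.shape[0])
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        d = x[:, idx[:n_case]].mean(axis=1) - x[:, idx[n_case:]].mean(axis=1)
        exceed += np.abs(d) >= obs - 1e-12
    return (1.0 + exceed) / (n_permutations + 1.0)


def differential_test(rpm: pd.DataFrame, sheet: pd.DataFrame,
                      compartment: str | None = None,
                      features: set | list | None = None,
                      fold_threshold: float = 1.5, alpha: float = 0.05,
                      test: str = "welch", n_permutations: int = 10000,
                      seed: int = 0,
                      annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Case-vs-control differential abundance on log2(RPM + 1)."""
    if compartment is not None:
        sheet = sheet[sheet["compartment"] == compartment]
    rpm = rpm[sheet.index]
    if features is not None:
        rpm = rpm.loc[sorted(set(features) & set(rpm.index))]
    case_ids = sheet.index[sheet["condition"] == "case"]
    ctrl_ids = sheet.index[sheet["condition"] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    x = np.log2(rpm.to_numpy(dtype=float) + 1.0)
    case = x[:, [rpm.columns.get_loc(c) for c in case_ids]]
    ctrl = x[:, [rpm.columns.get_loc(c) for c in ctrl_ids]]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    if test == "welch":
        p = _welch(case, ctrl)
    elif test == "permutation":
        p = _permutation(case, ctrl, n_permutations, np.random.default_rng(seed))
    else:
        raise ValueError("test must be 'welch' or 'permutation'")
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame({
        "feature_id": rpm.index,
        "compartment": compartment if compartment is not None else "all",
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "mean_rpm_case": rpm[case_ids].mean(axis=1).to_numpy(),
        "mean_rpm_control": rpm[ctrl_ids].mean(axis=1).to_numpy(),
    }).set_index("feature_id")
    out["significant"] = ((np.abs(out["log2fc"]) >= np.log2(fold_threshold))
                          & (out["p_value"] <= alpha))
    if annotation is not None:
        ann = annotation.set_index("feature_id") if "feature_id" in annotation else annotation
        out["cluster_label"] = ann["cluster_label"].reindex(out.index).fillna("none")
    return out


def mean_centred_profiles(rpm: pd.DataFrame,
                          features: list | None = None) -> pd.DataFrame:
    """Row-centred log2(RPM + 1) expression profiles (heatmap input)."""
    if features is not None:
        rpm = rpm.loc[list(features)]
    x = np.log2(rpm + 1.0)
    return x.sub(x.mean(axis=1), axis=0)


def cluster_summary(de: pd.DataFrame, annotation: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster differential-abundance summary plus a chromosome track.

    Features missing from the annotation are counted under "none".  The
    fraction column apportions all significant calls across clusters (sums
    to 1 when any call is significant).
    """
    ann = annotation.set_index("feature_id") if "feature_id" in annotation else annotation
    labels = ann["cluster_label"].reindex(de.index).fillna("none")
    n_sig_total = int(de["significant"].sum())
    rows = []
    for cluster in ("clusterA", "clusterB", "none"):
        sub = de[labels == cluster]
        n_sig = int(sub["significant"].sum())
        rows.append({
            "cluster_label": cluster,
            "n_features": len(sub),
            "n_significant": n_sig,
            "n_significant_negative": int((sub["significant"] & (sub["log2fc"] < 0)).sum()),
            "fraction_of_significant": n_sig / n_sig_total if n_sig_total else 0.0,
        })
    summary = pd.DataFrame(rows).set_index("cluster_label")
    track = pd.DataFrame({
        "feature_id": de.index,
        "chrom": ann["chrom"].reindex(de.index).to_numpy(),
        "position": ann["start"].reindex(de.index).to_numpy(),
        "log2fc": de["log2fc"].to_numpy(),
        "significant": de["significant"].to_numpy(),
        "cluster_label": labels.to_numpy(),
    }).set_index("feature_id")
    return summary, track


def qpcr_concordance(de: pd.DataFrame, ct: pd.DataFrame, sheet: pd.DataFrame,
                     normalizer_id: str) -> tuple[pd.DataFrame, int]:
    """Compare sequencing log2FC with delta-delta-Ct fold changes.

    deltaCt(s, f) = Ct(s, f) - Ct(s, normalizer); qPCR log2FC(f) =
    -(mean case deltaCt - mean control deltaCt).  Returns the paired table
    and the number of sign-concordant features.
    """
    wide = ct.pivot(index="sample_id", columns="feature_id", values="ct")
    if normalizer_id not in wide.columns or wide[normalizer_id].isna().any():
        raise ValueError(f"normalizer {normalizer_id!r} missing in some samples")
    dct = wide.sub(wide[normalizer_id], axis=0)
    cond = sheet["condition"].reindex(wide.index)
    ddct = dct[cond == "case"].mean(axis=0) - dct[cond == "control"].mean(axis=0)
    qpcr_lfc = -ddct.drop(index=normalizer_id)
    common = [f for f in qpcr_lfc.index if f in de.index]
    table = pd.DataFrame({
        "seq_log2fc": de.loc[common, "log2fc"],
        "qpcr_log2fc": qpcr_lfc[common],
    })
    table["sign_agree"] = np.sign(table["seq_log2fc"]) == np.sign(table["qpcr_log2fc"])
    return table, int(table["sign_agree"].sum())
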