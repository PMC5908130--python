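"""Published summary-table fixtures and run reporting.

The package ships the study's printed table of differentially abundant
miRNAs (DEmiRNAs) across whole plasma, EV and EV-depleted plasma as a
machine-readable fixture, transcribed once from the article text with a
stored checksum.  The loader normalizes typographic Unicode (non-breaking
hyphens in miRNA ids, minus signs in numbers) and validates the table
against its own significance criterion: every printed (log2FC, p) pair must
satisfy |log2FC| >= log2(1.5) and p <= 0.05.

`render_report` assembles the pipeline's stage outputs into one markdown
document without recomputing anything.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

COMPARTMENT_KEYS = ("whole_plasma", "EV", "EV_depleted")
_PAIR_COLS = {
    "whole_plasma": ("whole_plasma_log2fc", "whole_plasma_p"),
    "EV": ("ev_log2fc", "ev_p"),
    "EV_depleted": ("ev_depleted_log2fc", "ev_depleted_p"),
}

# U+2010 hyphen, U+2011 non-breaking hyphen, U+2212 minus sign
_ASCII = str.maketrans({"‐": "-", "‑": "-", "−": "-"})


def _fixture_path() -> Path:
    return Path(resources.files("plasmir") / "data" / "demirna_table.tsv")


def load_demirna_table(path=None, fold_threshold: float = 1.5,
                       alpha: float = 0.05,
                       verify_checksum: bool | None = None) -> pd.DataFrame:
    """Load the DEmiRNA fixture, validating its internal invariants.

    Each row must carry at least one (log2fc, p) compartment pair, every
    pair must satisfy the significance criterion, and ids must be unique.
    Ids are hyphen-normalized to ASCII; the verbatim id is kept in
    `mirna_id_original`.
    """
    if path is None:
        path = _fixture_path()
        if verify_checksum is None:
            verify_checksum = True
    if verify_checksum:
        expected = (Path(resources.files("plasmir") / "data" / "demirna_table.sha256")
                    .read_text().strip())
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        if digest != expected:
            raise ValueError("DEmiRNA fixture checksum mismatch")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    thr = np.log2(fold_threshold)
    for i, row in raw.iterrows():
        rec = {"mirna_id_original": row["mirna_id"],
               "mirna_id": row["mirna_id"].translate(_ASCII),
               "c14mc": row["c14mc"].strip() == "X",
               "c19mc": row["c19mc"].strip() == "X"}
        n_pairs = 0
        for comp, (fc_col, p_col) in _PAIR_COLS.items():
            fc_s = row[fc_col].translate(_ASCII).strip()
            p_s = row[p_col].translate(_ASCII).strip()
            if bool(fc_s) != bool(p_s):
                raise ValueError(f"row {i}: half-specified {comp} pair")
            if not fc_s:
                rec[fc_col] = np.nan
                rec[p_col] = np.nan
                continue
            try:
                fc, p = float(fc_s), float(p_s)
            except ValueError as exc:
                raise ValueError(f"row {i}: unparseable {comp} pair") from exc
            if abs(fc) < thr - 1e-9 or p > alpha + 1e-12 or p <= 0:
                raise ValueError(
                    f"row {i} ({rec['mirna_id']}): {comp} pair ({fc}, {p}) "
                    f"violates |log2FC| >= log2({fold_threshold}), p <= {alpha}")
            rec[fc_col] = fc
            rec[p_col] = p
            n_pairs += 1
        if n_pairs == 0:
            raise ValueError(f"row {i}: no compartment pair present")
        rows.append(rec)
    df = pd.DataFrame(rows)
    if df["mirna_id"].duplicated().any():
        dups = df.loc[df["mirna_id"].duplicated(), "mirna_id"].tolist()
        raise ValueError(f"duplicate miRNA ids in fixture: {dups}")
    return df.set_index("mirna_id")


def compartment_sets(rows: pd.DataFrame) -> dict[str, set]:
    """miRNA-id sets with a printed significant pair, per compartment."""
    return {comp: set(rows.index[rows[_PAIR_COLS[comp][0]].notna()])
            for comp in COMPARTMENT_KEYS}


def count_significant(rows: pd.DataFrame, compartment: str) -> int:
    """Number of table rows significant in the given compartment (presence
    of a printed pair defines significance there)."""
    if compartment not in _PAIR_COLS:
        raise ValueError(f"unknown compartment {compartment!r}; "
                         f"expected one of {COMPARTMENT_KEYS}")
    return int(rows[_PAIR_COLS[compartment][0]].notna().sum())


def set_relations(rows: pd.DataFrame) -> dict:
    """Set algebra over compartment membership: singles, pairwise
    intersections, the triple intersection, and the union (checked against
    the inclusion-exclusion identity)."""
    sets = compartment_sets(rows)
    wp, ev, dep = (sets[c] for c in COMPARTMENT_KEYS)
    union = wp | ev | dep
    triple = wp & ev & dep
    singles = {c: len(sets[c]) for c in COMPARTMENT_KEYS}
    pairs = {"whole_plasma&EV": len(wp & ev),
             "whole_plasma&EV_depleted": len(wp & dep),
             "EV&EV_depleted": len(ev & dep)}
    incl_excl = sum(singles.values()) - sum(pairs.values()) + len(triple)
    assert incl_excl == len(union), "inclusion-exclusion identity violated"
    return {"singles": singles, "pairs": pairs, "triple": triple,
            "union_count": len(union), "union": union}


def detectable_arithmetic(shared: int, unique_control: int, unique_case: int) -> int:
    """Total detectable features = shared + group-unique counts."""
    for name, v in (("shared", shared), ("unique_control", unique_control),
                    ("unique_case", unique_case)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return shared + unique_control + unique_case


def _frame(df: pd.DataFrame, max_rows: int = 25) -> str:
    shown = df.head(max_rows)
    text = shown.to_string()
    more = len(df) - len(shown)
    return text + (f"\n... ({more} more rows)" if more > 0 else "")


def render_report(outputs: dict, path=None) -> str:
    """Assemble stage outputs into one markdown report.

    Recognized keys: mapping_summary, de (dict compartment -> DataFrame),
    chromosome_track, cluster_summary, qpcr, network_summary.  Missing
    stages render as absent sections; nothing is recomputed here.
    """
    sections = []

    def section(title: str, body: str | None) -> None:
        sections.append(f"## {title}\n\n" +
                        (body if body is not None else "_section absent_") + "\n")

    ms = outputs.get("mapping_summary")
    section("Mapping summary", None if ms is None else "```\n" + _frame(ms) + "\n```")

    de = outputs.get("de")
    if de is None:
        section("Differential abundance (volcano data)", None)
    else:
        parts = []
        for comp, df in de.items():
            sig = df[df["significant"]]
            parts.append(f"**{comp}**: {len(df)} tested, {len(sig)} significant\n\n"
                         "```\n" + _frame(sig.sort_values("p_value")) + "\n```")
        section("Differential abundance (volcano data)", "\n\n".join(parts))

    track = outputs.get("chromosome_track")
    section("Chromosome track",
            None if track is None else "```\n" +
            _frame(track[track["significant"]]) + "\n```")

    cs = outputs.get("cluster_summary")
    section("Cluster summary", None if cs is None else "```\n" + _frame(cs) + "\n```")

    qpcr = outputs.get("qpcr")
    section("qPCR concordance",
            None if qpcr is None else "```\n" + _frame(qpcr) + "\n```")

    net = outputs.get("network_summary")
    if net is None:
        section("Network summary", None)
    else:
        body = (f"miRNAs: {net.n_mirnas}; genes: {net.n_genes}; "
                f"interactions: {net.n_interactions}\n\n"
                + "\n".join(f"- {p}: {n} genes" for p, n in net.per_pathway.items()))
        section("Network summary", body)

    text = "# plasmir run report\n\n" + "\n".join(sections)
    if path is not None:
        Path(path).write_text(text)
    return text
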