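"""End-to-end orchestration: simulate -> preprocess -> map -> quantify ->
compartment analysis -> report.

Samples are processed one at a time (simulate, trim and map in a fused
stream) so raw FASTQ never needs to be held for the whole cohort; pass
keep_fastq=True to retain the raw files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import compartments as comp_mod
from . import network as net_mod
from .mapping import count_features, map_reads, summarize_mapping, table1
from .preprocess import TrimParams, TrimReport, iter_fastq, preprocess_stream
from .quantify import (cluster_summary, detectable_features, differential_test,
                       qpcr_concordance, rpm_normalize)
from .reporting import render_report
from .simulate import (COMPARTMENTS, SimulationConfig, _rng, sample_truth,
                       simulate_qpcr, simulate_sample_reads, _subject_table,
                       build_reference_bundle)


def run_cohort_pipeline(config: SimulationConfig, workdir,
                        compartments: tuple[str, ...] = COMPARTMENTS,
                        keep_fastq: bool = False,
                        cascade_order: str = "db-major") -> dict:
    """Simulate a cohort and run every analysis stage; returns stage outputs."""
    config.validate()
    workdir = Path(workdir)
    (workdir / "fastq").mkdir(parents=True, exist_ok=True)

    bundle = build_reference_bundle(config)
    bundle.write(workdir / "references")
    truth = sample_truth(config, bundle)
    truth.to_csv(workdir / "truth.tsv", sep="\t")
    config.to_yaml(workdir / "config.yaml")

    params = TrimParams(adapter=config.adapter)
    subjects = _subject_table(config)
    sheet_rows = []
    trim_reports: dict[str, TrimReport] = {}
    mapped = {}
    true_counts = {}
    for ci, comp in enumerate(compartments):
        for si, subj in subjects.iterrows():
            sample_id = f"{subj['subject_id']}_{comp}"
            rng = _rng(config, 3, ci, si)
            sim = simulate_sample_reads(truth, config, comp, subj["condition"],
                                        sample_id, rng=rng)
            fastq_path = workdir / "fastq" / f"{sample_id}.fastq"
            fastq_path.write_text(sim.fastq_text)
            report = TrimReport()
            with open(fastq_path) as fh:
                stream = preprocess_stream(iter_fastq(fh), params, report)
                mapped[sample_id] = map_reads(
                    ((rid, insert) for rid, insert, _ in stream),
                    bundle.cascade, order=cascade_order, sample_id=sample_id)
            trim_reports[sample_id] = report
            true_counts[sample_id] = sim.true_counts
            if not keep_fastq:
                fastq_path.unlink()
            sheet_rows.append({"sample_id": sample_id,
                               "subject_id": subj["subject_id"],
                               "condition": subj["condition"],
                               "compartment": comp,
                               "fastq_path": str(fastq_path)})
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    sheet.to_csv(workdir / "sample_sheet.tsv", sep="\t")
    pd.DataFrame(true_counts).rename_axis("feature_id") \
        .to_csv(workdir / "true_counts.tsv", sep="\t")

    cm = count_features(mapped, bundle.mirna, sheet)
    cm.write(workdir / "counts")
    rpm = rpm_normalize(cm)
    summary = summarize_mapping(trim_reports, cm, mapped)
    summary.to_csv(workdir / "mapping_summary.tsv", sep="\t")

    de = {}
    detect = {}
    detectable_counts = {}
    for comp in compartments:
        det = detectable_features(cm.features, sheet, compartment=comp)
        detect[comp] = det
        for grp, s in det.groups.items():
            detectable_counts[f"{comp}_{grp}"] = len(s)
        de[comp] = differential_test(rpm.features, sheet, compartment=comp,
                                     features=det.universe,
                                     annotation=bundle.annotation)
        de[comp].to_csv(workdir / f"de_{comp}.tsv", sep="\t")
    t1 = table1(summary, sheet, detectable_counts)
    t1.to_csv(workdir / "table1.tsv", sep="\t")

    results: dict = {"workdir": workdir, "bundle": bundle, "truth": truth,
                     "sheet": sheet, "counts": cm, "rpm": rpm,
                     "trim_reports": trim_reports,
                     "mapping_summary": summary, "table1": t1,
                     "detectable": detect, "de": de}

    ref_comp = compartments[0]
    clusters, track = cluster_summary(de[ref_comp], bundle.annotation)
    clusters.to_csv(workdir / "cluster_summary.tsv", sep="\t")
    track.to_csv(workdir / "chromosome_track.tsv", sep="\t")
    results["cluster_summary"] = clusters
    results["chromosome_track"] = track

    if "EV" in compartments and "EV_depleted" in compartments:
        ev, dep, _ = comp_mod.paired_compartment_counts(cm.features, sheet)
        partition = comp_mod.partition_table(ev, dep)
        partition.to_csv(workdir / "partition.tsv", sep="\t")
        results["partition"] = partition
        seqs = truth["sequence"]
        ev_set = partition.index[partition["enrichment_class"] == comp_mod.EV_ENRICHED]
        dep_set = partition.index[
            partition["enrichment_class"] == comp_mod.DEPLETED_ENRICHED]
        if len(ev_set) and len(dep_set):
            frac_ev, frac_dep, p_u = comp_mod.terminal_u_test(
                list(seqs[ev_set]), list(seqs[dep_set]))
            motifs = comp_mod.motif_enrichment(list(seqs[ev_set]), list(seqs[dep_set]))
            motifs.to_csv(workdir / "motif_enrichment.tsv", sep="\t")
            results["terminal_u"] = {"ev_enriched": frac_ev,
                                     "depleted_enriched": frac_dep, "p": p_u}
            results["motifs"] = motifs

    sig_wp = de[ref_comp][de[ref_comp]["significant"]]
    assay = list(sig_wp.sort_values("p_value").index[:8])
    if assay:
        qres = simulate_qpcr(truth, config, features=assay)
        table, n_agree = qpcr_concordance(de[ref_comp], qres.ct, qres.sheet,
                                          qres.normalizer_id)
        table.to_csv(workdir / "qpcr_concordance.tsv", sep="\t")
        results["qpcr"] = table
        results["qpcr_sign_agree"] = n_agree

    toy = net_mod.toy_network_data(seed=config.seed)
    edges = net_mod.select_targets(toy["de_mirnas"], toy["interactions"])
    edges = net_mod.filter_tissue_enriched(edges, toy["tissue"])
    expanded = net_mod.expand_first_neighbors(set(edges["gene"]), toy["ppi"])
    enrich = net_mod.pathway_enrichment(expanded, toy["pathways"])
    selected = list(enrich.index[:4])
    network = net_mod.build_pathway_network(edges, expanded, selected,
                                            toy["pathways"], toy["tissue"],
                                            ppi=toy["ppi"])
    enrich.to_csv(workdir / "pathway_enrichment.tsv", sep="\t")
    network.edges.to_csv(workdir / "network_edges.tsv", sep="\t", index=False)
    results["pathway_enrichment"] = enrich
    results["network"] = network
    results["network_summary"] = network.summary

    report_inputs = {"mapping_summary": summary, "de": de,
                     "chromosome_track": track, "cluster_summary": clusters,
                     "qpcr": results.get("qpcr"),
                     "network_summary": network.summary}
    results["report_path"] = workdir / "report.md"
    results["report"] = render_report(report_inputs, results["report_path"])
    return results
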