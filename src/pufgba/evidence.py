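"""Per-PUF evidence integration and the end-to-end pipeline driver.

Each protein of unknown function (PUF) accumulates guilt-by-association
evidence from independent streams — differential expression at matched
growth phases, co-expression cluster membership with the clusters'
enriched terms, differential co-expression (dCp), coevolving partner
orthogroups on the species tree, and operon co-membership — and the
integrator flattens them into one row per PUF with absent evidence
explicitly encoded as missing.

:func:`run_pipeline` drives the whole chain on a directory of input
files (which :func:`write_synthetic_inputs` can generate with planted
ground truth), writing every intermediate table plus the evidence table
and a JSON run log; a rerun with the same configuration reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .coexpression import DcpConfig, build_profiles, cluster_profiles, dcp_permutation
from .coevolution import CoevoConfig, screen_pairs, traits_from_orthogroups
from .diffexpr import DeConfig, DesignSpec, run_de, sample_pca
from .enrichment import EnrichConfig, propagate, run_go_enrichment
from .proteoquant import QuantConfig, quantify
from .simulate import SimStudyConfig, SimTraitConfig, sim_go, sim_operons, sim_study, sim_trait_matrix, sim_tree

__all__ = [
    "PipelineConfig",
    "operon_partners",
    "integrate",
    "write_synthetic_inputs",
    "run_pipeline",
]

MISSING = "NA"


def operon_partners(gene: str, operons: pd.DataFrame):
    """Co-members of the gene's operon with their annotation strings.

    Returns ``(partners, annotations, reason)``; empty lists with a
    reason when the gene is unlisted or its operon is a singleton.
    """
    for _, row in operons.iterrows():
        if gene in row["genes"]:
            partners, anns = [], []
            for g, a in zip(row["genes"], row["annotations"]):
                if g != gene:
                    partners.append(g)
                    anns.append(a)
            if not partners:
                return [], [], "singleton operon"
            return partners, anns, ""
    return [], [], "not in operon table"


def _top_terms(enrich: pd.DataFrame, n: int = 5, p_max: float = 0.05) -> str:
    hits = enrich[enrich["p"] < p_max].nsmallest(n, "p")
    return ";".join(f"{r.term}({r.p:.3g})" for r in hits.itertuples()) or ""


def integrate(study, de_results: pd.DataFrame, cluster_sets: dict,
              enrichments: dict, dcp_results: pd.DataFrame,
              coevo_results, operons: pd.DataFrame, puf_list: list[str],
              puf_to_og: dict[str, str] | None = None,
              og_annotations: dict[str, str] | None = None):
    """One evidence record per PUF, plus a run summary.

    ``cluster_sets`` maps strain -> ClusterSet, ``enrichments`` maps
    (strain, cluster_id) -> enrichment table, ``puf_to_og`` maps PUF ids
    to their orthogroup for the coevolution stream.  Returns
    ``(records, summary)``.
    """
    puf_to_og = puf_to_og or {}
    og_annotations = og_annotations or {}
    detected = set(study.matrix.index)
    grand = study.matrix.mean(axis=1)
    pct = grand.rank(pct=True) * 100.0

    coevo_partners: dict[str, list[str]] = {}
    for res in coevo_results:
        if res.coevolving:
            coevo_partners.setdefault(res.og_puf, []).append(res.og_other)

    contrasts = list(dict.fromkeys(de_results["contrast"])) if len(de_results) else []
    de_idx = de_results.set_index(["protein", "contrast"]) if len(de_results) else None
    dcp_idx = dcp_results.set_index("protein") if len(dcp_results) else None

    rows = []
    summary = {"n_puf": len(puf_list), "with_de": 0, "with_cluster": 0,
               "with_dcp": 0, "with_coevolution": 0, "with_operon": 0}
    for puf in puf_list:
        row: dict[str, object] = {"puf": puf, "detected": puf in detected}
        row["abundance_percentile"] = (
            round(float(pct[puf]), 2) if puf in pct.index else None)
        any_de = False
        for c in contrasts:
            key = (puf, c)
            if de_idx is not None and key in de_idx.index:
                rec = de_idx.loc[key]
                row[f"de_{c}_log2fc"] = round(float(rec["log2FC"]), 4)
                row[f"de_{c}_q"] = round(float(rec["q"]), 4)
                sig = bool(rec["significant"])
                row[f"de_{c}_significant"] = sig
                any_de |= sig
            else:
                row[f"de_{c}_log2fc"] = None
                row[f"de_{c}_q"] = None
                row[f"de_{c}_significant"] = None
        summary["with_de"] += any_de

        in_cluster = False
        for strain, cs in cluster_sets.items():
            cid = next((c for c, members in cs.clusters.items()
                        if puf in members), None)
            row[f"cluster_{strain}"] = (f"{strain}_C{cid}" if cid is not None
                                        else None)
            if cid is not None:
                in_cluster = True
                enr = enrichments.get((strain, cid))
                row[f"cluster_{strain}_terms"] = (
                    _top_terms(enr) or None) if enr is not None else None
            else:
                row[f"cluster_{strain}_terms"] = None
        summary["with_cluster"] += in_cluster

        if dcp_idx is not None and puf in dcp_idx.index:
            rec = dcp_idx.loc[puf]
            row["dcp"] = round(float(rec["dcp"]), 4)
            row["dcp_q"] = round(float(rec["q"]), 4)
            row["dcp_flagged"] = bool(rec["flagged"])
            summary["with_dcp"] += bool(rec["flagged"])
        else:
            row["dcp"] = row["dcp_q"] = row["dcp_flagged"] = None

        og = puf_to_og.get(puf)
        partners = coevo_partners.get(og, []) if og else []
        row["orthogroup"] = og
        row["coevolving_partners"] = ";".join(partners) or None
        row["coevolving_partner_annotations"] = ";".join(
            og_annotations.get(p, "") for p in partners) or None
        summary["with_coevolution"] += bool(partners)

        ops, anns, _reason = operon_partners(puf, operons)
        row["operon_partners"] = ";".join(ops) or None
        row["operon_partner_annotations"] = ";".join(a for a in anns) or None
        summary["with_operon"] += bool(ops)

        if not row["detected"]:
            warnings.warn(f"PUF {puf} absent from the quantified study; "
                          "record emitted with missing evidence")
        rows.append(row)
    records = pd.DataFrame(rows)
    return records, summary


@dataclass
class PipelineConfig:
    """Paths and per-stage settings for one end-to-end run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    quant: QuantConfig = field(default_factory=QuantConfig)
    de: DeConfig = field(default_factory=DeConfig)
    dcp: DcpConfig = field(default_factory=DcpConfig)
    coevo: CoevoConfig = field(default_factory=CoevoConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    cluster_k_range: tuple[int, int] = (2, 8)
    cluster_tau: float = 0.7
    cluster_min_size: int = 5

    def validate(self) -> None:
        base = Path(self.input_dir)
        required = ["peptides.tsv", "samples.tsv", "proteins.tsv", "tree.nwk",
                    "orthogroups.tsv", "go.obo", "annotations.tsv",
                    "operons.tsv", "puf_list.txt"]
        missing = [f for f in required if not (base / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing pipeline inputs under {base}: {missing}")


def write_synthetic_inputs(input_dir, study_config: SimStudyConfig,
                           trait_config: SimTraitConfig,
                           n_species: int = 27, seed: int | None = None):
    """Generate and serialize a complete synthetic input directory.

    Study PUFs are attached to the simulated PUF orthogroups (one gene
    in the first species of each orthogroup that is present there), so
    the coevolution stream can be traced back to study proteins.
    Returns the truth sets of the study and the trait matrix.
    """
    base = Path(input_dir)
    base.mkdir(parents=True, exist_ok=True)
    seed = study_config.seed if seed is None else seed

    peptides, samples, proteins, study_truth = sim_study(study_config)
    peptides.to_csv(base / "peptides.tsv", sep="\t", index=False, na_rep="NA")
    samples.reset_index().to_csv(base / "samples.tsv", sep="\t", index=False)
    proteins.reset_index().to_csv(base / "proteins.tsv", sep="\t", index=False)

    tree = sim_tree(n_species, seed=seed + 1)
    io_formats.write_newick(tree, base / "tree.nwk")
    traits, trait_truth = sim_trait_matrix(tree, trait_config)

    puf_ids = sorted(proteins.index[proteins["is_puf"]])
    (base / "puf_list.txt").write_text("\n".join(puf_ids) + "\n")

    # orthogroup table: synthetic members per present species; PUF
    # orthogroups carry one detected PUF gene in the first present species
    focal_pufs = iter(puf_ids)
    puf_to_og = {}
    with open(base / "orthogroups.tsv", "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(traits.species) + "\n")
        for og in traits.orthogroups:
            col = traits.column(og)
            cells = []
            assigned_puf = None
            if og in traits.puf_orthogroups and col.sum() > 0:
                assigned_puf = next(focal_pufs, None)
            first_present = int(np.argmax(col == 1)) if col.sum() else -1
            for i, sp in enumerate(traits.species):
                if col[i] == 0:
                    cells.append("")
                    continue
                genes = [f"{og}_{sp}"]
                if assigned_puf is not None and i == first_present:
                    genes.insert(0, assigned_puf)
                cells.append(",".join(genes))
            if assigned_puf is not None:
                puf_to_og[assigned_puf] = og
            fh.write(og + "\t" + "\t".join(cells) + "\n")
    (base / "puf_to_og.json").write_text(json.dumps(puf_to_og, indent=1))

    dag, annotation = sim_go(40, 4, list(proteins.index), seed=seed + 2)
    with open(base / "go.obo", "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        for term in dag.nodes:
            fh.write("[Term]\n")
            fh.write(f"id: {term}\nname: {dag.nodes[term]['name']}\n")
            fh.write(f"namespace: {dag.nodes[term]['namespace']}\n")
            for _, parent, key in dag.out_edges(term, keys=True):
                fh.write(f"is_a: {parent} ! {dag.nodes[parent]['name']}\n")
            fh.write("\n")
    with open(base / "annotations.tsv", "w") as fh:
        fh.write("# gene -> semicolon-separated GO terms\n")
        for gene in proteins.index:
            fh.write(gene + "\t" + ";".join(sorted(annotation[gene])) + "\n")

    operons = sim_operons(list(proteins.index), mean_size=3.0, seed=seed + 3)
    io_formats.write_operon_table(operons, base / "operons.tsv")
    return study_truth, trait_truth


def run_pipeline(config: PipelineConfig) -> Path:
    """Quantify -> DE -> cluster -> dCp -> coevolve -> enrich -> integrate.

    Writes all intermediate tables, the per-PUF evidence table and a run
    log under ``config.output_dir``; raises naming the failing stage,
    keeping earlier outputs in place.
    """
    config.validate()
    base = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"seed": config.seed, "stages": {}}
    t_start = time.time()
    stage = "setup"
    try:
        stage = "quantify"
        t0 = time.time()
        peptides = io_formats.read_peptide_table(base / "peptides.tsv")
        samples = pd.read_csv(base / "samples.tsv", sep="\t").set_index("sample")
        proteins = pd.read_csv(base / "proteins.tsv", sep="\t").set_index("protein")
        study = quantify(peptides, samples, proteins, config.quant)
        study.matrix.round(6).to_csv(out / "abundance.tsv", sep="\t", na_rep=MISSING)
        coords, varexp = sample_pca(study)
        coords.round(6).assign(
            phase=study.samples["phase"]).to_csv(out / "sample_pca.tsv", sep="\t")
        log["stages"]["quantify"] = {
            "seconds": round(time.time() - t0, 2),
            "proteins": int(study.matrix.shape[0]),
            "pc1_var": round(float(varexp[0]), 4)}

        stage = "de"
        t0 = time.time()
        design = DesignSpec.from_samples(study.samples)
        de_results = run_de(study, design, config.de)
        de_results.round(6).to_csv(out / "de_results.tsv", sep="\t", index=False)
        log["stages"]["de"] = {
            "seconds": round(time.time() - t0, 2),
            "significant": int(de_results["significant"].sum())}

        stage = "cluster"
        t0 = time.time()
        strains = list(dict.fromkeys(study.samples["strain"]))
        cluster_sets = {}
        profile_mats = {}
        for strain in strains:
            prof = build_profiles(study, strain)
            profile_mats[strain] = prof
            cluster_sets[strain] = cluster_profiles(
                prof, k_range=config.cluster_k_range, tau=config.cluster_tau,
                min_size=config.cluster_min_size, seed=config.seed)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("strain\tcluster\tprotein\n")
            for strain, cs in cluster_sets.items():
                for cid, members in cs.clusters.items():
                    for m in members:
                        fh.write(f"{strain}\t{strain}_C{cid}\t{m}\n")
        log["stages"]["cluster"] = {
            "seconds": round(time.time() - t0, 2),
            "clusters": {s: len(cs.clusters) for s, cs in cluster_sets.items()}}

        stage = "dcp"
        t0 = time.time()
        shared = sorted(set(profile_mats[strains[0]].replicates.index)
                        & set(profile_mats[strains[1]].replicates.index))
        dcp_results = dcp_permutation(
            profile_mats[strains[0]].replicates.loc[shared],
            profile_mats[strains[1]].replicates.loc[shared], config.dcp)
        dcp_results.round(6).to_csv(out / "dcp_results.tsv", sep="\t", index=False)
        log["stages"]["dcp"] = {
            "seconds": round(time.time() - t0, 2),
            "tested": int(len(dcp_results)),
            "flagged": int(dcp_results["flagged"].sum()) if len(dcp_results) else 0}

        stage = "coevolve"
        t0 = time.time()
        tree = io_formats.read_newick(base / "tree.nwk")
        membership = io_formats.read_orthogroup_table(base / "orthogroups.tsv")
        puf_list = [ln.strip() for ln in
                    (base / "puf_list.txt").read_text().splitlines() if ln.strip()]
        detected_pufs = {p for p in puf_list if p in study.matrix.index}
        traits = traits_from_orthogroups(membership, tree,
                                         puf_genes=detected_pufs)
        coevo_results, skipped = screen_pairs(traits, tree, config.coevo)
        with open(out / "coevolution.tsv", "w") as fh:
            fh.write("og_puf\tog_other\tlogL_indep\tlogL_dep\taicc_indep\t"
                     "aicc_dep\tdelta\tcoevolving\n")
            for r in coevo_results:
                fh.write(f"{r.og_puf}\t{r.og_other}\t{r.fit_indep.logL:.6f}\t"
                         f"{r.fit_dep.logL:.6f}\t{r.aicc_indep:.6f}\t"
                         f"{r.aicc_dep:.6f}\t{r.delta:.6f}\t{r.coevolving}\n")
        log["stages"]["coevolve"] = {
            "seconds": round(time.time() - t0, 2),
            "pairs_tested": len(coevo_results), "pairs_skipped": len(skipped),
            "coevolving": int(sum(r.coevolving for r in coevo_results))}

        stage = "enrich"
        t0 = time.time()
        dag = io_formats.read_obo(base / "go.obo")
        annotation = propagate(dag, io_formats.read_annotation_map(
            base / "annotations.tsv"))
        background = set(study.matrix.index)
        enrichments = {}
        enr_rows = []
        for strain, cs in cluster_sets.items():
            for cid, members in cs.clusters.items():
                enr = run_go_enrichment(
                    set(members) & background, background, dag,
                    annotation, config.enrich)
                enrichments[(strain, cid)] = enr
                enr = enr.assign(strain=strain, cluster=f"{strain}_C{cid}")
                enr_rows.append(enr)
        pd.concat(enr_rows, ignore_index=True).round(6).to_csv(
            out / "cluster_enrichment.tsv", sep="\t", index=False)
        log["stages"]["enrich"] = {"seconds": round(time.time() - t0, 2),
                                   "cluster_tests": len(enrichments)}

        stage = "integrate"
        t0 = time.time()
        operons = io_formats.read_operon_table(base / "operons.tsv",
                                               known_genes=set(proteins.index))
        puf_to_og = {}
        if (base / "puf_to_og.json").exists():
            puf_to_og = json.loads((base / "puf_to_og.json").read_text())
        records, summary = integrate(
            study, de_results, cluster_sets, enrichments, dcp_results,
            coevo_results, operons, puf_list, puf_to_og=puf_to_og)
        io_formats.write_evidence_table(records, out / "evidence.tsv")
        log["stages"]["integrate"] = {"seconds": round(time.time() - t0, 2),
                                      **summary}
    except Exception as exc:
        (out / "run_log.json").write_text(json.dumps(
            {**log, "failed_stage": stage, "error": str(exc)}, indent=1,
            sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    log["total_seconds"] = round(time.time() - t_start, 2)
    del log["total_seconds"]  # wall time varies; keep the log byte-stable
    for st in log["stages"].values():
        st.pop("seconds", None)
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return out
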