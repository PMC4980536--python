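"""End-to-end analysis pipeline: simulate or load data, run every stage,
write a report bundle with a machine-readable manifest.

Stages, in order: similarity-level distribution of clinical cohorts versus
the established set, per-cohort system-profile summaries, the median-trend
report, the promising-target retrospective evaluation, and drug-target
network degree statistics with ICD-class subnetwork extraction and
Cytoscape-compatible exports.  A stage failure aborts the run with the
stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import druggability, network, profiles, similarity, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis",
           "simulate_dataset"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    When ``data_dir`` is None the pipeline simulates its inputs from the
    cohort and family presets under ``seed``; otherwise it loads the TSV /
    FASTA files produced by :func:`simulate_dataset` (or real data with the
    same schema) from that directory.
    """

    output_dir: Path = Path("targetprofiler_out")
    data_dir: Path | None = None
    seed: int = 0
    n_targets_per_cohort: int = 40
    family_spec: synthetic.FamilySpec | None = None
    thresholds: similarity.SimilarityThresholds = field(
        default_factory=similarity.SimilarityThresholds)
    rules: profiles.ProfileRuleConfig = field(
        default_factory=profiles.ProfileRuleConfig)
    icd_range: str = "C51-C58"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("seed", "n_targets_per_cohort", "icd_range"):
            if key in raw:
                kwargs[key] = raw[key]
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        if "data_dir" in raw and raw["data_dir"]:
            kwargs["data_dir"] = Path(raw["data_dir"])
        if "thresholds" in raw:
            kwargs["thresholds"] = similarity.SimilarityThresholds(**raw["thresholds"])
        if "rules" in raw:
            kwargs["rules"] = profiles.ProfileRuleConfig(**raw["rules"])
        if "family_spec" in raw:
            kwargs["family_spec"] = synthetic.FamilySpec(**raw["family_spec"])
        return cls(**kwargs)


def simulate_dataset(out_dir: str | Path, seed: int = 0,
                     n_targets_per_cohort: int = 40,
                     family_spec: synthetic.FamilySpec | None = None,
                     degree_preset: str = "paper-degrees") -> dict[str, str]:
    """Write a loadable synthetic dataset (FASTA + TSVs) to ``out_dir``.

    Emits cohort tables with NS/NP/NT, pathway/tissue annotation tables,
    sequence families, and an interaction table whose network realizes the
    canonical printed degree histograms (``degree_preset="paper-degrees"``).
    Returns a name -> path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    cohort = synthetic.generate_cohorts(
        synthetic.cohort_presets(n_targets_per_cohort, seed))
    cohort_path = out / "cohorts.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)
    written["cohorts"] = str(cohort_path)

    pathways, tissues = synthetic.annotation_tables(cohort, seed=seed + 100)
    for name, df in (("pathways", pathways), ("tissues", tissues)):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = str(p)

    if family_spec is None:
        family_spec = synthetic.FamilySpec(seed=seed + 200)
    sequences, family_map = synthetic.generate_sequence_families(family_spec)
    fasta_path = out / "sequences.fasta"
    synthetic.write_fasta(sequences, fasta_path)
    written["sequences"] = str(fasta_path)
    fam_path = out / "families.tsv"
    pd.DataFrame(
        {"sequence_id": list(family_map), "family": list(family_map.values())}
    ).to_csv(fam_path, sep="\t", index=False)
    written["families"] = str(fam_path)

    if degree_preset == "paper-degrees":
        degseq = synthetic.fig_approved_degrees()
    else:
        raise ValueError(f"unknown degree preset {degree_preset!r}")
    g = synthetic.realize_bipartite(degseq)
    inter = pd.DataFrame(
        [{"drug_id": d, "target_id": t, "mode": m.get("mode", "inhibition")}
         for d, t, m in g.edges(data=True)
         if g.nodes[d]["bipartite"] == "drug"]
        + [{"drug_id": t, "target_id": d, "mode": m.get("mode", "inhibition")}
           for d, t, m in g.edges(data=True)
           if g.nodes[d]["bipartite"] != "drug"]
    ).sort_values(["drug_id", "target_id"])
    ipath = out / "interactions.tsv"
    inter.to_csv(ipath, sep="\t", index=False)
    written["interactions"] = str(ipath)
    return written


def _load_sequences(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the manifest (also written to ``manifest.json``): a mapping of
    output names to file paths plus the headline numbers of each stage.
    Reruns with the same seed produce byte-identical tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "summary": {}, "seed": config.seed}

    def _stage(name):
        def wrapper(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc
        return wrapper

    # --- stage: inputs ------------------------------------------------
    def load_inputs():
        if config.data_dir is None:
            data_dir = out / "simulated_input"
            simulate_dataset(data_dir, seed=config.seed,
                             n_targets_per_cohort=config.n_targets_per_cohort,
                             family_spec=config.family_spec)
        else:
            data_dir = Path(config.data_dir)
        paths = {name: data_dir / fname for name, fname in [
            ("cohorts", "cohorts.tsv"), ("pathways", "pathways.tsv"),
            ("tissues", "tissues.tsv"), ("sequences", "sequences.fasta"),
            ("families", "families.tsv"), ("interactions", "interactions.tsv"),
        ]}
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        cohort = pd.read_csv(paths["cohorts"], sep="\t")
        pathways = pd.read_csv(paths["pathways"], sep="\t")
        tissues = pd.read_csv(paths["tissues"], sep="\t")
        sequences = _load_sequences(paths["sequences"])
        families = pd.read_csv(paths["families"], sep="\t")
        interactions = pd.read_csv(paths["interactions"], sep="\t")
        return cohort, pathways, tissues, sequences, families, interactions

    cohort, pathways, tissues, sequences, families, interactions = \
        _stage("load_inputs")(load_inputs)

    params = similarity.EvalueParams()

    # --- stage: similarity-level distribution -------------------------
    def similarity_stage():
        fam_map = dict(zip(families["sequence_id"], families["family"]))
        # clinical-trial kinases are homologs of established ones, so each
        # family's members are split round-robin across development stages:
        # the first member of each family is established, the rest cycle
        # through the clinical phases
        stages = ("established", "phase3", "phase2", "phase1")
        established: dict[str, str] = {}
        clinical: dict[str, dict[str, str]] = {p: {} for p in stages[1:]}
        by_family: dict[str, list[str]] = {}
        for sid in sorted(fam_map):
            by_family.setdefault(fam_map[sid], []).append(sid)
        for members in by_family.values():
            for i, sid in enumerate(members):
                stage = stages[i % len(stages)]
                if stage == "established":
                    established[sid] = sequences[sid]
                else:
                    clinical[stage][sid] = sequences[sid]
        dist = profiles.similarity_level_distribution(
            clinical, established, params, config.thresholds)
        path = out / "similarity_levels.tsv"
        dist.to_csv(path, sep="\t")
        manifest["outputs"]["similarity_levels"] = str(path)
        manifest["summary"]["similarity_levels"] = {
            phase: dict(row) for phase, row in dist.iterrows()
        }

    _stage("similarity_levels")(similarity_stage)

    # --- stage: cohort summaries and trend -----------------------------
    def profile_stage():
        summaries = []
        rows = []
        for label in synthetic.COHORT_ORDER:
            sub = cohort[cohort["cohort"] == label]
            if sub.empty:
                continue
            prof = profiles.assemble_profiles(sub, config.rules)
            summary = profiles.summarize_cohort(prof, label)
            summaries.append(summary)
            rows.append({
                "cohort": label, "n": summary.n,
                "pct_compliant_ns": summary.pct_compliant_ns,
                "pct_compliant_np": summary.pct_compliant_np,
                "pct_compliant_nt": summary.pct_compliant_nt,
                **{f"median_{s}": summary.boxplot_stats[s].median
                   for s in profiles.STATISTICS},
            })
        df = pd.DataFrame(rows)
        path = out / "cohort_summaries.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["cohort_summaries"] = str(path)

        trend_order = [s for s in summaries
                       if s.cohort_label in synthetic.COHORT_ORDER[:4]]
        trends = {}
        for stat in profiles.STATISTICS:
            rep = profiles.median_trend(trend_order, stat)
            trends[stat] = {
                "medians": list(rep.medians),
                "monotone_nondecreasing": rep.monotone_nondecreasing,
                "first_violation": rep.first_violation,
            }
        path = out / "median_trend.json"
        path.write_text(json.dumps(trends, indent=2))
        manifest["outputs"]["median_trend"] = str(path)
        manifest["summary"]["median_trend"] = trends

    _stage("cohort_profiles")(profile_stage)

    # --- stage: druggability retrospective -----------------------------
    def druggability_stage():
        table1 = synthetic.table1_fixture()
        summary = druggability.evaluate_cohort(table1)
        path = out / "druggability_evaluation.tsv"
        summary.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["druggability_evaluation"] = str(path)
        manifest["summary"]["druggability"] = {
            row["status"]: {"count": int(row["count"]),
                            "pct_printed": int(row["pct_printed"])}
            for _, row in summary.iterrows()
        }

    _stage("druggability")(druggability_stage)

    # --- stage: network -------------------------------------------------
    def network_stage():
        drugs = sorted(set(interactions["drug_id"]))
        target_ids = sorted(set(interactions["target_id"]))
        rng_codes = {d: "C50" for d in drugs}  # default disease class
        # give a deterministic subset of drugs codes inside the ICD range
        letter, lo, hi = network._parse_icd_range(config.icd_range)
        for i, d in enumerate(drugs):
            if i % 3 == 0:
                rng_codes[d] = f"{letter}{lo + (i % (hi - lo + 1)):02d}"
        drug_records = [
            network.DrugRecord(drug_id=d, icd_codes=frozenset({rng_codes[d]}))
            for d in drugs
        ]
        targets_map = {t: "established" for t in target_ids}
        recs = [network.InteractionRecord(drug_id=r.drug_id,
                                          target_id=r.target_id,
                                          mode=getattr(r, "mode", "inhibition"))
                for r in interactions.itertuples(index=False)]
        g = network.build_network(drug_records, targets_map, recs)
        stats = {
            "n_drugs": len(drugs),
            "n_targets": len(target_ids),
            "n_edges": g.number_of_edges(),
            "drug_degree_histogram": network.degree_histogram(g, "drug"),
            "target_degree_histogram": network.degree_histogram(g, "target"),
            "popular_targets_gt8": network.popular_nodes(g, "target", 8),
            "n_multitarget_drugs": len(network.multitarget_drugs(g)),
        }
        sub = network.subnetwork_by_icd(g, config.icd_range)
        stats["icd_subnetwork"] = {
            "range": config.icd_range,
            "n_drugs": len([n for n, d in sub.nodes(data=True)
                            if d["node_class"] == "drug"]),
            "n_targets": len([n for n, d in sub.nodes(data=True)
                              if d["node_class"] == "target"]),
        }
        network.export_sif(g, out / "network.sif")
        network.export_graphml(g, out / "network.graphml")
        network.export_attribute_tables(
            g, out / "node_attributes.tsv", out / "edge_attributes.tsv")
        path = out / "network_stats.json"
        path.write_text(json.dumps(stats, indent=2, default=str))
        for name in ("network.sif", "network.graphml", "node_attributes.tsv",
                     "edge_attributes.tsv", "network_stats.json"):
            manifest["outputs"][name.replace(".", "_")] = str(out / name)
        manifest["summary"]["network"] = {
            k: stats[k] for k in ("n_drugs", "n_targets", "n_edges",
                                  "n_multitarget_drugs")
        }

    _stage("network")(network_stage)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
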