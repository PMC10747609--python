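"""End-to-end orchestration: haplotypes -> distances -> partitioning ->
threshold delimitation -> biogeographic concordance -> trait summaries.

A run is fully determined by one :class:`RunConfig` (paths + parameters +
one master seed).  Each stage either succeeds or is recorded as skipped or
failed with a reason; agreement between the molecular delimitations, the
biogeographic row clusters and (when supplied) the generator truth is
scored with the Adjusted Rand Index on shared units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .asap import AsapPartitioner
from .biogeo import (
    TRAIT_COLUMNS,
    DoubleKMeans,
    build_frequency_matrix,
    load_occurrences,
    partition_concordance,
    thermal_order,
    trait_group_summary,
)
from .errors import DelimError
from .gmyc import GmycModel
from .seqdata import collapse_haplotypes, read_alignment
from .simdata import ScenarioTruth
from .trees import UltrametricTree

log = logging.getLogger("delimpy")


@dataclass
class RunConfig:
    fasta: str | None = None
    tree: str | None = None
    occurrences: str | None = None
    truth: str | None = None
    models: tuple = ("p", "JC69", "K80")
    n_perm: int = 999
    seed: int = 0
    k_rows: int = 3
    k_cols: int = 4
    repeats: int = 25
    reference_threshold: float = 5e-4
    tree_tol: float = 1e-6


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    asap: dict | None = None
    gmyc: dict | None = None
    biogeo: dict | None = None
    traits: dict | None = None
    agreement: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    failed: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failed

    def to_dict(self) -> dict:
        return asdict(self)


def _ari_flag(part_a: dict, part_b: dict) -> dict:
    ari, exact = partition_concordance(part_a, part_b)
    return {"ari": ari, "agree": bool(ari == 1.0 and exact)}


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every configured stage; never raises on stage failure."""
    report = RunReport(config=asdict(cfg))
    asap_part = gmyc_part = None
    truth = None
    if cfg.truth:
        truth = ScenarioTruth.from_json(cfg.truth)

    # --- molecular partitioning -----------------------------------------
    if cfg.fasta:
        try:
            log.info("reading alignment from %s", cfg.fasta)
            aln = read_alignment(cfg.fasta)
            ht = collapse_haplotypes(aln)
            est = AsapPartitioner(
                models=cfg.models, n_perm=cfg.n_perm,
                reference_threshold=cfg.reference_threshold,
                random_state=cfg.seed,
            ).fit(aln)
            asap_part = {i: int(l) for i, l in zip(est.ids_, est.labels_)}
            report.asap = {
                "n_haplotypes": ht.n,
                "best_model": est.best_model_,
                "best": est.best_.to_dict(),
                "candidates": {
                    m: [c.to_dict() for c in cands[:10]]
                    for m, cands in est.candidates_.items()
                },
            }
            log.info("best partition: %d species (model %s)",
                     est.best_.n_species, est.best_model_)
        except (DelimError, OSError, ValueError) as e:
            report.failed["asap"] = str(e)
    else:
        report.skipped["asap"] = "no alignment supplied"

    # --- threshold delimitation ------------------------------------------
    if cfg.tree:
        try:
            log.info("reading genealogy from %s", cfg.tree)
            tree = UltrametricTree.read(cfg.tree, tol=cfg.tree_tol)
            gm = GmycModel(tol=cfg.tree_tol).fit(tree)
            r = gm.result_
            gmyc_part = dict(r.entity_map)
            report.gmyc = {
                "n_entities": r.n_entities,
                "n_clusters": r.n_clusters,
                "threshold": r.ml_params.T,
                "lnl_alt": r.lnl_alt,
                "lnl_null": r.lnl_null,
                "lrt_stat": r.lrt_stat,
                "lrt_p": r.lrt_p,
                "ci_entities": list(r.ci_entities),
                "entity_map": r.entity_map,
                "node_support": [
                    {"tips": sorted(k), "support": v}
                    for k, v in sorted(
                        r.node_support.items(), key=lambda kv: -len(kv[0])
                    )
                ],
                "summary": r.summary(),
            }
            log.info("%s", r.summary())
        except (DelimError, OSError, ValueError) as e:
            report.failed["gmyc"] = str(e)
    else:
        report.skipped["gmyc"] = "no tree supplied"

    # --- biogeographic concordance ---------------------------------------
    occ = None
    if cfg.occurrences:
        try:
            occ = load_occurrences(cfg.occurrences)
            order = thermal_order(occ)
            F = build_frequency_matrix(occ, col_order=order)
            dk = DoubleKMeans(
                k_rows=cfg.k_rows, k_cols=cfg.k_cols,
                repeats=cfg.repeats, random_state=cfg.seed,
            ).fit(F)
            report.biogeo = {
                "thermal_order": order,
                "frequencies": F.freqs.to_dict(),
                "row_partition": dk.row_partition_,
                "col_partition": dk.col_partition_,
                "consistent": dk.consistent_,
            }
        except (DelimError, OSError, ValueError, KeyError) as e:
            report.failed["biogeo"] = str(e)
    else:
        report.skipped["biogeo"] = "no occurrence table supplied"

    # --- trait summaries ---------------------------------------------------
    if occ is not None and all(c in occ.columns for c in TRAIT_COLUMNS[:2]):
        try:
            tdf = occ.rename(columns={"population_id": "individual_id"})
            group_col = "species_label" if "species_label" in occ else "haplogroup"
            summary = trait_group_summary(tdf, grouping=group_col)
            report.traits = json.loads(summary.to_json(orient="index"))
        except (ValueError, KeyError) as e:
            report.failed["traits"] = str(e)
    else:
        report.skipped["traits"] = "no trait columns supplied"

    # --- agreement ---------------------------------------------------------
    agr = report.agreement
    if asap_part and gmyc_part:
        shared = sorted(set(asap_part) & set(gmyc_part))
        if shared:
            agr["asap_vs_gmyc"] = _ari_flag(
                {k: asap_part[k] for k in shared}, {k: gmyc_part[k] for k in shared}
            )
    if truth is not None:
        if asap_part:
            shared = sorted(set(asap_part) & set(truth.tip_species))
            if shared:
                agr["asap_vs_truth"] = _ari_flag(
                    {k: asap_part[k] for k in shared},
                    {k: truth.tip_species[k] for k in shared},
                )
        if gmyc_part:
            shared = sorted(set(gmyc_part) & set(truth.tip_species))
            if shared:
                agr["gmyc_vs_truth"] = _ari_flag(
                    {k: gmyc_part[k] for k in shared},
                    {k: truth.tip_species[k] for k in shared},
                )
        if report.biogeo and truth.hap_species:
            rows = report.biogeo["row_partition"]
            shared = sorted(set(rows) & set(truth.hap_species))
            if shared:
                agr["biogeo_vs_truth"] = _ari_flag(
                    {k: rows[k] for k in shared},
                    {k: truth.hap_species[k] for k in shared},
                )
    agr["all_agree"] = bool(agr) and all(
        v["agree"] for k, v in agr.items() if isinstance(v, dict)
    )
    return report


def write_report(report: RunReport, out_dir) -> dict[str, Path]:
    """JSON + flat TSVs + a plain-text summary of the delimitation tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"json": out / "report.json", "summary": out / "summary.txt"}
    with open(paths["json"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=str)

    lines = [f"delimpy {report.version} run report", ""]
    if report.asap:
        lines.append("== Distance partitioning (best candidates per model) ==")
        lines.append(
            "model\tasap_score\tn_species\tp_value\tW\tthreshold_dist"
        )
        for m, cands in report.asap["candidates"].items():
            for c in cands[:2]:
                lines.append(
                    f"{m}\t{c['asap_score']:.2f}\t{c['n_species']}\t"
                    f"{c['p_value']:.3g}\t{c['W']:.3g}\t{c['threshold_dist']:.6g}"
                )
        paths["asap_tsv"] = out / "asap_candidates.tsv"
        rows = []
        for m, cands in report.asap["candidates"].items():
            for c in cands:
                rows.append({"model": m, **{k: v for k, v in c.items()
                                            if k != "groups"}})
        pd.DataFrame(rows).to_csv(paths["asap_tsv"], sep="\t", index=False)
    if report.gmyc:
        g = report.gmyc
        lines += ["", "== Threshold delimitation ==", g["summary"]]
        paths["entities_tsv"] = out / "gmyc_entities.tsv"
        pd.Series(g["entity_map"], name="entity").rename_axis("tip").to_csv(
            paths["entities_tsv"], sep="\t"
        )
    if report.biogeo:
        lines += [
            "",
            "== Biogeographic concordance ==",
            f"consistent across repeats: {report.biogeo['consistent']}",
            f"row clusters: {report.biogeo['row_partition']}",
        ]
    if report.skipped:
        lines += ["", "skipped: " + json.dumps(report.skipped)]
    if report.failed:
        lines += ["", "FAILED: " + json.dumps(report.failed)]
    if report.agreement:
        lines += ["", "agreement: " + json.dumps(report.agreement, sort_keys=True)]
    with open(paths["summary"], "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return paths
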