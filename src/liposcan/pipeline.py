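"""End-to-end orchestration: build -> scan -> annotate -> profile -> compare.

``run_pipeline`` executes the whole screening workflow from one RunConfig —
in demo mode entirely on synthetic inputs — writing every intermediate as a
plain-text artifact (FASTA/TSV/Newick/GraphML/JSON) plus a manifest and a
summary report.  Runs are deterministic: re-running with the same config
reproduces identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from liposcan import community as comm
from liposcan.annotate import (
    Thresholds,
    annotate_proteins,
    decisions_to_frame,
    summarize_verdicts,
)
from liposcan.profile_hmm import MsaFamily, build_hmm, calibrate, write_hmm_db
from liposcan.records import write_fasta
from liposcan.synthetic_data import (
    ROUTE_CONFIRM_PROFILE,
    ROUTE_FAMILY,
    GeneratorConfig,
    gen_community,
    gen_families,
    gen_protein_set,
    gen_reference_registry,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("liposcan.pipeline")


@dataclass
class RunConfig:
    """Configuration of a demo-mode end-to-end run."""

    out_dir: str = "liposcan_run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    calib_n_decoys: int = 200
    calib_decoy_length: int = 350
    calib_seed: int = 42
    anosim_permutations: int = 9999
    indicator_permutations: int = 999
    stats_seed: int = 1

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        gen = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("generator", {}).items()})
        th = Thresholds(**raw.pop("thresholds", {}))
        return cls(generator=gen, thresholds=th, **raw)


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-demo workflow; returns the manifest dict.

    Any stage failure aborts with the stage name attached to the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {}

    stage = "generate_families"
    try:
        _stage(stage)
        families = gen_families(config.generator)
        for fam in families:
            path = out / f"msa_{fam.family_name}.afa"
            with open(path, "w") as fh:
                for i, row in enumerate(fam.msa.rows):
                    fh.write(f">{fam.family_name}_{i}\n{row}\n")
            manifest[f"msa_{fam.family_name}"] = str(path)

        stage = "build_profiles"
        _stage(stage)
        elf_fams = [f for f in families if f.family_name != ROUTE_FAMILY]
        route_fams = [f for f in families if f.family_name == ROUTE_FAMILY]
        db = [build_hmm(f.msa) for f in elf_fams]
        route_db = [build_hmm(f.msa) for f in route_fams]
        confirm_db = []
        if route_fams:
            sub = MsaFamily(ROUTE_CONFIRM_PROFILE, route_fams[0].msa.rows[: max(2, len(route_fams[0].msa.rows) // 2)])
            confirm_db = [build_hmm(sub)]
        for hmm in db + route_db + confirm_db:
            calibrate(hmm, config.calib_n_decoys, config.calib_decoy_length, config.calib_seed)
        db_path = out / "db.hmm"
        write_hmm_db(db, db_path)
        manifest["hmm_db"] = str(db_path)
        if route_db:
            write_hmm_db(route_db, out / "route.hmm")
            write_hmm_db(confirm_db, out / "confirm.hmm")
            manifest["route_db"] = str(out / "route.hmm")
            manifest["confirm_db"] = str(out / "confirm.hmm")

        stage = "generate_proteins"
        _stage(stage)
        proteins, truth = gen_protein_set(config.generator, families)
        write_fasta(proteins, out / "proteins.faa")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest["proteins"] = str(out / "proteins.faa")
        manifest["truth"] = str(out / "truth.tsv")
        refs, registry = gen_reference_registry(config.generator, families)
        registry.to_tsv(out / "registry.tsv")
        manifest["registry"] = str(out / "registry.tsv")

        stage = "annotate"
        _stage(stage)
        decisions = annotate_proteins(
            proteins, db, refs, registry, config.thresholds,
            route_db=route_db or None, confirm_db=confirm_db or None,
        )
        table = decisions_to_frame(decisions)
        table.to_csv(out / "decisions.tsv", sep="\t", index=False)
        manifest["decisions"] = str(out / "decisions.tsv")
        summary["verdict_counts"] = summarize_verdicts(decisions)
        assigned = table[table.verdict == "assigned"]
        summary["assigned_per_family"] = (
            assigned.groupby("family").size().sort_index().to_dict()
        )

        stage = "community_profile"
        _stage(stage)
        counts, metadata, planted = gen_community(config.generator)
        counts.to_csv(out / "community_counts.tsv", sep="\t")
        lpgm = comm.lpgm_normalize(counts, metadata)
        lpgm.to_csv(out / "lpgm_matrix.tsv", sep="\t")
        meta_df = pd.DataFrame([asdict(m) for m in metadata])
        meta_df.to_csv(out / "metadata.tsv", sep="\t", index=False)
        manifest["lpgm_matrix"] = str(out / "lpgm_matrix.tsv")
        manifest["metadata"] = str(out / "metadata.tsv")

        stage = "compare"
        _stage(stage)
        dist = comm.bray_curtis(comm.log_transform(lpgm))
        merges = comm.ward_cluster(dist)
        (out / "dendrogram.nwk").write_text(comm.dendrogram_to_newick(merges) + "\n")
        manifest["dendrogram"] = str(out / "dendrogram.nwk")
        habitats = [m.habitat for m in metadata]
        res = comm.anosim(dist, habitats, config.anosim_permutations, config.stats_seed)
        summary["anosim"] = {
            "R": res.R, "p_value": res.p_value, "n_permutations": res.n_permutations,
        }
        assocs = comm.indicator_analysis(
            lpgm, habitats, n_permutations=config.indicator_permutations,
            seed=config.stats_seed,
        )
        assoc_df = pd.DataFrame(
            [
                {"category": a.category, "habitats": ",".join(a.habitats),
                 "r": a.r, "p_value": a.p_value, "mean_lpgm": a.mean_lpgm}
                for a in assocs
            ]
        )
        assoc_df.to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["associations"] = str(out / "associations.tsv")
        net = comm.bipartite_network(assocs)
        import networkx as nx

        nx.write_graphml(net, out / "network.graphml")
        comm.network_edge_frame(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        manifest["network"] = str(out / "network.graphml")
        summary["n_significant_indicators"] = len(assocs)
        summary["planted_indicators"] = {h: g for h, g in planted.items()}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest["summary"] = str(out / "summary.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
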