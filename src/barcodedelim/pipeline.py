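"""End-to-end delimitation pipeline: one config in, a result bundle out.

Stages, in order, each writing its outputs under the configured directory:

1. ``distances`` — TN93 (gamma shape 1) matrix of the input alignment.
2. ``cluster`` — single-linkage OTUs at the cluster threshold (the
   registry-emulating partition).
3. ``abgd`` — K2P-based barcode-gap scan over the prior grid; the most
   prior-stable partition is carried forward to consensus.
4. ``tree`` — NJ tree (optionally bootstrapped), rooted on the configured
   outgroup or at the midpoint, plus the per-cluster monophyly report.
5. ``consensus`` — Full/Partial verdict per cluster.
6. ``summaries`` — per-OTU distance table, barcode-gap scatter table, and
   (given at least 3 groups) the group-level MDS coordinates.

A machine-readable ``manifest.json`` records the configuration, seed,
package versions and SHA-256 checksums of all inputs and outputs. A stage
failure leaves a ``FAILED`` marker naming the stage; outputs of completed
stages are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abgd import AbgdConfig, abgd_scan
from .consensus import consensus_classify, consensus_table, write_consensus_json
from .distances import (
    DistanceMatrix,
    DistanceModelConfig,
    distance_matrix,
    group_distance_summary,
)
from .otu_stats import (
    barcode_gap_table,
    mds_embed,
    otu_summaries,
    summaries_table,
    threshold_cluster,
)
from .seqio import Alignment, read_fasta
from .trees import bootstrap_support, monophyly_report, nj_tree, root_with_outgroup, write_newick

logger = logging.getLogger("barcodedelim")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Defaults: TN93 with gamma shape 1 for distance matrices, K2P for the
    barcode-gap scan; scan priors 0.001-0.1 in 10 steps with relative gap
    width 1.5 over 20 bins (``study_mode`` narrows to P max 0.01, X = 1);
    cluster threshold 0.0112 substitutions/site (the complement of the
    98.88% assignment similarity); 1000 bootstrap replicates.
    """

    fasta: str | Path | None = None
    metadata: str | Path | None = None
    out_dir: str | Path = "results"
    matrix_model: DistanceModelConfig = field(
        default_factory=lambda: DistanceModelConfig(model="tn93", gamma_shape=1.0)
    )
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    study_mode: bool = False
    cluster_threshold: float = 0.0112
    assignment_threshold: float = 98.88
    bootstrap_reps: int = 1000
    run_bootstrap: bool = False
    outgroup: tuple[str, ...] = ()
    seed: int = 0

    def abgd_config(self) -> AbgdConfig:
        if self.study_mode:
            return dataclasses.replace(self.abgd, p_max=0.01, x_gap=1.0)
        return self.abgd


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    alignment: Alignment
    distance_matrix: DistanceMatrix
    clusters: "object"
    scan: "object"
    abgd_partition: "object"
    tree: "object"
    monophyly: dict
    consensus: list
    consensus_frame: pd.DataFrame
    summaries: list
    gap_table: pd.DataFrame
    mds: pd.DataFrame | None
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(
    cfg: PipelineConfig, alignment: Alignment | None = None
) -> PipelineResult:
    """Run every stage on *alignment* (or the configured FASTA input)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "inputs": {},
        "outputs": {},
    }
    stage = "input"
    try:
        if alignment is None:
            if cfg.fasta is None:
                raise ValueError("no alignment given and no FASTA path configured")
            alignment = read_fasta(cfg.fasta, cfg.metadata)
            manifest["inputs"][str(cfg.fasta)] = _sha256(Path(cfg.fasta))
            if cfg.metadata:
                manifest["inputs"][str(cfg.metadata)] = _sha256(Path(cfg.metadata))

        stage = "distances"
        dm = distance_matrix(alignment, cfg.matrix_model)
        dm.to_tsv(out / "distances.tsv")

        stage = "cluster"
        clusters = threshold_cluster(dm, cfg.cluster_threshold)
        clusters.to_tsv(out / "clusters.tsv")

        stage = "abgd"
        abgd_cfg = cfg.abgd_config()
        abgd_dm = (
            dm
            if abgd_cfg.metric == cfg.matrix_model
            else distance_matrix(alignment, abgd_cfg.metric)
        )
        scan = abgd_scan(abgd_dm, abgd_cfg)
        scan.to_tsv(out / "abgd_scan.tsv")
        abgd_part = scan.stable_row().partition
        abgd_part.to_tsv(out / "abgd_partition.tsv")

        stage = "tree"
        if cfg.run_bootstrap:
            tree = bootstrap_support(
                alignment, cfg.matrix_model, n_reps=cfg.bootstrap_reps, seed=cfg.seed
            )
        else:
            tree = nj_tree(dm)
        if cfg.outgroup:
            rooted = root_with_outgroup(tree, cfg.outgroup)
        else:
            rooted = tree.root_at_midpoint()
        write_newick(rooted, out / "tree.nwk")
        mono = monophyly_report(rooted, clusters)
        pd.DataFrame(
            [
                {"group": g, "status": s.status, "n_subclades": s.n_subclades}
                for g, s in mono.items()
            ]
        ).to_csv(out / "monophyly.tsv", sep="\t", index=False)

        stage = "consensus"
        taxa = {r.id: r.taxon for r in alignment.records}
        records = consensus_classify(clusters, abgd_part, mono, taxa=taxa)
        cframe = consensus_table(records, out / "consensus.tsv")
        write_consensus_json(records, out / "consensus.json")

        stage = "summaries"
        summaries = otu_summaries(dm, clusters)
        summaries_table(summaries).to_csv(out / "otu_summaries.tsv", sep="\t",
                                          index=False)
        gap = barcode_gap_table(summaries)
        gap.to_csv(out / "barcode_gap.tsv", sep="\t", index=False)
        mds = None
        if clusters.n_groups >= 3:
            gmeans = group_distance_summary(dm, clusters)
            gdm = DistanceMatrix(
                list(gmeans.index),
                np.nan_to_num(gmeans.to_numpy(), nan=0.0) * (1 - np.eye(len(gmeans))),
                cfg.matrix_model,
            )
            mds = mds_embed(gdm, k=2)
            mds.to_csv(out / "mds.tsv", sep="\t", index_label="group")
        else:
            logger.info("fewer than 3 groups; MDS skipped")
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                       + "\n")
    return PipelineResult(
        out_dir=out,
        alignment=alignment,
        distance_matrix=dm,
        clusters=clusters,
        scan=scan,
        abgd_partition=abgd_part,
        tree=rooted,
        monophyly=mono,
        consensus=records,
        consensus_frame=cframe,
        summaries=summaries,
        gap_table=gap,
        mds=mds,
        manifest=manifest,
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["fasta"] = str(d["fasta"]) if d["fasta"] else None
    d["metadata"] = str(d["metadata"]) if d["metadata"] else None
    d["out_dir"] = str(d["out_dir"])
    d["outgroup"] = list(d["outgroup"])
    return d


def _versions() -> dict:
    import Bio
    import scipy
    import skbio
    import sklearn

    return {
        "barcodedelim": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-bio": skbio.__version__,
        "scikit-learn": sklearn.__version__,
        "biopython": Bio.__version__,
    }
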