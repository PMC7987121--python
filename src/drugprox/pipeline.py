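"""End-to-end pipeline: proximity -> significance -> similarity -> clusters
-> adjustment -> sigmoid normalization -> (optional) ROC evaluation.

All randomness flows from ``master_seed``: each (drug, disease) pair's null
model gets a stable per-pair seed derived from the master seed, so adding
pairs never reshuffles existing scores, and a rerun with the same inputs
and config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, evaluation, interactome, proximity, similarity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

NETWORK_COLUMNS = [
    "drug", "disease", "p_value", "proximity", "similarity",
    "adjusted_similarity", "normalized_similarity",
    "cluster_drug", "cluster_disease", "same_cluster",
]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults follow the method's stated operating point: significance
    level ``alpha = 0.05`` and ``n_random = 1000`` degree-preserving
    randomizations per pair.  ``sigmoid_midpoint=None`` resolves to the
    median adjusted similarity at run time; the resolved value is written
    back into the serialized config.
    """

    interactome: str = ""
    drug_targets: str = ""
    disease_genes: str = ""
    gold: str | None = None
    output_dir: str = "drugprox_results"
    alpha: float = 0.05
    n_random: int = 1000
    min_bin_size: int = 100
    sigmoid_steepness: float = 25.0
    sigmoid_midpoint: float | None = None
    max_p_scope: str = "significant_pairs"
    keep_largest_component: bool = True
    p_method: str = "normal"
    roc_scope: str = "all_scored"  # or "significant"
    master_seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        for name in ("interactome", "drug_targets", "disease_genes"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p!r}")
        if self.gold and not Path(self.gold).exists():
            raise FileNotFoundError(f"gold file not found: {self.gold!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_random < 2:
            raise ValueError("n_random must be >= 2")
        if self.roc_scope not in ("all_scored", "significant"):
            raise ValueError(f"unknown roc_scope {self.roc_scope!r}")


@dataclass
class PipelineResult:
    """Everything a run produced, in memory plus on disk."""

    records: list = field(default_factory=list)
    significant: list = field(default_factory=list)
    network: similarity.AssociationNetwork | None = None
    partition: clustering.Partition | None = None
    roc: evaluation.RocCurve | None = None
    outputs: dict[str, Path] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def _network_table(net: similarity.AssociationNetwork) -> pd.DataFrame:
    df = net.edges.copy()
    for col in NETWORK_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[NETWORK_COLUMNS]


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full scoring pipeline and write the output bundle.

    On failure every partial output written so far is removed and the
    error re-raised, so an output directory is either complete or absent.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    written: list[Path] = []

    def emit(key: str, name: str) -> Path:
        p = outdir / name
        result.outputs[key] = p
        written.append(p)
        return p

    log_handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("drugprox")
    root.addHandler(log_handler)
    written.append(outdir / "pipeline.log")
    try:
        g = interactome.load_interactome(
            cfg.interactome, keep_largest_component=cfg.keep_largest_component
        )
        drug_mods = interactome.modules_from_gene_sets(
            interactome.load_gene_sets(cfg.drug_targets), g
        )
        disease_mods = interactome.modules_from_gene_sets(
            interactome.load_gene_sets(cfg.disease_genes), g
        )
        if not drug_mods or not disease_mods:
            raise ValueError("no usable drug or disease modules after mapping")
        bins = interactome.build_degree_bins(g, cfg.min_bin_size)
        logger.info(
            "scoring %d drugs x %d diseases (n_random=%d)",
            len(drug_mods), len(disease_mods), cfg.n_random,
        )
        records = proximity.score_all_pairs(
            g, bins, drug_mods, disease_mods,
            n_random=cfg.n_random, master_seed=cfg.master_seed,
            p_method=cfg.p_method,
        )
        result.records = records
        proximity.write_proximity_table(records, emit("proximity", "proximity.tsv"))

        significant = proximity.significant_associations(records, cfg.alpha)
        result.significant = significant
        result.counts = {
            "pairs_scored": len(records),
            "pairs_significant": len(significant),
        }
        logger.info(
            "%d/%d pairs significant at alpha=%g",
            len(significant), len(records), cfg.alpha,
        )

        if significant:
            net = similarity.proximity_to_similarity(
                significant, scope=cfg.max_p_scope, all_records=records
            )
            part = clustering.greedy_modularity_partition(net, rng_seed=cfg.master_seed)
            result.partition = part
            clustering.write_partition_table(part, emit("partition", "partition.tsv"))
            net = similarity.adjust_similarity(net, part)
            params = similarity.SimilarityParams(
                sigmoid_steepness=cfg.sigmoid_steepness,
                sigmoid_midpoint=cfg.sigmoid_midpoint,
                max_p_scope=cfg.max_p_scope,
            )
            net = similarity.sigmoid_normalize(net, params)
            result.network = net
            cfg.sigmoid_midpoint = net.meta["sigmoid_midpoint"]  # resolved value
            result.counts["clusters_found"] = len(part.clusters)
            result.counts["network_edges"] = len(net)
        else:
            logger.warning("no significant associations at alpha=%g", cfg.alpha)
            net = None
            result.counts["clusters_found"] = 0
            result.counts["network_edges"] = 0

        table = (_network_table(net) if net is not None
                 else pd.DataFrame(columns=NETWORK_COLUMNS))
        table.to_csv(emit("network", "associations.tsv"),
                     sep="\t", index=False, float_format="%.17g")

        if cfg.gold:
            gold = evaluation.load_gold_standard(cfg.gold)
            if cfg.roc_scope == "significant" and net is not None:
                preds = net.edges[["drug", "disease", "p_value",
                                   "normalized_similarity"]]
            else:
                preds = pd.DataFrame(
                    [{"drug": r.drug, "disease": r.disease, "p_value": r.p_value}
                     for r in records]
                )
                if net is not None:
                    sim_map = {
                        (d, s): w for d, s, w in zip(
                            net.edges["drug"], net.edges["disease"],
                            net.edges["normalized_similarity"])
                    }
                    preds["normalized_similarity"] = [
                        sim_map.get((d, s), 0.0)
                        for d, s in zip(preds["drug"], preds["disease"])
                    ]
            ranking = evaluation.label_predictions(preds, gold)
            result.roc = evaluation.roc_curve(ranking)
            evaluation.write_roc_table(result.roc, emit("roc", "roc.tsv"))
            logger.info("ROC AUC = %.4f (%d known / %d unknown)",
                        result.roc.auc, ranking.n_known, ranking.n_unknown)

        cfg.to_yaml(emit("config", "config.yaml"))
        for stage, count in result.counts.items():
            logger.info("count %s = %d", stage, count)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return result
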