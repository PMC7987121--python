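"""Synthetic interactomes, drug/disease modules, and gold standards.

The generator emulates the structural features the pipeline's statistics
depend on, without any external downloads:

* a preferential-attachment (Barabási–Albert) interactome, whose
  heavy-tailed degree distribution is exactly the confounder the
  degree-preserving null model exists to control for;
* disease modules grown as connected neighborhoods (network medicine's
  disease-module hypothesis: disease genes agglomerate rather than
  scatter);
* "planted" drugs whose targets are drawn mostly from within a small hop
  radius of a designated disease module — true repurposing candidates by
  construction — versus background drugs with uniformly random targets;
* a gold standard listing exactly the planted (drug, disease) pairs, plus
  a JSON truth manifest recording every generator parameter.

Everything is deterministic given ``rng_seed``, and the emitted files use
exactly the TSV dialects the loading functions consume.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .interactome import Interactome

logger = logging.getLogger(__name__)

__all__ = ["GenerationError", "FixtureSpec", "Fixture", "generate_fixture"]


class GenerationError(RuntimeError):
    """Raised when a fixture spec cannot be realized (e.g. module too large)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark instance.

    ``planted_fraction`` of drugs are true repurposing candidates: each is
    matched round-robin to a disease and draws at least 80% of its targets
    from within ``planting_radius`` hops of that disease's module (radius 0
    means targets are a subset of the disease genes).
    """

    n_nodes: int = 2000
    attachment_edges: int = 3
    n_diseases: int = 5
    n_drugs: int = 60
    disease_module_size: tuple[int, int] = (15, 30)
    drug_module_size: tuple[int, int] = (3, 8)
    planted_fraction: float = 0.3
    planting_radius: int = 1
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 10:
            raise GenerationError("n_nodes must be >= 10")
        if not (0 < self.attachment_edges < self.n_nodes):
            raise GenerationError("attachment_edges must be in (0, n_nodes)")
        for lo, hi in (self.disease_module_size, self.drug_module_size):
            if not (1 <= lo <= hi <= self.n_nodes):
                raise GenerationError(
                    f"module size range ({lo}, {hi}) must satisfy 1 <= lo <= hi <= n_nodes"
                )
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise GenerationError("planted_fraction must be in [0, 1]")
        if self.planting_radius < 0:
            raise GenerationError("planting_radius must be >= 0")
        if self.n_diseases < 1 or self.n_drugs < 1:
            raise GenerationError("need at least one disease and one drug")


@dataclass(frozen=True)
class Fixture:
    """In-memory fixture plus the truth manifest."""

    interactome: Interactome
    drug_targets: dict[str, set[str]]
    disease_genes: dict[str, set[str]]
    gold: tuple[tuple[str, str], ...]
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all TSVs plus manifest.json; byte-deterministic."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactome": outdir / "interactome.tsv",
            "drug_targets": outdir / "drug_targets.tsv",
            "disease_genes": outdir / "disease_genes.tsv",
            "gold": outdir / "gold.tsv",
            "manifest": outdir / "manifest.json",
        }
        with open(paths["interactome"], "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.interactome.graph.edges):
                fh.write(f"{u}\t{v}\n")
        for key, sets in (("drug_targets", self.drug_targets),
                          ("disease_genes", self.disease_genes)):
            with open(paths[key], "w") as fh:
                fh.write("set_id\tgene_id\n")
                for name in sets:  # insertion order
                    for gene in sorted(sets[name]):
                        fh.write(f"{name}\t{gene}\n")
        with open(paths["gold"], "w") as fh:
            fh.write("drug_id\tdisease_id\n")
            for drug, disease in self.gold:
                fh.write(f"{drug}\t{disease}\n")
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _grow_connected_module(
    g: Interactome, size: int, rng: np.random.Generator
) -> set[str]:
    """Random-expansion neighborhood: start at a random seed node, repeatedly
    absorb a uniformly chosen frontier node until *size* is reached."""
    order = g.node_order
    seed = order[int(rng.integers(len(order)))]
    members = {seed}
    frontier = set(g.graph[seed]) - members
    while len(members) < size:
        if not frontier:
            raise GenerationError(
                f"module of size {size} not reachable from seed {seed!r}"
            )
        cand = sorted(frontier)
        pick = cand[int(rng.integers(len(cand)))]
        members.add(pick)
        frontier |= set(g.graph[pick])
        frontier -= members
    return members


def generate_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> Fixture:
    """Build one synthetic benchmark instance; optionally write it to disk."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    ba = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attachment_edges, seed=int(rng.integers(2**31 - 1))
    )
    width = max(5, len(str(spec.n_nodes)))
    g = Interactome(nx.relabel_nodes(ba, {i: f"G{i:0{width}d}" for i in ba.nodes}))
    all_nodes = list(g.node_order)

    lo, hi = spec.disease_module_size
    disease_genes: dict[str, set[str]] = {}
    for j in range(spec.n_diseases):
        size = int(rng.integers(lo, hi + 1))
        disease_genes[f"DIS{j:02d}"] = _grow_connected_module(g, size, rng)
    disease_names = list(disease_genes)

    # node pools within planting_radius hops of each disease module
    near_pool: dict[str, list[str]] = {}
    for name, module in disease_genes.items():
        dist = g.min_hop_distances(module)
        near_pool[name] = [
            n for i, n in enumerate(all_nodes) if dist[i] <= spec.planting_radius
        ]

    n_planted = int(round(spec.planted_fraction * spec.n_drugs))
    lo_d, hi_d = spec.drug_module_size
    drug_targets: dict[str, set[str]] = {}
    gold: list[tuple[str, str]] = []
    for i in range(spec.n_drugs):
        name = f"DRUG{i:03d}"
        size = int(rng.integers(lo_d, hi_d + 1))
        if i < n_planted:
            disease = disease_names[i % spec.n_diseases]
            pool = near_pool[disease]
            n_near = min(size, math.ceil(0.8 * size))
            if len(pool) < n_near:
                raise GenerationError(
                    f"planting pool of {disease} has {len(pool)} nodes; "
                    f"cannot draw {n_near} targets within radius "
                    f"{spec.planting_radius}"
                )
            near = set(rng.choice(pool, size=n_near, replace=False))
            targets = set(near)
            remaining = sorted(set(all_nodes) - targets)
            while len(targets) < size:
                pick = remaining[int(rng.integers(len(remaining)))]
                targets.add(pick)
                remaining.remove(pick)
            gold.append((name, disease))
        else:
            targets = set(rng.choice(all_nodes, size=size, replace=False))
        drug_targets[name] = targets

    manifest = {
        "spec": {**asdict(spec),
                 "disease_module_size": list(spec.disease_module_size),
                 "drug_module_size": list(spec.drug_module_size)},
        "planted_pairs": [list(p) for p in gold],
        "n_planted_drugs": n_planted,
        "disease_module_sizes": {k: len(v) for k, v in disease_genes.items()},
        "drug_module_sizes": {k: len(v) for k, v in drug_targets.items()},
        "n_interactome_nodes": g.number_of_nodes(),
        "n_interactome_edges": g.number_of_edges(),
    }
    fixture = Fixture(
        interactome=g,
        drug_targets=drug_targets,
        disease_genes=disease_genes,
        gold=tuple(gold),
        manifest=manifest,
    )
    if outdir is not None:
        fixture.write(outdir)
        logger.info("fixture written to %s", outdir)
    return fixture
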