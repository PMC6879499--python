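"""End-to-end three-axis screen orchestration.

``run_pipeline`` composes the library modules in order: parse compounds,
build the structural similarity matrix and cluster it; read the docking
matrix and cluster the raw score profiles; rank-normalise, read the PPI
network, weight ranks by node degree and cluster the network-effect
profiles.  All three trees share the compound leaf set, get multiscale-
bootstrap AU support, and are compared pairwise at a range of flat cuts.
Every artifact (matrices, Newick trees, support tables, comparison table,
JSON report) is written to the output directory; reruns with the same config
and seed are byte-identical for all text outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import CompoundSet, McsParams, SimilarityMatrix, load_compounds, similarity_matrix
from .clustering import (
    ClusterSupport,
    ClusterTree,
    DEFAULT_SCALES,
    compare_trees,
    multiscale_bootstrap,
    plot_dendrogram,
    support_table,
    to_newick,
)
from .docking import rank_normalize, read_docking_matrix
from .network import (
    betweenness,
    network_effect,
    node_degrees,
    read_ppi,
    write_degree_table,
    write_sif,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ScreenReport", "run_pipeline"]

AXES = ("structure", "docking", "network")


@dataclass
class PipelineConfig:
    """Validated inputs and knobs for one pipeline run.

    ``seed`` is mandatory: the bootstrap is stochastic and the run must be
    reproducible.  ``id_map`` optionally aliases compound ids between the
    structure file and the docking matrix (TSV: ``from_id<TAB>to_id``).
    """

    compounds: str
    docking: str
    ppi: str
    out_dir: str
    seed: int
    compound_format: str = "auto"
    similarity_method: str = "mcs_overlap"
    mcs: McsParams = field(default_factory=McsParams)
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    ppi_format: str = "string_tsv"
    min_confidence: float = 0.7
    missing_protein_policy: str = "zero"
    linkage: str = "average"
    scales: tuple[float, ...] = DEFAULT_SCALES
    n_boot: int = 1000
    compare_ks: tuple[int, ...] = (2, 3, 4)
    id_map: str | None = None
    transpose_docking: bool = False
    strict: bool = False
    write_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "mcs" in raw and isinstance(raw["mcs"], dict):
            raw["mcs"] = McsParams(**raw["mcs"])
        for key in ("scales", "compare_ks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (("compounds", self.compounds), ("docking", self.docking),
                         ("ppi", self.ppi)):
            if p is None:
                raise ValueError(f"config is missing the {label} input path")
            if not Path(p).is_file():
                raise ValueError(f"{label} input does not exist: {p}")
        if self.id_map is not None and not Path(self.id_map).is_file():
            raise ValueError(f"id_map file does not exist: {self.id_map}")
        if self.seed is None:
            raise ValueError("seed is mandatory for a reproducible bootstrap")

    def echo(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        d["compare_ks"] = list(self.compare_ks)
        return d


@dataclass
class ScreenReport:
    """Results of one three-axis screen.

    ``trees`` / ``supports`` are keyed by axis (structure, docking, network);
    all trees share an identical compound leaf set.  ``comparisons`` holds
    one row per (axis pair, k).
    """

    trees: dict[str, ClusterTree]
    supports: dict[str, ClusterSupport]
    comparisons: pd.DataFrame
    metadata: dict

    def leaf_set(self) -> frozenset[str]:
        sets = {frozenset(t.labels) for t in self.trees.values()}
        if len(sets) != 1:
            raise AssertionError("axis trees disagree on the compound leaf set")
        return next(iter(sets))


def _apply_id_map(ids: pd.Index, id_map_path: str | None) -> pd.Index:
    if id_map_path is None:
        return ids
    mapping = {}
    for raw in Path(id_map_path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed id-map line: {raw!r}")
        mapping[parts[0]] = parts[1]
    return pd.Index([mapping.get(i, i) for i in ids])


def _axis_seed(seed: int, axis: str) -> int:
    # stable per-axis sub-seeds below 2**31
    return int(np.random.SeedSequence([seed, AXES.index(axis)]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> ScreenReport:
    """Run the full structure / docking / network-effect screen.

    Raises before any computation when the config is invalid, and on a
    compound-id mismatch between the structure file and the docking matrix
    (the symmetric difference is listed).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # --- inputs -----------------------------------------------------------
    compounds = load_compounds(config.compounds, format=config.compound_format,
                               strict=config.strict)
    scores = read_docking_matrix(config.docking, transpose=config.transpose_docking)
    scores.scores.index = _apply_id_map(scores.scores.index, config.id_map)

    struct_ids, dock_ids = set(compounds.ids), set(scores.scores.index)
    if struct_ids != dock_ids:
        raise ValueError(
            "compound ids differ between structure file and docking matrix; "
            f"symmetric difference: {sorted(struct_ids ^ dock_ids)}"
        )
    scores.scores = scores.scores.reindex(compounds.ids)

    # --- structure axis ---------------------------------------------------
    sim = similarity_matrix(
        compounds, method=config.similarity_method, params=config.mcs,
        radius=config.fingerprint_radius, n_bits=config.fingerprint_bits,
    )
    sim.to_csv(out / "similarity_matrix.csv")
    # features = each compound's similarity profile over all compounds
    structure_features = sim.to_dataframe()

    # --- docking axis -----------------------------------------------------
    if scores.scores.isna().any().any():
        raise ValueError(
            "docking matrix has missing cells; clustering requires complete "
            "score profiles"
        )
    docking_features = scores.scores

    # --- network axis -----------------------------------------------------
    ranks = rank_normalize(scores)
    ranks.to_csv(out / "rank_matrix.csv")
    graph = read_ppi(config.ppi, format=config.ppi_format,
                     min_confidence=config.min_confidence, strict=config.strict)
    degrees = node_degrees(graph)
    write_degree_table(degrees, out / "degree_table.csv")
    betweenness(graph).to_csv(out / "betweenness.csv")  # report-only topology
    write_sif(graph, out / "ppi_network.sif")
    effects = network_effect(ranks, degrees,
                             missing_protein_policy=config.missing_protein_policy)
    effects.to_csv(out / "network_effect.csv")
    network_features = effects.effects

    # --- cluster each axis ------------------------------------------------
    features = {
        "structure": structure_features,
        "docking": docking_features,
        "network": network_features,
    }
    trees: dict[str, ClusterTree] = {}
    supports: dict[str, ClusterSupport] = {}
    for axis in AXES:
        tree, support = multiscale_bootstrap(
            features[axis], linkage=config.linkage, scales=config.scales,
            n_boot_per_scale=config.n_boot, seed=_axis_seed(config.seed, axis),
        )
        trees[axis], supports[axis] = tree, support
        (out / f"{axis}_dendrogram.nwk").write_text(to_newick(tree, support) + "\n")
        support_table(tree, support).to_csv(out / f"{axis}_support.csv", index=False)
        if config.write_plots:
            plot_dendrogram(tree, support, out / f"{axis}_dendrogram.png",
                            title=f"{axis} axis (AU %)")

    # --- compare the three dendrograms -------------------------------------
    rows = []
    pairs = [("structure", "docking"), ("structure", "network"), ("docking", "network")]
    max_k = len(compounds)
    for a, b in pairs:
        for k in config.compare_ks:
            if not 2 <= k <= max_k:
                warnings.append(f"skipping comparison cut k={k}: out of [2, {max_k}]")
                continue
            cmp_rec = compare_trees(trees[a], trees[b], k)
            rows.append({
                "axis_a": a, "axis_b": b, "k": k,
                "adjusted_rand": cmp_rec.adjusted_rand,
                "fowlkes_mallows": cmp_rec.fowlkes_mallows,
                "cophenetic_correlation": cmp_rec.cophenetic_correlation,
            })
    comparisons = pd.DataFrame(
        rows, columns=["axis_a", "axis_b", "k", "adjusted_rand",
                       "fowlkes_mallows", "cophenetic_correlation"],
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)

    metadata = {
        "netscreen_version": __version__,
        "config": config.echo(),
        "n_compounds": len(compounds),
        "n_proteins_docked": len(scores.protein_ids),
        "ppi_nodes": graph.number_of_nodes(),
        "ppi_edges": graph.number_of_edges(),
        "bootstrap_orientation": "items=compounds, resampled features=matrix columns",
        "warnings": warnings,
    }
    (out / "report.json").write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    report = ScreenReport(trees=trees, supports=supports, comparisons=comparisons,
                          metadata=metadata)
    report.leaf_set()  # invariant: identical leaves on all axes
    return report
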