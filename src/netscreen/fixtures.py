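"""Synthetic screen fixtures and packaged reference inputs.

:func:`generate_fixtures` builds a complete, miniature screening study with
known ground truth on every axis:

* **compounds** — SMILES sampled from four embedded scaffold families
  (sugar polyols, salicylates, alkyl diamines, alkyl pyridines), so the
  structural clusters are known by construction;
* **PPI network** — a preferential-attachment (Barabasi-Albert) random
  graph, giving the heavy-tailed degree distribution of real interactomes,
  with STRING-style combined scores sampled at or above the high-confidence
  0.7 threshold;
* **docking scores** — two planted compound groups: group X binds the hub
  proteins strongly (8-10) and everything else weakly (1-3), group Y is the
  mirror image; Gaussian noise (sd 0.5) is added and scores are clipped to
  [0, 10].

Group membership is deliberately misaligned with the scaffold families so
that one structurally dissimilar pair shares a network profile (and should
co-cluster on the docking/network axes) while one structurally similar pair
is split across groups (and should separate there) — the discordance pattern
the three-axis comparison is designed to surface.

:func:`reference_compounds` / :func:`reference_targets` expose the packaged
static benchmark: twelve anti-ageing-related compounds and the 45-protein
docking target panel with PPI degrees (degree left missing where the source
transcription was ambiguous).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .chem import CompoundSet, load_compounds
from .docking import DockingScoreMatrix

__all__ = [
    "FixtureBundle",
    "SCAFFOLD_FAMILIES",
    "generate_fixtures",
    "reference_compounds",
    "reference_targets",
]

# Four structurally distinct scaffold families; within-family members differ
# only by chain homology, so MCS overlap within a family is ~1 and the
# structural ground truth is the family label.
SCAFFOLD_FAMILIES: dict[str, list[str]] = {
    "polyol": [
        "OCC(O)CO",
        "OCC(O)C(O)CO",
        "OCC(O)C(O)C(O)CO",
        "OCC(O)C(O)C(O)C(O)CO",
    ],
    "salicylate": [
        "Oc1ccccc1C(O)=O",
        "CC(=O)Oc1ccccc1C(O)=O",
        "CCC(=O)Oc1ccccc1C(O)=O",
        "CCCCC(=O)Oc1ccccc1C(O)=O",
    ],
    "diamine": [
        "NCCCCN",
        "NCCCCCN",
        "NCCCCCCN",
        "NCCCCCCCN",
    ],
    "pyridine": [
        "Cc1ccncc1",
        "CCc1ccncc1",
        "Cc1ccnc(C)c1",
        "CCc1ccnc(C)c1",
    ],
}

HIGH_RANGE = (8.0, 10.0)  # planted strong-binder scores
LOW_RANGE = (1.0, 3.0)  # planted weak-binder scores
NOISE_SD = 0.5


@dataclass
class FixtureBundle:
    """Paths and ground truth of one generated fixture set.

    ``truth`` maps axis name -> {compound_id: label} plus the planted pair
    bookkeeping (hub proteins, discordant/concordant pairs).
    """

    smiles_path: Path
    docking_path: Path
    ppi_path: Path
    truth_path: Path
    truth: dict


def _family_assignment(n_compounds: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Round-robin compounds over families; returns (family, smiles) per compound.

    Family members are drawn without replacement in a seeded random order so
    different seeds see different homologues, while the family (= structural
    ground truth) sequence stays fixed.
    """
    families = list(SCAFFOLD_FAMILIES)
    capacity = sum(len(v) for v in SCAFFOLD_FAMILIES.values())
    if n_compounds > capacity:
        raise ValueError(
            f"n_compounds={n_compounds} exceeds the {capacity} embedded scaffolds"
        )
    shuffled = {
        fam: [SCAFFOLD_FAMILIES[fam][j] for j in rng.permutation(len(SCAFFOLD_FAMILIES[fam]))]
        for fam in families
    }
    taken = {fam: 0 for fam in families}
    assignment: list[tuple[str, str]] = []
    for i in range(n_compounds):
        fam = families[i % len(families)]
        if taken[fam] >= len(shuffled[fam]):
            fam = next(f for f in families if taken[f] < len(shuffled[f]))
        assignment.append((fam, shuffled[fam][taken[fam]]))
        taken[fam] += 1
    return assignment


def generate_fixtures(
    out_dir: str | Path,
    seed: int,
    n_compounds: int = 12,
    n_proteins: int = 45,
    n_hub_proteins: int = 5,
    noise_sd: float = NOISE_SD,
) -> FixtureBundle:
    """Write a planted-structure fixture bundle; bit-identical for a fixed seed.

    Requires ``n_compounds >= 4`` and ``n_proteins >= 6``.  Emits a SMILES
    file, a docking-score CSV, a STRING-style TSV and a JSON ground-truth
    record (per-axis labels, hub list, planted pairs, parameters).
    """
    if n_compounds < 4:
        raise ValueError("need n_compounds >= 4")
    if n_proteins < 6:
        raise ValueError("need n_proteins >= 6")
    if not 1 <= n_hub_proteins <= n_proteins // 2:
        raise ValueError("n_hub_proteins must be in [1, n_proteins/2]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- compounds -------------------------------------------------------
    fam_smiles = _family_assignment(n_compounds, rng)
    fam_counter: dict[str, int] = {}
    compound_ids, structure_labels, smiles_lines = [], {}, []
    for fam, smi in fam_smiles:
        fam_counter[fam] = fam_counter.get(fam, 0) + 1
        cid = f"{fam}_{fam_counter[fam]}"
        compound_ids.append(cid)
        structure_labels[cid] = fam
        smiles_lines.append(f"{smi}\t{cid}")
    smiles_path = out_dir / "compounds.smi"
    smiles_path.write_text(
        "# synthetic scaffold-family compounds\n" + "\n".join(smiles_lines) + "\n"
    )

    # --- PPI graph -------------------------------------------------------
    proteins = [f"PROT{i + 1:03d}" for i in range(n_proteins)]
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(n_proteins, m=2, seed=ba_seed)
    g = nx.relabel_nodes(g, {i: proteins[i] for i in range(n_proteins)})
    ppi_path = out_dir / "ppi_string.tsv"
    with open(ppi_path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
            score = int(rng.integers(700, 1000))
            fh.write(f"{a} {b} {score}\n")
    degree = pd.Series(dict(g.degree()))
    hubs = sorted(degree.sort_values(ascending=False, kind="stable").index[:n_hub_proteins])

    # --- planted docking groups -----------------------------------------
    # misalign groups with families: first two members of family 0 -> X with
    # its third -> Y (similar pair that splits); first member of family 1 ->
    # X (dissimilar pair that co-clusters); remaining compounds alternate to
    # balance group sizes.
    group: dict[str, str] = {}
    fam_order = list(dict.fromkeys(f for f, _ in fam_smiles))
    by_family: dict[str, list[str]] = {}
    for cid in compound_ids:
        by_family.setdefault(structure_labels[cid], []).append(cid)
    f0, f1 = fam_order[0], fam_order[1]
    group[by_family[f0][0]] = "X"
    if len(by_family[f0]) > 1:
        group[by_family[f0][1]] = "X"
    if len(by_family[f0]) > 2:
        group[by_family[f0][2]] = "Y"
    group[by_family[f1][0]] = "X"
    unassigned = [c for c in compound_ids if c not in group]
    n_x = sum(1 for v in group.values() if v == "X")
    for c in unassigned:
        want_x = n_x < (len(compound_ids) + 1) // 2
        # keep at least one Y; alternate to balance
        group[c] = "X" if want_x else "Y"
        n_x += group[c] == "X"
    if "Y" not in group.values():
        group[compound_ids[-1]] = "Y"

    similar_pair_split = (
        (by_family[f0][0], by_family[f0][2]) if len(by_family[f0]) > 2 else None
    )
    dissimilar_pair_cocluster = (by_family[f0][0], by_family[f1][0])

    hub_mask = np.array([p in hubs for p in proteins])
    scores = np.empty((n_compounds, n_proteins))
    for i, cid in enumerate(compound_ids):
        on_hubs = group[cid] == "X"
        hi = rng.uniform(*HIGH_RANGE, size=n_proteins)
        lo = rng.uniform(*LOW_RANGE, size=n_proteins)
        scores[i] = np.where(hub_mask == on_hubs, hi, lo)
    scores += rng.normal(0.0, noise_sd, size=scores.shape)
    np.clip(scores, 0.0, 10.0, out=scores)
    docking = pd.DataFrame(
        np.round(scores, 4), index=compound_ids, columns=proteins
    )
    docking_path = out_dir / "docking_scores.csv"
    DockingScoreMatrix(scores=docking).to_csv(docking_path)

    truth = {
        "seed": seed,
        "n_compounds": n_compounds,
        "n_proteins": n_proteins,
        "n_hub_proteins": n_hub_proteins,
        "noise_sd": noise_sd,
        "hub_proteins": list(hubs),
        "labels": {
            "structure": structure_labels,
            "docking": dict(group),
            "network": dict(group),
        },
        "planted_pairs": {
            "structurally_similar_network_split": similar_pair_split,
            "structurally_dissimilar_network_cocluster": dissimilar_pair_cocluster,
        },
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return FixtureBundle(
        smiles_path=smiles_path,
        docking_path=docking_path,
        ppi_path=ppi_path,
        truth_path=truth_path,
        truth=truth,
    )


def _data_path(name: str):
    return resources.files("netscreen.data").joinpath(name)


def reference_compounds() -> CompoundSet:
    """The packaged twelve-compound anti-ageing benchmark set."""
    with resources.as_file(_data_path("reference_compounds.smi")) as p:
        return load_compounds(p, format="smiles")


def reference_targets() -> pd.DataFrame:
    """The packaged 45-protein docking target panel.

    Columns: ``symbol``, ``pdb_id``, ``ppi_degree`` (nullable integer; left
    missing where the published table's digit grouping was ambiguous).
    """
    with resources.as_file(_data_path("docked_targets.csv")) as p:
        df = pd.read_csv(p, dtype={"symbol": str, "pdb_id": str})
    df["ppi_degree"] = df["ppi_degree"].astype("Int64")
    return df
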