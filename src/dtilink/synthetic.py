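"""Self-contained synthetic world with planted, recoverable structure.

The generator emulates the five input tables of the pipeline without
any external downloads: drugs fall into structural clusters (a shared
166-bit centroid fingerprint with independent bit flips), proteins
into families (a shared ancestor sequence with point mutations), and
diseases attach preferentially to one (drug cluster, protein cluster)
pair each, bridging the two layers.  A total ``type_rule`` maps every
cluster pair either to one of the six interaction-type labels or to
``None``; known positives are sampled from typed cells and validated
negatives from untyped cells.  Because the interaction type is a
deterministic function of the planted cluster pair, a pipeline that
recovers the cluster structure in its embeddings can recover the types
— which is exactly what the recovery harness measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .config import PipelineConfig
from .dataset import L6, InteractionRow, InteractionTable
from .embedding import WalkConfig, embed_graph
from .exceptions import ConfigError
from .graph import (
    ASSOC_DISEASE_DRUG,
    ASSOC_DISEASE_PROTEIN,
    AssociationTable,
    build_hetero_graph,
)
from .model import DrugTargetModel, TrainConfig
from .similarity import (
    MACCS_NBITS,
    BitFingerprint,
    ProteinRecord,
    fingerprint_similarity_matrix,
    protein_similarity_matrix,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def default_type_rule(n_drug_clusters: int, n_protein_clusters: int) -> dict:
    """Assign the six labels to cluster cells row-major, leaving the rest untyped.

    For the default 3x3 grid this yields six typed cells (one per
    label) and three untyped cells that supply validated negatives.
    """
    rule: dict[tuple[int, int], str | None] = {}
    cells = [(i, j) for i in range(n_drug_clusters) for j in range(n_protein_clusters)]
    # spread untyped cells across drug-cluster rows so every row has negatives
    untyped = {(i, n_protein_clusters - 1) for i in range(n_drug_clusters)}
    lab_iter = iter(np.resize(np.array(L6, dtype=object), len(cells)))
    for cell in cells:
        rule[cell] = None if cell in untyped else str(next(lab_iter))
    return rule


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the planted-cluster world.

    Defaults give a minutes-scale world: 3x3 clusters, 15 drugs and 20
    proteins per cluster, 30 diseases, 5% fingerprint bit-flip noise
    and 10% sequence point mutations.
    """

    n_drug_clusters: int = 3
    n_protein_clusters: int = 3
    drugs_per_cluster: int = 15
    proteins_per_cluster: int = 20
    n_diseases: int = 30
    fingerprint_noise: float = 0.05
    sequence_mutation_rate: float = 0.10
    type_rule: Mapping[tuple[int, int], str | None] | None = None
    negative_fraction: float = 0.05
    positive_rate: float = 0.25
    protein_length: int = 120
    centroid_density: float = 0.25
    disease_degree: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fingerprint_noise < 0.5:
            raise ConfigError("fingerprint_noise must lie in [0, 0.5)")
        if not 0 <= self.sequence_mutation_rate < 1:
            raise ConfigError("sequence_mutation_rate must lie in [0, 1)")
        if not 0 < self.negative_fraction < 1:
            raise ConfigError("negative_fraction must lie in (0, 1)")

    def resolved_rule(self) -> dict[tuple[int, int], str | None]:
        if self.type_rule is not None:
            rule = dict(self.type_rule)
            cells = {
                (i, j)
                for i in range(self.n_drug_clusters)
                for j in range(self.n_protein_clusters)
            }
            if set(rule) != cells:
                raise ConfigError("type_rule must cover every cluster pair")
            bad = {v for v in rule.values() if v is not None and v not in L6}
            if bad:
                raise ConfigError(f"type_rule labels outside vocabulary: {sorted(bad)}")
            return rule
        return default_type_rule(self.n_drug_clusters, self.n_protein_clusters)


@dataclass
class World:
    """In-memory synthetic world plus its ground truth."""

    cfg: WorldConfig
    drug_ids: list[str]
    fingerprints: list[BitFingerprint]
    drug_cluster: dict[str, int]
    proteins: list[ProteinRecord]
    protein_cluster: dict[str, int]
    ddis: AssociationTable
    disp: AssociationTable
    interactions: InteractionTable
    truth: dict[tuple[str, str], str | None] = field(repr=False)

    def planted_label(self, drug_id: str, protein_id: str) -> str | None:
        rule = self.cfg.resolved_rule()
        return rule[(self.drug_cluster[drug_id], self.protein_cluster[protein_id])]

    def write(self, outdir) -> None:
        """Write the five pipeline inputs plus the ground-truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "drugs.tsv", "w") as fh:
            fh.write("drug_id\tfingerprint\n")
            for did, fp in zip(self.drug_ids, self.fingerprints):
                fh.write(did + "\t" + "".join("1" if b else "0" for b in fp.bits) + "\n")
        with open(outdir / "proteins.fasta", "w") as fh:
            for rec in self.proteins:
                fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
        self.ddis.to_tsv(outdir / "ddis.tsv")
        self.disp.to_tsv(outdir / "disp.tsv")
        self.interactions.to_tsv(outdir / "interactions.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("drug_id\tprotein_id\tplanted_label\n")
            for (d, p), lab in sorted(self.truth.items()):
                fh.write(f"{d}\t{p}\t{lab if lab is not None else 'none'}\n")


def read_fingerprint_table(path) -> tuple[list[str], list[BitFingerprint]]:
    """Read ``drug_id<TAB>166-char bitstring`` rows."""
    ids, fps = [], []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#") or ln.startswith("drug_id\t"):
                continue
            did, bits = ln.split("\t")[:2]
            ids.append(did)
            fps.append(BitFingerprint(np.array([c == "1" for c in bits])))
    return ids, fps


def generate_world(cfg: WorldConfig, outdir=None) -> World:
    """Generate the full world deterministically from ``cfg.seed``."""
    rule = cfg.resolved_rule()
    rng = np.random.default_rng(cfg.seed)

    # drugs: cluster centroid fingerprints with independent bit flips
    centroids = rng.random((cfg.n_drug_clusters, MACCS_NBITS)) < cfg.centroid_density
    drug_ids, fingerprints, drug_cluster = [], [], {}
    for c in range(cfg.n_drug_clusters):
        for k in range(cfg.drugs_per_cluster):
            did = f"d{c * cfg.drugs_per_cluster + k:03d}"
            flips = rng.random(MACCS_NBITS) < cfg.fingerprint_noise
            fingerprints.append(BitFingerprint(np.logical_xor(centroids[c], flips)))
            drug_ids.append(did)
            drug_cluster[did] = c

    # proteins: cluster ancestor sequences with point mutations
    proteins, protein_cluster = [], {}
    aa = np.array(list(AMINO_ACIDS))
    for c in range(cfg.n_protein_clusters):
        ancestor = rng.choice(aa, size=cfg.protein_length)
        for k in range(cfg.proteins_per_cluster):
            pid = f"p{c * cfg.proteins_per_cluster + k:03d}"
            seq = ancestor.copy()
            sites = np.flatnonzero(rng.random(cfg.protein_length) < cfg.sequence_mutation_rate)
            for s in sites:
                choices = [x for x in AMINO_ACIDS if x != seq[s]]
                seq[s] = choices[rng.integers(0, len(choices))]
            proteins.append(ProteinRecord(pid, "".join(seq)))
            protein_cluster[pid] = c

    # diseases: each bridges one (drug cluster, protein cluster) pair
    cells = sorted(rule)
    ddis_edges, disp_edges = [], []
    drugs_by_cluster = [
        [d for d in drug_ids if drug_cluster[d] == c] for c in range(cfg.n_drug_clusters)
    ]
    prots_by_cluster = [
        [p.protein_id for p in proteins if protein_cluster[p.protein_id] == c]
        for c in range(cfg.n_protein_clusters)
    ]
    for z in range(cfg.n_diseases):
        zid = f"z{z:03d}"
        ci, cj = cells[int(rng.integers(0, len(cells)))]
        for d in rng.choice(
            drugs_by_cluster[ci],
            size=min(cfg.disease_degree, len(drugs_by_cluster[ci])),
            replace=False,
        ):
            ddis_edges.append((zid, str(d)))
        for p in rng.choice(
            prots_by_cluster[cj],
            size=min(cfg.disease_degree, len(prots_by_cluster[cj])),
            replace=False,
        ):
            disp_edges.append((zid, str(p)))

    # interactions: positives from typed cells, negatives from untyped cells
    none_cells = [cell for cell, lab in rule.items() if lab is None]
    if not none_cells:
        raise ConfigError(
            "negative_fraction requires at least one untyped (None) cluster pair"
        )
    rows, truth = [], {}
    for d in drug_ids:
        for p in proteins:
            cell = (drug_cluster[d], protein_cluster[p.protein_id])
            lab = rule[cell]
            truth[(d, p.protein_id)] = lab
            u = rng.random()
            if lab is not None and u < cfg.positive_rate:
                rows.append(InteractionRow(d, p.protein_id, frozenset([lab])))
            elif lab is None and u < cfg.negative_fraction:
                rows.append(InteractionRow(d, p.protein_id, frozenset()))
    interactions = InteractionTable(rows)

    world = World(
        cfg=cfg,
        drug_ids=drug_ids,
        fingerprints=fingerprints,
        drug_cluster=drug_cluster,
        proteins=proteins,
        protein_cluster=protein_cluster,
        ddis=AssociationTable(ddis_edges, ASSOC_DISEASE_DRUG),
        disp=AssociationTable(disp_edges, ASSOC_DISEASE_PROTEIN),
        interactions=interactions,
        truth=truth,
    )
    if outdir is not None:
        world.write(outdir)
    return world


def shuffle_interaction_labels(
    table: InteractionTable, seed: int = 0
) -> InteractionTable:
    """Permute label sets among positive rows — the destroyed-structure control."""
    positives = table.positives
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(positives))
    shuffled_labels = [positives[int(i)].labels for i in perm]
    rows = []
    k = 0
    for r in table.rows:
        if r.is_negative:
            rows.append(r)
        else:
            rows.append(InteractionRow(r.drug_id, r.protein_id, shuffled_labels[k]))
            k += 1
    return InteractionTable(rows)


def recovery_harness(
    cfg: WorldConfig,
    pipeline: PipelineConfig | None = None,
    shuffle_labels: bool = False,
    return_objects: bool = False,
) -> dict:
    """Run the whole pipeline on a generated world and score recovery.

    similarity -> graph -> embedding -> dataset -> model -> evaluate,
    reporting macro accuracy/F1/precision on the external test split
    and the binary screen accuracy.  With ``shuffle_labels`` the
    planted structure is destroyed first (permutation control).
    """
    pipeline = pipeline or PipelineConfig(seed=cfg.seed)
    world = generate_world(cfg)
    dds = fingerprint_similarity_matrix(world.drug_ids, world.fingerprints)
    pps = protein_similarity_matrix(world.proteins, workers=pipeline.workers)
    g = build_hetero_graph(dds, pps, world.ddis, world.disp, pipeline.sim_threshold)
    emb = embed_graph(
        g,
        WalkConfig(
            num_walks_per_node=pipeline.num_walks_per_node,
            walk_length=pipeline.walk_length,
            p=pipeline.p,
            q=pipeline.q,
            seed=pipeline.seed,
        ),
        dim=pipeline.dim,
        window=pipeline.window,
        negatives=pipeline.negatives,
        epochs=pipeline.epochs,
        seed=pipeline.seed,
    )
    interactions = world.interactions
    if shuffle_labels:
        interactions = shuffle_interaction_labels(interactions, seed=pipeline.seed)
    train_cfg = TrainConfig(**{**pipeline.train.__dict__, "seed": pipeline.seed})
    model = DrugTargetModel(emb, interactions, config=train_cfg)
    results = model.fit(repeats=pipeline.repeats, seed=pipeline.seed)
    report = {
        "macro_accuracy": results.macro_accuracy,
        "macro_f1": results.macro_f1,
        "macro_precision": results.macro_precision,
        "binary_accuracy": results.binary_accuracy,
        "n_interactions": len(interactions),
        "n_positive": len(interactions.positives),
        "n_negative": len(interactions.negatives),
    }
    if return_objects:
        report["world"] = world
        report["embeddings"] = emb
        report["results"] = results
    return report
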