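"""Node embeddings via second-order biased random walks and skip-gram.

The walk procedure follows node2vec: from the previous node ``t`` and
current node ``v``, a neighbour ``x`` is drawn with unnormalised weight

    w(v, x) * alpha(t, x),   alpha = 1/p if x == t,
                                     1   if x adjacent to t,
                                     1/q otherwise,

where ``p`` controls the tendency to return and ``q`` the tendency to
explore outward.  Edge weights (the similarities) multiply the bias, so
walks prefer strongly similar neighbours.  The walk corpus trains a
skip-gram model with negative sampling; the trainer here is a compact,
single-threaded numpy implementation so a fixed seed yields bit-stable
embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .exceptions import DimensionError, MissingEmbeddingError

#: sentinel passed as ``prev`` on the first step of a walk
WALK_START = None

DEFAULT_DIM = 100


@dataclass(frozen=True)
class WalkConfig:
    """Second-order random-walk parameters.

    Defaults are the canonical ones of the walk family: 10 walks per
    node of length 80 with p = q = 1 (unbiased within edge weights).
    """

    num_walks_per_node: int = 10
    walk_length: int = 80
    p: float = 1.0
    q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_walks_per_node < 1 or self.walk_length < 1:
            raise ValueError("walk counts and lengths must be positive")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


class EmbeddingTable:
    """Map node identifier -> fixed-dimension real vector."""

    def __init__(self, ids: Sequence[str], vectors: np.ndarray):
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[0] != len(ids):
            raise DimensionError("vectors must be a (n_ids, dim) matrix")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embedding vectors must be finite")
        self.ids = list(ids)
        self.vectors = vectors
        self._index = {node: i for i, node in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def get(self, node_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[node_id]]
        except KeyError:
            raise MissingEmbeddingError(f"no embedding for node {node_id!r}") from None

    def to_tsv(self, path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            for node, vec in zip(self.ids, self.vectors):
                fh.write(node + "\t" + "\t".join(f"{v:.8g}" for v in vec) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingTable":
        ids, rows = [], []
        with open(path) as fh:
            for ln in fh:
                ln = ln.rstrip("\n")
                if not ln.strip() or ln.startswith("#"):
                    continue
                parts = ln.split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(ids, np.asarray(rows, dtype=float))


# ---------------------------------------------------------------------------
# Biased walks
# ---------------------------------------------------------------------------

def transition_distribution(
    g: nx.Graph, prev, cur, p: float, q: float
) -> tuple[list, np.ndarray]:
    """Second-order transition probabilities out of ``cur`` given ``prev``.

    Returns (neighbours, probabilities); both empty when ``cur`` is
    isolated, which signals the walk to terminate.  At a walk start
    (``prev is WALK_START``) the bias factor is 1 for every neighbour,
    i.e. the step is first-order in the edge weights.
    """
    nbrs = sorted(g.neighbors(cur))
    if not nbrs:
        return [], np.array([])
    weights = np.array([g[cur][x].get("weight", 1.0) for x in nbrs], dtype=float)
    if prev is not WALK_START:
        alpha = np.empty(len(nbrs))
        prev_nbrs = set(g.neighbors(prev))
        for k, x in enumerate(nbrs):
            if x == prev:
                alpha[k] = 1.0 / p
            elif x in prev_nbrs:
                alpha[k] = 1.0
            else:
                alpha[k] = 1.0 / q
        weights = weights * alpha
    return nbrs, weights / weights.sum()


def generate_walks(g: nx.Graph, cfg: WalkConfig) -> list[list]:
    """Generate ``num_walks_per_node`` biased walks from every node.

    Deterministic for a fixed config seed.  Walks stop early only at a
    dead end (isolated node), giving a single-node walk.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot walk an empty graph")
    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(g.nodes)

    # cache of cumulative transition distributions keyed by (prev, cur)
    cache: dict[tuple, tuple[list, np.ndarray]] = {}

    def step(prev, cur):
        key = (prev, cur)
        if key not in cache:
            nbrs, probs = transition_distribution(g, prev, cur, cfg.p, cfg.q)
            cache[key] = (nbrs, np.cumsum(probs) if len(nbrs) else probs)
        nbrs, cum = cache[key]
        if not nbrs:
            return None
        return nbrs[int(np.searchsorted(cum, rng.random(), side="right"))]

    walks: list[list] = []
    for _ in range(cfg.num_walks_per_node):
        for start in nodes:
            walk = [start]
            prev = WALK_START
            while len(walk) < cfg.walk_length:
                nxt = step(prev, walk[-1])
                if nxt is None:
                    break
                prev = walk[-1]
                walk.append(nxt)
            walks.append(walk)
    return walks


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling
# ---------------------------------------------------------------------------

def _skipgram_pairs(tokens: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) pairs within ``window`` of one walk, both directions."""
    centers, contexts = [], []
    n = len(tokens)
    for off in range(1, min(window, n - 1) + 1):
        a, b = tokens[:-off], tokens[off:]
        centers.append(a)
        contexts.append(b)
        centers.append(b)
        contexts.append(a)
    if not centers:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_embeddings(
    walks: Sequence[Sequence[str]],
    dim: int = DEFAULT_DIM,
    window: int = 10,
    negatives: int = 5,
    epochs: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    batch_size: int = 2048,
    seed: int = 0,
) -> EmbeddingTable:
    """Train skip-gram-with-negative-sampling embeddings on a walk corpus.

    Negative targets are drawn from the unigram distribution raised to
    the 3/4 power; the learning rate decays linearly across batches.
    Single-threaded and fully seeded, so output is reproducible.
    """
    if not walks:
        raise ValueError("walk corpus is empty")
    vocab = sorted({node for walk in walks for node in walk})
    index = {node: i for i, node in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(seed)

    encoded = [np.array([index[n] for n in w], dtype=np.int64) for w in walks]
    counts = np.bincount(np.concatenate(encoded), minlength=V).astype(float)
    noise = counts**0.75
    noise_cum = np.cumsum(noise / noise.sum())

    w_in = ((rng.random((V, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((V, dim), dtype=np.float32)

    # pre-count batches for the linear learning-rate schedule
    pairs_per_epoch = sum(
        2 * max(0, len(t) - off)
        for t in encoded
        for off in range(1, min(window, len(t) - 1) + 1)
    )
    total_batches = max(1, epochs * ((pairs_per_epoch + batch_size - 1) // batch_size))
    batch_no = 0

    for _ in range(epochs):
        order = rng.permutation(len(encoded))
        centers = []
        contexts = []
        for wi in order:
            c, o = _skipgram_pairs(encoded[wi], window)
            centers.append(c)
            contexts.append(o)
        centers = np.concatenate(centers)
        contexts = np.concatenate(contexts)
        perm = rng.permutation(len(centers))
        centers, contexts = centers[perm], contexts[perm]

        for s in range(0, len(centers), batch_size):
            lr = alpha + (min_alpha - alpha) * (batch_no / total_batches)
            batch_no += 1
            c = centers[s : s + batch_size]
            o = contexts[s : s + batch_size]
            B = len(c)
            negs = np.searchsorted(
                noise_cum, rng.random((B, negatives)), side="right"
            ).astype(np.int64)
            targets = np.concatenate([o[:, None], negs], axis=1)  # (B, 1+K)
            labels = np.zeros((B, 1 + negatives))
            labels[:, 0] = 1.0

            vc = w_in[c]  # (B, d)
            ut = w_out[targets]  # (B, 1+K, d)
            scores = np.einsum("bd,bkd->bk", vc, ut)
            # saturate beyond |score| = 6 (zero gradient), as in canonical word2vec
            sig = 1.0 / (1.0 + np.exp(-np.clip(scores, -6.0, 6.0)))
            sig = np.where(scores > 6.0, 1.0, np.where(scores < -6.0, 0.0, sig))
            gvec = ((labels - sig) * lr).astype(np.float32)
            grad_c = np.einsum("bk,bkd->bd", gvec, ut)
            grad_t = gvec[:, :, None] * vc[:, None, :]
            # per-row mean gradient keeps the step bounded by lr regardless of
            # how often a node recurs within the batch
            t_flat = targets.ravel()
            acc_out = np.zeros_like(w_out)
            np.add.at(acc_out, t_flat, grad_t.reshape(-1, dim))
            cnt_out = np.bincount(t_flat, minlength=V)[:, None]
            w_out += acc_out / np.maximum(cnt_out, 1)
            acc_in = np.zeros_like(w_in)
            np.add.at(acc_in, c, grad_c)
            cnt_in = np.bincount(c, minlength=V)[:, None]
            w_in += acc_in / np.maximum(cnt_in, 1)

    return EmbeddingTable(vocab, w_in.astype(float))


def write_walks(walks: Sequence[Sequence[str]], path) -> None:
    """Dump a walk corpus as whitespace-separated node-id lines."""
    with open(path, "w") as fh:
        for walk in walks:
            fh.write(" ".join(walk) + "\n")


def read_walks(path) -> list[list[str]]:
    with open(path) as fh:
        return [ln.split() for ln in fh if ln.strip()]


def embed_graph(
    g: nx.Graph,
    walk_cfg: WalkConfig | None = None,
    dim: int = DEFAULT_DIM,
    window: int = 10,
    negatives: int = 5,
    epochs: int = 5,
    seed: int = 0,
) -> EmbeddingTable:
    """Walk + train convenience wrapper; guarantees coverage of every node."""
    walk_cfg = walk_cfg or WalkConfig(seed=seed)
    walks = generate_walks(g, walk_cfg)
    table = train_embeddings(
        walks, dim=dim, window=window, negatives=negatives, epochs=epochs, seed=seed
    )
    missing = [n for n in g.nodes if n not in table]
    if missing:  # unreachable given generate_walks starts from every node
        raise MissingEmbeddingError(f"nodes absent from all walks: {sorted(missing)[:5]}")
    return table
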