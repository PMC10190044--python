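"""Chemical and protein similarity layers.

Drug-drug similarity is the Tanimoto coefficient over 166-bit MACCS
structural keys computed from canonical SMILES.  Protein-protein
similarity is a normalised local-alignment score: the Smith-Waterman
score of the pair divided by the geometric mean of the two
self-alignment scores, which keeps values in [0, 1] and symmetric.

Both layers are exposed as :class:`SimilarityMatrix` objects, the
inputs of the heterogeneous graph builder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .exceptions import (
    DimensionError,
    DuplicateIdentifierError,
    InvalidMoleculeError,
    InvalidSequenceError,
)

MACCS_NBITS = 166

# 20 standard residues; X tolerated as an unknown residue.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_SUBSTITUTION_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class Molecule:
    """A drug identified by an opaque id and a canonical SMILES string."""

    drug_id: str
    smiles: str


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by an opaque id and an amino-acid sequence."""

    protein_id: str
    sequence: str


@dataclass(frozen=True)
class BitFingerprint:
    """A 166-position binary structural-key vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=bool)
        if arr.shape != (MACCS_NBITS,):
            raise DimensionError(
                f"fingerprint must have exactly {MACCS_NBITS} bits, got shape {arr.shape}"
            )
        object.__setattr__(self, "bits", arr)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())

    @classmethod
    def from_on_bits(cls, on: Iterable[int]) -> "BitFingerprint":
        bits = np.zeros(MACCS_NBITS, dtype=bool)
        idx = list(on)
        if idx:
            bits[np.asarray(idx, dtype=int)] = True
        return cls(bits)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity matrix over one node layer.

    Invariants: square, symmetric, entries in [0, 1], unit diagonal,
    dimension equal to ``len(ids)``.
    """

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DimensionError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise DuplicateIdentifierError("similarity matrix ids must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def to_tsv(self, path, header_comments: Sequence[str] = ()) -> None:
        """Write as TSV with a leading id row and id column (10 significant digits)."""
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, node in enumerate(self.ids):
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{node}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")[1:]
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append([float(x) for x in parts[1:]])
        return cls(ids=header, values=np.asarray(rows, dtype=float))


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto
# ---------------------------------------------------------------------------

def maccs_fingerprint(mol: Molecule) -> BitFingerprint:
    """Compute the 166 MACCS structural keys of a molecule.

    rdkit emits a 167-bit vector whose bit 0 is a placeholder; it is
    dropped so positions 0..165 correspond to keys 1..166.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    rd = Chem.MolFromSmiles(mol.smiles) if mol.smiles else None
    if rd is None:
        raise InvalidMoleculeError(
            f"SMILES for drug {mol.drug_id!r} could not be parsed: {mol.smiles!r}"
        )
    fp = MACCSkeys.GenMACCSKeys(rd)
    bits = np.zeros(MACCS_NBITS, dtype=bool)
    for b in fp.GetOnBits():
        if b >= 1:  # bit 0 is unused in the MACCS definition
            bits[b - 1] = True
    return BitFingerprint(bits)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |a∧b| / (|a| + |b| - |a∧b|).

    Two all-zero fingerprints are treated as identical objects and
    score 1.0 (with a warning); the ratio itself is 0/0.
    """
    na, nb = a.popcount, b.popcount
    if na == 0 and nb == 0:
        warnings.warn(
            "Tanimoto of two empty fingerprints is undefined; returning 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    c = int(np.logical_and(a.bits, b.bits).sum())
    return c / (na + nb - c)


def drug_similarity_matrix(mols: Sequence[Molecule]) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over MACCS fingerprints, in input order."""
    ids = [m.drug_id for m in mols]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIdentifierError(f"duplicate drug ids: {dupes}")
    fps = [maccs_fingerprint(m) for m in mols]
    return fingerprint_similarity_matrix(ids, fps)


def fingerprint_similarity_matrix(
    ids: Sequence[str], fps: Sequence[BitFingerprint]
) -> SimilarityMatrix:
    """Tanimoto matrix from precomputed fingerprints (the synthetic-world path)."""
    if len(set(ids)) != len(ids):
        raise DuplicateIdentifierError("duplicate ids in fingerprint table")
    if len(ids) != len(fps):
        raise DimensionError("ids and fingerprints must align")
    mat = np.stack([fp.bits for fp in fps]).astype(np.int64)
    pops = mat.sum(axis=1)
    inter = mat @ mat.T
    denom = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(denom > 0, inter / np.maximum(denom, 1), 1.0)
    np.fill_diagonal(sims, 1.0)
    return SimilarityMatrix(ids=list(ids), values=sims)


# ---------------------------------------------------------------------------
# Protein similarity
# ---------------------------------------------------------------------------

def _make_aligner(substitution_matrix: str, gap_open: float, gap_extend: float):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _check_sequence(rec: ProteinRecord) -> None:
    if not rec.sequence:
        raise InvalidSequenceError(f"protein {rec.protein_id!r} has an empty sequence")
    bad = set(rec.sequence.upper()) - AMINO_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"protein {rec.protein_id!r} contains invalid characters: {sorted(bad)}"
        )


def protein_similarity(
    a: ProteinRecord,
    b: ProteinRecord,
    substitution_matrix: str = DEFAULT_SUBSTITUTION_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Normalised local-alignment similarity S(a,b)/sqrt(S(a,a)·S(b,b)), clipped to [0,1]."""
    _check_sequence(a)
    _check_sequence(b)
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    s_ab = max(aligner.score(a.sequence.upper(), b.sequence.upper()), 0.0)
    s_aa = aligner.score(a.sequence.upper(), a.sequence.upper())
    s_bb = aligner.score(b.sequence.upper(), b.sequence.upper())
    if s_aa <= 0 or s_bb <= 0:
        return 0.0
    return float(np.clip(s_ab / np.sqrt(s_aa * s_bb), 0.0, 1.0))


def _score_block(
    pairs: list[tuple[int, int]],
    sequences: list[str],
    substitution_matrix: str,
    gap_open: float,
    gap_extend: float,
) -> list[tuple[int, int, float]]:
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    out = []
    for i, j in pairs:
        out.append((i, j, max(aligner.score(sequences[i], sequences[j]), 0.0)))
    return out


def protein_similarity_matrix(
    prots: Sequence[ProteinRecord],
    workers: int = 1,
    substitution_matrix: str = DEFAULT_SUBSTITUTION_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> SimilarityMatrix:
    """Full pairwise normalised-alignment matrix.

    The pair list is partitioned into fixed blocks so the result is
    identical for any ``workers`` value; parallelism only changes wall
    time, never output.
    """
    ids = [p.protein_id for p in prots]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIdentifierError(f"duplicate protein ids: {dupes}")
    if workers < 1:
        raise ValueError("workers must be a positive integer")
    for p in prots:
        _check_sequence(p)
    seqs = [p.sequence.upper() for p in prots]
    n = len(seqs)

    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    self_scores = np.array([aligner.score(s, s) for s in seqs], dtype=float)

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if workers == 1 or len(pairs) < 64:
        blocks = [_score_block(pairs, seqs, substitution_matrix, gap_open, gap_extend)]
    else:
        chunk = max(1, (len(pairs) + workers - 1) // workers)
        chunks = [pairs[k : k + chunk] for k in range(0, len(pairs), chunk)]
        blocks = Parallel(n_jobs=workers)(
            delayed(_score_block)(c, seqs, substitution_matrix, gap_open, gap_extend)
            for c in chunks
        )

    mat = np.eye(n)
    for block in blocks:
        for i, j, raw in block:
            denom = np.sqrt(self_scores[i] * self_scores[j])
            val = float(np.clip(raw / denom, 0.0, 1.0)) if denom > 0 else 0.0
            mat[i, j] = mat[j, i] = val
    return SimilarityMatrix(ids=ids, values=mat)


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def read_drug_table(path) -> list[Molecule]:
    """Read a TSV with header ``drug_id<TAB>smiles``."""
    mols: list[Molecule] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    for ln in lines[1:]:
        drug_id, smiles = ln.split("\t")[:2]
        mols.append(Molecule(drug_id=drug_id, smiles=smiles))
    return mols


def read_protein_table(path) -> list[ProteinRecord]:
    """Read proteins from FASTA (``.fa``/``.fasta``) or 2-column TSV."""
    path = str(path)
    if path.endswith((".fa", ".fasta", ".faa")):
        from Bio import SeqIO

        return [
            ProteinRecord(protein_id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(path, "fasta")
        ]
    prots: list[ProteinRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    start = 1 if lines and lines[0].lower().startswith("protein_id") else 0
    for ln in lines[start:]:
        pid, seq = ln.split("\t")[:2]
        prots.append(ProteinRecord(protein_id=pid, sequence=seq))
    return prots
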