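"""Fixed per-residue amino-acid embeddings.

The transformer consumes frozen per-residue embedding matrices rather than
learning its own amino-acid vocabulary, the transfer-learning strategy used
with large pre-trained protein language models (TAPE / ESM-1b / UniRep).
Two providers are available:

* :class:`LookupTableProvider` — a deterministic offline table: each of the
  20 residues (plus ``X``) maps to a fixed random Gaussian vector drawn
  once from a seed.  Builds with no network or model weights; a pure
  function of (seed, residue).
* :class:`PrecomputedProvider` — serves per-sequence matrices exported from
  any external protein language model, stored as a compressed ``.npz``
  archive keyed by FASTA record id.

Both are frozen by contract: no gradient ever reaches them, and repeated
calls are bit-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # 20 residues + unknown
DEFAULT_L_MAX = 1000


@dataclasses.dataclass
class SequenceEmbedding:
    """Padded per-residue embedding matrix with its attention mask."""

    matrix: np.ndarray          # (L_max, d_seq)
    attention_mask: np.ndarray  # (L_max,) with 1 for real residues
    length: int                 # true sequence length

    @property
    def d_seq(self) -> int:
        return self.matrix.shape[1]


def _validate_sequence(sequence: str) -> None:
    for pos, ch in enumerate(sequence):
        if ch not in ALPHABET:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} (0-based); "
                f"alphabet is {ALPHABET}")


class LookupTableProvider:
    """Seeded per-residue lookup table; the offline default provider."""

    def __init__(self, seed: int = 0, d_seq: int = 128):
        self.seed = seed
        self.d_seq = d_seq
        rng = np.random.default_rng(seed)
        # unit-scale vectors; padding is a dedicated all-zero row
        self.table = {ch: rng.normal(0, 1.0, size=d_seq) / np.sqrt(d_seq)
                      for ch in ALPHABET}

    def matrix_for(self, sequence: str) -> np.ndarray:
        _validate_sequence(sequence)
        return np.stack([self.table[ch] for ch in sequence])


class ContextWindowProvider:
    """Seeded local-context embeddings: a fixed random linear code of each
    position's residue window.

    Mirrors the *contextual* character of pre-trained protein language
    models (a TAPE/ESM position vector encodes its sequence neighborhood,
    not just the residue identity) in a deterministic offline form: the
    embedding of position i is sum_k P_k @ t[s[i+k]] over offsets k in
    [-w, w], with per-residue vectors t and per-offset projections P_k all
    drawn once from the seed.  Frozen and a pure function of
    (seed, local window); positions near the ends use only in-range
    offsets.
    """

    def __init__(self, seed: int = 0, d_seq: int = 128, window: int = 2):
        self.seed = seed
        self.d_seq = d_seq
        self.window = window
        rng = np.random.default_rng(seed)
        self.table = {ch: rng.normal(0, 1.0, size=d_seq) / np.sqrt(d_seq)
                      for ch in ALPHABET}
        n_off = 2 * window + 1
        self.offset_proj = rng.normal(0, 1.0, size=(n_off, d_seq, d_seq)) \
            / np.sqrt(d_seq * n_off)

    def matrix_for(self, sequence: str) -> np.ndarray:
        _validate_sequence(sequence)
        L = len(sequence)
        base = np.stack([self.table[ch] for ch in sequence])  # (L, d)
        out = np.zeros((L, self.d_seq))
        for j, k in enumerate(range(-self.window, self.window + 1)):
            lo, hi = max(0, -k), min(L, L - k)
            out[lo:hi] += base[lo + k:hi + k] @ self.offset_proj[j].T
        return out


class PrecomputedProvider:
    """Serves per-id embedding matrices stored in a compressed npz archive."""

    def __init__(self, matrices: dict[str, np.ndarray]):
        widths = {m.shape[1] for m in matrices.values()}
        if len(widths) > 1:
            raise ValueError(f"inconsistent embedding widths across records: {widths}")
        self.matrices = {k: np.asarray(v, dtype=np.float64)
                         for k, v in matrices.items()}
        self.d_seq = next(iter(widths)) if widths else 0
        self._by_sequence: dict[str, str] = {}

    @classmethod
    def from_file(cls, path: str | Path) -> "PrecomputedProvider":
        with np.load(path) as data:
            return cls({k: data[k] for k in data.files})

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, **self.matrices)

    def bind_manifest(self, id_to_sequence: dict[str, str]) -> None:
        """Allow lookup by sequence for ids declared in a manifest."""
        missing = set(id_to_sequence) - set(self.matrices)
        if missing:
            raise KeyError(f"embedding file is missing ids: {sorted(missing)[:5]}")
        self._by_sequence = {seq: rid for rid, seq in id_to_sequence.items()}

    def matrix_for(self, sequence_or_id: str) -> np.ndarray:
        if sequence_or_id in self.matrices:
            return self.matrices[sequence_or_id]
        rid = self._by_sequence.get(sequence_or_id)
        if rid is None:
            raise KeyError("no precomputed embedding for the given id/sequence")
        return self.matrices[rid]


def load_precomputed(embedding_file: str | Path,
                     manifest: "dict[str, str] | None" = None) -> PrecomputedProvider:
    """Load a precomputed-embedding provider, optionally bound to a manifest
    (mapping record id -> sequence) so sequences can be looked up directly."""
    provider = PrecomputedProvider.from_file(embedding_file)
    if manifest is not None:
        provider.bind_manifest(manifest)
    return provider


def embed(sequence: str, provider, L_max: int = DEFAULT_L_MAX,
          truncate: bool = False) -> SequenceEmbedding:
    """Embed a sequence to an (L_max, d_seq) padded matrix plus mask.

    Rows beyond the true length are the zero padding vector and masked out.
    Sequences longer than ``L_max`` raise unless ``truncate`` is set, in
    which case the N-terminal ``L_max`` residues are kept.
    """
    _validate_sequence(sequence)
    if len(sequence) > L_max:
        if not truncate:
            raise ValueError(f"sequence length {len(sequence)} exceeds context "
                             f"L_max={L_max}; pass truncate=True to keep the "
                             "N-terminal portion")
        sequence = sequence[:L_max]
    mat = provider.matrix_for(sequence)
    if mat.shape[0] != len(sequence):
        raise ValueError("provider returned a matrix with the wrong length")
    d = mat.shape[1]
    out = np.zeros((L_max, d))
    out[:len(sequence)] = mat
    mask = np.zeros(L_max)
    mask[:len(sequence)] = 1.0
    return SequenceEmbedding(matrix=out, attention_mask=mask, length=len(sequence))
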