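"""MinHash genome sketching and k-mer distances.

A sketch keeps the ``s`` smallest 64-bit hash values over a genome's
canonical 21-mers (a k-mer and its reverse complement count once, as their
lexicographic minimum).  The fraction of shared hashes among the ``s``
smallest of the union of two sketches estimates the Jaccard similarity
``j`` of the underlying k-mer sets, which converts to a genome distance

    d = -(1/k) * ln(2j / (1 + j)),  capped at 1,

an estimate of per-base divergence, so ``1 - d`` approximates average
nucleotide identity and ``(1 - d) * 100`` a percent identity.

Hashing is a splitmix64-style finalizer over the 2-bit k-mer code, salted
with a configurable seed (default 42) so sketches are deterministic across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 100_000
DEFAULT_HASH_SEED = 42

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def splitmix64(values: np.ndarray, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Vectorized splitmix64 finalizer over uint64 values, salted by seed."""
    z = values.astype(np.uint64, copy=True)
    z += np.uint64((seed + 1) * 0x9E3779B97F4A7C15 % (1 << 64))
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def canonical_kmer_codes(sequence: str, k: int = DEFAULT_K) -> np.ndarray:
    """Distinct canonical k-mer codes of a sequence as sorted uint64.

    K-mers containing non-ACGT symbols are skipped.  Raises ``ValueError``
    if the sequence is shorter than ``k`` or yields no valid k-mer.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    if 4 ** k > 2 ** 63:
        raise ValueError(f"k={k} too large for 2-bit packing")
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    valid = codes != 255
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    win = win[ok].astype(np.uint64)
    if win.size == 0:
        raise ValueError("no valid (ACGT-only) k-mer in sequence")
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    forward = win @ powers
    # reverse complement: complement each base (3 - c) and reverse the order
    reverse = (np.uint64(3) - win) @ powers[::-1]
    return np.unique(np.minimum(forward, reverse))


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of one genome."""

    k: int
    size: int
    hash_seed: int
    hashes: np.ndarray = field(repr=False)  # sorted, strictly increasing uint64

    @property
    def n_hashes(self) -> int:
        return int(self.hashes.size)


@dataclass(frozen=True)
class DistanceRecord:
    query_id: str
    subject_id: str
    jaccard: float
    distance: float

    @property
    def pid(self) -> float:
        """Percent identity implied by the distance."""
        return (1.0 - self.distance) * 100.0


def sketch_genome(
    sequence: str,
    k: int = DEFAULT_K,
    size: int = DEFAULT_SKETCH_SIZE,
    seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Sketch a genome: the ``size`` smallest salted hashes of its canonical k-mers."""
    codes = canonical_kmer_codes(sequence, k)
    hashes = np.sort(splitmix64(codes, seed))[:size]
    return Sketch(k=k, size=size, hash_seed=seed, hashes=hashes)


def jaccard_to_distance(jaccard: float, k: int) -> float:
    """Convert an estimated k-mer Jaccard similarity to a genome distance."""
    if jaccard <= 0.0:
        return 1.0
    return min(1.0, max(0.0, -np.log(2.0 * jaccard / (1.0 + jaccard)) / k))


def _bottom_s_jaccard(a: np.ndarray, b: np.ndarray, s: int) -> float:
    """Shared fraction among the s smallest distinct hashes of the union."""
    values, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    bottom = min(s, values.size)
    if bottom == 0:
        return 0.0
    return int((counts[:bottom] > 1).sum()) / bottom


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """Estimate Jaccard similarity via the merged bottom-s procedure."""
    if (a.k, a.size, a.hash_seed) != (b.k, b.size, b.hash_seed):
        raise ValueError(
            "sketches are not comparable: "
            f"(k={a.k}, s={a.size}, seed={a.hash_seed}) vs "
            f"(k={b.k}, s={b.size}, seed={b.hash_seed})"
        )
    return _bottom_s_jaccard(a.hashes, b.hashes, a.size)


def sketch_distance(a: Sketch, b: Sketch, query_id: str = "a", subject_id: str = "b") -> DistanceRecord:
    j = sketch_jaccard(a, b)
    return DistanceRecord(query_id, subject_id, j, jaccard_to_distance(j, a.k))


def exact_kmer_distance(seq_a: str, seq_b: str, k: int = DEFAULT_K) -> DistanceRecord:
    """Distance from the exact (unsampled) canonical k-mer sets of two sequences."""
    ka = canonical_kmer_codes(seq_a, k)
    kb = canonical_kmer_codes(seq_b, k)
    inter = np.intersect1d(ka, kb, assume_unique=True).size
    j = inter / (ka.size + kb.size - inter)
    return DistanceRecord("a", "b", j, jaccard_to_distance(j, k))


def pairwise_sketch_distances(sketches: Mapping[str, Sketch]) -> pd.DataFrame:
    """Symmetric matrix of sketch distances over a set of genomes."""
    ids = list(sketches)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for jdx in range(i + 1, n):
            d = sketch_distance(sketches[ids[i]], sketches[ids[jdx]]).distance
            mat[i, jdx] = mat[jdx, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def min_distance_to_set(
    queries: Mapping[str, Sketch],
    references: Mapping[str, Sketch],
    pid_thresholds: Iterable[float] = (90.0,),
) -> tuple[pd.DataFrame, dict[float, int]]:
    """Closest reference for each query genome, plus binned identity counts.

    For each query the minimum sketch distance (equivalently maximum percent
    identity) to any reference is reported; a reference with the query's own
    id is skipped, so a set can be compared against itself.  The returned
    dict counts queries whose best percent identity reaches each threshold.
    """
    if not references:
        raise ValueError("empty reference set")
    rows = []
    for qid, qsk in queries.items():
        best: DistanceRecord | None = None
        for rid, rsk in references.items():
            if rid == qid:
                continue
            rec = sketch_distance(qsk, rsk, qid, rid)
            if best is None or rec.distance < best.distance:
                best = rec
        if best is None:
            raise ValueError(f"no reference to compare query {qid!r} against")
        rows.append(
            {
                "query_id": qid,
                "subject_id": best.subject_id,
                "jaccard": best.jaccard,
                "min_distance": best.distance,
                "max_pid": best.pid,
            }
        )
    table = pd.DataFrame(rows).set_index("query_id")
    counts = {
        float(t): int((table["max_pid"] >= t).sum()) for t in pid_thresholds
    }
    return table, counts
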