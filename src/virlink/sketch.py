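"""Bottom-s MinHash sketching of contigs and Mash-distance estimation.

A sketch retains the ``s`` smallest 64-bit hash values over the *canonical*
k-mers of a sequence (the lexicographic minimum of each k-mer and its
reverse complement, so a contig and its reverse complement sketch
identically).  The Jaccard index between two k-mer sets is estimated from
the merged bottom-s sketch, and converted to an evolutionary distance with
the Mash formula

    d = -(1/k) * ln( 2j / (1+j) )

which for closely related sequences behaves as d ~ 1 - ANI.  A distance
threshold of 0.05 therefore selects pairs at roughly >= 95% average
nucleotide identity.

K-mers are packed into 64-bit integers (2 bits per base, A<C<G<T matching
lexicographic order) and hashed with a splitmix64 finaliser.  The finaliser
is a bijection on 64-bit integers, so distinct canonical k-mers map to
distinct hash values and the sketch cardinality equals the true distinct
canonical k-mer count whenever ``s`` exceeds it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KmerSketch",
    "DistanceRecord",
    "sketch",
    "jaccard_estimate",
    "mash_distance",
    "pairwise_distances",
    "write_sketches",
    "read_sketches",
]

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_HASH_SEED = 42

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finaliser; bijective on uint64."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _seed_mix(hash_seed: int) -> np.uint64:
    return _splitmix64(np.uint64(hash_seed & 0xFFFFFFFFFFFFFFFF))


@dataclass
class KmerSketch:
    """Bottom-s MinHash sketch of one contig."""

    contig_id: str
    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray  # sorted, strictly increasing uint64
    n_distinct: int  # distinct canonical k-mers in the full sequence
    seq_length: int

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > 1 and not np.all(self.hashes[1:] > self.hashes[:-1]):
            raise ValueError("sketch hashes must be strictly increasing")

    @property
    def hash_set(self) -> frozenset:
        if not hasattr(self, "_hash_set"):
            object.__setattr__(self, "_hash_set", frozenset(self.hashes.tolist()))
        return self._hash_set


@dataclass(frozen=True)
class DistanceRecord:
    """An estimated pairwise Mash distance between two contigs."""

    contig_a: str
    contig_b: str
    jaccard_estimate: float
    mash_distance: float


def canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Return packed 2-bit codes of all canonical k-mers (non-ACGT skipped)."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    window_ok = np.ones(n, dtype=bool)
    # a window is valid iff it contains no invalid base
    bad = np.flatnonzero(~valid)
    for pos in bad:
        lo = max(0, pos - k + 1)
        hi = min(n, pos + 1)
        window_ok[lo:hi] = False
    c = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    rc = np.uint64(3) - c
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | c[i : i + n]
        rev = (rev << np.uint64(2)) | rc[k - 1 - i : k - 1 - i + n]
    canon = np.minimum(fwd, rev)
    return canon[window_ok]


def sketch(
    sequence: str,
    contig_id: str = "",
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> KmerSketch:
    """Sketch a nucleotide sequence.

    Parameters
    ----------
    sequence:
        Nucleotide string; k-mers containing non-ACGT symbols are skipped.
    k:
        Odd k-mer length in [11, 31] (odd so no k-mer is its own reverse
        complement).
    s:
        Sketch size: number of smallest hash values retained.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if not 11 <= k <= 31:
        raise ValueError(f"k must be within [11, 31], got {k}")
    if s < 1:
        raise ValueError("sketch size must be >= 1")
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} shorter than k={k}")
    canon = canonical_kmer_codes(sequence, k)
    with np.errstate(over="ignore"):
        hashes = _splitmix64(canon ^ _seed_mix(hash_seed))
    distinct = np.unique(hashes)  # sorted ascending
    return KmerSketch(
        contig_id=contig_id,
        k=k,
        s=s,
        hash_seed=hash_seed,
        hashes=distinct[:s],
        n_distinct=int(distinct.size),
        seq_length=len(sequence),
    )


def _check_compatible(a: KmerSketch, b: KmerSketch) -> None:
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError(f"mismatched hash seed: {a.hash_seed} vs {b.hash_seed}")


def jaccard_estimate(a: KmerSketch, b: KmerSketch) -> float:
    """Merged-sketch Jaccard estimate.

    Counts shared hash values among the s smallest of the union of the two
    sketches; the denominator is min(s, |union considered|).
    """
    _check_compatible(a, b)
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)
    sp = min(s, union.size)
    if sp == 0:
        return 0.0
    lowest = union[:sp]
    shared = int((np.isin(lowest, a.hashes) & np.isin(lowest, b.hashes)).sum())
    return shared / sp


def mash_distance(j: float, k: int) -> float:
    """Mash distance d = -(1/k) ln(2j/(1+j)), capped at 1.0; j=0 maps to 1.0."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"jaccard estimate outside [0,1]: {j}")
    if j == 0.0:
        return 1.0
    d = -(1.0 / k) * math.log(2.0 * j / (1.0 + j))
    return min(max(d, 0.0), 1.0)


def _jaccard_lower_threshold(threshold: float, k: int) -> float:
    """Smallest Jaccard that can still satisfy mash_distance <= threshold."""
    x = math.exp(-k * threshold)
    return x / (2.0 - x)


def pairwise_distances(
    sketches: Sequence[KmerSketch],
    threshold: float = 0.05,
) -> list[DistanceRecord]:
    """All-vs-all Mash distances, keeping records with distance <= threshold.

    Symmetric by construction (each unordered pair reported once, with
    contig_a < contig_b); no self-records.  A cheap intersection-size bound
    skips pairs that cannot reach the threshold.
    """
    if not sketches:
        return []
    ks = {sk.k for sk in sketches}
    seeds = {sk.hash_seed for sk in sketches}
    if len(ks) > 1 or len(seeds) > 1:
        raise ValueError("all sketches must share k and hash seed")
    k = ks.pop()
    records: list[DistanceRecord] = []
    sets = [sk.hash_set for sk in sketches]
    j_min = _jaccard_lower_threshold(threshold, k)
    for i in range(len(sketches)):
        a = sketches[i]
        for jdx in range(i + 1, len(sketches)):
            b = sketches[jdx]
            sp_bound = min(min(a.s, b.s), max(a.hashes.size, b.hashes.size))
            if sp_bound == 0:
                continue
            inter = len(sets[i] & sets[jdx])
            if inter / sp_bound < j_min:
                continue  # true estimate can only be lower
            jac = jaccard_estimate(a, b)
            d = mash_distance(jac, k)
            if d <= threshold:
                ca, cb = sorted((a.contig_id, b.contig_id))
                records.append(DistanceRecord(ca, cb, jac, d))
    return records


def write_sketches(sketches: Iterable[KmerSketch], path) -> None:
    """Write sketches as JSON lines (contig_id, k, s, seed, hashes)."""
    with open(path, "w") as fh:
        for sk in sketches:
            fh.write(json.dumps({
                "contig_id": sk.contig_id,
                "k": sk.k,
                "s": sk.s,
                "seed": sk.hash_seed,
                "n_distinct": sk.n_distinct,
                "seq_length": sk.seq_length,
                "hashes": [int(h) for h in sk.hashes],
            }) + "\n")


def read_sketches(path) -> list[KmerSketch]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(KmerSketch(
                contig_id=d["contig_id"], k=d["k"], s=d["s"],
                hash_seed=d["seed"],
                hashes=np.array(d["hashes"], dtype=np.uint64),
                n_distinct=d["n_distinct"], seq_length=d["seq_length"],
            ))
    return out
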