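"""Fragment-based ANI/AF estimation between genome sequences.

The estimator mimics the fragment-mapping approach of whole-genome ANI
tools: the shorter sequence is tiled into non-overlapping fixed-length
fragments; each fragment is aligned to its best local match anywhere on the
longer sequence; fragments reaching a minimum identity are "mapped".

  ANI = mean identity (%) over mapped fragments
  AF  = mapped fragments / tiled full fragments   (trailing partial
        fragments are excluded from both numerator and denominator)

If no fragment maps, ANI and AF are both 0 (so thresholds evaluate false
rather than propagating a missing value).

Fragment alignment uses edlib's infix mode (best location of the fragment
within the target, edit distance). A lightweight 16-mer sketch index is
provided to prune comparisons between unrelated sequences during
clustering: sequences below ~80% identity share essentially no 16-mers, so
skipped pairs are exactly those whose fragments could not map.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import edlib
import numpy as np

from .model import PairwiseSimilarity

DEFAULT_FRAGMENT_LEN = 1000
DEFAULT_MIN_FRAG_IDENTITY = 80.0


def compute_ani_af(
    seq_a: str,
    seq_b: str,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    min_frag_identity: float = DEFAULT_MIN_FRAG_IDENTITY,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseSimilarity:
    """Estimate ANI (percent) and AF (fraction of the shorter sequence)."""
    if min(len(seq_a), len(seq_b)) < fragment_len:
        raise ValueError(
            f"sequence shorter than fragment_len={fragment_len}; "
            "pass a smaller fragment_len for short inputs"
        )
    if len(seq_a) <= len(seq_b):
        shorter, longer = seq_a, seq_b
    else:
        shorter, longer = seq_b, seq_a
    n_frags = len(shorter) // fragment_len
    identities = []
    for i in range(n_frags):
        frag = shorter[i * fragment_len : (i + 1) * fragment_len]
        res = edlib.align(frag, longer, mode="HW", task="distance")
        identity = 100.0 * (1.0 - res["editDistance"] / fragment_len)
        if identity >= min_frag_identity:
            identities.append(identity)
    if not identities:
        return PairwiseSimilarity(id_a, id_b, 0.0, 0.0)
    ani = float(np.mean(identities))
    af = len(identities) / n_frags
    return PairwiseSimilarity(id_a, id_b, ani, af)


# ---------------------------------------------------------------------------
# k-mer sketch prefilter

_KMER_K = 16
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def kmer_codes(seq: str, k: int = _KMER_K) -> np.ndarray:
    """2-bit-encode all k-mers of ``seq`` as integers (non-ACGT excluded)."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    valid = arr >= 0
    codes = np.zeros(len(arr) - k + 1, dtype=np.int64)
    ok = np.ones(len(arr) - k + 1, dtype=bool)
    for j in range(k):
        codes = codes * 4 + np.where(valid[j : j + len(codes)], arr[j : j + len(codes)], 0)
        ok &= valid[j : j + len(codes)]
    return codes[ok]


class SketchIndex:
    """Inverted index from sampled k-mers to sequence labels.

    Indexed sequences contribute every ``stride``-th k-mer; queries probe
    with all their k-mers, so two related sequences at divergence d share
    an expected ~ len/stride * (1-d)^k sampled k-mers — plenty above the
    candidate threshold for every divergence at which fragments can map.
    """

    def __init__(self, stride: int = 16, min_hits: int = 3) -> None:
        self.stride = stride
        self.min_hits = min_hits
        self._index: dict[int, list[str]] = {}

    def add(self, label: str, seq: str) -> None:
        for code in kmer_codes(seq)[:: self.stride]:
            self._index.setdefault(int(code), []).append(label)

    def candidates(self, seq: str) -> list[str]:
        hits: dict[str, int] = {}
        index = self._index
        for code in kmer_codes(seq):
            bucket = index.get(int(code))
            if bucket:
                for label in bucket:
                    hits[label] = hits.get(label, 0) + 1
        return [label for label, n in hits.items() if n >= self.min_hits]


# ---------------------------------------------------------------------------
# similarity providers

class SimilarityProvider:
    """Computes and caches pairwise ANI/AF on demand."""

    def __init__(
        self,
        sequences: dict[str, str],
        fragment_len: int = DEFAULT_FRAGMENT_LEN,
        min_frag_identity: float = DEFAULT_MIN_FRAG_IDENTITY,
    ) -> None:
        self.sequences = sequences
        self.fragment_len = fragment_len
        self.min_frag_identity = min_frag_identity
        self._cache: dict[frozenset[str], PairwiseSimilarity] = {}

    def __call__(self, id_a: str, id_b: str) -> PairwiseSimilarity:
        key = frozenset((id_a, id_b))
        sim = self._cache.get(key)
        if sim is None:
            sim = compute_ani_af(
                self.sequences[id_a],
                self.sequences[id_b],
                fragment_len=min(
                    self.fragment_len,
                    len(self.sequences[id_a]),
                    len(self.sequences[id_b]),
                ),
                min_frag_identity=self.min_frag_identity,
                id_a=id_a,
                id_b=id_b,
            )
            self._cache[key] = sim
        return sim


class TableSimilarityProvider:
    """Adapter over a precomputed external ANI table (parity runs).

    Expects TSV columns query, reference, ani, frags_mapped, frags_total
    (the output convention of fragment-mapping ANI tools). Pairs absent
    from the table are treated as unmapped (ANI 0, AF 0).
    """

    def __init__(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        self._table: dict[frozenset[str], PairwiseSimilarity] = {}
        for row in df.itertuples(index=False):
            af = row.frags_mapped / row.frags_total if row.frags_total else 0.0
            self._table[frozenset((row.query, row.reference))] = PairwiseSimilarity(
                row.query, row.reference, float(row.ani), float(af)
            )

    def __call__(self, id_a: str, id_b: str) -> PairwiseSimilarity:
        sim = self._table.get(frozenset((id_a, id_b)))
        if sim is None:
            return PairwiseSimilarity(id_a, id_b, 0.0, 0.0)
        return sim


def hamming_identity_pct(seq_a: str, seq_b: str) -> float:
    """Exact percent identity for equal-length sequences (test oracle for
    the substitution-only mutation model)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("hamming identity requires equal lengths")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    return 100.0 * float((a == b).mean())


def iter_fragment_identities(seq_a: str, seq_b: str, fragment_len: int) -> Iterable[float]:
    """Per-fragment identities (diagnostics)."""
    shorter, longer = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    for i in range(len(shorter) // fragment_len):
        frag = shorter[i * fragment_len : (i + 1) * fragment_len]
        res = edlib.align(frag, longer, mode="HW", task="distance")
        yield 100.0 * (1.0 - res["editDistance"] / fragment_len)
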