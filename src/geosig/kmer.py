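"""Canonical k-mer space and random-projection signature tables.

DNA reads are strand-ambiguous: a sequencer reports either a fragment or
its reverse complement with equal probability.  We therefore work with
*canonical* k-mers — of a k-mer ``w`` and its reverse complement
``revcomp(w)``, the one that comes first alphabetically (A < C < G < T).
A k-mer and its reverse complement are the same feature.

Each canonical k-mer is assigned a random unit vector in ``R^N`` (an
isotropic Gaussian direction).  Because high-dimensional random vectors
are nearly orthogonal, summing the vectors of a read's k-mers yields a
locality-preserving embedding: reads sharing many k-mers land close
together.  Assigning identical vectors to a k-mer and its reverse
complement makes the whole projection strand-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ALPHABET",
    "revcomp",
    "canonical_kmer",
    "count_canonical",
    "KmerSpace",
    "SignatureTable",
    "build_signature_table",
]

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte -> 2-bit base code (A=0, C=1, G=2, T=3); -1 marks a degenerate symbol.
BASE_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    BASE_CODES[ord(_b)] = _i
    BASE_CODES[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(w: str) -> str:
    """Return the canonical form of a k-mer.

    The canonical form is the lexicographically smaller of ``w`` and its
    reverse complement under A < C < G < T.  Input is case-insensitive;
    any symbol outside {A, C, G, T} raises ``ValueError`` — callers
    streaming reads are expected to have filtered degenerate windows.
    """
    w = w.upper()
    if any(c not in ALPHABET for c in w):
        raise ValueError(f"degenerate symbol in k-mer {w!r}")
    rc = revcomp(w)
    return w if w <= rc else rc


def count_canonical(k: int) -> int:
    """Number of canonical k-mers (reverse-complement equivalence classes).

    For odd k no k-mer is its own reverse complement, giving 4^k / 2
    classes; for even k the 4^(k/2) palindromic k-mers are singleton
    classes, giving (4^k + 4^(k/2)) / 2.  E.g. 136 canonical 4-mers.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


def _kmer_code(w: str) -> int:
    """2-bit integer encoding of a k-mer (A=0, C=1, G=2, T=3)."""
    code = 0
    for c in w:
        code = (code << 2) | int(BASE_CODES[ord(c)])
    return code


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(ALPHABET[(code >> shift) & 3])
    return "".join(out)


def _revcomp_codes(k: int) -> np.ndarray:
    """Vector mapping each of the 4^k k-mer codes to its revcomp's code."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


@dataclass(frozen=True)
class KmerSpace:
    """Indexing of canonical k-mers.

    ``index`` maps each canonical k-mer string to a dense index in
    ``[0, n_canonical)`` following lexicographic order of the canonical
    forms; every non-canonical k-mer shares the index of its reverse
    complement (see :meth:`canonical_index_by_code`).
    """

    k: int
    index: dict[str, int] = field(repr=False)

    @classmethod
    def build(cls, k: int) -> "KmerSpace":
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        rc = _revcomp_codes(k)
        codes = np.arange(4**k)
        canon_codes = np.minimum(codes, rc)  # lexicographic == numeric under 2-bit coding
        uniq = np.unique(canon_codes)
        index = {_code_to_kmer(int(c), k): i for i, c in enumerate(uniq)}
        return cls(k=k, index=index)

    @property
    def n_canonical(self) -> int:
        return len(self.index)

    def canonical_index_by_code(self) -> np.ndarray:
        """Length-4^k array: k-mer code -> canonical index."""
        rc = _revcomp_codes(self.k)
        codes = np.arange(4**self.k)
        canon_codes = np.minimum(codes, rc)
        uniq, inverse = np.unique(canon_codes, return_inverse=True)
        return inverse.astype(np.int64)


@dataclass(frozen=True)
class SignatureTable:
    """4^k x N look-up of random unit vectors, one per canonical k-mer.

    ``rows[code(w)] == rows[code(revcomp(w))]`` bit-exactly for every
    k-mer ``w``; each row has unit Euclidean norm.  The table is fully
    determined by ``(k, N, seed)``: one RNG stream seeded once, with
    canonical k-mers consuming draws in canonical-index (lexicographic)
    order.
    """

    k: int
    N: int
    seed: int
    rows: np.ndarray = field(repr=False)  # (4^k, N) float64

    def row(self, w: str) -> np.ndarray:
        """Signature vector of k-mer ``w`` (case-insensitive)."""
        w = w.upper()
        if len(w) != self.k or any(c not in ALPHABET for c in w):
            raise ValueError(f"not a valid {self.k}-mer: {w!r}")
        return self.rows[_kmer_code(w)]

    def save(self, path) -> None:
        """Serialize to an .npz file; round-trips bit-exactly."""
        meta = json.dumps(
            {"format": "geosig-signature-table", "version": 1,
             "k": self.k, "N": self.N, "seed": self.seed}
        )
        np.savez(path, rows=self.rows, meta=np.array(meta))

    @classmethod
    def load(cls, path) -> "SignatureTable":
        with np.load(path) as npz:
            meta = json.loads(str(npz["meta"]))
            if meta.get("format") != "geosig-signature-table":
                raise ValueError(f"{path}: not a signature-table file")
            return cls(k=meta["k"], N=meta["N"], seed=meta["seed"],
                       rows=npz["rows"])


def build_signature_table(k: int, N: int | None = None, seed: int = 0) -> SignatureTable:
    """Build the random-projection signature table for k-mers.

    Parameters
    ----------
    k
        k-mer length.
    N
        Signature dimension.  Defaults to ``count_canonical(k)`` (e.g.
        136 for 4-mers, so 4-mer reads are projected onto R^136).
    seed
        Seed of the single RNG stream; ``(k, N, seed)`` fully determine
        the table.

    Each canonical k-mer, in lexicographic order, draws N i.i.d.
    standard normals, normalized to unit length; the vector is shared
    with the reverse complement's row.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if N is None:
        N = count_canonical(k)
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    space = KmerSpace.build(k)
    rng = np.random.default_rng(seed)
    canon = rng.standard_normal((space.n_canonical, N))
    canon /= np.linalg.norm(canon, axis=1, keepdims=True)
    rows = canon[space.canonical_index_by_code()]
    return SignatureTable(k=k, N=N, seed=seed, rows=rows)
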