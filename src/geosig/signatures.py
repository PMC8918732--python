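"""Read-signature transformation: reads to a centered, unit-normalized matrix.

A read of length L yields L - k + 1 sliding windows; windows containing
degenerate symbols (anything outside A/C/G/T) are discarded.  The raw
read signature is the sum of the signature-table rows of the surviving
windows.  A sample's raw signatures are stacked into a matrix, the
column-wise mean is subtracted from every row, and each row is rescaled
to unit Euclidean norm — removing the effect of read-length variation
and per-sample composition offsets in one step.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .errors import EmptySampleError
from .kmer import BASE_CODES, SignatureTable

__all__ = [
    "read_to_raw_signature",
    "sample_to_matrix",
    "ReadSignatureMatrix",
    "iter_reads",
]

DEFAULT_READ_CAP = 1_000_000

# rows dropped after centering when their norm falls below this
_ZERO_NORM_TOL = 1e-12


def _window_codes(read: str, k: int) -> np.ndarray | None:
    """2-bit codes of all non-degenerate k-windows of ``read``, or None."""
    if len(read) < k:
        return None
    codes = BASE_CODES[np.frombuffer(read.encode("ascii", "replace"), dtype=np.uint8)]
    valid = codes >= 0
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    win_valid = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    if not win_valid.any():
        return None
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[win_valid] @ powers


def read_to_raw_signature(read: str, table: SignatureTable) -> np.ndarray | None:
    """Sum of table rows over the read's valid k-windows.

    Returns ``None`` (the empty flag) when no window of length k is free
    of degenerate symbols — including reads shorter than k.  Because the
    table is canonical, a read and its reverse complement produce
    identical raw signatures.
    """
    kcodes = _window_codes(read, table.k)
    if kcodes is None:
        return None
    return table.rows[kcodes].sum(axis=0)


@dataclass
class ReadSignatureMatrix:
    """M x N matrix of centered, unit-normalized read signatures."""

    sample_id: str
    values: np.ndarray  # (M, N) float64, rows unit-norm
    n_input_reads: int
    n_discarded: int
    k: int
    N: int

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def save(self, path) -> None:
        meta = json.dumps(
            {"format": "geosig-signature-matrix", "version": 1,
             "sample_id": self.sample_id, "k": self.k, "N": self.N,
             "M": self.M, "n_input_reads": self.n_input_reads,
             "n_discarded": self.n_discarded}
        )
        np.savez(path, values=self.values, meta=np.array(meta))
        Path(str(path)).with_suffix(".json").write_text(meta + "\n")

    @classmethod
    def load(cls, path) -> "ReadSignatureMatrix":
        with np.load(path) as npz:
            meta = json.loads(str(npz["meta"]))
            if meta.get("format") != "geosig-signature-matrix":
                raise ValueError(f"{path}: not a signature-matrix file")
            return cls(sample_id=meta["sample_id"], values=npz["values"],
                       n_input_reads=meta["n_input_reads"],
                       n_discarded=meta["n_discarded"],
                       k=meta["k"], N=meta["N"])


def sample_to_matrix(
    reads: Iterable[str],
    table: SignatureTable,
    read_cap: int = DEFAULT_READ_CAP,
    sample_id: str = "",
    subsample_seed: int | None = None,
) -> ReadSignatureMatrix:
    """Convert a sample's reads into its read-signature matrix.

    The first ``read_cap`` reads (in input order) that yield a non-empty
    raw signature are used; with ``subsample_seed`` set, a seeded
    reservoir sample of all usable reads is taken instead.  Raw
    signatures are column-mean centered per sample, then each row is
    unit-normalized; rows that are numerically zero after centering
    (e.g. when every read is identical) are dropped and counted in
    ``n_discarded``.

    Raises
    ------
    EmptySampleError
        If no read yields a usable, nonzero signature.
    """
    raw: list[np.ndarray] = []
    n_input = 0
    n_discarded = 0
    if subsample_seed is None:
        for read in reads:
            n_input += 1
            sig = read_to_raw_signature(read, table)
            if sig is None:
                n_discarded += 1
                continue
            raw.append(sig)
            if len(raw) >= read_cap:
                break
    else:
        rng = np.random.default_rng(subsample_seed)
        n_seen = 0
        for read in reads:
            n_input += 1
            sig = read_to_raw_signature(read, table)
            if sig is None:
                n_discarded += 1
                continue
            n_seen += 1
            if len(raw) < read_cap:
                raw.append(sig)
            else:
                j = int(rng.integers(n_seen))
                if j < read_cap:
                    raw[j] = sig
    if not raw:
        raise EmptySampleError(
            f"sample {sample_id!r}: no read produced a valid signature"
        )
    mat = np.asarray(raw)
    mat -= mat.mean(axis=0)
    norms = np.linalg.norm(mat, axis=1)
    keep = norms > _ZERO_NORM_TOL
    n_discarded += int((~keep).sum())
    mat = mat[keep] / norms[keep, None]
    if mat.shape[0] == 0:
        raise EmptySampleError(
            f"sample {sample_id!r}: all signatures degenerate after centering"
        )
    return ReadSignatureMatrix(
        sample_id=sample_id, values=mat, n_input_reads=n_input,
        n_discarded=n_discarded, k=table.k, N=table.N,
    )


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path.name!r}")


def iter_reads(path) -> Iterator[str]:
    """Yield read sequences (uppercased strings) from FASTA/FASTQ(.gz).

    Format is inferred from the file name; quality values are ignored.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    opener = gzip.open if path.name.lower().endswith(".gz") else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield str(rec.seq).upper()


def file_to_matrix(
    path,
    table: SignatureTable,
    read_cap: int = DEFAULT_READ_CAP,
    sample_id: str | None = None,
    subsample_seed: int | None = None,
) -> ReadSignatureMatrix:
    """``sample_to_matrix`` over a FASTA/FASTQ(.gz) file."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    return sample_to_matrix(
        iter_reads(path), table, read_cap=read_cap,
        sample_id=sample_id, subsample_seed=subsample_seed,
    )
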