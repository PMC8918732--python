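"""Synthetic labelled read collections with a tunable city-separation knob.

The premise of k-mer-based geolocation is that samples from the same
city share a microbial footprint — and hence k-mer composition — that
samples from different cities do not.  The generator emulates exactly
that, and nothing more: each city owns a small set of private marker
motifs (standing in for city-enriched taxa) inserted into reads at a
Poisson rate, plus a mild city-specific skew of the background base
composition.  A single ``separation`` knob in [0, 1] scales both
effects; at 0 every city draws reads from the identical distribution,
so a classifier can only reach chance level.

Reads vary in length (default 50–292 bases, typical of overlap-merged
paired-end fragments) and may carry degenerate 'N' bases.  Collections
are written as standard FASTA/FASTQ plus a TSV manifest so synthetic
data exercises the real I/O path.  This is deliberately not a realistic
metagenome simulator: there are no genomes, abundances or error models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kmer import ALPHABET

__all__ = [
    "CityProfile",
    "SyntheticCollection",
    "generate_profiles",
    "generate_sample",
    "generate_collection",
    "write_collection",
]

DEFAULT_LENGTH_RANGE = (50, 292)
DEFAULT_MARKER_RATE = 2.0  # expected marker insertions per read at separation=1
DEFAULT_MOTIF_LENGTH = 24  # ~ a conserved fragment of a city-private organism
DEFAULT_N_MOTIFS = 5
_DIRICHLET_CONC = 10.0  # concentration of the per-city composition draw


@dataclass(frozen=True)
class CityProfile:
    """Generative profile of one city's reads."""

    city: str
    base_freqs: np.ndarray  # probability over A,C,G,T; sums to 1
    marker_motifs: tuple[str, ...]  # private motifs, length >= k
    marker_rate: float  # expected insertions per read
    seed: int


@dataclass
class SyntheticCollection:
    """Labelled synthetic samples plus the generation parameters."""

    samples: list[tuple[str, str, str, list[str]]]  # (sample_id, location_id, city, reads)
    params: dict = field(default_factory=dict)


def _random_motif(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(4, size=length))


def generate_profiles(
    n_cities: int,
    separation: float,
    seed: int = 0,
    n_motifs: int = DEFAULT_N_MOTIFS,
    motif_length: int = DEFAULT_MOTIF_LENGTH,
    marker_rate: float = DEFAULT_MARKER_RATE,
) -> list[CityProfile]:
    """Draw per-city generative profiles.

    Each city receives a base composition interpolated between uniform
    and a Dirichlet draw, and a private set of marker motifs (resampled
    on collision so motif sets are disjoint across cities).  Both the
    compositional deviation and the marker insertion rate scale
    linearly with ``separation``, so separation 0 makes all cities
    identically distributed.
    """
    if n_cities < 1:
        raise ValueError(f"n_cities must be >= 1, got {n_cities}")
    if not 0.0 <= separation <= 1.0:
        raise ValueError(f"separation must be in [0, 1], got {separation}")
    rng = np.random.default_rng(seed)
    uniform = np.full(4, 0.25)
    taken: set[str] = set()
    profiles = []
    for c in range(n_cities):
        draw = rng.dirichlet(np.full(4, _DIRICHLET_CONC))
        freqs = uniform + separation * (draw - uniform)
        motifs = []
        while len(motifs) < n_motifs:
            m = _random_motif(rng, motif_length)
            if m not in taken:
                taken.add(m)
                motifs.append(m)
        profiles.append(
            CityProfile(
                city=f"city{c:02d}",
                base_freqs=freqs,
                marker_motifs=tuple(motifs),
                marker_rate=separation * marker_rate,
                seed=int(rng.integers(2**31)),
            )
        )
    return profiles


def generate_sample(
    profile: CityProfile,
    n_reads: int,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    degenerate_rate: float = 0.0,
    seed: int = 0,
    _insertion_log: list[int] | None = None,
) -> list[str]:
    """Draw one sample's reads from a city profile.

    Read lengths are uniform over ``length_range``; bases i.i.d. from
    the city's base frequencies; a Poisson(marker_rate) number of
    markers (chosen uniformly from the city's motifs) overwrite the
    read at random positions; finally each base is independently
    replaced by 'N' with probability ``degenerate_rate``.
    """
    if n_reads < 1:
        raise ValueError(f"n_reads must be >= 1, got {n_reads}")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    bases = np.array(list(ALPHABET))
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        arr = rng.choice(bases, size=length, p=profile.base_freqs)
        if profile.marker_rate > 0 and profile.marker_motifs:
            n_ins = int(rng.poisson(profile.marker_rate))
            if _insertion_log is not None:
                _insertion_log.append(n_ins)
            for _ in range(n_ins):
                motif = profile.marker_motifs[int(rng.integers(len(profile.marker_motifs)))]
                if len(motif) > length:
                    continue
                pos = int(rng.integers(length - len(motif) + 1))
                arr[pos : pos + len(motif)] = list(motif)
        if degenerate_rate > 0:
            arr[rng.random(length) < degenerate_rate] = "N"
        reads.append("".join(arr))
    return reads


def generate_collection(
    n_cities: int,
    samples_per_city: int,
    n_reads: int,
    separation: float,
    seed: int = 0,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    degenerate_rate: float = 0.0,
    **profile_kwargs,
) -> SyntheticCollection:
    """Generate a labelled collection: one sample per location, several
    locations (samples) per city."""
    profiles = generate_profiles(n_cities, separation, seed=seed, **profile_kwargs)
    rng = np.random.default_rng(seed + 1)
    samples = []
    for profile in profiles:
        for s in range(samples_per_city):
            sample_id = f"{profile.city}_s{s:03d}"
            location_id = f"loc_{profile.city}_{s:03d}"
            reads = generate_sample(
                profile, n_reads, length_range=length_range,
                degenerate_rate=degenerate_rate, seed=int(rng.integers(2**31)),
            )
            samples.append((sample_id, location_id, profile.city, reads))
    return SyntheticCollection(
        samples=samples,
        params={
            "n_cities": n_cities, "samples_per_city": samples_per_city,
            "n_reads": n_reads, "separation": separation, "seed": seed,
            "length_range": list(length_range),
            "degenerate_rate": degenerate_rate,
        },
    )


def write_collection(
    collection: SyntheticCollection,
    outdir,
    fmt: str = "fasta",
) -> Path:
    """Write per-sample FASTA/FASTQ files and the manifest TSV.

    Returns the manifest path.  FASTQ records carry a constant dummy
    quality ('I').
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"fmt must be fasta or fastq, got {fmt!r}")
    ext = "fa" if fmt == "fasta" else "fq"
    rows = []
    for sample_id, location_id, city, reads in collection.samples:
        path = outdir / f"{sample_id}.{ext}"
        with open(path, "w") as fh:
            for i, read in enumerate(reads):
                if fmt == "fasta":
                    fh.write(f">{sample_id}.{i}\n{read}\n")
                else:
                    fh.write(f"@{sample_id}.{i}\n{read}\n+\n{'I' * len(read)}\n")
        rows.append({"sample_id": sample_id, "path": path.name,  # manifest-relative
                     "location_id": location_id, "city": city})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
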