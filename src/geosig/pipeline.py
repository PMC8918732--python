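"""Manifest handling, run configuration and the end-to-end pipeline.

The pipeline consumes pre-merged, pre-filtered single-end reads: pair
merging (e.g. PEAR) and host-read removal (e.g. Bowtie2 against the
human genome) are upstream of this tool and documented in the README.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .classify import SignatureLibrary, build_library
from .errors import ManifestError
from .evaluate import EvaluationResult, loo_crossval
from .kmer import SignatureTable, build_signature_table, count_canonical
from .signatures import DEFAULT_READ_CAP, file_to_matrix
from .tsvq import ClusterTree, sample_seed, tsvq_fit

__all__ = ["RunConfig", "read_manifest", "run_pipeline"]

logger = logging.getLogger("geosig")

MANIFEST_COLUMNS = ["sample_id", "path", "location_id", "city"]


@dataclass
class RunConfig:
    """Parameters of a pipeline run.

    Defaults follow the method's standard operating point: 4-mers,
    signature dimension equal to the canonical 4-mer count (136), a
    1,000,000-read cap per sample, TSVQ with order 10 and depth 4,
    classification with level-3 cluster-signatures and 3 nearest
    neighbours (vote improvements saturate around 3).
    """

    k: int = 4
    N: int | None = None  # default: count_canonical(k)
    seed: int = 0
    read_cap: int = DEFAULT_READ_CAP
    order: int = 10
    depth: int = 4
    level: int = 3
    K_neighbours: int = 3
    max_iter: int = 100
    tol: float = 1e-4
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.N is None:
            self.N = count_canonical(self.k)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_manifest(path) -> pd.DataFrame:
    """Load and validate a sample manifest TSV.

    Columns: sample_id, path (to FASTA/FASTQ reads, resolved relative
    to the manifest), location_id, city.  sample_id must be unique and
    each location must map to a single city.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ManifestError(f"{path}: duplicate sample_ids {dups}")
    loc_cities = df.groupby("location_id")["city"].nunique()
    bad = loc_cities[loc_cities > 1].index.tolist()
    if bad:
        raise ManifestError(f"{path}: locations with multiple cities {bad}")
    df = df.copy()
    df["path"] = [
        str(p if (p := Path(raw)).is_absolute() else path.parent / raw)
        for raw in df["path"]
    ]
    for p in df["path"]:
        if not Path(p).exists():
            raise ManifestError(f"reads file not found: {p}")
    return df[MANIFEST_COLUMNS]


def _file_sha256(path, chunk=1 << 20) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while block := fh.read(chunk):
            h.update(block)
    return h.hexdigest()


def _tree_cache_key(reads_path, config: RunConfig, sample_id: str) -> str:
    payload = json.dumps(
        {"reads": _file_sha256(reads_path), "sample_id": sample_id,
         "k": config.k, "N": config.N, "seed": config.seed,
         "read_cap": config.read_cap, "order": config.order,
         "depth": config.depth, "max_iter": config.max_iter,
         "tol": config.tol},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:24]


def sample_tree(
    reads_path,
    sample_id: str,
    table: SignatureTable,
    config: RunConfig,
    workdir: Path | None = None,
) -> ClusterTree:
    """Reads file → signature matrix → TSVQ tree, with optional caching.

    With a ``workdir``, the fitted tree is stored under a content hash
    of (reads file, relevant config); an unchanged rerun loads the
    cached tree instead of recomputing.
    """
    if workdir is not None:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        cache = workdir / f"tree_{_tree_cache_key(reads_path, config, sample_id)}.json"
        if cache.exists():
            logger.info("cache hit for sample %s", sample_id)
            return ClusterTree.load(cache)
    matrix = file_to_matrix(reads_path, table, read_cap=config.read_cap,
                            sample_id=sample_id)
    tree = tsvq_fit(matrix, order=config.order, depth=config.depth,
                    seed=sample_seed(config.seed, sample_id),
                    max_iter=config.max_iter, tol=config.tol)
    if workdir is not None:
        tree.save(cache)
    return tree


def run_pipeline(
    manifest: pd.DataFrame,
    config: RunConfig,
    workdir=None,
    loocv: bool = True,
) -> tuple[SignatureLibrary, EvaluationResult | None]:
    """Execute the full pipeline over a manifest.

    Builds the signature table, converts every sample to a TSVQ tree
    (cached in ``workdir`` when given), assembles the level library
    and, when ``loocv`` is set, runs leave-one-out cross-validation.
    All randomness flows from ``config.seed``.
    """
    logger.info("run config %s (hash %s)", asdict(config), config.hash())
    table = build_signature_table(config.k, config.N, seed=config.seed)
    collection = []
    for row in manifest.itertuples(index=False):
        tree = sample_tree(row.path, row.sample_id, table, config, workdir)
        collection.append((tree, row.location_id, row.city))
    library = build_library(collection, level=config.level, k=config.k)
    result = None
    if loocv:
        result = loo_crossval(collection, level=config.level,
                              K=config.K_neighbours, n_jobs=config.n_jobs)
        result.config.update(asdict(config))
    return library, result
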