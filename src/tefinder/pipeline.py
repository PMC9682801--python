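"""End-to-end orchestration with resumable disk-backed intermediates.

The expensive step of both algorithms is slicing and sorting k-mers from
FASTQ. Sorted catalogs are therefore persisted under the working directory,
keyed by a checksum of the input files and k, and transparently reused when
the same inputs are analysed again (e.g. a junction run followed by a TSD
run, or a re-run after an interruption). Outputs are a pure function of the
inputs and parameters: thread count and resume state never change results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .io import fasta_names, parse_fasta, parse_fastq
from .junction import DetectionResult, run_junction_method
from .kmer import DEFAULT_CHUNK_SIZE, KmerCatalog, external_sort_merge
from .model import Parameters, SAMPLE_A, SAMPLE_B
from .reference import ReferenceIndex, build_index, read_config, write_config
from ._sequence import iter_kmers
from .tsd import run_tsd_method

logger = logging.getLogger(__name__)


def _file_digest(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def expand_fastq_args(values: Sequence[str | Path]) -> list[Path]:
    """Each value may be a FASTQ file or a directory of FASTQ files."""
    paths: list[Path] = []
    for value in values:
        p = Path(value)
        if p.is_dir():
            found = sorted(q for q in p.iterdir()
                           if q.name.endswith((".fastq", ".fq", ".fastq.gz",
                                               ".fq.gz")))
            if not found:
                raise FileNotFoundError(f"no FASTQ files in directory {p}")
            paths.extend(found)
        elif p.exists():
            paths.append(p)
        else:
            raise FileNotFoundError(f"FASTQ input {p} does not exist")
    return paths


class Workspace:
    """Scratch directory holding reusable sorted catalogs and the index."""

    def __init__(self, workdir: str | Path,
                 chunk_size: int = DEFAULT_CHUNK_SIZE):
        self.workdir = Path(workdir)
        self.chunk_size = chunk_size
        (self.workdir / "catalogs").mkdir(parents=True, exist_ok=True)
        (self.workdir / "tmp").mkdir(parents=True, exist_ok=True)

    def catalog(self, fastq_paths: Sequence[Path], k: int, sample: str
                ) -> KmerCatalog:
        digest = hashlib.md5(
            (f"k={k};" + ";".join(_file_digest(p) for p in fastq_paths))
            .encode()).hexdigest()
        cache = self.workdir / "catalogs" / f"{sample}_{k}_{digest}.tsv"
        if cache.exists():
            logger.info("reused catalog %s", cache.name)
            return KmerCatalog.from_tsv(cache, k, sample)
        runs = ((kmer for read in parse_fastq(p)
                 for kmer in iter_kmers(read, k)) for p in fastq_paths)
        catalog = external_sort_merge(runs, self.workdir / "tmp",
                                      self.chunk_size, sample)
        if catalog.k != k:  # empty input edge case
            catalog = KmerCatalog(k, dict(catalog.counts), sample)
        catalog.to_tsv(cache)
        logger.info("built catalog %s (%d records)", cache.name, len(catalog))
        return catalog

    def index(self, contigs, config) -> ReferenceIndex:
        return build_index(contigs, config, cache_dir=self.workdir)


class ConfigPending(RuntimeError):
    """Raised when the reference config was just created and needs review."""


def prepare_reference(ref_path: str | Path,
                      config_path: str | Path | None = None,
                      workspace: Workspace | None = None) -> ReferenceIndex:
    """Load the reference and its config; create the config on first use.

    On the first run the contig-list config is written next to the FASTA
    and a :class:`ConfigPending` error asks the user to review it (contigs
    renamed to NOP are ignored) and re-run.
    """
    ref_path = Path(ref_path)
    config_path = Path(config_path) if config_path else \
        ref_path.with_name(ref_path.name + ".config")
    names = fasta_names(ref_path)
    if not config_path.exists():
        write_config(names, config_path)
        raise ConfigPending(
            f"created reference config {config_path}; review it (rename "
            "contigs to NOP to ignore them) and re-run")
    config = read_config(config_path, names)
    contigs = parse_fasta(ref_path)
    if workspace is not None:
        return workspace.index(contigs, config)
    return build_index(contigs, config)


@dataclass
class RunConfig:
    """Everything one invocation needs; mirrors the CLI flags."""

    sample_a: Sequence[str | Path]
    sample_b: Sequence[str | Path]
    ref: Optional[str | Path] = None
    ref_config: Optional[str | Path] = None
    tsd_size: Optional[int] = None
    workdir: str | Path = "tef_work"
    outdir: str | Path = "tef_out"
    threads: int = 1
    params: Parameters = field(default_factory=Parameters)


def run(config: RunConfig) -> dict[str, DetectionResult]:
    """Execute the configured method(s) and write all report files.

    With a reference the junction method runs (the default algorithm); with
    ``tsd_size`` the TSD method runs; with both, the junction method runs
    first and the TSD method reuses its sorted 40-mer catalogs.
    """
    from . import report

    if config.tsd_size is None and config.ref is None:
        raise ValueError("supply a reference (junction method) and/or "
                         "tsd_size (TSD method)")
    params = config.params
    if config.tsd_size is not None:
        params = Parameters(**{**params.__dict__, "tsd_size": config.tsd_size})

    ws = Workspace(config.workdir)
    paths_a = expand_fastq_args(config.sample_a)
    paths_b = expand_fastq_args(config.sample_b)
    index = None
    if config.ref is not None:
        index = prepare_reference(config.ref, config.ref_config, ws)

    k40 = 2 * params.end_k
    cat40_a = ws.catalog(paths_a, k40, SAMPLE_A)
    cat40_b = ws.catalog(paths_b, k40, SAMPLE_B)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, DetectionResult] = {}

    if index is not None:
        results["junction"] = run_junction_method(
            [], [], index, params, threads=config.threads,
            catalog_a=cat40_a, catalog_b=cat40_b)
        report.write_result(results["junction"], outdir, "junction",
                            contig_order=index.config.active)
    if params.tsd_size is not None:
        reads_a = [r for p in paths_a for r in parse_fastq(p)]
        reads_b = [r for p in paths_b for r in parse_fastq(p)]
        results["tsd"] = run_tsd_method(
            reads_a, reads_b, params.tsd_size, index, params,
            catalog40_a=cat40_a, catalog40_b=cat40_b)
        order = index.config.active if index is not None else None
        report.write_result(results["tsd"], outdir, "tsd", contig_order=order)

    manifest = {
        "version": __version__,
        "inputs": {
            "sample_a": {str(p): _file_digest(p) for p in paths_a},
            "sample_b": {str(p): _file_digest(p) for p in paths_b},
            "reference": str(config.ref) if config.ref else None,
        },
        "parameters": {k: v for k, v in params.__dict__.items()},
        "methods": sorted(results),
    }
    with open(outdir / "manifest.json", "w", newline="\n") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
    return results
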