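"""Tabular and BED output of detection results.

Pair and call tables are deterministic TSVs (stable sort, fixed float
format) so that re-runs and different worker counts produce byte-identical
files. BED6 export converts the 1-based closed call interval to 0-based
half-open at the boundary and says so in its header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .junction import DetectionResult
from .model import HeadTailPair, InsertionCall


def pairs_table(pairs: list[HeadTailPair], annotations: dict | None = None
                ) -> pd.DataFrame:
    rows = []
    for p in pairs:
        ann = (annotations or {}).get((p.head, p.tail))
        rows.append({
            "head": p.head,
            "tail": p.tail,
            "n_tsd_a": len(p.tsds_a),
            "n_tsd_b": len(p.tsds_b),
            "specificity": round(p.specificity, 4),
            "tsds_a": ",".join(sorted(p.tsds_a)),
            "tsds_b": ",".join(sorted(p.tsds_b)),
            "revcomp_pair": "/".join(p.cross_ref) if p.cross_ref else "",
            "te_length": ann.estimated_length if ann else None,
            "tg_ca": bool(ann.tg_ca_flag) if ann else None,
        })
    return pd.DataFrame(rows, columns=[
        "head", "tail", "n_tsd_a", "n_tsd_b", "specificity", "tsds_a",
        "tsds_b", "revcomp_pair", "te_length", "tg_ca"])


def calls_table(calls: list[InsertionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "contig": c.contig if c.contig is not None else "",
            "head_junction": c.head_junction,
            "tail_junction": c.tail_junction,
            "tsd": c.tsd,
            "tsd_len": c.tsd_len,
            "head": c.head,
            "tail": c.tail,
            "carrier": c.carrier,
            "genotype": c.genotype,
            "upstream_head_a": c.counts_a.upstream_head,
            "tail_downstream_a": c.counts_a.tail_downstream,
            "non_insertion_a": c.counts_a.non_insertion,
            "upstream_head_b": c.counts_b.upstream_head,
            "tail_downstream_b": c.counts_b.tail_downstream,
            "non_insertion_b": c.counts_b.non_insertion,
            "repetitive_flag": c.repetitive_flag,
            "overlap_flag": c.overlap_flag,
            "te_length": c.te_length,
            "tg_ca": c.tg_ca_flag,
        })
    return pd.DataFrame(rows, columns=[
        "contig", "head_junction", "tail_junction", "tsd", "tsd_len", "head",
        "tail", "carrier", "genotype", "upstream_head_a", "tail_downstream_a",
        "non_insertion_a", "upstream_head_b", "tail_downstream_b",
        "non_insertion_b", "repetitive_flag", "overlap_flag", "te_length",
        "tg_ca"])


def write_bed(calls: list[InsertionCall], path: str | Path) -> None:
    """BED6 of located insertion sites (the TSD interval)."""
    with open(path, "w", newline="\n") as out:
        out.write("# BED6; chromStart is 0-based half-open converted from "
                  "1-based closed [tail_junction, head_junction]\n")
        for c in calls:
            if c.contig is None:
                continue
            name = f"{c.head}..{c.tail}|{c.tsd}|{c.carrier}|{c.genotype}"
            out.write(f"{c.contig}\t{c.tail_junction - 1}\t{c.head_junction}"
                      f"\t{name}\t0\t+\n")


def write_result(result: DetectionResult, outdir: str | Path, prefix: str,
                 contig_order: Optional[list[str]] = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pairs": outdir / f"{prefix}_pairs.tsv",
        "calls": outdir / f"{prefix}_calls.tsv",
        "bed": outdir / f"{prefix}_calls.bed",
    }
    pairs_table(result.pairs, result.annotations).to_csv(
        paths["pairs"], sep="\t", index=False, lineterminator="\n")
    calls_table(result.calls).to_csv(
        paths["calls"], sep="\t", index=False, lineterminator="\n")
    write_bed(result.calls, paths["bed"])
    if result.repetitive_candidates:
        rep = pd.DataFrame(result.repetitive_candidates,
                           columns=["kind", "flank", "te_end", "sample"])
        rep.to_csv(outdir / f"{prefix}_repetitive_candidates.tsv", sep="\t",
                   index=False, lineterminator="\n")
    return paths
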