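"""Deterministic multi-process map.

Work is partitioned by the caller (typically by k-mer prefix) and results
are returned in submission order, so the output is identical for any worker
count. Uses fork so that large read-only state (the reference index) is
shared without pickling; a worker failure fails the whole run.
"""

from __future__ import annotations

import multiprocessing
from typing import Callable, Sequence, TypeVar

T = TypeVar("T")
R = TypeVar("R")


def parallel_map(fn: Callable[[T], R], items: Sequence[T],
                 threads: int = 1) -> list[R]:
    if threads <= 1 or len(items) <= 1:
        return [fn(x) for x in items]
    ctx = multiprocessing.get_context("fork")
    with ctx.Pool(min(threads, len(items))) as pool:
        return pool.map(fn, items)
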