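"""Sliding windows of consecutive genotyped SNPs: the regional units of the scan.

The genome scan uses 100-SNP windows advancing by 50 SNPs (so adjacent
windows share half their SNPs); fine mapping re-scans selected windows with
10-SNP windows advancing by 5.  Windows never cross chromosome boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WindowSpec", "make_windows", "select_fine_map_targets", "windows_to_frame"]


@dataclass(frozen=True)
class WindowSpec:
    """One regional test: a contiguous run of SNPs in chromosome-sorted order.

    ``start``/``end`` are half-open positional indices into the full
    (chromosome, position)-sorted variant registry; ``bp_start``/``bp_end``
    are the base-pair positions of the first and last SNP.
    """

    window_id: int
    chromosome: int
    start: int
    end: int
    snp_ids: tuple[str, ...]
    bp_start: int
    bp_end: int
    size: int
    stride: int

    def __post_init__(self) -> None:
        if self.end - self.start > self.size:
            raise ValueError("window wider than its nominal size")
        if self.bp_start > self.bp_end:
            raise ValueError("bp_start > bp_end")

    @property
    def n_snps(self) -> int:
        return self.end - self.start

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end)


def make_windows(variants: pd.DataFrame, size: int, stride: int,
                 terminal: str = "anchor", _id_offset: int = 0) -> list[WindowSpec]:
    """Tile each chromosome with ``size``-SNP windows every ``stride`` SNPs.

    Variants must be sorted by (chromosome, position); indices in the
    returned specs refer to that order.  Per chromosome the starts are
    0, stride, 2*stride, ...; when a start plus the window size would
    overrun the chromosome, the final window is anchored at
    ``max(0, n_c - size)`` (keeping full width) and iteration stops.
    With ``terminal="truncate"`` the final window instead keeps its natural
    start and is shortened.  A chromosome with fewer than ``size`` SNPs
    yields a single whole-chromosome window, with a warning.
    """
    if not (size > stride > 0):
        raise ValueError(f"need size > stride > 0, got size={size}, stride={stride}")
    if terminal not in ("anchor", "truncate"):
        raise ValueError(f"terminal must be 'anchor' or 'truncate', got {terminal!r}")
    chrom = variants["chromosome"].to_numpy()
    pos = variants["position"].to_numpy()
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(variants))):
        raise ValueError("variants must be sorted by (chromosome, position)")

    specs: list[WindowSpec] = []
    wid = _id_offset
    for c in pd.unique(chrom):
        offs = np.flatnonzero(chrom == c)
        base, n_c = offs[0], offs.size
        if n_c < size:
            warnings.warn(f"chromosome {c}: {n_c} SNPs < window size {size}; one window")
            spans = [(0, n_c)]
        else:
            spans = []
            start = 0
            while True:
                if start + size > n_c:
                    if terminal == "anchor":
                        spans.append((max(0, n_c - size), n_c))
                    else:
                        spans.append((start, n_c))
                    break
                spans.append((start, start + size))
                if start + size == n_c:
                    break
                start += stride
            # an anchored terminal window can duplicate the previous one
            dedup = []
            for s in spans:
                if not dedup or s != dedup[-1]:
                    dedup.append(s)
            spans = dedup
        for s, e in spans:
            lo, hi = base + s, base + e
            specs.append(
                WindowSpec(
                    window_id=wid,
                    chromosome=int(c),
                    start=int(lo),
                    end=int(hi),
                    snp_ids=tuple(variants["snp_id"].iloc[lo:hi]),
                    bp_start=int(pos[lo]),
                    bp_end=int(pos[hi - 1]),
                    size=size,
                    stride=stride,
                )
            )
            wid += 1
    return specs


def select_fine_map_targets(results, k: int = 100, fine_size: int = 10,
                            fine_stride: int = 5,
                            variants: pd.DataFrame | None = None,
                            terminal: str = "anchor"):
    """Pick the top-k windows by LRT and tile each with fine windows.

    ``results`` is a list of scan results carrying ``.window``, ``.lrt`` and
    ``.neg_log10_p``.  Ties in LRT break by smaller −log p, then by window id
    (genomic order).  Returns ``(selected_coarse, fine_windows)``.
    """
    if not results:
        raise ValueError("no scan results to select from")
    if k > len(results):
        warnings.warn(f"k={k} > {len(results)} windows: selecting all")
        k = len(results)
    order = sorted(results, key=lambda r: (-r.lrt, r.neg_log10_p, r.window.window_id))
    selected = [r.window for r in order[:k]]
    if variants is None:
        raise ValueError("variant registry required to build fine windows")
    fine: list[WindowSpec] = []
    for w in selected:
        sub = variants.iloc[w.start:w.end].reset_index(drop=True)
        for f in make_windows(sub, fine_size, fine_stride, terminal=terminal,
                              _id_offset=len(fine)):
            # re-express indices relative to the full registry
            fine.append(
                WindowSpec(
                    window_id=f.window_id,
                    chromosome=f.chromosome,
                    start=w.start + f.start,
                    end=w.start + f.end,
                    snp_ids=f.snp_ids,
                    bp_start=f.bp_start,
                    bp_end=f.bp_end,
                    size=fine_size,
                    stride=fine_stride,
                )
            )
    return selected, fine


def windows_to_frame(specs: list[WindowSpec]) -> pd.DataFrame:
    """Tabulate windows (TSV-friendly; BED export uses bp_start-1, bp_end)."""
    return pd.DataFrame(
        {
            "window_id": [w.window_id for w in specs],
            "chromosome": [w.chromosome for w in specs],
            "start": [w.start for w in specs],
            "end": [w.end for w in specs],
            "bp_start": [w.bp_start for w in specs],
            "bp_end": [w.bp_end for w in specs],
            "n_snps": [w.n_snps for w in specs],
            "first_snp": [w.snp_ids[0] for w in specs],
            "last_snp": [w.snp_ids[-1] for w in specs],
        }
    )
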