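"""Peak-to-gene annotation and gene-level TF binding calls.

A TF is considered *bound* at a gene when one of its ChIP-seq peaks lies
anywhere in the gene body, or within ``window_bp`` (default 50 kb) of either
gene edge.  Distances are edge-to-edge gaps between half-open, 0-based
intervals; strand is ignored (upstream and downstream windows are equal, so
the rule is symmetric).  The boundary is inclusive: a gap of exactly
``window_bp`` counts as bound.

Candidate lookup uses an interval tree per chromosome; minimum gaps beyond
the window are resolved with sorted-edge bisection.  Both paths are exact
and are cross-checked against an O(n*m) all-pairs scan in the test suite.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 50_000
VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GeneModel:
    """One gene locus: half-open 0-based interval plus identifiers."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq binding interval for a named TF."""

    peak_id: str
    tf: str
    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError(f"peak {self.peak_id}: tf must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"peak {self.peak_id}: invalid interval [{self.start}, {self.end})"
            )


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Edge-to-edge gap between two half-open intervals on one sequence.

    Returns 0 when the intervals intersect or touch; otherwise the number of
    bases strictly between them.
    """
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def peak_gene_gap(peak: Peak, gene: GeneModel) -> int:
    """Gap in bp between a peak and a gene body (0 = overlap or touching)."""
    if peak.chrom != gene.chrom:
        raise ValueError(
            f"peak {peak.peak_id} ({peak.chrom}) and gene {gene.gene_id} "
            f"({gene.chrom}) are on different chromosomes"
        )
    return interval_gap(peak.start, peak.end, gene.start, gene.end)


class _ChromIndex:
    """Interval tree plus sorted edges for one chromosome."""

    def __init__(self, items: Sequence[tuple[int, int, object]]):
        self.tree = IntervalTree()
        for start, end, payload in items:
            self.tree.addi(start, end, payload)
        self._starts = sorted(start for start, _, _ in items)
        self._ends = sorted(end for _, end, _ in items)

    def within(self, start: int, end: int, window: int) -> list[object]:
        """Payloads whose gap to [start, end) is <= window (inclusive)."""
        # Expand by window+1: half-open overlap is strict, so the extra base
        # keeps a gap of exactly `window` inside the query.
        hits = self.tree.overlap(max(0, start - window - 1), end + window + 1)
        out = []
        for iv in hits:
            if interval_gap(start, end, iv.begin, iv.end) <= window:
                out.append(iv.data)
        return out

    def min_gap(self, start: int, end: int) -> int:
        """Smallest gap from [start, end) to any indexed interval."""
        if self.tree.overlap(start, end):
            return 0
        best = None
        i = bisect_right(self._ends, start)
        if i > 0:  # nearest interval ending at or left of `start`
            best = start - self._ends[i - 1]
        j = bisect_left(self._starts, end)
        if j < len(self._starts):  # nearest interval starting at or right of `end`
            right = self._starts[j] - end
            best = right if best is None else min(best, right)
        assert best is not None
        return best


class IntervalIndex:
    """Per-chromosome interval index over arbitrary payloads."""

    def __init__(self, items: Iterable[tuple[str, int, int, object]]):
        by_chrom: dict[str, list[tuple[int, int, object]]] = {}
        for chrom, start, end, payload in items:
            by_chrom.setdefault(chrom, []).append((start, end, payload))
        self._chroms = {c: _ChromIndex(v) for c, v in by_chrom.items()}

    @property
    def chroms(self) -> set[str]:
        return set(self._chroms)

    def within(self, chrom: str, start: int, end: int, window: int) -> list[object]:
        idx = self._chroms.get(chrom)
        return idx.within(start, end, window) if idx else []

    def min_gap(self, chrom: str, start: int, end: int) -> int | None:
        idx = self._chroms.get(chrom)
        return idx.min_gap(start, end) if idx else None


def gene_index(genes: Sequence[GeneModel]) -> IntervalIndex:
    return IntervalIndex((g.chrom, g.start, g.end, g) for g in genes)


def annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel] | IntervalIndex,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> str | None:
    """Assign a peak to its closest gene within ``window_bp``, or None.

    Ties are broken by smaller gap, then smaller gene start, then
    lexicographic gene_id.
    """
    index = genes if isinstance(genes, IntervalIndex) else gene_index(genes)
    candidates = index.within(peak.chrom, peak.start, peak.end, window_bp)
    if not candidates:
        return None
    best = min(
        candidates,
        key=lambda g: (interval_gap(peak.start, peak.end, g.start, g.end), g.start, g.gene_id),
    )
    return best.gene_id


def call_binding(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Gene-level binding calls for every (gene, TF) pair.

    Returns a table with columns ``gene_id, tf, bound, min_gap_bp,
    supporting_peak_ids``.  ``bound`` is True iff some same-TF peak has gap
    <= window_bp (inclusive).  ``min_gap_bp`` is the smallest gap to any
    same-chromosome peak of that TF (NA when the TF has no peak on the
    gene's chromosome).  Peaks on chromosomes absent from the gene set are
    ignored with a logged warning.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    gene_chroms = {g.chrom for g in genes}
    kept: dict[str, list[Peak]] = {}
    tfs = sorted({p.tf for p in peaks})
    for p in peaks:
        if p.chrom not in gene_chroms:
            log.warning(
                "peak %s (%s) is on a chromosome absent from the gene set; ignored",
                p.peak_id,
                p.chrom,
            )
            continue
        kept.setdefault(p.tf, []).append(p)

    rows = []
    for tf in tfs:
        tf_peaks = kept.get(tf, [])
        index = IntervalIndex((p.chrom, p.start, p.end, p) for p in tf_peaks)
        for g in sorted(genes, key=lambda g: g.gene_id):
            support = index.within(g.chrom, g.start, g.end, window_bp)
            min_gap = index.min_gap(g.chrom, g.start, g.end)
            support_ids = sorted(
                p.peak_id
                for p in support
            )
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "tf": tf,
                    "bound": bool(support_ids),
                    "min_gap_bp": min_gap,
                    "supporting_peak_ids": ",".join(support_ids),
                }
            )
    out = pd.DataFrame(
        rows, columns=["gene_id", "tf", "bound", "min_gap_bp", "supporting_peak_ids"]
    )
    out["min_gap_bp"] = out["min_gap_bp"].astype("Int64")
    return out


def binding_lookup(binding: pd.DataFrame) -> dict[tuple[str, str], bool]:
    """Map (gene_id, tf) -> bound for quick membership tests."""
    return {
        (r.gene_id, r.tf): bool(r.bound)
        for r in binding.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# File I/O (BED6 and header TSV dialects)
# ---------------------------------------------------------------------------

_TSV_GENE_COLS = {"chrom", "start", "end", "gene_id"}


def read_gene_models(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    """Read gene models from BED6 or a header TSV.

    BED6 columns: chrom, start, end, name (gene_id), score (ignored), strand.
    TSV must have a header with at least chrom, start, end, gene_id; symbol
    and strand are optional.  Set ``one_based=True`` for 1-based inclusive
    TSV coordinates; they are converted to 0-based half-open on read.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ValueError(f"{path}: empty file")
    header_fields = first.rstrip("\n").split("\t")
    is_tsv = _TSV_GENE_COLS.issubset(header_fields)

    genes: list[GeneModel] = []
    seen: set[str] = set()

    def add(gene: GeneModel, lineno: int) -> None:
        if gene.gene_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        genes.append(gene)

    if is_tsv:
        df = pd.read_csv(path, sep="\t")
        offset = 1 if one_based else 0
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                add(
                    GeneModel(
                        gene_id=str(row.gene_id),
                        symbol=str(getattr(row, "symbol", row.gene_id)),
                        chrom=str(row.chrom),
                        start=int(row.start) - offset,
                        end=int(row.end),
                        strand=str(getattr(row, "strand", ".")),
                    ),
                    i,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: {exc}") from exc
    else:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{i}: expected >=4 BED columns")
                try:
                    add(
                        GeneModel(
                            gene_id=fields[3],
                            symbol=fields[6] if len(fields) > 6 else fields[3],
                            chrom=fields[0],
                            start=int(fields[1]),
                            end=int(fields[2]),
                            strand=fields[5] if len(fields) > 5 else ".",
                        ),
                        i,
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{i}: {exc}") from exc
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (name=gene_id, score=0) plus symbol col 7."""
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in ordered:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.symbol}\n"
            )


def read_peaks(path: str | Path, tf: str) -> list[Peak]:
    """Read one TF's peaks from BED (name column optional)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: expected >=3 BED columns")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{tf}_p{i:05d}"
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                peaks.append(
                    Peak(
                        peak_id=name,
                        tf=tf,
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        score=score,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.peak_id)):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t.\n")
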