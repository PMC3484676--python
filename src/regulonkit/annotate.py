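"""Promoter-proximal peak annotation.

Peaks are linked to every transcription start site within a window (default
2 kb, inclusive) of the summit. Signed distances are strand-aware: negative
means the summit lies upstream of the TSS in the gene's direction of
transcription, so a promoter-proximal binder shows a negative mode.

The module also summarizes the signed-distance histogram (100-bp bins with a
centered moving-average smooth) and the spread of peak intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .peaks import Peak, PeakSet
from .seqio import Genome, TSSAnnotation, TSSRecord, reverse_complement


@dataclass(frozen=True)
class Link:
    peak_id: str
    gene_id: str
    distance: int  # signed, bp; negative = upstream of TSS


@dataclass
class PeakGeneAssignment:
    """Peak-to-TSS links within a window; one peak may hit several genes."""

    links: List[Link]
    window: int
    unassigned: List[str] = field(default_factory=list)  # peak ids with no TSS in range

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def assigned_peak_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for link in self.links:
            seen.setdefault(link.peak_id, None)
        return list(seen)

    @property
    def gene_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for link in self.links:
            seen.setdefault(link.gene_id, None)
        return list(seen)

    def nearest_only(self) -> "PeakGeneAssignment":
        """Keep only each peak's nearest TSS (ties: smaller signed distance last
        wins deterministically by |distance|, then upstream link preferred)."""
        best: Dict[str, Link] = {}
        for link in self.links:
            cur = best.get(link.peak_id)
            if cur is None or (abs(link.distance), link.distance) < (abs(cur.distance), cur.distance):
                best[link.peak_id] = link
        return PeakGeneAssignment(
            links=list(best.values()), window=self.window, unassigned=list(self.unassigned)
        )

    def genes_of_peak(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for link in self.links:
            out.setdefault(link.peak_id, []).append(link.gene_id)
        return out

    def peaks_of_gene(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for link in self.links:
            out.setdefault(link.gene_id, []).append(link.peak_id)
        return out


def assign_peaks_to_tss(
    peaks: PeakSet | Sequence[Peak], annotation: TSSAnnotation, window: int = 2000
) -> PeakGeneAssignment:
    """Link each peak to every TSS with |summit - tss| <= window (inclusive)."""
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    by_chrom: Dict[str, List[TSSRecord]] = {}
    for rec in annotation:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    tss_sorted = {
        chrom: sorted(recs, key=lambda r: r.tss) for chrom, recs in by_chrom.items()
    }
    tss_arrays = {chrom: np.array([r.tss for r in recs]) for chrom, recs in tss_sorted.items()}

    links: List[Link] = []
    unassigned: List[str] = []
    for p in peaks:
        recs = tss_sorted.get(p.chrom)
        if not recs:
            unassigned.append(p.peak_id)
            continue
        arr = tss_arrays[p.chrom]
        lo = int(np.searchsorted(arr, p.summit - window, side="left"))
        hi = int(np.searchsorted(arr, p.summit + window, side="right"))
        hit = False
        for rec in recs[lo:hi]:
            d = p.summit - rec.tss if rec.strand == "+" else rec.tss - p.summit
            links.append(Link(peak_id=p.peak_id, gene_id=rec.gene_id, distance=d))
            hit = True
        if not hit:
            unassigned.append(p.peak_id)
    return PeakGeneAssignment(links=links, window=window, unassigned=unassigned)


@dataclass
class DistanceHistogram:
    bin_width: int
    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray
    smoothed: np.ndarray
    mode_bin_center: float

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered binomial-kernel smoother (window 3 -> weights 1/4, 1/2, 1/4).

    A flat boxcar is useless for locating a mode: comparing two adjacent
    boxcar means cancels every shared bin, so the decision rests entirely on
    the outermost bins. Binomial weights keep the center dominant, and the
    kernel converges to a Gaussian as the window grows. Edge windows are
    truncated and renormalized.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smooth window must be a positive odd integer, got {window}")
    from scipy.special import comb

    weights = np.array([comb(window - 1, k) for k in range(window)], dtype=float)
    weights /= weights.sum()
    half = window // 2
    out = np.empty(len(x), dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        w = weights[lo - (i - half) : window - ((i + half + 1) - hi)]
        out[i] = (x[lo:hi] * w).sum() / w.sum()
    return out


def distance_distribution(
    assignment: PeakGeneAssignment, bin_width: int = 100, smooth_window: int = 3
) -> DistanceHistogram:
    """Histogram of signed summit-TSS distances with a smoothed mode.

    Bins of ``bin_width`` bp cover [-window, +window]; the smoothed curve is
    a centered binomial-weighted average over ``smooth_window`` bins, and
    the mode is the center of the bin maximizing it. Ties on the smoothed
    curve are resolved by the higher raw count, then by the bin center
    nearest 0, then by the upstream bin.
    """
    if not assignment.links:
        raise ValueError("empty assignment: no links to histogram")
    distances = np.array([link.distance for link in assignment.links])
    w = assignment.window
    edges = np.arange(-w, w + bin_width, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    smoothed = _smooth(counts.astype(float), smooth_window)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best = smoothed.max()
    tied = np.flatnonzero(smoothed == best)
    mode_idx = min(tied, key=lambda i: (-counts[i], abs(centers[i]), centers[i]))
    return DistanceHistogram(
        bin_width=bin_width,
        bin_edges=edges,
        counts=counts,
        smoothed=smoothed,
        mode_bin_center=float(centers[mode_idx]),
    )


@dataclass
class IntensitySummary:
    n: int
    median: float
    max_over_median: float
    n_above_10x_median: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def intensity_summary(peaks: PeakSet | Sequence[Peak], n_bins: int = 20) -> IntensitySummary:
    """Median (lower middle for even n), max/median ratio, and the count of
    outlier peaks with intensity more than tenfold above the median."""
    intensities = np.array([p.intensity for p in peaks], dtype=float)
    if intensities.size == 0:
        raise ValueError("empty peak set: no intensities to summarize")
    ordered = np.sort(intensities)
    median = float(ordered[(len(ordered) - 1) // 2])
    counts, edges = np.histogram(intensities, bins=n_bins)
    return IntensitySummary(
        n=len(intensities),
        median=median,
        max_over_median=float(ordered[-1] / median) if median > 0 else float("inf"),
        n_above_10x_median=int((intensities > 10 * median).sum()),
        hist_counts=counts,
        hist_edges=edges,
    )


def extract_promoter_windows(
    genome: Genome,
    annotation: TSSAnnotation,
    window: Tuple[int, int] = (-300, -100),
) -> List[Tuple[str, str]]:
    """Strand-aware promoter window sequences, one per gene.

    ``window`` is (a, b) in TSS-relative coordinates, half-open [a, b),
    negative upstream of transcription. For a '+' gene at TSS t this is the
    genomic slice [t+a, t+b); for a '-' gene, the reverse complement of
    [t-b+1, t-a+1). Genes whose window runs off the contig are dropped with
    a warning.
    """
    a, b = window
    if a >= b:
        raise ValueError(f"window must satisfy a < b, got {window}")
    out: List[Tuple[str, str]] = []
    dropped: List[str] = []
    for rec in annotation:
        if rec.chrom not in genome:
            raise KeyError(f"chromosome {rec.chrom!r} absent from genome")
        chrom_seq = genome[rec.chrom]
        if rec.strand == "+":
            lo, hi = rec.tss + a, rec.tss + b
        else:
            lo, hi = rec.tss - b + 1, rec.tss - a + 1
        if lo < 0 or hi > len(chrom_seq):
            dropped.append(rec.gene_id)
            continue
        seq = chrom_seq[lo:hi]
        if rec.strand == "-":
            seq = reverse_complement(seq)
        out.append((rec.gene_id, seq))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} genes whose promoter window runs off a contig edge "
            f"(first: {dropped[0]})",
            stacklevel=2,
        )
    return out


def write_links(path: str | Path, assignment: PeakGeneAssignment) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tgene_id\tdistance\n")
        for link in assignment.links:
            fh.write(f"{link.peak_id}\t{link.gene_id}\t{link.distance}\n")


def write_histogram(path: str | Path, hist: DistanceHistogram) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tbin_center\tcount\tsmoothed\n")
        for lo, hi, c, cnt, s in zip(
            hist.bin_edges[:-1], hist.bin_edges[1:], hist.bin_centers, hist.counts, hist.smoothed
        ):
            fh.write(f"{lo:g}\t{hi:g}\t{c:g}\t{cnt}\t{s:.4f}\n")
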