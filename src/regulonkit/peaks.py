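"""Peak tables and replicate reconciliation.

Two biological ChIP replicates rarely call identical peak lists. Following
standard practice for summit-based reconciliation, peaks from the two
replicates whose summits (maximum-height positions) lie within ``max_dist``
(default 200 bp) of each other on the same chromosome are treated as one
concordant binding event (Class A); the remainders are replicate-specific
Class B (replicate 1 only) and Class C (replicate 2 only).

Matching is one-to-one and greedy by ascending summit distance, so the
additive accounting |A| + |B| = |rep1| and |A| + |C| = |rep2| always holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .seqio import Genome


@dataclass(frozen=True)
class Peak:
    """A called peak: interval, summit (absolute coordinate) and intensity."""

    chrom: str
    start: int
    end: int
    summit: int
    intensity: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit must satisfy start <= summit < end, got "
                f"start={self.start} summit={self.summit} end={self.end}"
            )
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")

    @property
    def peak_id(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.summit}"


@dataclass
class PeakSet:
    """A replicate's peak calls, sorted by (chrom, summit), summits unique."""

    replicate_id: str
    peaks: List[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.summit))
        seen = set()
        for p in self.peaks:
            key = (p.chrom, p.summit)
            if key in seen:
                raise ValueError(
                    f"duplicate summit {p.chrom}:{p.summit} in replicate "
                    f"{self.replicate_id!r}; summits are the peak identity key"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> Dict[str, List[Peak]]:
        out: Dict[str, List[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


MatchedPair = Tuple[Peak, Peak, int]  # (rep1 peak, rep2 peak, summit distance)


@dataclass
class PeakClassification:
    """Outcome of two-replicate reconciliation at a summit-distance cutoff."""

    class_a: List[MatchedPair]
    class_b: List[Peak]
    class_c: List[Peak]
    max_dist: int

    @property
    def class_a_peaks(self) -> List[Peak]:
        """One logical peak per concordant pair.

        The replicate-1 member represents the pair (its summit and its
        intensity), replicate 1 being the deeper, higher-intensity library.
        """
        return [p1 for p1, _p2, _d in self.class_a]

    def counts(self) -> Dict[str, int]:
        return {"A": len(self.class_a), "B": len(self.class_b), "C": len(self.class_c)}


def read_peaks(path: str | Path, dialect: str = "tsv", replicate_id: str | None = None) -> PeakSet:
    """Read a peak table.

    dialect 'tsv': header line then chrom, start, end, summit, intensity
    (summit is an absolute coordinate). dialect 'narrowPeak': standard
    10-column ENCODE narrowPeak, where column 10 is the summit offset from
    ``start`` and column 7 (signalValue) is taken as the intensity.
    """
    if dialect not in ("tsv", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: List[Peak] = []
    errors: List[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start_at = 0
    if dialect == "tsv":
        if lines and lines[0].lower().startswith("chrom"):
            start_at = 1
    for lineno, line in enumerate(lines[start_at:], start_at + 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if dialect == "tsv":
                if len(fields) < 5:
                    raise ValueError(f"expected 5 columns, got {len(fields)}")
                chrom, start, end, summit, intensity = fields[:5]
                name = fields[5] if len(fields) > 5 else ""
                peak = Peak(chrom, int(start), int(end), int(summit), float(intensity), name)
            else:
                if len(fields) < 10:
                    raise ValueError(f"expected 10 narrowPeak columns, got {len(fields)}")
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                signal, offset = float(fields[6]), int(fields[9])
                if offset < 0:
                    raise ValueError("narrowPeak summit offset is -1 (not called)")
                peak = Peak(chrom, start, end, start + offset, signal, name)
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        peaks.append(peak)
    if errors:
        raise ValueError(f"malformed peak lines in {path}: " + "; ".join(errors))
    if replicate_id is None:
        replicate_id = Path(path).stem
    return PeakSet(replicate_id=replicate_id, peaks=peaks)


def write_peaks(path: str | Path, peakset: PeakSet) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsummit\tintensity\tname\n")
        for p in peakset:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.summit}\t{p.intensity:g}\t{p.name}\n")


def classify_replicates(rep1: PeakSet, rep2: PeakSet, max_dist: int = 200) -> PeakClassification:
    """Reconcile two replicates into Class A/B/C by summit distance.

    Candidate pairs (same chromosome, |summit1 - summit2| <= max_dist) are
    matched one-to-one, greedily by ascending distance; ties break on the
    lower replicate-1 summit, then the lower replicate-2 summit. One-to-one
    matching keeps the accounting additive: a single replicate-2 peak can
    never absorb two replicate-1 peaks.
    """
    if max_dist < 0:
        raise ValueError(f"max_dist must be >= 0, got {max_dist}")
    by1, by2 = rep1.by_chrom(), rep2.by_chrom()
    class_a: List[MatchedPair] = []
    matched1: set = set()
    matched2: set = set()
    for chrom in sorted(set(by1) & set(by2)):
        p1s, p2s = by1[chrom], by2[chrom]
        summits2 = np.array([p.summit for p in p2s])
        candidates: List[Tuple[int, int, int, Peak, Peak]] = []
        for p1 in p1s:
            lo = int(np.searchsorted(summits2, p1.summit - max_dist, side="left"))
            hi = int(np.searchsorted(summits2, p1.summit + max_dist, side="right"))
            for p2 in p2s[lo:hi]:
                d = abs(p1.summit - p2.summit)
                candidates.append((d, p1.summit, p2.summit, p1, p2))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        for d, _s1, _s2, p1, p2 in candidates:
            k1, k2 = (p1.chrom, p1.summit), (p2.chrom, p2.summit)
            if k1 in matched1 or k2 in matched2:
                continue
            matched1.add(k1)
            matched2.add(k2)
            class_a.append((p1, p2, d))
    class_b = [p for p in rep1 if (p.chrom, p.summit) not in matched1]
    class_c = [p for p in rep2 if (p.chrom, p.summit) not in matched2]
    return PeakClassification(class_a=class_a, class_b=class_b, class_c=class_c, max_dist=max_dist)


def write_classification(path: str | Path, cls: PeakClassification) -> None:
    """Write a classification table with a `class` column in {A, B, C}.

    Class A rows carry both source summits and their distance; B/C rows
    carry the single replicate's coordinates.
    """
    with open(path, "w") as fh:
        fh.write(
            "class\tchrom\tstart\tend\tsummit\tintensity\tname\t"
            "summit_rep1\tsummit_rep2\tsummit_distance\n"
        )
        for p1, p2, d in cls.class_a:
            fh.write(
                f"A\t{p1.chrom}\t{p1.start}\t{p1.end}\t{p1.summit}\t{p1.intensity:g}\t"
                f"{p1.name}\t{p1.summit}\t{p2.summit}\t{d}\n"
            )
        for label, group in (("B", cls.class_b), ("C", cls.class_c)):
            for p in group:
                fh.write(
                    f"{label}\t{p.chrom}\t{p.start}\t{p.end}\t{p.summit}\t"
                    f"{p.intensity:g}\t{p.name}\t\t\t\n"
                )


def extract_peak_sequences(
    genome: Genome, peaks: PeakSet | Sequence[Peak], flank: int = 100
) -> List[Tuple[str, str]]:
    """Extract the summit +/- flank sequence for each peak (2*flank bp).

    Windows running off a chromosome end are truncated with a warning.
    """
    out: List[Tuple[str, str]] = []
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"chromosome {p.chrom!r} absent from genome")
        chrom_seq = genome[p.chrom]
        lo, hi = p.summit - flank, p.summit + flank
        if lo < 0 or hi > len(chrom_seq):
            warnings.warn(
                f"peak {p.peak_id}: window [{lo}, {hi}) truncated to chromosome bounds",
                stacklevel=2,
            )
            lo, hi = max(lo, 0), min(hi, len(chrom_seq))
        out.append((p.peak_id, chrom_seq[lo:hi]))
    return out
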