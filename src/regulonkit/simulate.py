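"""Synthetic genomes, annotations, peak replicates and planted motifs.

The generator emulates the data shapes a promoter-proximal ChIP-seq regulon
analysis consumes, with known ground truth at every stage:

* an i.i.d. genome at a chosen GC fraction with uniformly spaced TSSs
  (minimum spacing twice the 2-kb assignment window, so peak-gene links are
  unambiguous);
* motif instances planted into strand-aware promoter windows
  ([TSS-300, TSS-100), the same window later used for background promoter
  extraction) at configurable per-motif frequencies, with a ledger of every
  plant;
* two replicate peak lists sharing a controlled number of summits, each
  summit offset from its TSS by a Normal(offset_mean, offset_sd) draw
  (default mean -205 bp, i.e. upstream) and jittered independently per
  replicate, plus replicate-specific extras; log-normal intensities
  spanning roughly an order of magnitude.

All randomness flows from one integer seed through per-stage substreams
(genome / plants / peaks), so changing one stage's parameters never
perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .motifscan import PWM
from .peaks import Peak, PeakSet
from .seqio import Genome, TSSAnnotation, TSSRecord, reverse_complement

ASSIGNMENT_WINDOW = 2000  # bp; the TSS-assignment window downstream
MIN_TSS_SPACING = 2 * ASSIGNMENT_WINDOW
PROMOTER_WINDOW = (-300, -100)  # strand-aware, TSS-relative, half-open
EDGE_MARGIN = 400  # keeps promoter windows and summit+/-100 slices on-contig

_STAGE = {"genome": 0, "plants": 1, "peaks": 2}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 400
    gc_fraction: float = 0.42
    n_shared_peaks: int = 200
    n_unique_rep1: int = 150
    n_unique_rep2: int = 20
    summit_jitter_sd: float = 30.0
    summit_tss_offset_mean: float = -205.0  # negative = upstream
    summit_tss_offset_sd: float = 40.0
    motif_plant_freqs: Dict[str, float] = field(
        default_factory=lambda: {"E2F": 0.35, "DREF": 0.25, "FOXJ2": 0.20, "RAM": 0.20}
    )
    motif_plant_strength: float = 0.95
    intensity_log_mean: float = 3.0
    intensity_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_shared_peaks",
                     "n_unique_rep1", "n_unique_rep2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_chroms == 0 and self.n_genes > 0:
            raise ValueError("cannot place genes with n_chroms == 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction must be in [0, 1], got {self.gc_fraction}")
        if not 0.0 <= self.motif_plant_strength <= 1.0:
            raise ValueError(
                f"motif_plant_strength must be in [0, 1], got {self.motif_plant_strength}"
            )
        for motif, freq in self.motif_plant_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"plant frequency for {motif!r} must be in [0, 1], got {freq}")
        if self.chrom_length <= 2 * ASSIGNMENT_WINDOW:
            raise ValueError(
                f"chrom_length must exceed twice the assignment window "
                f"(2 x {ASSIGNMENT_WINDOW} = {2 * ASSIGNMENT_WINDOW}), got {self.chrom_length}"
            )
        if self.summit_tss_offset_sd < 0:
            raise ValueError("summit_tss_offset_sd must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream of the config seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE[stage],))
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SyntheticConfig":
        return cls(**dict(mapping))


def _genes_per_chrom(config: SyntheticConfig) -> List[int]:
    base, extra = divmod(config.n_genes, max(config.n_chroms, 1))
    return [base + (1 if i < extra else 0) for i in range(config.n_chroms)]


def generate_genome(config: SyntheticConfig) -> Tuple[Genome, TSSAnnotation]:
    """I.i.d. genome at the configured GC fraction plus a TSS annotation.

    TSSs are placed uniformly at random per chromosome subject to a minimum
    spacing of twice the assignment window and an edge margin that keeps
    promoter windows on-contig; strands are assigned 50/50.
    """
    rng = config.rng("genome")
    at, gc = (1 - config.gc_fraction) / 2, config.gc_fraction / 2
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: Genome = {}
    for i in range(config.n_chroms):
        codes = rng.choice(4, size=config.chrom_length, p=[at, gc, gc, at])
        genome[f"chr{i + 1}"] = lut[codes].tobytes().decode("ascii")

    annotation: TSSAnnotation = []
    gene_no = 0
    for i, n_c in enumerate(_genes_per_chrom(config)):
        if n_c == 0:
            continue
        usable = config.chrom_length - 2 * EDGE_MARGIN - (n_c - 1) * MIN_TSS_SPACING
        if usable < 0:
            raise ValueError(
                f"config infeasible: {n_c} genes on a {config.chrom_length}-bp chromosome "
                f"violate the minimum TSS spacing of {MIN_TSS_SPACING} bp "
                f"(need chrom_length >= {2 * EDGE_MARGIN + (n_c - 1) * MIN_TSS_SPACING})"
            )
        draws = np.sort(rng.integers(0, usable + 1, size=n_c))
        tss = EDGE_MARGIN + draws + np.arange(n_c) * MIN_TSS_SPACING
        strands = np.where(rng.random(n_c) < 0.5, "+", "-")
        for t, s in zip(tss, strands):
            annotation.append(
                TSSRecord(gene_id=f"g{gene_no:05d}", chrom=f"chr{i + 1}", tss=int(t), strand=str(s))
            )
            gene_no += 1
    return genome, annotation


def promoter_window_bounds(rec: TSSRecord) -> Tuple[int, int]:
    """Genomic half-open bounds of the strand-aware planting window."""
    a, b = PROMOTER_WINDOW
    if rec.strand == "+":
        return rec.tss + a, rec.tss + b
    return rec.tss - b + 1, rec.tss - a + 1


@dataclass
class PlantResult:
    genome: Genome
    ledger: pd.DataFrame  # gene_id, motif_id, chrom, start, strand, sequence
    failures: List[Tuple[str, str]]  # (gene_id, motif_id) that could not be placed


_LEDGER_COLUMNS = ["gene_id", "motif_id", "chrom", "start", "strand", "sequence"]
_MAX_PLANT_ATTEMPTS = 20


def _sample_instance(pwm: PWM, strength: float, rng: np.random.Generator) -> str:
    """Per position: consensus base with probability ``strength``, else a
    background draw. strength 1.0 always yields the exact consensus."""
    bases = "ACGT"
    consensus = pwm.consensus
    out = []
    for i in range(pwm.width):
        if rng.random() < strength:
            out.append(consensus[i])
        else:
            out.append(bases[int(rng.choice(4, p=pwm.background))])
    return "".join(out)


def plant_motifs(
    genome: Genome,
    annotation: TSSAnnotation,
    pwms: Sequence[PWM],
    config: SyntheticConfig,
) -> PlantResult:
    """Write motif instances into promoter windows; return the edited genome
    and a ground-truth ledger of every successful plant.

    For each gene and each motif, a Bernoulli(plant frequency) coin decides
    whether one instance is planted at a uniform-random offset and strand
    within the gene's promoter window. Overlapping plants for the same gene
    are re-drawn up to a bounded number of attempts, then reported as
    failures.
    """
    rng = config.rng("plants")
    window_len = PROMOTER_WINDOW[1] - PROMOTER_WINDOW[0]
    editable = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    rows: List[Tuple] = []
    failures: List[Tuple[str, str]] = []
    for rec in annotation:
        ws, we = promoter_window_bounds(rec)
        if ws < 0 or we > len(genome[rec.chrom]):
            raise ValueError(
                f"promoter window of {rec.gene_id} ([{ws}, {we})) exceeds chromosome bounds"
            )
        occupied: List[Tuple[int, int]] = []
        for pwm in pwms:
            freq = config.motif_plant_freqs.get(pwm.motif_id, 0.0)
            if rng.random() >= freq:
                continue
            if pwm.width > window_len:
                raise ValueError(
                    f"motif {pwm.motif_id} (width {pwm.width}) does not fit the "
                    f"{window_len}-bp promoter window"
                )
            placed = False
            for _attempt in range(_MAX_PLANT_ATTEMPTS):
                offset = int(rng.integers(0, window_len - pwm.width + 1))
                start = ws + offset
                end = start + pwm.width
                if any(not (end <= s or start >= e) for s, e in occupied):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                inst = _sample_instance(pwm, config.motif_plant_strength, rng)
                written = inst if strand == "+" else reverse_complement(inst)
                editable[rec.chrom][start:end] = written.encode("ascii")
                occupied.append((start, end))
                rows.append((rec.gene_id, pwm.motif_id, rec.chrom, start, strand, inst))
                placed = True
                break
            if not placed:
                failures.append((rec.gene_id, pwm.motif_id))
    new_genome = {chrom: seq.decode("ascii") for chrom, seq in editable.items()}
    ledger = pd.DataFrame(rows, columns=_LEDGER_COLUMNS)
    return PlantResult(genome=new_genome, ledger=ledger, failures=failures)


def generate_peak_replicates(
    annotation: TSSAnnotation, config: SyntheticConfig
) -> Tuple[PeakSet, PeakSet]:
    """Two replicate peak lists with shared and replicate-specific summits.

    Shared summits sit at TSS + Normal(offset_mean, offset_sd) in the gene's
    transcription direction, duplicated into both replicates with
    independent Normal(0, jitter_sd) jitter (jitter_sd <= 0 means exact
    duplication); replicate-specific extras occupy further random TSSs.
    Shared pairs carry the same peak name in both replicates, so the
    ground-truth pairing is recoverable. Intensities are log-normal;
    start/end = summit +/- 100 bp.
    """
    rng = config.rng("peaks")
    n_total = config.n_shared_peaks + config.n_unique_rep1 + config.n_unique_rep2
    if n_total > len(annotation):
        raise ValueError(
            f"config infeasible: {n_total} peaks requested but only "
            f"{len(annotation)} genes available to anchor them"
        )
    chosen = rng.choice(len(annotation), size=n_total, replace=False)
    offsets = rng.normal(config.summit_tss_offset_mean, config.summit_tss_offset_sd, n_total)
    jitter_sd = max(config.summit_jitter_sd, 0.0)

    def true_summit(idx: int, off: float) -> int:
        rec = annotation[chosen[idx]]
        shift = int(np.rint(off))
        return rec.tss + shift if rec.strand == "+" else rec.tss - shift

    def make_peak(chrom: str, summit: int, name: str, taken: set) -> Peak:
        while (chrom, summit) in taken:
            summit += 1  # summit is the identity key; nudge exact collisions
        taken.add((chrom, summit))
        intensity = float(rng.lognormal(config.intensity_log_mean, config.intensity_log_sd))
        return Peak(
            chrom=chrom,
            start=max(summit - 100, 0),
            end=summit + 100,
            summit=summit,
            intensity=intensity,
            name=name,
        )

    rep1: List[Peak] = []
    rep2: List[Peak] = []
    taken1: set = set()
    taken2: set = set()
    for k in range(config.n_shared_peaks):
        rec = annotation[chosen[k]]
        base = true_summit(k, offsets[k])
        j1 = int(np.rint(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
        j2 = int(np.rint(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
        name = f"shared_{rec.gene_id}"
        rep1.append(make_peak(rec.chrom, base + j1, name, taken1))
        rep2.append(make_peak(rec.chrom, base + j2, name, taken2))
    for k in range(config.n_shared_peaks, config.n_shared_peaks + config.n_unique_rep1):
        rec = annotation[chosen[k]]
        rep1.append(make_peak(rec.chrom, true_summit(k, offsets[k]), f"r1_{rec.gene_id}", taken1))
    for k in range(config.n_shared_peaks + config.n_unique_rep1, n_total):
        rec = annotation[chosen[k]]
        rep2.append(make_peak(rec.chrom, true_summit(k, offsets[k]), f"r2_{rec.gene_id}", taken2))
    return (
        PeakSet(replicate_id="rep1", peaks=rep1),
        PeakSet(replicate_id="rep2", peaks=rep2),
    )
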