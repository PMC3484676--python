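"""PWM scanning with exact p-values and scramble-calibrated presence calls.

A motif is a position weight matrix (PWM): per-position base probabilities
scored against a background composition as summed log-odds in bits,

    S(w) = sum_i log2( p_i(w_i) / q(w_i) ).

The null distribution of a single window score under i.i.d. background is
computed *exactly* by column-wise convolution on a discretized score grid
(default 0.01 bits), so the best-hit p-value needs no sampling:

    p_site = P(S >= s_best),
    p_seq  = 1 - (1 - p_site)^m,   m = number of scorable windows x 2 strands,

a Sidak correction over all window placements on both strands. Windows
containing non-ACGT letters are skipped and m reduced accordingly.

Presence thresholds are calibrated the way ChIP studies calibrate against
scrambles: each region is letter-permuted (composition preserved) several
times, the fraction of real vs scrambled regions called present is computed
over a grid of candidate p-value thresholds, and the threshold maximizing
the real-minus-scrambled difference is chosen.

Note a hard floor of this statistic: the smallest attainable p_seq for a
width-w motif in a region with m scorable windows is 1-(1-p_min)^m with
p_min >= prod_i q(consensus_i). An 8-bp motif in a 200-bp region can never
reach p_seq < ~6e-3 under a uniform background, which is why thresholds are
calibrated per motif rather than fixed globally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

DEFAULT_GRANULARITY = 0.01  # bits per score-grid unit
DEFAULT_CANDIDATES = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A,C,G,T -> 0..3; anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


Regions = Sequence[Union[str, Tuple[str, str]]]


def _as_id_seq(regions: Regions) -> List[Tuple[str, str]]:
    out = []
    for i, r in enumerate(regions):
        if isinstance(r, str):
            out.append((f"region_{i}", r))
        else:
            out.append((r[0], r[1]))
    return out


@dataclass
class PWM:
    """Position probability matrix with a background model."""

    motif_id: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"probs must be a (width, 4) matrix, got {self.probs.shape}")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: probability rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.probs < 0).any() or (self.background <= 0).any():
            raise ValueError("probabilities must be non-negative, background positive")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) log2(p/q) matrix; zero-probability cells get -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    def int_scores(self, granularity: float = DEFAULT_GRANULARITY) -> np.ndarray:
        """(width, 4) integer score matrix on the discretized grid.

        -inf (zero-probability) cells are clamped to a sentinel far below
        anything reachable, so such windows always score at the floor.
        """
        lo = self.log_odds
        finite = np.isfinite(lo)
        ints = np.zeros_like(lo, dtype=np.int64)
        ints[finite] = np.round(lo[finite] / granularity).astype(np.int64)
        if not finite.all():
            sentinel = ints[finite].min() - int(100 / granularity) if finite.any() else -10**6
            ints[~finite] = sentinel
        return ints

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def build_pwm(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.25,
    background: Optional[np.ndarray] = None,
    motif_id: str = "motif",
) -> PWM:
    """Build a PWM from equal-length aligned sites.

    probs[i][b] = (count(i, b) + pseudocount) / (n + 4 * pseudocount).
    """
    if not aligned_sites:
        raise ValueError("need at least one aligned site")
    width = len(aligned_sites[0])
    if any(len(s) != width for s in aligned_sites):
        raise ValueError("aligned sites must all have the same length")
    counts = np.zeros((width, 4), dtype=float)
    for s in aligned_sites:
        codes = encode(s)
        bad = np.flatnonzero(codes == 4)
        if bad.size:
            raise ValueError(
                f"site {s!r}: non-ACGT character at position {int(bad[0])}"
            )
        counts[np.arange(width), codes] += 1.0
    n = len(aligned_sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PWM(motif_id=motif_id, probs=probs, background=bg, pseudocount=pseudocount)


def score_window(pwm: PWM, window: str, strand: str = "+") -> Optional[float]:
    """Log-odds score (bits) of one window; None if it contains non-ACGT."""
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    codes = encode(window)
    if strand == "-":
        codes = codes[::-1].copy()
        acgt = codes != 4
        codes[acgt] = 3 - codes[acgt]  # complement; N stays N
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if (codes == 4).any():
        return None
    return float(pwm.log_odds[np.arange(pwm.width), codes].sum())


@dataclass
class ScoreDistribution:
    """Exact pmf of the single-window score under i.i.d. background."""

    granularity: float
    support: np.ndarray  # integer grid values, strictly increasing
    pmf: np.ndarray

    def __post_init__(self) -> None:
        if not math.isclose(float(self.pmf.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("pmf must sum to 1")
        self._tail = np.cumsum(self.pmf[::-1])[::-1]  # P(S >= support[i])

    @property
    def scores_bits(self) -> np.ndarray:
        return self.support * self.granularity

    def sf(self, score_int: int) -> float:
        """P(S >= score_int) on the integer grid."""
        i = int(np.searchsorted(self.support, score_int, side="left"))
        return float(self._tail[i]) if i < len(self.support) else 0.0


def score_distribution(pwm: PWM, granularity: float = DEFAULT_GRANULARITY) -> ScoreDistribution:
    """Column-wise convolution of per-position score pmfs (exact DP).

    Discretization error of the resulting scores is bounded by
    width * granularity / 2.
    """
    if granularity <= 0:
        raise ValueError(f"granularity must be > 0, got {granularity}")
    ints = pwm.int_scores(granularity)
    # start with an empty product: probability 1 at score 0
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.width):
        col = ints[i]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            start = cur_lo + int(col[b]) - new_lo
            new[start : start + len(cur)] += cur * pwm.background[b]
        cur, cur_lo = new, new_lo
    nz = np.flatnonzero(cur > 0)
    support = nz + cur_lo
    return ScoreDistribution(granularity=granularity, support=support, pmf=cur[nz])


def _strand_luts(pwm: PWM, granularity: float) -> Tuple[np.ndarray, np.ndarray]:
    """Padded (5, width) integer lookup tables for forward and reverse scans.

    Row 4 (non-ACGT) scores 0 but such windows are masked out separately.
    The reverse table scores the reverse complement of a forward window.
    """
    ints = pwm.int_scores(granularity)  # (w, 4)
    fwd = np.zeros((5, pwm.width), dtype=np.int64)
    fwd[:4, :] = ints.T
    rev = np.zeros((5, pwm.width), dtype=np.int64)
    rev[:4, :] = ints.T[::-1, ::-1]  # complement bases, reverse positions
    return fwd, rev


@dataclass
class BestHit:
    """Best-hit statistics of one motif over one region (both strands)."""

    p_sequence: float
    p_site: float
    best_score_bits: float
    n_windows: int  # m: scorable window placements counting both strands
    best_pos: int
    best_strand: str


def _window_score_arrays(
    codes: np.ndarray, fwd: np.ndarray, rev: np.ndarray, width: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    windows = np.lib.stride_tricks.sliding_window_view(codes, width)
    valid = ~(windows == 4).any(axis=1)
    pos = np.arange(width)
    s_fwd = fwd[windows, pos].sum(axis=1)
    s_rev = rev[windows, pos].sum(axis=1)
    return s_fwd, s_rev, valid


def best_hit_pvalue(
    pwm: PWM,
    sequence: str,
    dist: Optional[ScoreDistribution] = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> Optional[BestHit]:
    """Sequence-level best-hit p-value of one motif over both strands.

    Returns None when no window is scorable (e.g. an all-N region) — an
    unscorable result, never a silent p = 1.
    """
    if len(sequence) < pwm.width:
        raise ValueError(
            f"sequence length {len(sequence)} < PWM width {pwm.width}"
        )
    if dist is None:
        dist = score_distribution(pwm, granularity)
    fwd, rev = _strand_luts(pwm, dist.granularity)
    codes = encode(sequence)
    s_fwd, s_rev, valid = _window_score_arrays(codes, fwd, rev, pwm.width)
    if not valid.any():
        return None
    m = int(valid.sum()) * 2
    vf, vr = s_fwd[valid], s_rev[valid]
    if_, ir = int(vf.argmax()), int(vr.argmax())
    if vf[if_] >= vr[ir]:
        best_int, best_pos, best_strand = int(vf[if_]), int(np.flatnonzero(valid)[if_]), "+"
    else:
        best_int, best_pos, best_strand = int(vr[ir]), int(np.flatnonzero(valid)[ir]), "-"
    p_site = dist.sf(best_int)
    p_seq = -math.expm1(m * math.log1p(-min(p_site, 1.0))) if p_site < 1.0 else 1.0
    return BestHit(
        p_sequence=p_seq,
        p_site=p_site,
        best_score_bits=best_int * dist.granularity,
        n_windows=m,
        best_pos=best_pos,
        best_strand=best_strand,
    )


def best_hit_pvalues(
    pwm: PWM,
    regions: Sequence[str],
    dist: Optional[ScoreDistribution] = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> np.ndarray:
    """Vector of sequence-level p-values; NaN for unscorable regions."""
    if dist is None:
        dist = score_distribution(pwm, granularity)
    out = np.empty(len(regions))
    for i, seq in enumerate(regions):
        hit = best_hit_pvalue(pwm, seq, dist=dist)
        out[i] = math.nan if hit is None else hit.p_sequence
    return out


def shuffle_sequence(
    sequence: str,
    seed: Union[int, np.random.Generator] = 0,
    method: str = "mono",
) -> str:
    """Composition-preserving scramble of a sequence.

    'mono' (default): uniform random letter permutation (Fisher-Yates),
    preserving the base multiset exactly. 'dinuc': doublet shuffle that also
    preserves dinucleotide counts (rejection-sampled Eulerian walk).
    """
    if not sequence:
        raise ValueError("cannot shuffle an empty sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "mono":
        letters = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        return rng.permutation(letters).tobytes().decode("ascii")
    if method != "dinuc":
        raise ValueError(f"unknown shuffle method {method!r}")
    if len(sequence) < 3:
        return sequence
    # doublet shuffle: random walk over the dinucleotide multigraph,
    # retried until the walk consumes every edge (Eulerian)
    edges: Dict[str, List[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(sequence) - 1
    for _attempt in range(1000):
        pool = {k: list(rng.permutation(v)) for k, v in edges.items()}
        walk = [sequence[0]]
        cur = sequence[0]
        for _ in range(n_edges):
            nxt_list = pool.get(cur)
            if not nxt_list:
                break
            cur = nxt_list.pop()
            walk.append(cur)
        if len(walk) == len(sequence):
            return "".join(walk)
    raise RuntimeError("doublet shuffle failed to find an Eulerian walk")


@dataclass
class CalibrationResult:
    """Scramble-calibration of a presence threshold for one motif."""

    motif_id: str
    candidate_thresholds: List[float]  # descending
    frac_bound: List[float]
    frac_scrambled: List[float]  # mean over scrambles
    chosen_threshold: float
    n_shuffles: int

    @property
    def differences(self) -> List[float]:
        return [b - s for b, s in zip(self.frac_bound, self.frac_scrambled)]


def calibrate_threshold(
    pwm: PWM,
    regions: Regions,
    n_shuffles: int = 5,
    candidates: Iterable[float] = DEFAULT_CANDIDATES,
    seed: Union[int, np.random.Generator] = 0,
    dist: Optional[ScoreDistribution] = None,
) -> CalibrationResult:
    """Choose the presence p-value threshold by real-vs-scramble contrast.

    For each candidate t, frac_bound is the fraction of regions with
    sequence-level p < t, and frac_scrambled the mean of the same fraction
    over ``n_shuffles`` full scrambles of every region. The chosen threshold
    maximizes frac_bound - frac_scrambled; ties go to the more stringent
    (smaller) candidate.
    """
    pairs = _as_id_seq(regions)
    if not pairs:
        raise ValueError("need at least one region to calibrate")
    cands = sorted(candidates, reverse=True)
    if not cands:
        raise ValueError("need at least one candidate threshold")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist is None:
        dist = score_distribution(pwm)
    seqs = [s for _id, s in pairs]
    p_real = best_hit_pvalues(pwm, seqs, dist=dist)
    real_ok = ~np.isnan(p_real)
    if not real_ok.any():
        raise ValueError("no scorable region to calibrate on")
    frac_bound = [float((p_real[real_ok] < t).mean()) for t in cands]
    scr_fracs = np.zeros((n_shuffles, len(cands)))
    for s in range(n_shuffles):
        shuffled = [shuffle_sequence(seq, rng) for seq in seqs]
        p_scr = best_hit_pvalues(pwm, shuffled, dist=dist)
        ok = ~np.isnan(p_scr)
        scr_fracs[s] = [float((p_scr[ok] < t).mean()) for t in cands]
    frac_scrambled = scr_fracs.mean(axis=0).tolist()
    diffs = np.array(frac_bound) - np.array(frac_scrambled)
    # maximize the difference; exact ties go to the more stringent candidate
    best_i = min(range(len(cands)), key=lambda i: (-diffs[i], cands[i]))
    return CalibrationResult(
        motif_id=pwm.motif_id,
        candidate_thresholds=list(cands),
        frac_bound=frac_bound,
        frac_scrambled=frac_scrambled,
        chosen_threshold=cands[best_i],
        n_shuffles=n_shuffles,
    )


@dataclass
class MotifPresenceMatrix:
    """Boolean presence calls: regions x motifs at per-motif thresholds.

    Multiple hits of one motif in a region still count as a single presence.
    ``ok`` flags scorable regions; unscorable rows are excluded from any
    denominator downstream.
    """

    region_ids: List[str]
    motif_ids: List[str]
    present: np.ndarray  # (n_regions, n_motifs) bool
    threshold_p: Dict[str, float]
    ok: np.ndarray  # (n_regions,) bool

    def __post_init__(self) -> None:
        if self.present.shape != (len(self.region_ids), len(self.motif_ids)):
            raise ValueError("presence matrix shape does not match id lists")
        for t in self.threshold_p.values():
            if not (0.0 < t < 1.0):
                raise ValueError(f"threshold must be in (0, 1), got {t}")

    def motifs_of_region(self, i: int) -> frozenset:
        return frozenset(
            m for j, m in enumerate(self.motif_ids) if self.present[i, j]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.present.astype(int), index=self.region_ids, columns=self.motif_ids
        )


def scan_regions(
    pwms: Sequence[PWM],
    regions: Regions,
    thresholds: Mapping[str, float],
    dists: Optional[Mapping[str, ScoreDistribution]] = None,
) -> MotifPresenceMatrix:
    """Call per-region, per-motif presence at per-motif p-value thresholds."""
    pairs = _as_id_seq(regions)
    for pwm in pwms:
        if pwm.motif_id not in thresholds:
            raise KeyError(f"no threshold supplied for motif {pwm.motif_id!r}")
    region_ids = [rid for rid, _ in pairs]
    seqs = [s for _, s in pairs]
    present = np.zeros((len(pairs), len(pwms)), dtype=bool)
    ok = np.ones(len(pairs), dtype=bool)
    for j, pwm in enumerate(pwms):
        dist = dists[pwm.motif_id] if dists else None
        p = best_hit_pvalues(pwm, seqs, dist=dist)
        ok &= ~np.isnan(p)
        with np.errstate(invalid="ignore"):
            present[:, j] = p < thresholds[pwm.motif_id]
    present[~ok, :] = False
    return MotifPresenceMatrix(
        region_ids=region_ids,
        motif_ids=[p.motif_id for p in pwms],
        present=present,
        threshold_p=dict(thresholds),
        ok=ok,
    )


def write_presence(path: str | Path, matrix: MotifPresenceMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\t" + "\t".join(matrix.motif_ids) + "\tscorable\n")
        for i, rid in enumerate(matrix.region_ids):
            row = "\t".join(str(int(v)) for v in matrix.present[i])
            fh.write(f"{rid}\t{row}\t{int(matrix.ok[i])}\n")


def read_presence(path: str | Path) -> MotifPresenceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        motif_ids = header[1:-1]
        region_ids, rows, oks = [], [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            region_ids.append(fields[0])
            rows.append([bool(int(v)) for v in fields[1:-1]])
            oks.append(bool(int(fields[-1])))
    return MotifPresenceMatrix(
        region_ids=region_ids,
        motif_ids=motif_ids,
        present=np.array(rows, dtype=bool).reshape(len(region_ids), len(motif_ids)),
        threshold_p={m: 0.5 for m in motif_ids},  # thresholds not stored in the TSV
        ok=np.array(oks, dtype=bool),
    )


def write_calibration(path: str | Path, results: Sequence[CalibrationResult]) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tthreshold\tfrac_bound\tfrac_scrambled\tdifference\tchosen\n")
        for res in results:
            for t, b, s in zip(res.candidate_thresholds, res.frac_bound, res.frac_scrambled):
                fh.write(
                    f"{res.motif_id}\t{t:g}\t{b:.6f}\t{s:.6f}\t{b - s:.6f}\t"
                    f"{int(t == res.chosen_threshold)}\n"
                )


# ---------------------------------------------------------------------------
# PWM file formats


def read_meme(path: str | Path) -> List[PWM]:
    """Read MEME minimal motif format (letter-probability matrices)."""
    pwms: List[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freqs = {tokens[k]: float(tokens[k + 1]) for k in range(0, len(tokens), 2)}
            background = np.array([freqs.get(b, 0.25) for b in _BASES])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i].strip()
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            probs = np.array(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            pwms.append(PWM(motif_id=motif_id, probs=probs, background=background.copy()))
        i += 1
    return pwms


def write_meme(path: str | Path, pwms: Sequence[PWM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {q:.5f}" for b, q in zip(_BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_matrix(path: str | Path) -> List[PWM]:
    """Read plain whitespace matrices: optional '>id' headers, rows of 4
    numbers (probabilities or counts; rows are normalized)."""
    pwms: List[PWM] = []
    name = "motif_1"
    rows: List[List[float]] = []

    def flush() -> None:
        nonlocal rows
        if rows:
            probs = np.array(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            pwms.append(PWM(motif_id=name, probs=probs))
            rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip() or f"motif_{len(pwms) + 1}"
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"matrix rows need 4 values, got {len(vals)}: {line!r}")
                rows.append(vals)
    flush()
    return pwms
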