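"""Motif enrichment, constellation counting and category profiles.

Three read-outs over a motif presence matrix:

* **constellations** — each peak region is assigned the subset of the motif
  panel it contains (presence is boolean: multiple hits of one motif still
  count once), and regions are tallied per subset and per subset size;
* **background enrichment** — the fraction of bound regions containing each
  motif versus the mean fraction over several random sets of unbound
  promoter windows (default five sets of 1000, matching standard
  scramble-independent background practice);
* **category profiles** — for a gene-category map, the fraction of genes in
  each category whose assigned peaks contain each motif (a gene is positive
  if ANY of its peaks is), plus a "none" column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotate import PeakGeneAssignment
from .motifscan import PWM, MotifPresenceMatrix, best_hit_pvalues, score_distribution


@dataclass
class ConstellationCounts:
    """Partition of regions by the exact subset of panel motifs present."""

    counts: Dict[FrozenSet[str], int]
    n_regions: int
    motif_ids: List[str]

    def by_size(self) -> Dict[int, int]:
        out: Dict[int, int] = {k: 0 for k in range(len(self.motif_ids) + 1)}
        for subset, n in self.counts.items():
            out[len(subset)] += n
        return out

    def fraction_by_size(self) -> Dict[int, float]:
        if self.n_regions == 0:
            return {k: 0.0 for k in range(len(self.motif_ids) + 1)}
        return {k: n / self.n_regions for k, n in self.by_size().items()}

    def fraction_with(self, motif_id: str) -> float:
        if self.n_regions == 0:
            return 0.0
        n = sum(c for subset, c in self.counts.items() if motif_id in subset)
        return n / self.n_regions


def constellation_counts(matrix: MotifPresenceMatrix) -> ConstellationCounts:
    """Count regions per motif subset; unscorable rows are excluded."""
    if len(matrix.region_ids) == 0:
        raise ValueError("empty presence matrix")
    counts: Dict[FrozenSet[str], int] = {}
    n = 0
    for i in range(len(matrix.region_ids)):
        if not matrix.ok[i]:
            continue
        subset = matrix.motifs_of_region(i)
        counts[subset] = counts.get(subset, 0) + 1
        n += 1
    return ConstellationCounts(counts=counts, n_regions=n, motif_ids=list(matrix.motif_ids))


@dataclass
class EnrichmentResult:
    motif_id: str
    frac_bound: float
    background_fracs: List[float]
    background_mean: float
    background_sd: float
    ratio: float
    z_score: float  # empirical z of frac_bound vs the background sets


def background_promoter_enrichment(
    pwms: Sequence[PWM],
    bound_regions: Sequence[Union[str, Tuple[str, str]]],
    unbound_promoters: Sequence[Union[str, Tuple[str, str]]],
    thresholds: Mapping[str, float],
    n_sets: int = 5,
    set_size: int = 1000,
    seed: Union[int, np.random.Generator] = 0,
) -> List[EnrichmentResult]:
    """Per-motif fraction of bound regions vs random unbound-promoter sets.

    ``unbound_promoters`` are promoter-window sequences of genes without a
    peak (extract them with :func:`regulonkit.annotate.extract_promoter_windows`).
    Each of ``n_sets`` background sets is an independent sample of
    ``set_size`` promoters; sampling is with replacement (with a warning)
    when the pool is smaller than ``set_size``.
    """

    def seqs(regions):
        return [r if isinstance(r, str) else r[1] for r in regions]

    bound_seqs = seqs(bound_regions)
    pool = seqs(unbound_promoters)
    if not pool:
        raise ValueError("empty unbound promoter pool")
    if not bound_seqs:
        raise ValueError("no bound regions")
    replace = len(pool) < set_size
    if replace:
        warnings.warn(
            f"unbound pool ({len(pool)}) smaller than set_size ({set_size}); "
            "sampling with replacement",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sets = [
        [pool[i] for i in rng.choice(len(pool), size=set_size, replace=replace)]
        for _ in range(n_sets)
    ]
    results: List[EnrichmentResult] = []
    for pwm in pwms:
        t = thresholds[pwm.motif_id]
        dist = score_distribution(pwm)
        p_bound = best_hit_pvalues(pwm, bound_seqs, dist=dist)
        okb = ~np.isnan(p_bound)
        frac_bound = float((p_bound[okb] < t).mean())
        bg_fracs = []
        for bg in sets:
            p_bg = best_hit_pvalues(pwm, bg, dist=dist)
            okg = ~np.isnan(p_bg)
            bg_fracs.append(float((p_bg[okg] < t).mean()))
        bg_mean = float(np.mean(bg_fracs))
        bg_sd = float(np.std(bg_fracs, ddof=1)) if n_sets > 1 else 0.0
        ratio = frac_bound / bg_mean if bg_mean > 0 else float("inf")
        z = (frac_bound - bg_mean) / bg_sd if bg_sd > 0 else float("inf")
        results.append(
            EnrichmentResult(
                motif_id=pwm.motif_id,
                frac_bound=frac_bound,
                background_fracs=bg_fracs,
                background_mean=bg_mean,
                background_sd=bg_sd,
                ratio=ratio,
                z_score=z,
            )
        )
    return results


@dataclass
class CategoryMotifTable:
    """Fractions of genes per category whose peaks contain each motif."""

    categories: List[str]
    motifs: List[str]  # + trailing "none" column
    fractions: np.ndarray  # (n_categories, n_motifs + 1); NaN for empty categories
    gene_counts: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.categories, columns=self.motifs)


CategoryMap = Mapping[str, Sequence[str]]  # gene_id -> categories (multi-membership)


def gene_motif_sets(
    assignment: PeakGeneAssignment, matrix: MotifPresenceMatrix
) -> Dict[str, FrozenSet[str]]:
    """Per-gene union of panel motifs over all assigned, scorable peaks."""
    region_index = {rid: i for i, rid in enumerate(matrix.region_ids)}
    out: Dict[str, set] = {}
    for gene_id, peak_ids in assignment.peaks_of_gene().items():
        motifs: set = set()
        for pid in peak_ids:
            i = region_index.get(pid)
            if i is None or not matrix.ok[i]:
                continue
            motifs |= matrix.motifs_of_region(i)
        out[gene_id] = motifs
    return {g: frozenset(m) for g, m in out.items()}


def category_motif_fractions(
    assignment: PeakGeneAssignment,
    matrix: MotifPresenceMatrix,
    categories: CategoryMap,
    all_label: str = "all",
) -> CategoryMotifTable:
    """Per-(category, motif) fraction of genes with the motif in any peak.

    An ``all`` row covers every assigned gene. Categories with no assigned
    gene get an explicit NaN row rather than being dropped silently.
    """
    per_gene = gene_motif_sets(assignment, matrix)
    cat_genes: Dict[str, List[str]] = {}
    for gene, cats in categories.items():
        for cat in cats:
            cat_genes.setdefault(cat, []).append(gene)
    cat_names = sorted(cat_genes)
    rows = [all_label] + cat_names
    motif_cols = list(matrix.motif_ids) + ["none"]
    fractions = np.full((len(rows), len(motif_cols)), np.nan)
    gene_counts: Dict[str, int] = {}
    for r, cat in enumerate(rows):
        genes = list(per_gene) if cat == all_label else [
            g for g in cat_genes[cat] if g in per_gene
        ]
        gene_counts[cat] = len(genes)
        if not genes:
            continue
        for c, motif in enumerate(matrix.motif_ids):
            fractions[r, c] = sum(motif in per_gene[g] for g in genes) / len(genes)
        fractions[r, -1] = sum(not per_gene[g] for g in genes) / len(genes)
    return CategoryMotifTable(
        categories=rows, motifs=motif_cols, fractions=fractions, gene_counts=gene_counts
    )


def read_category_map(path: str | Path) -> Dict[str, List[str]]:
    """Read a 2-column TSV (gene_id, category); multi-membership allowed."""
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("gene_id", "gene"):
                continue
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns (gene_id, category)")
            out.setdefault(fields[0], []).append(fields[1])
    return out


def write_constellation(path: str | Path, counts: ConstellationCounts) -> None:
    with open(path, "w") as fh:
        fh.write("motif_subset\tcount\tfraction\n")
        for subset in sorted(counts.counts, key=lambda s: (len(s), sorted(s))):
            n = counts.counts[subset]
            label = "+".join(sorted(subset)) if subset else "none"
            fh.write(f"{label}\t{n}\t{n / counts.n_regions:.6f}\n")


def write_enrichment(path: str | Path, results: Sequence[EnrichmentResult]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "motif_id\tfrac_bound\tbackground_mean\tbackground_sd\tratio\tz_score\t"
            "background_fracs\n"
        )
        for r in results:
            fracs = ",".join(f"{v:.6f}" for v in r.background_fracs)
            fh.write(
                f"{r.motif_id}\t{r.frac_bound:.6f}\t{r.background_mean:.6f}\t"
                f"{r.background_sd:.6f}\t{r.ratio:.4f}\t{r.z_score:.4f}\t{fracs}\n"
            )
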