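"""Cross-species regulon comparison.

Fly target genes are mapped through an orthology table to human genes, and
binding conservation is assessed at the level of *ortholog families*: a
family counts as bound in both species when at least one fly member and at
least one human member are bound. When the input table carries no family
ids, families are taken as connected components of the fly-human link
graph, which is the natural reading of "orthologous family" for a many-to-
many orthology relation.

Overlap with per-condition human bound-gene sets (e.g. RB or p130 occupancy
in growing / quiescent / senescent fibroblasts) is reported as pairwise
intersections plus full Venn partitions, and category enrichment of any
gene subset against a universe uses the hypergeometric upper tail with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MAX_VENN_SETS = 5  # combinatorial guard


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


@dataclass
class OrthologMap:
    """Fly-to-human ortholog links, grouped into families.

    ``links`` are (fly_gene_id, human_gene_id, family_id-or-None) triples.
    Gene ids are case-sensitive opaque strings; fly and human namespaces are
    kept apart internally, so the same string may appear on both sides.
    """

    links: List[Tuple[str, str, Optional[str]]]

    def __post_init__(self) -> None:
        explicit = {fam for _f, _h, fam in self.links if fam is not None}
        partial = any(fam is None for _f, _h, fam in self.links)
        if explicit and partial:
            raise ValueError("family_id must be given for all links or for none")
        if explicit:
            fams: Dict[str, str] = {}
            for fly, human, fam in self.links:
                for side, gene in (("fly", fly), ("human", human)):
                    key = f"{side}:{gene}"
                    if fams.setdefault(key, fam) != fam:
                        raise ValueError(
                            f"{side} gene {gene!r} appears in families "
                            f"{fams[key]!r} and {fam!r}; families must be consistent"
                        )
            self._family_of = fams
        else:
            # families = connected components of the bipartite link graph
            uf = _UnionFind()
            for fly, human, _fam in self.links:
                uf.union(f"fly:{fly}", f"human:{human}")
            self._family_of = {
                node: uf.find(node)
                for fly, human, _fam in self.links
                for node in (f"fly:{fly}", f"human:{human}")
            }

    @property
    def fly_genes(self) -> Set[str]:
        return {f for f, _h, _fam in self.links}

    @property
    def human_genes(self) -> Set[str]:
        return {h for _f, h, _fam in self.links}

    def family_of_fly(self, gene: str) -> Optional[str]:
        return self._family_of.get(f"fly:{gene}")

    def family_of_human(self, gene: str) -> Optional[str]:
        return self._family_of.get(f"human:{gene}")

    def family_members(self) -> Dict[str, Tuple[Set[str], Set[str]]]:
        """family_id -> (fly members, human members)."""
        fams: Dict[str, Tuple[Set[str], Set[str]]] = {}
        for fly, human, _f in self.links:
            fam_f = self._family_of[f"fly:{fly}"]
            fams.setdefault(fam_f, (set(), set()))[0].add(fly)
            fam_h = self._family_of[f"human:{human}"]
            fams.setdefault(fam_h, (set(), set()))[1].add(human)
        return fams

    def humans_of(self, fly_gene: str) -> Set[str]:
        return {h for f, h, _fam in self.links if f == fly_gene}


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a TSV of fly_id, human_id[, family_id] (header optional)."""
    links: List[Tuple[str, str, Optional[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("fly_id", "fly_gene_id", "fly"):
                continue
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 columns")
            fam = fields[2] if len(fields) > 2 and fields[2] else None
            links.append((fields[0], fields[1], fam))
    return OrthologMap(links=links)


ConditionSets = Dict[str, Set[str]]  # condition_id -> human genes bound


def read_condition_sets(path: str | Path) -> ConditionSets:
    """Read a long-format TSV (condition, gene_id)."""
    out: ConditionSets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("condition", "condition_id"):
                continue
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns (condition, gene)")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


@dataclass
class OrthologProjection:
    human_genes: Set[str]
    multiplicity: Dict[str, int]  # fly gene -> number of human orthologs
    no_ortholog: List[str]  # fly genes absent from the map


def map_fly_to_human(fly_targets: Iterable[str], omap: OrthologMap) -> OrthologProjection:
    """Union of human orthologs of the fly target set, with a per-fly-gene
    fan-out report and the list of fly genes lacking any ortholog."""
    humans_by_fly: Dict[str, Set[str]] = {}
    for fly, human, _fam in omap.links:
        humans_by_fly.setdefault(fly, set()).add(human)
    human_genes: Set[str] = set()
    multiplicity: Dict[str, int] = {}
    no_ortholog: List[str] = []
    for fly in fly_targets:
        humans = humans_by_fly.get(fly)
        if not humans:
            no_ortholog.append(fly)
            multiplicity[fly] = 0
        else:
            human_genes |= humans
            multiplicity[fly] = len(humans)
    return OrthologProjection(
        human_genes=human_genes, multiplicity=multiplicity, no_ortholog=no_ortholog
    )


def family_bound_in_both(
    fly_bound: Iterable[str], human_bound: Iterable[str], omap: OrthologMap
) -> Set[str]:
    """Families with >= 1 bound fly member AND >= 1 bound human member."""
    fly_bound, human_bound = set(fly_bound), set(human_bound)
    out: Set[str] = set()
    for fam, (fly_members, human_members) in omap.family_members().items():
        if fly_members & fly_bound and human_members & human_bound:
            out.add(fam)
    return out


def venn_partition(sets: Mapping[str, Set[str]]) -> Dict[FrozenSet[str], int]:
    """Counts of every intersection region over the union of the sets.

    Keys are the non-empty subsets of set names; a gene contributes to
    exactly one key (the set of names containing it), so counts sum to the
    size of the union.
    """
    if len(sets) > MAX_VENN_SETS:
        raise ValueError(
            f"Venn partition over {len(sets)} sets refused (max {MAX_VENN_SETS})"
        )
    universe: Set[str] = set().union(*sets.values()) if sets else set()
    out: Dict[FrozenSet[str], int] = {}
    for gene in universe:
        key = frozenset(name for name, members in sets.items() if gene in members)
        out[key] = out.get(key, 0) + 1
    return out


@dataclass
class OverlapTable:
    set_a_size: int
    per_condition: Dict[str, int]  # |A  intersect  condition|
    per_condition_fraction: Dict[str, float]
    venn: Dict[FrozenSet[str], int]  # partition over {A} | conditions


def overlap_table(
    set_a: Iterable[str], conditions: ConditionSets, set_a_label: str = "A"
) -> OverlapTable:
    """Overlap of a gene set with per-condition bound sets, plus the Venn
    partition over the set and all conditions (guarded at 5 sets)."""
    a = set(set_a)
    if not a:
        raise ValueError("set A is empty")
    if len(conditions) + 1 > MAX_VENN_SETS:
        raise ValueError(
            f"{len(conditions)} conditions plus the query set exceed the "
            f"{MAX_VENN_SETS}-set Venn guard; partition conditions in batches"
        )
    per = {cond: len(a & genes) for cond, genes in conditions.items()}
    frac = {cond: n / len(a) for cond, n in per.items()}
    venn = venn_partition({set_a_label: a, **conditions})
    return OverlapTable(
        set_a_size=len(a), per_condition=per, per_condition_fraction=frac, venn=venn
    )


def category_enrichment(
    subset: Iterable[str],
    universe: Iterable[str],
    categories: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric category enrichment of ``subset`` within ``universe``.

    For each category with K members in the universe, of which k fall in the
    size-n subset: fold = (k/n) / (K/N), upper-tail hypergeometric p for
    enrichment, lower-tail p for depletion (flagged when fold < 1), and a
    Benjamini-Hochberg q across categories on the enrichment p-values.
    """
    subset, universe = set(subset), set(universe)
    if not subset <= universe:
        extra = sorted(subset - universe)[:3]
        raise ValueError(f"subset is not contained in universe (e.g. {extra})")
    n, big_n = len(subset), len(universe)
    cat_members: Dict[str, Set[str]] = {}
    for gene, cats in categories.items():
        if gene not in universe:
            continue
        for cat in cats:
            cat_members.setdefault(cat, set()).add(gene)
    rows = []
    for cat in sorted(cat_members):
        members = cat_members[cat]
        big_k, k = len(members), len(members & subset)
        frac_sub = k / n if n else 0.0
        frac_uni = big_k / big_n
        fold = frac_sub / frac_uni if frac_uni > 0 else float("nan")
        p_enrich = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        p_deplete = float(stats.hypergeom.cdf(k, big_n, big_k, n))
        rows.append(
            {
                "category": cat,
                "n_universe": big_k,
                "n_subset": k,
                "fold": fold,
                "p_hyper": p_enrich,
                "p_depletion": p_deplete,
                "depleted": fold < 1.0,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_bh"] = multipletests(df["p_hyper"], method="fdr_bh")[1]
    else:
        df = pd.DataFrame(
            columns=[
                "category", "n_universe", "n_subset", "fold",
                "p_hyper", "p_depletion", "depleted", "q_bh",
            ]
        )
    return df


def write_overlap(path: str | Path, table: OverlapTable) -> None:
    with open(path, "w") as fh:
        fh.write("condition\toverlap\tfraction_of_A\n")
        for cond in sorted(table.per_condition):
            fh.write(
                f"{cond}\t{table.per_condition[cond]}\t"
                f"{table.per_condition_fraction[cond]:.6f}\n"
            )


def write_venn(path: str | Path, venn: Mapping[FrozenSet[str], int]) -> None:
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for key in sorted(venn, key=lambda k: (len(k), sorted(k))):
            fh.write("&".join(sorted(key)) + f"\t{venn[key]}\n")
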