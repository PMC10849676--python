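"""Reciprocal-best-hit orthology from tabular alignment hits.

Hit tables follow BLAST outfmt-6 column order; only query, subject,
e-value and bit score are used. Hits above the e-value ceiling (1e-5) are
discarded, the best hit per query is chosen by bit score (ties: lower
e-value, then lexicographic subject), and a pair is a reciprocal best hit
(RBH) iff each gene is the other's best hit. Allotetraploid homeolog
suffixes (.S/.L) are collapsed to the gene root before RBH computation.

Three-species target overlaps are built on a graph whose nodes are target
genes and whose edges are target-target RBH links. "Shared by all three"
is reported under two rules: triangle-closed (all three pairwise RBH edges
present) and chain-linked (one connected component touching all species).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_homeologs",
    "compute_rbh",
    "OrthologySet",
    "overlap_targets",
    "read_hits_outfmt6",
    "best_hits",
]

_HIT_COLS = ["query", "subject", "evalue", "bitscore"]


def _as_hits_frame(hits: pd.DataFrame | Sequence[tuple]) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        df = hits.copy()
        missing = [c for c in _HIT_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        return df[_HIT_COLS].reset_index(drop=True)
    return pd.DataFrame(hits, columns=_HIT_COLS)


def read_hits_outfmt6(path) -> pd.DataFrame:
    """Read BLAST outfmt-6 (12 columns); keeps query/subject/evalue/bitscore."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError("expected 12-column BLAST outfmt-6 table")
    out = df[[0, 1, 10, 11]].copy()
    out.columns = _HIT_COLS
    out["query"] = out["query"].astype(str)
    out["subject"] = out["subject"].astype(str)
    return out


def _strip_suffix(gene_id: str, suffixes: Sequence[str]) -> str:
    for suf in suffixes:
        if gene_id.endswith(suf) and len(gene_id) > len(suf):
            return gene_id[: -len(suf)]
    return gene_id


def collapse_homeologs(
    hits: pd.DataFrame | Sequence[tuple],
    suffixes: Sequence[str] = (".S", ".L"),
) -> pd.DataFrame:
    """Strip terminal homeolog suffixes and deduplicate (query, subject) rows.

    Among rows duplicated after collapsing, the highest bit score wins
    (ties: lowest e-value, then input order). Suffixes must terminate the
    id; mid-string occurrences are untouched.
    """
    if not suffixes:
        raise ValueError("suffix list must be non-empty")
    df = _as_hits_frame(hits)
    df["query"] = [_strip_suffix(q, suffixes) for q in df["query"]]
    df["subject"] = [_strip_suffix(s, suffixes) for s in df["subject"]]
    df["_ord"] = range(len(df))
    df = df.sort_values(
        ["query", "subject", "bitscore", "evalue", "_ord"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    ).drop_duplicates(["query", "subject"], keep="first")
    return df.sort_values("_ord").drop(columns="_ord").reset_index(drop=True)


def best_hits(hits: pd.DataFrame | Sequence[tuple], evalue_max: float = 1e-5) -> dict[str, str]:
    """Best subject per query: max bit score, ties by lower e-value then
    lexicographic subject; rows with evalue > evalue_max are discarded."""
    df = _as_hits_frame(hits)
    df = df[df["evalue"] <= evalue_max]
    if df.empty:
        return {}
    df = df.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("query", keep="first")
    return dict(zip(df["query"], df["subject"]))


def compute_rbh(
    hits_ab: pd.DataFrame | Sequence[tuple],
    hits_ba: pd.DataFrame | Sequence[tuple],
    evalue_max: float = 1e-5,
) -> set[tuple[str, str]]:
    """Reciprocal best hits between species A and B.

    (a, b) is an RBH iff b is a's best hit in B and a is b's best hit in A.
    The result is one-to-one within the species pair.
    """
    fwd = best_hits(hits_ab, evalue_max)
    rev = best_hits(hits_ba, evalue_max)
    if not fwd or not rev:
        logger.info("compute_rbh: empty hit table after e-value filtering")
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}


@dataclass
class OrthologySet:
    """Pairwise RBH sets plus per-species target lists for three species.

    ``pair_rbh`` keys are ordered species-name pairs; ``hit_partners``
    optionally records, per ordered pair, the query genes with any
    post-e-value-filter hit in the subject species (used by the
    hits-in-all-species filter; the filter is skipped if absent).
    """

    pair_rbh: dict[tuple[str, str], set[tuple[str, str]]]
    species_targets: dict[str, set[str]]
    hit_partners: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def species(self) -> list[str]:
        return sorted(self.species_targets)

    def rbh(self, a: str, b: str) -> set[tuple[str, str]]:
        if (a, b) in self.pair_rbh:
            return self.pair_rbh[(a, b)]
        if (b, a) in self.pair_rbh:
            return {(y, x) for x, y in self.pair_rbh[(b, a)]}
        raise KeyError(f"missing RBH set for species pair ({a}, {b})")


def overlap_targets(ortho: OrthologySet) -> dict:
    """Three-way overlap report of target genes linked by RBH.

    Genes are first restricted to those with hit partners in both other
    species. Edges of the overlap graph connect target genes that are RBH
    partners and targets in both species. Reported: per-species target
    counts (post-filter), pairwise overlap counts, ortholog groups
    conserved in >= 2 species, and the all-three count under the
    triangle-closure and chain-linkage rules.
    """
    species = ortho.species()
    if len(species) != 3:
        raise ValueError("overlap_targets requires exactly three species")
    for a, b in itertools.combinations(species, 2):
        ortho.rbh(a, b)  # raises if a pair is missing

    def has_hits_everywhere(sp: str, gene: str) -> bool:
        # without hit tables the filter cannot be evaluated (an absent RBH
        # edge does not imply absent hits) and is skipped
        if not ortho.hit_partners:
            return True
        for other in species:
            if other == sp:
                continue
            if gene not in ortho.hit_partners.get((sp, other), set()):
                return False
        return True

    targets = {
        sp: {g for g in ortho.species_targets[sp] if has_hits_everywhere(sp, g)}
        for sp in species
    }

    g = nx.Graph()
    for sp in species:
        for gene in targets[sp]:
            g.add_node((sp, gene))
    pair_overlap: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(species, 2):
        n_pair = 0
        for ga, gb in ortho.rbh(a, b):
            if ga in targets[a] and gb in targets[b]:
                g.add_edge((a, ga), (b, gb))
                n_pair += 1
        pair_overlap[(a, b)] = n_pair

    groups_2plus = 0
    all3_chain = 0
    all3_triangle = 0
    for comp in nx.connected_components(g):
        sp_in = {sp for sp, _ in comp}
        if len(sp_in) < 2:
            continue
        groups_2plus += 1
        if len(sp_in) == 3:
            all3_chain += 1
            # triangle: some (a, b, c) with all three pairwise RBH edges
            nodes_by_sp = {sp: [gene for s, gene in comp if s == sp] for sp in species}
            found = False
            for ga in nodes_by_sp[species[0]]:
                for gb in nodes_by_sp[species[1]]:
                    for gc in nodes_by_sp[species[2]]:
                        if (
                            g.has_edge((species[0], ga), (species[1], gb))
                            and g.has_edge((species[0], ga), (species[2], gc))
                            and g.has_edge((species[1], gb), (species[2], gc))
                        ):
                            found = True
                            break
                    if found:
                        break
                if found:
                    break
            if found:
                all3_triangle += 1

    return {
        "species_target_counts": {sp: len(targets[sp]) for sp in species},
        "pair_overlap": {f"{a}-{b}": n for (a, b), n in pair_overlap.items()},
        "groups_conserved_in_2plus": groups_2plus,
        "shared_all3_triangle": all3_triangle,
        "shared_all3_chain": all3_chain,
    }
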