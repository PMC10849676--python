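"""Cross-lane peak joining, significance filtering, gene association,
enhancer intersection and PWM motif scanning.

Joined peaks follow the study's rule of merging summits across replicate
lanes within a maximum distance of 100 bp (single linkage on summit
position), and the significance filter keeps joined peaks whose mean
enrichment is at least 10 and mean overall score at least 80 (inclusive
thresholds). Gene association is deterministic nearest-TSS within a
distance cap; enhancer overlap means >= 1 bp intersection in 0-based
half-open coordinates (bedtools semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from bmptargets.peakcall import Peak

logger = logging.getLogger(__name__)

__all__ = [
    "JoinedPeak",
    "GeneModel",
    "AnnotatedTarget",
    "join_peaks",
    "filter_significant",
    "associate_genes",
    "intersect_enhancers",
    "scan_motif",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed",
    "write_bed",
    "read_jaspar_pfm",
    "targets_to_frame",
]


@dataclass
class JoinedPeak:
    """Cross-lane consensus peak (means over member peaks)."""

    chrom: str
    consensus_summit: int
    members: list[Peak]
    n_lanes: int
    mean_height: float
    mean_enrichment: float
    mean_score: float
    start: int
    end: int


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: tuple[int, int]  # 0-based half-open

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not (self.span[0] <= self.tss < self.span[1]):
            raise ValueError(f"gene {self.gene_id}: TSS outside span")


@dataclass
class AnnotatedTarget:
    joined_peak: JoinedPeak
    gene_id: str | None
    distance_to_tss: int | None  # signed; negative = upstream of TSS
    in_enhancer: bool = False
    has_motif: bool = False
    stage_label: str = ""


def join_peaks(
    peaks_by_lane: Mapping[str, Sequence[Peak]],
    join_dist: int = 100,
    min_lanes: int = 2,
) -> list[JoinedPeak]:
    """Single-linkage clustering of summits within ``join_dist`` per chromosome.

    Consecutive (sorted) summits with gap <= join_dist join one cluster;
    clusters supported by fewer than ``min_lanes`` distinct lanes are
    dropped (count logged).
    """
    if join_dist < 0:
        raise ValueError("join_dist must be >= 0")
    allp = [p for lane in sorted(peaks_by_lane) for p in peaks_by_lane[lane]]
    if not allp:
        return []
    allp.sort(key=lambda p: (p.chrom, p.summit))
    clusters: list[list[Peak]] = []
    for p in allp:
        if (
            clusters
            and clusters[-1][-1].chrom == p.chrom
            and p.summit - clusters[-1][-1].summit <= join_dist
        ):
            clusters[-1].append(p)
        else:
            clusters.append([p])
    joined: list[JoinedPeak] = []
    dropped = 0
    for members in clusters:
        lanes = {p.lane_id for p in members}
        if len(lanes) < min_lanes:
            dropped += 1
            continue
        joined.append(
            JoinedPeak(
                chrom=members[0].chrom,
                consensus_summit=int(np.floor(np.mean([p.summit for p in members]))),
                members=members,
                n_lanes=len(lanes),
                mean_height=float(np.mean([p.height for p in members])),
                mean_enrichment=float(np.mean([p.enrichment for p in members])),
                mean_score=float(np.mean([p.score for p in members])),
                start=min(p.start for p in members),
                end=max(p.end for p in members),
            )
        )
    if dropped:
        logger.info("join_peaks: dropped %d clusters below min_lanes=%d", dropped, min_lanes)
    return joined


def filter_significant(
    joined: Sequence[JoinedPeak],
    min_enrichment: float = 10.0,
    min_score: float = 80.0,
) -> list[JoinedPeak]:
    """Keep joined peaks with mean E >= min_enrichment AND mean S >= min_score."""
    if min_enrichment < 0 or min_score < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        jp for jp in joined if jp.mean_enrichment >= min_enrichment and jp.mean_score >= min_score
    ]


def _signed_distance(summit: int, gene: GeneModel) -> int:
    # negative = peak upstream of the TSS on the gene's strand
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def associate_genes(
    joined: Sequence[JoinedPeak],
    genes: Sequence[GeneModel],
    max_assoc_dist: int = 20_000,
    stage_label: str = "",
) -> list[AnnotatedTarget]:
    """Assign each joined peak to a gene: containment first, then nearest TSS.

    A peak whose summit lies inside a gene span is assigned to that gene
    (nearest TSS among several containing genes); otherwise the gene with
    the nearest TSS within ``max_assoc_dist`` wins. Ties break to the
    lexicographically smaller gene id.
    """
    if max_assoc_dist <= 0:
        raise ValueError("max_assoc_dist must be > 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[AnnotatedTarget] = []
    for jp in joined:
        cands = by_chrom.get(jp.chrom, [])
        s = jp.consensus_summit
        containing = [g for g in cands if g.span[0] <= s < g.span[1]]
        pool = containing if containing else [
            g for g in cands if abs(s - g.tss) <= max_assoc_dist
        ]
        if pool:
            best = min(pool, key=lambda g: (abs(s - g.tss), g.gene_id))
            out.append(
                AnnotatedTarget(
                    joined_peak=jp,
                    gene_id=best.gene_id,
                    distance_to_tss=_signed_distance(s, best),
                    stage_label=stage_label,
                )
            )
        else:
            out.append(
                AnnotatedTarget(
                    joined_peak=jp, gene_id=None, distance_to_tss=None, stage_label=stage_label
                )
            )
    return out


def intersect_enhancers(
    joined: Sequence[JoinedPeak],
    enhancers: pd.DataFrame | Sequence[tuple[str, int, int]],
) -> list[bool]:
    """True per joined peak iff its span overlaps any enhancer by >= 1 bp.

    Both sides are 0-based half-open, so abutting intervals do not overlap.
    """
    if isinstance(enhancers, pd.DataFrame):
        rows = list(zip(enhancers.iloc[:, 0], enhancers.iloc[:, 1], enhancers.iloc[:, 2]))
    else:
        rows = list(enhancers)
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in rows:
        if end <= start:
            continue
        trees.setdefault(str(chrom), IntervalTree()).addi(int(start), int(end))
    return [
        bool(trees[jp.chrom].overlap(jp.start, jp.end)) if jp.chrom in trees else False
        for jp in joined
    ]


# ---------------------------------------------------------------------------
# motif scanning

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class MotifHit:
    has_motif: bool
    position: int | None
    strand: str | None
    score: float


def scan_motif(
    sequence: str,
    pfm: np.ndarray,
    threshold: float,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> MotifHit:
    """Log-odds PWM scan of both strands; N bases score 0 bits.

    ``pfm`` is a 4 x L position frequency matrix (rows A, C, G, T) whose
    columns sum to a constant count. Scores are log2(p_base / background)
    summed over motif columns; the best site over both strands is reported,
    and ``has_motif`` is true iff that score >= threshold. Positions are
    0-based starts on the forward strand; + strand wins score ties.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError("PFM must be 4 x L (rows A, C, G, T)")
    colsum = pfm.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("PFM has a zero column sum")
    bg = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        logodds = np.log2((pfm / colsum) / bg[:, None])
    L = pfm.shape[1]
    seq = sequence.upper()
    if len(seq) < L:
        return MotifHit(False, None, None, float("-inf"))
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    idx = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))

    def strand_scores(mat: np.ndarray) -> np.ndarray:
        m5 = np.vstack([mat, np.zeros(L)])  # N row scores 0 bits
        n_pos = len(seq) - L + 1
        scores = np.zeros(n_pos)
        for j in range(L):
            scores += m5[idx[j : j + n_pos], j]
        return scores

    fwd = strand_scores(logodds)
    rev = strand_scores(logodds[::-1, ::-1])  # reverse-complement matrix
    best_f, best_r = int(np.argmax(fwd)), int(np.argmax(rev))
    if fwd[best_f] >= rev[best_r]:
        pos, strand, score = best_f, "+", float(fwd[best_f])
    else:
        pos, strand, score = best_r, "-", float(rev[best_r])
    return MotifHit(score >= threshold, pos, strand, score)


# ---------------------------------------------------------------------------
# plain-text I/O


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene without ID attribute")
            span = (int(start) - 1, int(end))
            tss = span[0] if strand == "+" else span[1] - 1
            genes.append(GeneModel(gene_id, chrom, strand, tss, span))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbmptargets\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """Read BED (>= 3 columns, 0-based half-open) with line-number errors."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED coordinates") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")


def read_jaspar_pfm(path) -> np.ndarray:
    """Read a JASPAR-style PFM: optional '>' header, then 4 rows A/C/G/T."""
    rows: dict[str, list[float]] = {}
    order = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            token = line.split()[0].rstrip(":")
            if token in "ACGT":
                nums = line.replace("[", " ").replace("]", " ").split()[1:]
                rows[token] = [float(x) for x in nums]
                order.append(token)
            else:
                nums = line.replace("[", " ").replace("]", " ").split()
                base = "ACGT"[len(order)]
                rows[base] = [float(x) for x in nums]
                order.append(base)
    if set(rows) != set("ACGT"):
        raise ValueError("PFM must provide rows for A, C, G, T")
    return np.array([rows[b] for b in "ACGT"])


def targets_to_frame(targets: Sequence[AnnotatedTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [t.joined_peak.chrom for t in targets],
            "summit": [t.joined_peak.consensus_summit for t in targets],
            "n_lanes": [t.joined_peak.n_lanes for t in targets],
            "mean_H": [t.joined_peak.mean_height for t in targets],
            "mean_E": [t.joined_peak.mean_enrichment for t in targets],
            "mean_S": [t.joined_peak.mean_score for t in targets],
            "gene_id": [t.gene_id for t in targets],
            "distance_to_tss": [t.distance_to_tss for t in targets],
            "in_enhancer": [t.in_enhancer for t in targets],
            "has_motif": [t.has_motif for t in targets],
            "stage": [t.stage_label for t in targets],
        }
    )
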