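"""ChIP-qPCR fold enrichment, condition comparison, and target classification.

Fold enrichment follows the input-normalized delta-delta-Ct convention
against an intergenic reference region ("IntA"):

    dCt_region = Ct_IP - Ct_input
    fold       = 2 ** -(dCt_target - dCt_reference)

Between-condition comparisons report the ratio of mean folds and a Welch
two-sample two-tailed t-test on the per-replicate folds (pooled-variance
t available by flag). Normality is assumed, not tested; a warning is
emitted below five replicates per group, mirroring small-n ChIP-qPCR
practice.

Differential-expression classification of ChIP targets consumes an
external DE results table (gene, log2 fold change, adjusted p): a target
is DE iff padj <= 0.05 (inclusive) and 2xDE iff additionally
|log2FC| >= 1. Functional-category composition is compared against a
seeded uniform random draw of background genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "fold_enrichment",
    "condition_ratio_and_test",
    "ConditionComparison",
    "classify_de_targets",
    "de_percent",
    "category_fractions",
    "read_ct_tsv",
    "read_de_tsv",
]

REFERENCE_REGION = "IntA"

_CT_COLS = ["region", "condition", "replicate", "ct_ip", "ct_input"]


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {missing}")
    return df


def read_de_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "log2fc", "padj") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DE table missing columns {missing}")
    return df


def fold_enrichment(
    ct: pd.DataFrame,
    region: str,
    condition: str,
    reference: str = REFERENCE_REGION,
) -> pd.Series:
    """Per-replicate fold enrichment of ``region`` vs the reference region.

    Replicates of target and reference are paired by replicate id within
    the condition; unpaired replicates raise an error.
    """
    sub = ct[ct["condition"] == condition]
    tgt = sub[sub["region"] == region].set_index("replicate")
    ref = sub[sub["region"] == reference].set_index("replicate")
    if tgt.empty:
        raise ValueError(f"no measurements for region {region!r} in condition {condition!r}")
    if set(tgt.index) != set(ref.index):
        raise ValueError(
            f"replicate mismatch between {region!r} and reference {reference!r} "
            f"in condition {condition!r}"
        )
    ref = ref.loc[tgt.index]
    d_tgt = tgt["ct_ip"] - tgt["ct_input"]
    d_ref = ref["ct_ip"] - ref["ct_input"]
    folds = np.power(2.0, -(d_tgt - d_ref))
    folds.name = f"{region}:{condition}"
    return folds


@dataclass
class ConditionComparison:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    ratio: float  # mean1 / mean2
    t_statistic: float
    p_two_tailed: float


def condition_ratio_and_test(
    folds_cond1,
    folds_cond2,
    welch: bool = True,
) -> ConditionComparison:
    """Means, SDs, ratio of means, and a two-tailed t-test between conditions.

    Welch (unequal-variance) by default; ``welch=False`` pools variances.
    Two identical zero-variance groups return t = 0, p = 1 by convention.
    """
    a = np.asarray(folds_cond1, dtype=float)
    b = np.asarray(folds_cond2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if len(a) < 5 or len(b) < 5:
        logger.warning(
            "t-test on small samples (n1=%d, n2=%d): normality assumed, not tested",
            len(a),
            len(b),
        )
    mean1, mean2 = float(a.mean()), float(b.mean())
    sd1 = float(a.std(ddof=1))
    sd2 = float(b.std(ddof=1))
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            logger.warning("zero variance in both groups with equal means; p = 1 by convention")
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, mean1 - mean2), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ConditionComparison(
        mean1=mean1,
        mean2=mean2,
        sd1=sd1,
        sd2=sd2,
        ratio=mean1 / mean2,
        t_statistic=t_stat,
        p_two_tailed=p,
    )


def classify_de_targets(
    targets,
    de: pd.DataFrame,
    padj_max: float = 0.05,
    min_fold: float = 2.0,
) -> pd.Series:
    """Label each target gene as not-DE, DE, or 2xDE.

    DE iff padj <= padj_max (inclusive); 2xDE iff additionally
    |log2fc| >= log2(min_fold). Genes absent from the DE table count as
    not-DE (logged).
    """
    if min_fold < 1.0:
        raise ValueError("min_fold must be >= 1")
    de_idx = de.set_index("gene_id")
    labels = {}
    n_missing = 0
    log2_min = math.log2(min_fold)
    for gene in targets:
        if gene not in de_idx.index:
            labels[gene] = "not-DE"
            n_missing += 1
            continue
        row = de_idx.loc[gene]
        padj = row["padj"]
        if pd.isna(padj) or padj > padj_max:
            labels[gene] = "not-DE"
        elif abs(row["log2fc"]) >= log2_min:
            labels[gene] = "2xDE"
        else:
            labels[gene] = "DE"
    if n_missing:
        logger.info("classify_de_targets: %d genes absent from DE table -> not-DE", n_missing)
    return pd.Series(labels, name="de_class")


def de_percent(labels: pd.Series) -> float:
    """Percentage of targets labelled DE or 2xDE."""
    if len(labels) == 0:
        raise ValueError("empty label series")
    return 100.0 * float((labels != "not-DE").mean())


def category_fractions(
    gene_list,
    categories: pd.DataFrame | dict,
    background_n: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Category fractions of a gene list vs a seeded random background draw.

    ``categories`` maps every genome gene to one functional category; the
    background is drawn uniformly without replacement from all genes in
    the table. Fractions sum to 1 for each set.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("empty gene list")
    if isinstance(categories, dict):
        cat = pd.Series(categories)
    else:
        cat = categories.set_index("gene_id")["category"]
    if background_n > len(cat):
        raise ValueError("background_n exceeds genome gene count")
    rng = np.random.default_rng(seed)
    background = rng.choice(cat.index.to_numpy(), size=background_n, replace=False)
    all_cats = sorted(cat.unique())

    def fracs(genes) -> pd.Series:
        counts = cat.reindex(genes).value_counts()
        return pd.Series({c: counts.get(c, 0) / len(genes) for c in all_cats})

    return pd.DataFrame({"targets": fracs(gene_list), "background": fracs(background)})
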