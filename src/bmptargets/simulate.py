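"""Seeded synthetic-data generator for every pipeline input.

Each generator plants a known ground truth — ChIP peak summits and
strengths over a toy genome, gene models near those summits, ortholog
triples across three toy proteomes, cosine-decay nuclear intensity
gradients, and qPCR Ct values implying chosen fold enrichments — so that
downstream modules can be tested for parameter recovery. All randomness
flows from one root seed through named per-generator substreams: adding
a generator never perturbs the output of another, and the same
(seed, config) reproduces byte-identical files.

The fragment model places fragment midpoints Normal(summit, sd) around
each planted summit and uniformly for background; no read-level sequence
or sequencing-error simulation is attempted, since alignment is upstream
of this pipeline. Intensities are in arbitrary units with no camera
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bmptargets.annotate import GeneModel
from bmptargets.peakcall import FragmentSet

__all__ = [
    "SynthConfig",
    "default_config",
    "chrom_sizes",
    "gen_chip_experiment",
    "gen_annotation",
    "gen_nuclei_tables",
    "gen_hit_tables",
    "gen_qpcr_plate",
    "write_all",
    "SPECIES",
]

SPECIES = ("Nve", "Dme", "Xla")

# fixed substream ids: adding a generator appends here without moving others
_STREAMS = {
    "chip": 1,
    "input": 2,
    "annotation": 3,
    "nuclei": 4,
    "hits": 5,
    "qpcr": 6,
    "de": 7,
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic experiment (one root seed)."""

    seed: int = 0
    genome_length: int = 2_000_000  # total bp over all chromosomes
    n_chromosomes: int = 2
    planted_peaks: list = field(default_factory=list)  # (chrom, summit, strength fpm)
    n_lanes: int = 3
    n_chip_fragments: int = 200_000
    n_input_fragments: int = 200_000
    fragment_length_mean: int = 200
    fragment_length_sd: int = 40
    n_genes: int = 100
    enhancer_fraction: float = 0.5
    gradient_amp: float = 10.0
    gradient_base: float = 1.0
    gradient_noise_sd: float = 0.5
    n_nuclei_per_embryo: int = 60
    n_embryos: int = 10
    planted_ortho_groups: list = field(default_factory=list)  # (nve, dme, xla) triples
    planted_species_targets: dict = field(default_factory=dict)  # species -> list of ids
    homeolog_fraction: float = 0.3
    planted_fold_enrichments: dict = field(default_factory=dict)  # region -> {condition: fold}
    ct_noise_sd: float = 0.05
    n_qpcr_replicates: int = 4

    def validate(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if self.n_chip_fragments <= 0 or self.n_input_fragments <= 0:
            raise ValueError("fragment counts must be positive")
        if self.fragment_length_mean <= 0 or self.fragment_length_sd <= 0:
            raise ValueError("fragment length parameters must be positive")
        sizes = chrom_sizes(self)
        for chrom, summit, strength in self.planted_peaks:
            if chrom not in sizes:
                raise ValueError(f"planted peak on unknown chromosome {chrom!r}")
            if not (0 <= summit < sizes[chrom]):
                raise ValueError(f"planted summit {summit} outside {chrom}")
            if strength <= 0:
                raise ValueError("planted peak strengths must be > 0")
        if self.gradient_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for sp_idx in range(3):
            ids = [g[sp_idx] for g in self.planted_ortho_groups]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate gene id within species {SPECIES[sp_idx]}")
        for region, by_cond in self.planted_fold_enrichments.items():
            for cond, fold in by_cond.items():
                if fold <= 0:
                    raise ValueError(f"planted fold for {region}/{cond} must be > 0")


def chrom_sizes(config: SynthConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    sizes = {f"chr{i + 1}": base for i in range(config.n_chromosomes)}
    sizes[f"chr{config.n_chromosomes}"] += config.genome_length - base * config.n_chromosomes
    return sizes


def default_config(seed: int = 0) -> SynthConfig:
    """The default synthetic study: 20 summits over a 2 Mb toy genome,
    triplicate lanes, ten ortholog triples with partially shared targets,
    and the study's printed qPCR folds as planted truth."""
    cfg = SynthConfig(seed=seed)
    sizes = chrom_sizes(cfg)
    peaks = []
    per_chrom = 10
    for chrom, size in sizes.items():
        for pos in np.linspace(60_000, size - 60_000, per_chrom):
            peaks.append((chrom, int(pos), 2000.0))
    cfg.planted_peaks = peaks
    cfg.planted_ortho_groups = [
        (f"NVE_g{i}", f"Dme_g{i}", f"Xla_g{i}") for i in range(1, 11)
    ]
    # targets per species: all three species share groups 1-4; groups 5-6
    # are targets in Nve+Dme only; 7-8 in Nve only
    cfg.planted_species_targets = {
        "Nve": [f"NVE_g{i}" for i in range(1, 9)],
        "Dme": [f"Dme_g{i}" for i in range(1, 7)],
        "Xla": [f"Xla_g{i}" for i in range(1, 5)],
    }
    cfg.planted_fold_enrichments = {
        "chordin": {"transgenic": 1.82, "wildtype": 0.15},
        "gremlin": {"transgenic": 0.27, "wildtype": 0.35},
    }
    return cfg


def _rng(config: SynthConfig, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream], extra))
    )


# ---------------------------------------------------------------------------
# ChIP fragments


def _fragments_from_midpoints(
    rng: np.random.Generator,
    chroms: np.ndarray,
    mids: np.ndarray,
    config: SynthConfig,
    sizes: dict[str, int],
) -> pd.DataFrame:
    lengths = np.clip(
        np.round(rng.normal(config.fragment_length_mean, config.fragment_length_sd, len(mids))),
        50,
        None,
    ).astype(np.int64)
    starts = mids - lengths // 2
    ends = starts + lengths
    size_arr = np.array([sizes[c] for c in chroms])
    starts = np.clip(starts, 0, None)
    ends = np.minimum(ends, size_arr)
    starts = np.minimum(starts, ends - 1)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def gen_chip_experiment(
    config: SynthConfig,
) -> tuple[list[FragmentSet], list[FragmentSet], pd.DataFrame]:
    """Per-lane ChIP and input fragment sets plus the planted-summit truth.

    Fragment midpoints around each planted summit are Normal(summit,
    fragment_length_sd); background midpoints are uniform over the
    genome. Every lane contains exactly the configured fragment count.
    """
    config.validate()
    sizes = chrom_sizes(config)
    chrom_names = sorted(sizes)
    offsets = np.cumsum([0] + [sizes[c] for c in chrom_names])

    def uniform_fragments(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        flat = rng.integers(0, config.genome_length, n)
        idx = np.searchsorted(offsets, flat, side="right") - 1
        return np.array(chrom_names, dtype=object)[idx], flat - offsets[idx]

    n_per_peak = [
        int(round(strength * config.n_chip_fragments / 1e6))
        for _, _, strength in config.planted_peaks
    ]
    n_signal = sum(n_per_peak)
    if n_signal > config.n_chip_fragments:
        raise ValueError("planted strengths exceed the ChIP library size")

    chip_lanes, input_lanes = [], []
    for lane in range(config.n_lanes):
        rng = _rng(config, "chip", lane)
        chroms_list, mids_list = [], []
        for (chrom, summit, _), n_pk in zip(config.planted_peaks, n_per_peak):
            m = np.round(rng.normal(summit, config.fragment_length_sd, n_pk)).astype(np.int64)
            m = np.clip(m, 0, sizes[chrom] - 1)
            chroms_list.append(np.full(n_pk, chrom, dtype=object))
            mids_list.append(m)
        bg_chrom, bg_mid = uniform_fragments(rng, config.n_chip_fragments - n_signal)
        chroms = np.concatenate(chroms_list + [bg_chrom]) if chroms_list else bg_chrom
        mids = np.concatenate(mids_list + [bg_mid]) if mids_list else bg_mid
        chip_lanes.append(
            FragmentSet(
                f"chip_lane{lane + 1}",
                _fragments_from_midpoints(rng, chroms, mids, config, sizes),
            )
        )
        rng_in = _rng(config, "input", lane)
        in_chrom, in_mid = uniform_fragments(rng_in, config.n_input_fragments)
        input_lanes.append(
            FragmentSet(
                f"input_lane{lane + 1}",
                _fragments_from_midpoints(rng_in, in_chrom, in_mid, config, sizes),
            )
        )
    truth = pd.DataFrame(
        {
            "chrom": [p[0] for p in config.planted_peaks],
            "summit": [p[1] for p in config.planted_peaks],
            "strength_fpm": [p[2] for p in config.planted_peaks],
            "n_fragments_per_lane": n_per_peak,
        }
    )
    return chip_lanes, input_lanes, truth


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(
    config: SynthConfig,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Gene models near each planted summit, decoy genes, and enhancers.

    For every planted peak a gene is placed with its TSS 1-5 kb from the
    summit and its body pointing away, so nearest-TSS association has an
    unambiguous planted answer (returned as the truth table). A
    configurable fraction of planted summits receives a covering
    enhancer. Gene spans never overlap; failure to place the requested
    density raises.
    """
    config.validate()
    sizes = chrom_sizes(config)
    rng = _rng(config, "annotation")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}

    def free(chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > sizes[chrom]:
            return False
        return all(end <= s or start >= e for s, e in occupied[chrom])

    genes: list[GeneModel] = []
    truth_rows = []
    n_peak_genes = min(len(config.planted_peaks), config.n_genes)
    for i, (chrom, summit, _) in enumerate(config.planted_peaks[:n_peak_genes]):
        placed = False
        for _attempt in range(100):
            offset = int(rng.integers(1000, 5001))
            length = int(rng.integers(2000, 8001))
            right = bool(rng.integers(0, 2))
            if right:
                tss = summit + offset
                span = (tss, tss + length)
                strand = "+"
            else:
                tss = summit - offset
                span = (tss - length + 1, tss + 1)
                strand = "-"
            if free(chrom, *span):
                gid = f"NVE_t{i + 1}"
                genes.append(GeneModel(gid, chrom, strand, tss, span))
                occupied[chrom].append(span)
                truth_rows.append((chrom, summit, gid, abs(summit - tss)))
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place a gene near planted summit {chrom}:{summit}")

    n_decoy = max(config.n_genes - len(genes), 0)
    for j in range(n_decoy):
        placed = False
        for _attempt in range(500):
            chrom = sorted(sizes)[int(rng.integers(0, len(sizes)))]
            length = int(rng.integers(2000, 8001))
            start = int(rng.integers(0, sizes[chrom] - length))
            span = (start, start + length)
            if free(chrom, *span):
                strand = "+" if rng.integers(0, 2) else "-"
                tss = span[0] if strand == "+" else span[1] - 1
                genes.append(GeneModel(f"NVE_d{j + 1}", chrom, strand, tss, span))
                occupied[chrom].append(span)
                placed = True
                break
        if not placed:
            raise ValueError("could not place genes without overlap at requested density")

    n_peaks = len(config.planted_peaks)
    n_enh = int(math.ceil(config.enhancer_fraction * n_peaks))
    chosen = rng.permutation(n_peaks)[:n_enh] if n_peaks else np.array([], dtype=int)
    enh_rows = [
        (config.planted_peaks[i][0], config.planted_peaks[i][1] - 250,
         config.planted_peaks[i][1] + 250)
        for i in sorted(chosen)
    ]
    for j in range(10):  # decoy enhancers away from peaks
        chrom = sorted(sizes)[int(rng.integers(0, len(sizes)))]
        start = int(rng.integers(0, sizes[chrom] - 500))
        enh_rows.append((chrom, start, start + 500))
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    truth = pd.DataFrame(truth_rows, columns=["chrom", "summit", "gene_id", "tss_distance"])
    return genes, enhancers, truth


# ---------------------------------------------------------------------------
# nuclei


def gen_nuclei_tables(config: SynthConfig, shape: str = "control") -> pd.DataFrame:
    """Per-embryo nucleus tables with a planted cosine-decay arc gradient.

    intensity(theta) = base + amp * (1 + cos theta) / 2 + N(0, noise_sd)
    with theta assigned implicitly by record order (seq_index / N * pi).
    ``flattened`` divides the amplitude by 4; ``expanded`` widens the
    high plateau using a cos(theta / 2) profile at full amplitude.
    """
    config.validate()
    if config.n_nuclei_per_embryo < 3:
        raise ValueError("need at least 3 nuclei per embryo")
    if shape not in {"control", "flattened", "expanded"}:
        raise ValueError(f"unknown gradient shape {shape!r}")
    rng = _rng(config, "nuclei", {"control": 0, "flattened": 1, "expanded": 2}[shape])
    rows = []
    n = config.n_nuclei_per_embryo
    for e in range(1, config.n_embryos + 1):
        i = np.arange(1, n + 1)
        theta = i / n * np.pi
        if shape == "flattened":
            signal = (config.gradient_amp / 4.0) * (1 + np.cos(theta)) / 2.0
        elif shape == "expanded":
            signal = config.gradient_amp * (1 + np.cos(theta / 2.0)) / 2.0
        else:
            signal = config.gradient_amp * (1 + np.cos(theta)) / 2.0
        intensity = config.gradient_base + signal + rng.normal(0, config.gradient_noise_sd, n)
        for idx, val in zip(i, intensity):
            rows.append((f"embryo{e}", "endoderm", int(idx), float(val)))
    return pd.DataFrame(rows, columns=["embryo_id", "layer", "seq_index", "raw_intensity"])


# ---------------------------------------------------------------------------
# orthology hit tables


def gen_hit_tables(config: SynthConfig) -> dict[tuple[str, str], pd.DataFrame]:
    """Directed hit tables for all six species-pair directions.

    Planted triples are mutual best hits (bit score 500, e-value 1e-50).
    Each planted gene also receives two adversarial decoys per direction:
    one with a *better* e-value but lower bit score (RBH must pick by bit
    score) and one with a higher bit score but e-value above the 1e-5
    ceiling (must be filtered out). A leading fraction of frog genes is
    emitted as homeolog .S/.L duplicates of the same root.
    """
    config.validate()
    rng = _rng(config, "hits")
    groups = config.planted_ortho_groups
    n_homeo = int(round(config.homeolog_fraction * len(groups)))
    homeo_roots = {g[2] for g in groups[:n_homeo]}  # Xla ids split into .S/.L

    tables: dict[tuple[str, str], list[tuple]] = {}
    for ai, bi in [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]:
        a_sp, b_sp = SPECIES[ai], SPECIES[bi]
        rows: list[tuple] = []
        for gi, group in enumerate(groups):
            q, s = group[ai], group[bi]
            rows.append((q, s, 1e-50, 500.0 + gi))  # planted mutual best
            others = [g[bi] for gj, g in enumerate(groups) if gj != gi]
            if others:
                decoy = others[int(rng.integers(0, len(others)))]
                rows.append((q, decoy, 1e-80, float(rng.uniform(100, 300))))
                decoy2 = others[int(rng.integers(0, len(others)))]
                rows.append((q, decoy2, 1e-4, float(rng.uniform(600, 900))))
        tables[(a_sp, b_sp)] = rows

    out: dict[tuple[str, str], pd.DataFrame] = {}
    for pair, rows in tables.items():
        expanded: list[tuple] = []
        for q, s, ev, bs in rows:
            qs = [f"{q}.S", f"{q}.L"] if q in homeo_roots else [q]
            ss = [f"{s}.S", f"{s}.L"] if s in homeo_roots else [s]
            for i, qq in enumerate(qs):
                for j, sssub in enumerate(ss):
                    expanded.append((qq, sssub, ev, bs - 5.0 * (i + j)))
        out[pair] = pd.DataFrame(expanded, columns=["query", "subject", "evalue", "bitscore"])
    return out


# ---------------------------------------------------------------------------
# qPCR


def gen_qpcr_plate(config: SynthConfig) -> pd.DataFrame:
    """Ct table whose delta-delta-Ct folds equal the planted enrichments.

    The reference region (IntA) has a fixed IP-minus-input delta-Ct of 4
    cycles; each target region's IP Ct is set so that 2^-ddCt equals the
    planted fold, then Normal(0, ct_noise_sd) is added to every Ct.
    """
    config.validate()
    if config.n_qpcr_replicates < 2:
        raise ValueError("need >= 2 qPCR replicates")
    if not config.planted_fold_enrichments:
        raise ValueError("no planted fold enrichments configured")
    rng = _rng(config, "qpcr")
    d_ref = 4.0
    rows = []
    conditions = sorted({c for by in config.planted_fold_enrichments.values() for c in by})
    for cond in conditions:
        for rep in range(1, config.n_qpcr_replicates + 1):
            rows.append(("IntA", cond, rep, 20.0 + d_ref, 20.0))
            for region in sorted(config.planted_fold_enrichments):
                by_cond = config.planted_fold_enrichments[region]
                if cond not in by_cond:
                    continue
                d_tgt = d_ref - math.log2(by_cond[cond])
                rows.append((region, cond, rep, 20.0 + d_tgt, 20.0))
    df = pd.DataFrame(rows, columns=["region", "condition", "replicate", "ct_ip", "ct_input"])
    df["ct_ip"] = df["ct_ip"] + rng.normal(0, config.ct_noise_sd, len(df))
    df["ct_input"] = df["ct_input"] + rng.normal(0, config.ct_noise_sd, len(df))
    return df


def gen_de_table(
    config: SynthConfig,
    gene_ids,
    frac_de: float = 0.6,
    frac_strong: float = 0.5,
) -> pd.DataFrame:
    """Toy differential-expression results for the given genes.

    A ``frac_de`` fraction receives padj <= 0.05; of those, ``frac_strong``
    receive |log2FC| >= 1 (at least twofold). Emulates the consumed
    DESeq2-style output table, not its statistics.
    """
    rng = _rng(config, "de")
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    de_mask = rng.random(n) < frac_de
    strong_mask = de_mask & (rng.random(n) < frac_strong)
    padj = np.where(de_mask, rng.uniform(1e-6, 0.05, n), rng.uniform(0.06, 1.0, n))
    magnitude = np.where(strong_mask, rng.uniform(1.0, 4.0, n), rng.uniform(0.05, 0.95, n))
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    return pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": sign * magnitude, "padj": padj}
    )


# ---------------------------------------------------------------------------
# file emission


def write_all(config: SynthConfig, outdir) -> dict[str, list[str] | str]:
    """Materialise every synthetic input as plain-text files under outdir."""
    from bmptargets.annotate import write_gff3_genes
    from bmptargets.peakcall import write_bedpe

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str] | str] = {}

    chip, ctrl, truth = gen_chip_experiment(config)
    chip_files, input_files = [], []
    for fs in chip:
        p = outdir / f"{fs.lane_id}.bedpe"
        write_bedpe(fs, p)
        chip_files.append(str(p))
    for fs in ctrl:
        p = outdir / f"{fs.lane_id}.bedpe"
        write_bedpe(fs, p)
        input_files.append(str(p))
    truth.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
    manifest["chip"] = chip_files
    manifest["input"] = input_files
    manifest["truth_peaks"] = str(outdir / "truth_peaks.tsv")

    genes, enhancers, gene_truth = gen_annotation(config)
    write_gff3_genes(genes, outdir / "genes.gff3")
    enhancers.to_csv(outdir / "enhancers.bed", sep="\t", header=False, index=False)
    gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    manifest["genes"] = str(outdir / "genes.gff3")
    manifest["enhancers"] = str(outdir / "enhancers.bed")

    for shape in ("control", "flattened"):
        df = gen_nuclei_tables(config, shape)
        df.to_csv(outdir / f"nuclei_{shape}.tsv", sep="\t", index=False)
        manifest[f"nuclei_{shape}"] = str(outdir / f"nuclei_{shape}.tsv")

    for (a, b), df in gen_hit_tables(config).items():
        p = outdir / f"hits_{a}_{b}.tsv"
        df.to_csv(p, sep="\t", index=False)
        manifest[f"hits_{a}_{b}"] = str(p)

    gen_qpcr_plate(config).to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    manifest["qpcr"] = str(outdir / "qpcr_ct.tsv")
    return manifest
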