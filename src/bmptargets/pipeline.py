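"""End-to-end orchestration: simulate -> call -> join -> filter -> annotate ->
overlap/classify -> report.

A :class:`RunConfig` holds one shared synthetic study configuration, the
per-stage subsets of planted peaks (emulating ChIP at two developmental
stages on one genome), and every pipeline threshold. ``run_pipeline``
executes the stages in fixed order, writes every intermediate with a
manifest of parameters and SHA-256 checksums, and returns a report with
per-stage peak/gene counts, the stage-overlap comparison,
enhancer-overlap counts, DE classification counts, orthology overlap
counts, and the gradient-profile summary. Reruns with the same config
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from bmptargets import annotate as ann
from bmptargets import gradient as grad
from bmptargets import orthology as ortho
from bmptargets import peakcall as pc
from bmptargets import qpcr as qp
from bmptargets import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compare_stages", "default_run_config"]


@dataclass
class RunConfig:
    synth: sim.SynthConfig
    stage_peak_indices: dict  # stage label -> list of indices into planted_peaks
    outdir: str = "pipeline_out"
    window: int = 300
    step: int = 75
    pseudocount: float = 0.5
    poisson_p: float = 1e-3
    join_dist: int = 100
    min_lanes: int = 2
    min_enrichment: float = 10.0
    min_score: float = 80.0
    max_assoc_dist: int = 20_000
    evalue_max: float = 1e-5
    padj_max: float = 0.05
    min_fold: float = 2.0
    quantile_q: float = 0.75
    loess_span: float = 0.75
    loess_level: float = 0.99
    bin_pct: float = 0.5
    trim_pct: float = 5.0

    def validate(self) -> None:
        self.synth.validate()
        n = len(self.synth.planted_peaks)
        for stage, idx in self.stage_peak_indices.items():
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"stage {stage!r}: peak index out of range")
        if not (0 < self.quantile_q < 1):
            raise ValueError("quantile_q must be in (0, 1)")
        if self.join_dist < 0 or self.max_assoc_dist <= 0:
            raise ValueError("invalid distance thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        synth = sim.SynthConfig(**raw.pop("synth", {}))
        if not synth.planted_peaks:
            synth = sim.default_config(synth.seed)
        raw.setdefault(
            "stage_peak_indices",
            {"LG": list(range(12)), "4dP": list(range(8, len(synth.planted_peaks)))},
        )
        return cls(synth=synth, **raw)

    def defaults_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            if f.name in {"synth", "stage_peak_indices", "outdir"}:
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines)


def default_run_config(seed: int = 0, outdir: str = "pipeline_out") -> RunConfig:
    """Two-stage run over the default synthetic study: the stages share
    four planted peaks (indices 8-11 of 20) so the report exhibits the
    little-overlap shape of two developmental stages."""
    synth = sim.default_config(seed)
    return RunConfig(
        synth=synth,
        stage_peak_indices={"LG": list(range(0, 12)), "4dP": list(range(8, 20))},
        outdir=outdir,
    )


def compare_stages(targets_stage1, targets_stage2, labels=("stage1", "stage2")):
    """Set sizes, intersection, and per-gene stage labels."""
    s1, s2 = set(targets_stage1), set(targets_stage2)
    shared = s1 & s2
    gene_labels = {}
    for g in sorted(s1 | s2):
        if g in shared:
            gene_labels[g] = "both"
        elif g in s1:
            gene_labels[g] = f"{labels[0]}-only"
        else:
            gene_labels[g] = f"{labels[1]}-only"
    return len(s1), len(s2), len(shared), gene_labels


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the report (also written to report.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df_or_text, name: str) -> Path:
        p = outdir / name
        if hasattr(df_or_text, "to_csv"):
            df_or_text.to_csv(p, sep="\t", index=False)
        else:
            p.write_text(df_or_text)
        written.append(p)
        return p

    base = config.synth
    sizes = sim.chrom_sizes(base)
    params = pc.PeakCallParams(
        window=config.window,
        step=config.step,
        pseudocount=config.pseudocount,
        poisson_p=config.poisson_p,
        chrom_sizes=sizes,
    )

    # shared annotation over the full planted-peak set
    genes, enhancers, gene_truth = sim.gen_annotation(base)
    ann.write_gff3_genes(genes, outdir / "genes.gff3")
    written.append(outdir / "genes.gff3")
    emit(enhancers, "enhancers.bed")
    truth_by_summit = dict(zip(gene_truth["summit"], gene_truth["gene_id"]))

    report: dict = {"stages": {}, "parameters": config.defaults_text()}
    stage_targets: dict[str, set] = {}
    for stage, idx in config.stage_peak_indices.items():
        try:
            stage_cfg = dataclasses.replace(
                base,
                planted_peaks=[base.planted_peaks[i] for i in idx],
                seed=base.seed + 1 + sorted(config.stage_peak_indices).index(stage),
            )
            chip, ctrl, truth = sim.gen_chip_experiment(stage_cfg)
            emit(truth, f"{stage}_truth_peaks.tsv")
            peaks_by_lane = {}
            for fs_chip, fs_ctrl in zip(chip, ctrl):
                peaks = pc.call_peaks(fs_chip, fs_ctrl, params)
                peaks_by_lane[fs_chip.lane_id] = peaks
            normed = pc.quantile_normalize_heights(peaks_by_lane)
            for lane, peaks in normed.items():
                emit(pc.peaks_to_frame(peaks), f"{stage}_{lane}_peaks.tsv")
            joined = ann.join_peaks(normed, config.join_dist, config.min_lanes)
            significant = ann.filter_significant(
                joined, config.min_enrichment, config.min_score
            )
            targets = ann.associate_genes(
                significant, genes, config.max_assoc_dist, stage_label=stage
            )
            in_enh = ann.intersect_enhancers(significant, enhancers)
            for t, flag in zip(targets, in_enh):
                t.in_enhancer = flag
            emit(ann.targets_to_frame(targets), f"{stage}_targets.tsv")
            assigned = {t.gene_id for t in targets if t.gene_id is not None}
            stage_targets[stage] = assigned
            report["stages"][stage] = {
                "n_peaks_per_lane": {ln: len(pk) for ln, pk in normed.items()},
                "n_joined": len(joined),
                "n_significant": len(significant),
                "n_target_genes": len(assigned),
                "n_enhancer_overlap": int(sum(in_enh)),
                "n_unassigned": sum(1 for t in targets if t.gene_id is None),
                "n_motif": None,  # motif flagging needs a user-supplied FASTA + PFM
            }
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stages = list(config.stage_peak_indices)
    if len(stages) >= 2:
        n1, n2, n_shared, gene_labels = compare_stages(
            stage_targets[stages[0]], stage_targets[stages[1]], labels=tuple(stages[:2])
        )
        report["stage_overlap"] = {
            "stage_names": stages[:2],
            "n": [n1, n2],
            "n_shared": n_shared,
        }
        emit(
            "\n".join(f"{g}\t{lab}" for g, lab in gene_labels.items()) + "\n",
            "stage_gene_labels.tsv",
        )

    # DE classification over the union of stage targets
    all_targets = sorted(set().union(*stage_targets.values())) if stage_targets else []
    if all_targets:
        de = sim.gen_de_table(base, all_targets)
        emit(de, "de_table.tsv")
        labels = qp.classify_de_targets(all_targets, de, config.padj_max, config.min_fold)
        report["de_classification"] = labels.value_counts().to_dict()

    # orthology
    if base.planted_ortho_groups:
        hits = sim.gen_hit_tables(base)
        collapsed = {pair: ortho.collapse_homeologs(df) for pair, df in hits.items()}
        pair_rbh = {}
        hit_partners = {}
        for a, b in itertools.combinations(sim.SPECIES, 2):
            pair_rbh[(a, b)] = ortho.compute_rbh(
                collapsed[(a, b)], collapsed[(b, a)], config.evalue_max
            )
        for pair, df in collapsed.items():
            kept = df[df["evalue"] <= config.evalue_max]
            hit_partners[pair] = set(kept["query"])
        oset = ortho.OrthologySet(
            pair_rbh=pair_rbh,
            species_targets={
                sp: set(base.planted_species_targets.get(sp, [])) for sp in sim.SPECIES
            },
            hit_partners=hit_partners,
        )
        report["orthology"] = ortho.overlap_targets(oset)

    # gradient profiles: control vs flattened morphant
    ctrl_nuc = sim.gen_nuclei_tables(base, "control")
    flat_nuc = sim.gen_nuclei_tables(base, "flattened")
    emit(ctrl_nuc, "nuclei_control.tsv")
    emit(flat_nuc, "nuclei_flattened.tsv")
    ctrl_nuc = grad.assign_arc_positions(ctrl_nuc)
    flat_nuc = grad.assign_arc_positions(flat_nuc)
    import pandas as pd

    pool = pd.concat([ctrl_nuc, flat_nuc], ignore_index=True)
    divisor = float(np.quantile(pool["raw_intensity"], config.quantile_q))
    grid = np.linspace(float(pool["theta"].min()), np.pi, 100)
    profs = {}
    for name, df in (("control", ctrl_nuc), ("flattened", flat_nuc)):
        prof = grad.loess_profile(
            df["theta"].to_numpy(),
            df["raw_intensity"].to_numpy() / divisor,
            span=config.loess_span,
            level=config.loess_level,
            grid=grid,
        )
        profs[name] = prof
        emit(
            pd.DataFrame(
                {
                    "theta": prof.grid,
                    "fit": prof.fit,
                    "ci_low": prof.ci_low,
                    "ci_high": prof.ci_high,
                }
            ),
            f"gradient_{name}.tsv",
        )
    at = lambda prof, frac: float(prof.fit[np.argmin(np.abs(prof.grid - frac * np.pi))])  # noqa: E731
    report["gradient"] = {
        "control_fit_at_0.1pi": at(profs["control"], 0.1),
        "control_fit_at_0.9pi": at(profs["control"], 0.9),
        "flattened_fit_at_0.1pi": at(profs["flattened"], 0.1),
        "normalization_divisor": divisor,
    }

    # qPCR enrichment
    if base.planted_fold_enrichments:
        plate = sim.gen_qpcr_plate(base)
        emit(plate, "qpcr_ct.tsv")
        conditions = sorted(plate["condition"].unique())
        qrep = {}
        for region in sorted(base.planted_fold_enrichments):
            folds = {
                c: qp.fold_enrichment(plate, region, c)
                for c in conditions
                if c in base.planted_fold_enrichments[region]
            }
            entry = {c: {"mean": float(f.mean()), "sd": float(f.std(ddof=1))} for c, f in folds.items()}
            if len(folds) == 2:
                c1, c2 = sorted(folds)
                cmpres = qp.condition_ratio_and_test(folds[c1], folds[c2])
                entry["ratio"] = {
                    "numerator": c1,
                    "denominator": c2,
                    "ratio": cmpres.ratio,
                    "t": cmpres.t_statistic,
                    "p_two_tailed": cmpres.p_two_tailed,
                }
            qrep[region] = entry
        report["qpcr"] = qrep

    # manifest with checksums; deterministic ordering
    manifest = {
        "parameters": config.defaults_text(),
        "seed": base.seed,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    report["manifest"] = manifest
    return report
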