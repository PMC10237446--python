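"""One-command orchestration of the full analysis sequence.

For each population in the input PED/MAP (populations = PED family IDs) the
pipeline runs QC, diversity, PCA, LD decay, haplotype blocks, ROH, the four
inbreeding estimators and the LD-based Ne trajectory; for each population
pair it computes phase persistence on the intersection of post-QC markers.
Every stage writes a TSV so stages can be rerun and inspected in isolation;
a manifest records the configuration and seed (no timestamps, so reruns are
byte-identical).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocks import BlockConfig, block_summary, find_blocks
from .genotype_io import (
    GenotypeMatrix,
    HaplotypeMatrix,
    read_ped_map,
    read_phased,
)
from .ld import distance_bins_bp, ld_decay
from .ne import ne_bin_edges_bp, ne_trajectory
from .phase import default_phase_bins_bp, phase_persistence, signed_r_table
from .qc import QCConfig, heterozygosity, pca, run_qc
from .roh import (
    ROHParams,
    detect_roh,
    f_roh,
    f_roh_per_chromosome,
    grm_inbreeding,
    min_roh_snps,
    roh_length_classes,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "summarize"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and population."""


@dataclass
class PipelineConfig:
    ped_path: str = ""
    map_path: str = ""
    out_dir: str = "snppop_out"
    #: optional phased haplotype table per population label
    phased_paths: dict[str, str] = field(default_factory=dict)
    qc: QCConfig = field(default_factory=QCConfig)
    ld_max_pair_distance_bp: float = 20e6
    block: BlockConfig = field(default_factory=BlockConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    roh_alpha: float = 0.05
    roh_min_segment_mb: float = 1.0
    ne_alpha: float = 1.0
    mb_per_cm: float = 1.0
    phase_bin_width_kb: float = 10.0
    phase_max_distance_kb: float = 100.0
    pca_components: int = 10
    seed: int = 0
    log_level: str = "INFO"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for every population; returns the report bundle.

    The bundle maps ``(population, stage)`` to the DataFrame written to the
    stage's TSV.  On failure a ``FAILED`` marker naming the stage is written
    and :class:`PipelineError` is raised; earlier outputs are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    g_all = read_ped_map(cfg.ped_path, cfg.map_path)
    pops = list(dict.fromkeys(g_all.populations))
    bundle: dict = {}
    stage = "setup"
    pop = ""
    try:
        post_qc: dict[str, GenotypeMatrix] = {}
        phased: dict[str, HaplotypeMatrix] = {}
        for pop in pops:
            mask = np.array([p == pop for p in g_all.populations])
            g_pop = g_all.subset(sample_mask=mask)

            stage = "qc"
            g_clean, report = run_qc(g_pop, cfg.qc)
            post_qc[pop] = g_clean
            rep = report.to_frame()
            _write(rep, out / f"{pop}.qc_report.tsv")
            bundle[(pop, "qc")] = rep
            if g_clean.n_markers == 0 or g_clean.n_samples == 0:
                raise PipelineError(f"stage qc [{pop}]: QC removed everything")

            if pop in cfg.phased_paths:
                phased[pop] = read_phased(cfg.phased_paths[pop], g_clean)
            source = phased.get(pop, g_clean)

            stage = "diversity"
            div = heterozygosity(g_clean)
            summary = pd.DataFrame(
                [
                    ("mean_ho", div.mean_ho), ("sd_ho", div.sd_ho),
                    ("mean_he", div.mean_he), ("sd_he", div.sd_he),
                    ("mean_maf", div.mean_maf),
                    ("mean_spacing_kb", div.mean_spacing_kb),
                ],
                columns=["statistic", "value"],
            )
            _write(summary, out / f"{pop}.diversity.tsv")
            _write(div.spacing_kb_by_chromosome, out / f"{pop}.spacing.tsv")
            bundle[(pop, "diversity")] = summary

            stage = "pca"
            res = pca(g_clean, cfg.pca_components)
            coords = res.to_frame()
            _write(coords, out / f"{pop}.pca.tsv")
            _write(
                pd.DataFrame(
                    {
                        "axis": [f"PC{i+1}" for i in range(len(res.explained_variance_ratio))],
                        "variance_fraction": res.explained_variance_ratio,
                    }
                ),
                out / f"{pop}.pca_variance.tsv",
            )
            bundle[(pop, "pca")] = coords

            stage = "ld"
            decay = ld_decay(source, max_pair_distance=cfg.ld_max_pair_distance_bp)
            tbl = decay.pooled.copy()
            _write(tbl, out / f"{pop}.ld_decay.tsv")
            _write(decay.per_chromosome, out / f"{pop}.ld_decay_by_chrom.tsv")
            _write(
                pd.DataFrame(
                    [
                        ("adjacent_mean_r2", decay.adjacent_mean_r2),
                        ("adjacent_mean_r2_within_10kb", decay.adjacent_mean_r2_within_10kb),
                        ("frac_pairs_10kb_r2_above_030", decay.frac_pairs_10kb_r2_above_030),
                        ("distance_bp_at_r2_02", decay.distance_at_threshold(0.2)),
                    ],
                    columns=["statistic", "value"],
                ),
                out / f"{pop}.ld_headline.tsv",
            )
            bundle[(pop, "ld")] = tbl
            bundle[(pop, "ld_summary")] = decay

            stage = "blocks"
            blks = find_blocks(source, cfg.block)
            blk_df = pd.DataFrame(
                [
                    (b.chromosome, b.start_bp, b.end_bp, b.n_snps, b.length_kb)
                    for b in blks
                ],
                columns=["chromosome", "start_bp", "end_bp", "n_snps", "length_kb"],
            )
            _write(blk_df, out / f"{pop}.blocks.tsv")
            bsum = block_summary(blks, g_clean).to_frame()
            _write(bsum, out / f"{pop}.block_summary.tsv")
            bundle[(pop, "blocks")] = blk_df
            bundle[(pop, "block_summary")] = bsum

            stage = "roh"
            params = cfg.roh
            if params.min_snp_count == 0:
                params = dataclasses.replace(
                    params,
                    min_snp_count=min_roh_snps(
                        g_clean.n_markers,
                        g_clean.n_samples,
                        cfg.roh_alpha,
                        float(np.nanmean(div.ho)),
                    ),
                )
            segs = detect_roh(g_clean, params)
            seg_df = pd.DataFrame(
                [
                    (s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_snps, s.length_kb)
                    for s in segs
                ],
                columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_kb"],
            )
            _write(seg_df, out / f"{pop}.roh_segments.tsv")
            bundle[(pop, "roh")] = seg_df

            stage = "inbreeding"
            pos = g_clean.positions
            chrom_spans = {
                int(c): float(pos[idx].max() - pos[idx].min() + 1)
                for c, idx in g_clean.chromosome_groups()
            }
            l_auto = sum(chrom_spans.values())
            froh = f_roh(segs, g_clean.sample_ids, l_auto, cfg.roh_min_segment_mb)
            fhat = grm_inbreeding(g_clean)
            inb = fhat.copy()
            inb["f_roh"] = froh
            inb = inb.reset_index()
            _write(inb, out / f"{pop}.inbreeding.tsv")
            _write(
                f_roh_per_chromosome(
                    segs, g_clean.sample_ids, chrom_spans, cfg.roh_min_segment_mb
                ).reset_index(),
                out / f"{pop}.froh_by_chrom.tsv",
            )
            _write(
                roh_length_classes(segs, g_clean.sample_ids, g_clean.populations),
                out / f"{pop}.roh_length_classes.tsv",
            )
            bundle[(pop, "inbreeding")] = inb

            stage = "ne"
            ne_decay = ld_decay(
                source,
                bins=ne_bin_edges_bp(cfg.mb_per_cm),
                max_pair_distance=float(ne_bin_edges_bp(cfg.mb_per_cm)[-1]),
            )
            traj = ne_trajectory(ne_decay, cfg.mb_per_cm, cfg.ne_alpha)
            _write(traj, out / f"{pop}.ne_trajectory.tsv")
            bundle[(pop, "ne")] = traj

        stage = "phase"
        if len(pops) < 2:
            logger.info("single population: phase-persistence stage skipped")
        bins = default_phase_bins_bp(
            int(cfg.phase_bin_width_kb * 1000), int(cfg.phase_max_distance_kb * 1000)
        )
        for a_i in range(len(pops)):
            for b_i in range(a_i + 1, len(pops)):
                pa, pb = pops[a_i], pops[b_i]
                shared = sorted(
                    set(post_qc[pa].marker_ids) & set(post_qc[pb].marker_ids)
                )
                shared_set = set(shared)

                def _restrict(pop_label):
                    src = phased.get(pop_label, post_qc[pop_label])
                    keep = np.array([mk.id in shared_set for mk in src.markers])
                    return src.subset(marker_mask=keep)

                ta = signed_r_table(_restrict(pa), cfg.phase_max_distance_kb * 1000)
                tb = signed_r_table(_restrict(pb), cfg.phase_max_distance_kb * 1000)
                pp = phase_persistence(ta, tb, bins)
                pp.insert(0, "pop_pair", f"{pa}-{pb}")
                _write(pp, out / f"{pa}-{pb}.phase_persistence.tsv")
                bundle[((pa, pb), "phase")] = pp
    except PipelineError:
        (out / "FAILED").write_text(f"stage {stage} [{pop}]\n")
        raise
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        (out / "FAILED").write_text(f"stage {stage} [{pop}]: {exc}\n")
        raise PipelineError(f"stage {stage} [{pop}]: {exc}") from exc

    manifest = {
        "package": "snppop",
        "version": __version__,
        "seed": cfg.seed,
        "populations": pops,
        "config": _jsonable(dataclasses.asdict(cfg)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["manifest"] = manifest
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def summarize(out_dir: str) -> tuple[str, int]:
    """Digest the headline numbers of a report bundle directory.

    Returns (markdown text, exit code); the exit code is nonzero when no
    population tables were found.  Every number quoted comes straight from
    the stage TSVs.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    pops: list[str] = []
    if manifest_path.exists():
        pops = json.loads(manifest_path.read_text()).get("populations", [])
    else:
        pops = sorted(
            {p.name.split(".")[0] for p in out.glob("*.qc_report.tsv")}
        )
    lines = [f"# snppop summary — {out_dir}", ""]
    if not pops:
        lines.append("No population reports found.")
        return "\n".join(lines) + "\n", 1

    for pop in pops:
        lines.append(f"## {pop}")
        ld_path = out / f"{pop}.ld_headline.tsv"
        if ld_path.exists():
            ld = pd.read_csv(ld_path, sep="\t").set_index("statistic")["value"]
            lines.append(
                f"- mean adjacent-SNP r² (≤10 kb): {ld.get('adjacent_mean_r2_within_10kb', float('nan')):.3f}"
            )
            lines.append(
                f"- pairs ≤10 kb with r² > 0.3: {100 * ld.get('frac_pairs_10kb_r2_above_030', float('nan')):.1f}%"
            )
        else:
            lines.append("- LD summary: absent")
        blk_path = out / f"{pop}.blocks.tsv"
        if blk_path.exists():
            n_blocks = len(pd.read_csv(blk_path, sep="\t"))
            lines.append(f"- haplotype blocks: {n_blocks}")
        else:
            lines.append("- haplotype blocks: absent")
        inb_path = out / f"{pop}.inbreeding.tsv"
        if inb_path.exists():
            inb = pd.read_csv(inb_path, sep="\t")
            lines.append(f"- mean F_ROH: {inb['f_roh'].mean():.4f}")
        else:
            lines.append("- inbreeding: absent")
        ne_path = out / f"{pop}.ne_trajectory.tsv"
        if ne_path.exists():
            traj = pd.read_csv(ne_path, sep="\t")
            if len(traj):
                recent = traj.loc[traj["t_generations"].idxmin()]
                lines.append(
                    f"- Ne at t={recent['t_generations']:.0f} generations: {recent['Ne']:.0f}"
                )
            else:
                lines.append("- Ne trajectory: empty")
        else:
            lines.append("- Ne trajectory: absent")
        lines.append("")
    for pp_path in sorted(out.glob("*.phase_persistence.tsv")):
        df = pd.read_csv(pp_path, sep="\t")
        first = df.dropna(subset=["R"]).head(1)
        if len(first):
            row = first.iloc[0]
            lines.append(
                f"- phase persistence {row['pop_pair']}, "
                f"{row['bin_lo_bp'] / 1000:.0f}-{row['bin_hi_bp'] / 1000:.0f} kb: R = {row['R']:.3f}"
            )
    return "\n".join(lines) + "\n", 0
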