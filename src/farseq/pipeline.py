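"""End-to-end orchestration: simulate/load -> filter -> count -> compare.

A run is driven by one JSON config and a seed; identical (config, seed)
pairs produce byte-identical outputs. Each stage failure is surfaced with
the stage name and the sample or comparison it concerned.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .alignments import (
    filter_alignments,
    read_alignments,
    read_alignments_tsv,
    write_sam,
)
from .annotation import GenomeAnnotation, read_annotation, write_gff3
from .counting import CountTable, count_reads, read_count_tsv, write_count_tsv
from .differential import (
    SampleGroup,
    ThresholdScheme,
    classify_change,
    compare_conditions,
    write_comparison_tsv,
)
from .simulate import (
    SimulationConfig,
    build_genome,
    default_study_scenario,
    simulate_alignments,
    simulate_counts,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the item."""


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one input source: either ``simulate`` (a scenario) or an
    ``annotation`` path plus a sample ``manifest`` of alignment files
    (SAM, or the documented TSV dialect). ``comparisons`` name baseline
    and other conditions; policies mirror the library defaults.
    """

    comparisons: list[tuple[str, str]]
    simulate: SimulationConfig | None = None
    simulate_mode: str = "counts"  # "counts" | "alignments"
    annotation_path: str | None = None
    manifest: list[dict] = field(default_factory=list)
    thresholds: ThresholdScheme = field(default_factory=ThresholdScheme)
    unique_policy: str = "nh-mapq"
    stranded: bool = False
    multi_orf: str = "count-each"
    pseudocount: str | None = None
    z_mode: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.annotation_path is None):
            raise ValueError(
                "config must provide exactly one of 'simulate' or "
                "'annotation' + 'manifest'"
            )
        if self.simulate_mode not in ("counts", "alignments"):
            raise ValueError(f"unknown simulate mode {self.simulate_mode!r}")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        sim = doc.get("simulate")
        if sim is not None:
            sim = dict(sim)
            scenario = sim.pop("scenario", None)
            if "seed" in doc:  # the run seed drives the simulation
                sim["seed"] = doc["seed"]
            if scenario == "default":
                sim.setdefault("seed", 0)
                doc["simulate"] = default_study_scenario(**sim)
            else:
                doc["simulate"] = SimulationConfig.from_dict(sim)
        thr = doc.get("thresholds")
        if isinstance(thr, dict):
            doc["thresholds"] = ThresholdScheme(
                up_levels=tuple(thr.get("up_levels", (2.0, 10.0))),
                down_levels=tuple(thr.get("down_levels", (0.5, 0.1))),
                boundary_inclusive=thr.get("boundary_inclusive", True),
            )
        doc["comparisons"] = [tuple(c) for c in doc.get("comparisons", [])]
        return cls(**doc)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _stage(name: str, item: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed for {item!r}: {exc}") from exc
            return False

    return _Ctx()


def _load_sample(entry: dict, annotation: GenomeAnnotation, cfg: RunConfig) -> CountTable:
    path = entry["path"]
    if not os.path.exists(path):
        raise FileNotFoundError(f"alignment file for sample {entry['sample_id']!r}: {path}")
    fmt = entry.get("format", "tsv" if path.endswith(".tsv") else "sam")
    if fmt == "sam":
        records = read_alignments(path, unique_policy=cfg.unique_policy)
    elif fmt == "tsv":
        records = read_alignments_tsv(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    retained, stats = filter_alignments(records, annotation, stranded=cfg.stranded)
    return count_reads(
        retained,
        annotation,
        sample_id=entry["sample_id"],
        filter_stats=stats,
        stranded=cfg.stranded,
        multi_orf=cfg.multi_orf,
    )


def run_pipeline(config: RunConfig, outdir: str) -> str:
    """Execute a full run and write all artifacts under ``outdir``.

    Per sample: a counts+normalizations TSV. Per comparison: the
    differential table and a scatter export. Plus truth/annotation files
    when simulating, and a machine-readable run log. Returns ``outdir``.
    """
    os.makedirs(outdir, exist_ok=True)
    samples_by_condition: dict[str, list[CountTable]] = {}
    regulon_members: Mapping[str, list[str]] = {}

    if config.simulate is not None:
        sim = config.simulate
        with _stage("simulate", "genome"):
            annotation, truth = build_genome(sim)
            write_gff3(annotation, os.path.join(outdir, "annotation.gff3"))
            truth.write_tsv(os.path.join(outdir, "truth.tsv"))
            sim.to_json(os.path.join(outdir, "scenario.json"))
            regulon_members = truth.regulon_members
        ref_lengths = {sim.reference_name: sim.reference_length}
        for cond, n_rep in sim.conditions.items():
            for rep in range(n_rep):
                with _stage("simulate", f"{cond} replicate {rep + 1}"):
                    if config.simulate_mode == "alignments":
                        records = simulate_alignments(
                            truth, cond, sim, sim.seed, replicate=rep
                        )
                        sam_path = os.path.join(outdir, f"{cond}_rep{rep + 1}.sam")
                        write_sam(records, ref_lengths, sam_path)
                        retained, stats = filter_alignments(records, annotation)
                        table = count_reads(
                            retained,
                            annotation,
                            sample_id=f"{cond}_rep{rep + 1}",
                            filter_stats=stats,
                            multi_orf=config.multi_orf,
                        )
                    else:
                        table = simulate_counts(
                            truth, cond, sim.depth, sim.seed, replicate=rep,
                            overdispersion=sim.overdispersion,
                        )
                samples_by_condition.setdefault(cond, []).append(table)
    else:
        with _stage("annotation", config.annotation_path):
            annotation = read_annotation(config.annotation_path)
        for entry in config.manifest:
            with _stage("count", entry.get("sample_id", "?")):
                table = _load_sample(entry, annotation, config)
            samples_by_condition.setdefault(entry["condition_id"], []).append(table)

    for cond, tables in samples_by_condition.items():
        for table in tables:
            with _stage("write-counts", table.sample_id):
                write_count_tsv(
                    table, annotation, os.path.join(outdir, f"{table.sample_id}.counts.tsv")
                )

    results: dict[tuple[str, str], pd.DataFrame] = {}
    for base_cond, other_cond in config.comparisons:
        name = f"{other_cond}_vs_{base_cond}"
        with _stage("compare", name):
            for cond in (base_cond, other_cond):
                if cond not in samples_by_condition:
                    raise ValueError(f"comparison references unknown condition {cond!r}")
            df = compare_conditions(
                SampleGroup(base_cond, samples_by_condition[base_cond]),
                SampleGroup(other_cond, samples_by_condition[other_cond]),
                scheme=config.thresholds,
                pseudocount=config.pseudocount,
                z_mode=config.z_mode,
            )
            write_comparison_tsv(df, os.path.join(outdir, f"{name}.comparison.tsv"))
            export_scatter(
                df, config.thresholds, os.path.join(outdir, f"{name}.scatter.tsv")
            )
            results[(base_cond, other_cond)] = df

    if regulon_members:
        with _stage("report", "regulon summary"):
            frames = []
            for (base_cond, other_cond), df in results.items():
                summary = regulon_summary(df, regulon_members, config.thresholds)
                summary.insert(0, "comparison", f"{other_cond}_vs_{base_cond}")
                frames.append(summary)
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    os.path.join(outdir, "regulon_summary.tsv"),
                    sep="\t",
                    index=False,
                    float_format="%.10g",
                )

    with _stage("log", "run_log.json"):
        log = {
            "versions": {
                "farseq": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "policies": {
                "unique_policy": config.unique_policy,
                "stranded": config.stranded,
                "multi_orf": config.multi_orf,
                "pseudocount": config.pseudocount,
                "z_mode": config.z_mode,
                "boundary_inclusive": config.thresholds.boundary_inclusive,
                "filter_order": "uniqueness-then-rrna-trna",
                "simulate_mode": config.simulate_mode if config.simulate else None,
            },
            "thresholds": {
                "up_levels": list(config.thresholds.up_levels),
                "down_levels": list(config.thresholds.down_levels),
            },
            "comparisons": [list(c) for c in config.comparisons],
            "samples": {
                cond: [t.sample_id for t in tables]
                for cond, tables in samples_by_condition.items()
            },
        }
        with open(os.path.join(outdir, "run_log.json"), "wt", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return outdir


def export_scatter(
    results: pd.DataFrame,
    scheme: ThresholdScheme,
    path: str | None = None,
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Per-gene scatter export: x = baseline abundance, y = other.

    Threshold lines are encoded as ``#`` metadata; undefined ratios are
    kept with their sentinel class, never dropped. Optionally renders a
    log-log scatter plot (matplotlib) — the TSV is the tested contract.
    """
    if results.empty:
        raise ValueError("no results to export")
    df = results[["feature_id", "r_baseline", "r_other", "ratio", "change_class"]].rename(
        columns={"r_baseline": "x", "r_other": "y"}
    )
    if path is not None:
        with open(path, "wt", encoding="utf-8") as fh:
            for level in scheme.up_levels:
                fh.write(f"#threshold_up={level:g}\n")
            for level in scheme.down_levels:
                fh.write(f"#threshold_down={level:g}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="NA")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        pos = df[(df["x"] > 0) & (df["y"] > 0)]
        ax.loglog(pos["x"], pos["y"], ".", color="0.5", ms=3)
        lims = [pos[["x", "y"]].min().min() / 2, pos[["x", "y"]].max().max() * 2]
        for level in list(scheme.up_levels) + list(scheme.down_levels):
            ax.plot(lims, [v * level for v in lims], "-", lw=0.8)
        ax.plot(lims, lims, "k-", lw=0.8)
        ax.set_xlabel("relative abundance (baseline)")
        ax.set_ylabel("relative abundance (other)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def regulon_summary(
    results: pd.DataFrame,
    memberships: Mapping[str, list[str]],
    scheme: ThresholdScheme | None = None,
) -> pd.DataFrame:
    """Per-regulon roll-up of one comparison.

    Median ratio excludes undefined ratios (their count is reported);
    per-class counts always sum to the member count. Direction verdict:
    ``mixed`` when at least 25% of members fall in up classes and 25% in
    down classes; otherwise ``up`` for median ratio >= 2, ``down`` for
    <= 0.5, else ``unchanged``.
    """
    scheme = scheme or ThresholdScheme()
    known = set(results["feature_id"])
    indexed = results.set_index("feature_id")
    up_classes = {scheme.up_class(u) for u in scheme.up_levels}
    down_classes = {scheme.down_class(d) for d in scheme.down_levels}
    rows = []
    for name, members in memberships.items():
        missing = [m for m in members if m not in known]
        if missing:
            raise KeyError(
                f"regulon {name!r} references unknown features: {missing[:10]}"
            )
        sub = indexed.loc[list(members)]
        ratios = sub["ratio"].dropna()
        n_undefined = int(sub["ratio"].isna().sum())
        median = float(ratios.median()) if len(ratios) else float("nan")
        class_counts = {cls: int((sub["change_class"] == cls).sum()) for cls in scheme.classes()}
        n = len(members)
        up_frac = sum(class_counts[c] for c in up_classes) / n
        down_frac = sum(class_counts[c] for c in down_classes) / n
        if up_frac >= 0.25 and down_frac >= 0.25:
            verdict = "mixed"
        elif median >= 2:
            verdict = "up"
        elif median <= 0.5:
            verdict = "down"
        else:
            verdict = "unchanged"
        row = {
            "regulon": name,
            "n_members": n,
            "median_ratio": median,
            "n_undefined_ratio": n_undefined,
            "verdict": verdict,
        }
        row.update({f"n_{cls}": v for cls, v in class_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)
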