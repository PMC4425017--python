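"""Orchestration of the full barcode-evaluation workflow per dataset.

For every region alignment the pipeline computes, in order: the
characteristics row (individuals/species/singletons, site classes, overall
K2P), the intra/inter pairwise summary with gap statistics and histogram,
best-match and best-close-match identification reports, a neighbor-joining
tree with bootstrap supports scored for species monophyly, and monophyly
scores for any externally supplied support-annotated trees. A failing stage
aborts only its own region (BCM alone is skipped when the 95% threshold is
undefined, e.g. all-singleton datasets); other regions continue.

All tables are written as TSV/CSV under the output directory together with a
JSON manifest of every parameter, sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import (
    DEFAULT_HEADER_PATTERN,
    alignment_stats,
    read_labeled_fasta,
    stats_table,
)
from .distances import (
    DEFAULT_MIN_OVERLAP,
    distance_histogram,
    distance_matrix,
    pairwise_summary,
)
from .exceptions import BarcodevalError, ThresholdUndefinedError
from .similarity_id import (
    DEFAULT_TIE_TOLERANCE,
    best_close_match,
    best_match,
    summarize_by_dataset,
)
from .tree_id import (
    bootstrap_supports,
    read_newick_with_supports,
    score_monophyly,
)


@dataclass
class EvaluationConfig:
    """Inputs and parameters of one evaluation run."""

    regions: list[tuple[str, str]]  # (region tag, FASTA path)
    external_trees: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (region tag, method tag e.g. "ML"/"BI", newick path, support scale)
    out_dir: str | None = None
    header_pattern: str = DEFAULT_HEADER_PATTERN
    min_overlap: int = DEFAULT_MIN_OVERLAP
    percentile_rule: str = "linear"
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE
    bin_width: float = 0.01
    bootstrap_replicates: int = 1000
    seed: int = 0
    support_cutoff: float | None = None  # None -> scale default (80 / 0.80)
    singleton_mode: str = "count_incorrect"
    run_trees: bool = True

    def __post_init__(self):
        for _, path in self.regions:
            if not Path(path).exists():
                raise FileNotFoundError(path)
        for _, _, path, _ in self.external_trees:
            if not Path(path).exists():
                raise FileNotFoundError(path)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["regions"] = [list(r) for r in self.regions]
        d["external_trees"] = [list(t) for t in self.external_trees]
        return d


@dataclass
class RegionResult:
    """Everything computed for one region; ``error`` set if the region aborted."""

    region: str
    stats: object | None = None
    summary: object | None = None
    histogram: pd.DataFrame | None = None
    bm: object | None = None
    bcm: object | None = None
    bcm_error: str | None = None
    nj_tree: object | None = None
    monophyly: dict = field(default_factory=dict)  # method tag -> MonophylyReport
    error: str | None = None


def _evaluate_region(cfg: EvaluationConfig, region: str, path: str, log: list[str]):
    res = RegionResult(region=region)
    aln = read_labeled_fasta(path, header_pattern=cfg.header_pattern, region=region)
    dm = distance_matrix(aln, min_overlap=cfg.min_overlap)
    res.stats = alignment_stats(aln, dm)

    try:
        res.summary = pairwise_summary(dm, percentile_rule=cfg.percentile_rule)
        res.histogram = distance_histogram(res.summary, bin_width=cfg.bin_width)
    except ThresholdUndefinedError as exc:
        res.bcm_error = str(exc)
        log.append(f"[{region}] pairwise summary unavailable: {exc}")

    res.bm = best_match(dm, tie_tolerance=cfg.tie_tolerance)
    if res.summary is not None:
        res.bcm = best_close_match(dm, res.summary, tie_tolerance=cfg.tie_tolerance)
    else:
        log.append(f"[{region}] BCM skipped (threshold undefined); BM still reported")

    if cfg.run_trees:
        stree = bootstrap_supports(
            aln,
            n_replicates=cfg.bootstrap_replicates,
            seed=cfg.seed,
            min_overlap=cfg.min_overlap,
        )
        res.nj_tree = stree
        res.monophyly["NJ"] = score_monophyly(
            stree,
            support_cutoff=cfg.support_cutoff,
            singleton_mode=cfg.singleton_mode,
            expected_labels=aln.labels,
        )
        for reg_tag, method, tpath, scale in cfg.external_trees:
            if reg_tag != region:
                continue
            ext = read_newick_with_supports(tpath, scale=scale)
            res.monophyly[method] = score_monophyly(
                ext,
                support_cutoff=cfg.support_cutoff
                if (cfg.support_cutoff is not None and scale == "bootstrap")
                else None,
                singleton_mode=cfg.singleton_mode,
                expected_labels=aln.labels,
            )
    return res


def run_evaluation(cfg: EvaluationConfig) -> dict:
    """Run the full evaluation; returns the in-memory report bundle.

    The bundle maps region tags to :class:`RegionResult` plus the combined
    tables under ``"stats"``, ``"similarity"``, ``"monophyly"``,
    ``"comparison"`` and the run ``"log"``. When ``cfg.out_dir`` is set,
    every table, tree and the manifest are also written there.
    """
    log: list[str] = [f"barcodeval {__version__} evaluation run (seed={cfg.seed})"]
    results: dict[str, RegionResult] = {}
    for region, path in cfg.regions:
        try:
            results[region] = _evaluate_region(cfg, region, path, log)
            log.append(f"[{region}] completed")
        except BarcodevalError as exc:
            results[region] = RegionResult(region=region, error=str(exc))
            log.append(f"[{region}] ABORTED: {exc}")

    ok = {r: res for r, res in results.items() if res.error is None}
    stats_df = stats_table((r, res.stats) for r, res in ok.items())

    sim_rows = []
    for r, res in ok.items():
        sim_rows.append((r, res.bm))
        if res.bcm is not None:
            sim_rows.append((r, res.bcm))
    similarity_df = summarize_by_dataset(sim_rows)

    mono_rows = [
        {
            "dataset": r,
            "method": method,
            "correct_individuals_pct": round(rep.pct_correct_individuals, 2),
            "support_cutoff": rep.support_cutoff,
        }
        for r, res in ok.items()
        for method, rep in res.monophyly.items()
    ]
    monophyly_df = pd.DataFrame(mono_rows)

    bundle = {
        "regions": results,
        "stats": stats_df,
        "similarity": similarity_df,
        "monophyly": monophyly_df,
        "log": log,
    }
    bundle["comparison"] = compare_regions(bundle)

    if cfg.out_dir is not None:
        _write_bundle(cfg, bundle)
    return bundle


def compare_regions(bundle: dict) -> pd.DataFrame:
    """Per-(region, method) percent-correct matrix with the best region flagged.

    Ties for best are all flagged, never broken. Purely descriptive: no
    significance testing is applied.
    """
    rows: dict[str, dict[str, float]] = {}
    sim = bundle["similarity"]
    for _, row in sim.iterrows():
        rows.setdefault(row["dataset"], {})[row["method"]] = row["correct_pct"]
    mono = bundle["monophyly"]
    if len(mono):
        for _, row in mono.iterrows():
            rows.setdefault(row["dataset"], {})[row["method"]] = row[
                "correct_individuals_pct"
            ]
    df = pd.DataFrame(rows).T.sort_index()
    df.index.name = "dataset"
    for method in df.columns:
        best = df[method].max()
        df[f"{method}_best"] = df[method] == best
    return df


def _write_bundle(cfg: EvaluationConfig, bundle: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["stats"].to_csv(out / "stats.tsv", sep="\t", index=False)
    bundle["similarity"].to_csv(out / "similarity_summary.tsv", sep="\t", index=False)
    bundle["monophyly"].to_csv(out / "monophyly_summary.tsv", sep="\t", index=False)
    bundle["comparison"].to_csv(out / "region_comparison.tsv", sep="\t")
    for region, res in bundle["regions"].items():
        if res.error is not None:
            continue
        rdir = out / region
        rdir.mkdir(exist_ok=True)
        if res.histogram is not None:
            res.histogram.to_csv(rdir / "distance_histogram.csv", index=False)
        res.bm.to_frame().to_csv(rdir / "bm_verdicts.csv", index=False)
        if res.bcm is not None:
            res.bcm.to_frame().to_csv(rdir / "bcm_verdicts.csv", index=False)
        if res.nj_tree is not None:
            res.nj_tree.write(rdir / "nj_bootstrap.nwk")
        for method, rep in res.monophyly.items():
            rep.to_frame().to_csv(rdir / f"monophyly_{method}.csv", index=False)
    manifest = {"barcodeval_version": __version__, "config": cfg.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(bundle["log"]) + "\n")
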