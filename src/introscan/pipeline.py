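"""Pipeline orchestration: simulate -> discover -> compare -> stats.

Each stage reads standard files, writes tabular outputs plus a JSON manifest
(parameters, package version, input checksums) into its output directory,
and returns the in-memory result object.  Outputs carry no timestamps, so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .io import read_bed, read_strain_panel, read_vcf, write_bed, write_strain_panel, write_vcf
from .scan import (
    IntrogressionScan,
    IntrogressionScanResult,
    ScanParams,
    apply_quality_filters,
    select_het_nonref,
)
from .simulate import (
    CohortConfig,
    IntrogressionTruth,
    QpcrConfig,
    SimulationConfig,
    default_introgression_truth,
    generate_cohort,
    generate_congenic_callset,
    generate_qpcr,
    generate_strain_panel,
)
from .stats import ContingencyTable, fisher_exact, monte_carlo_exact, welch_t, ddct_fold_change, MAX_ENUMERATION_TOTAL
from .strains import ProvenanceReport, compare_to_panel, densest_span

__all__ = [
    "run_simulate",
    "run_discover",
    "run_compare",
    "run_stats",
    "run_demo",
]

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, parameters: dict, inputs: dict) -> None:
    manifest = {
        "stage": stage,
        "package": "introscan",
        "version": __version__,
        "parameters": parameters,
        # file names only: checksums identify content, and manifests stay
        # byte-identical across reruns in different directories
        "inputs": {
            name: {"file": Path(p).name, "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if p
        },
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _params_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _params_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {str(k): _params_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_params_dict(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(
    outdir: str | Path,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    truth: IntrogressionTruth | None = None,
    cohort_config: CohortConfig | None = None,
    qpcr_config: QpcrConfig | None = None,
) -> dict[str, Path]:
    """Generate every pipeline input with planted truth; return output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim_config or SimulationConfig()
    sim = dataclasses.replace(sim, seed=seed)
    cohort_cfg = dataclasses.replace(cohort_config or CohortConfig(), seed=seed)
    qpcr_cfg = dataclasses.replace(qpcr_config or QpcrConfig(), seed=seed)
    truth = truth or default_introgression_truth()

    calls, truth_record = generate_congenic_callset(sim, truth)
    panel, site_truth = generate_strain_panel(sim, calls, truth_record)
    cohort = generate_cohort(cohort_cfg)
    qpcr = generate_qpcr(qpcr_cfg)

    paths = {
        "vcf": outdir / "calls.vcf",
        "truth_record": outdir / "truth_record.tsv",
        "panel": outdir / "panel.tsv",
        "panel_site_truth": outdir / "panel_site_truth.tsv",
        "cohort": outdir / "cohort.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "genome": outdir / "genome.tsv",
    }
    write_vcf(calls, paths["vcf"], contig_lengths=sim.chromosome_lengths)
    truth_record.to_csv(paths["truth_record"], sep="\t", index=False)
    write_strain_panel(panel, paths["panel"])
    site_truth.to_csv(paths["panel_site_truth"], sep="\t", index=False)
    cohort.to_csv(paths["cohort"], sep="\t", index=False)
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    pd.DataFrame(
        {"chromosome": list(sim.chromosome_lengths),
         "length": list(sim.chromosome_lengths.values())}
    ).to_csv(paths["genome"], sep="\t", index=False)

    _write_manifest(
        outdir,
        "simulate",
        {
            "simulation": _params_dict(sim),
            "cohort": _params_dict(cohort_cfg),
            "qpcr": _params_dict(qpcr_cfg),
            "truth": _params_dict(truth),
            "seed": seed,
        },
        {},
    )
    return paths


# ---------------------------------------------------------------------------
# discover
# ---------------------------------------------------------------------------


def run_discover(
    vcf_path: str | Path,
    chromosome_lengths: Mapping[str, int],
    outdir: str | Path,
    params: ScanParams | None = None,
    min_gap_bp: int = 1_000_000,
) -> IntrogressionScanResult:
    """Filter -> het selection -> density -> segments -> gaps; write all outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or ScanParams()
    result = IntrogressionScan.from_vcf(vcf_path, chromosome_lengths, params).fit()

    write_bed(result.segments, outdir / "segments.bed")
    result.track_frame().to_csv(outdir / "density.tsv", sep="\t", index=False)
    seg_frame = result.segment_frame()
    artifact = (
        seg_frame[seg_frame["classification"] == "artifact_candidate"]
        if not seg_frame.empty
        else seg_frame
    )
    artifact.to_csv(outdir / "artifact_report.tsv", sep="\t", index=False)
    gaps = result.devoid_gaps(min_gap_bp=min_gap_bp)
    pd.DataFrame(
        [
            {"chromosome": g.chromosome, "start": g.start, "end": g.end,
             "width_bp": g.width}
            for g in gaps
        ],
        columns=["chromosome", "start", "end", "width_bp"],
    ).to_csv(outdir / "devoid_gaps.tsv", sep="\t", index=False)
    (outdir / "scan_summary.txt").write_text(result.summary() + "\n")

    if result.het_calls.empty:
        log.warning("no heterozygous calls after filtering: empty segment set")
    _write_manifest(
        outdir,
        "discover",
        {
            "scan": _params_dict(params),
            "min_gap_bp": min_gap_bp,
            "chromosome_lengths": dict(chromosome_lengths),
        },
        {"vcf": vcf_path},
    )
    return result


# ---------------------------------------------------------------------------
# compare
# ---------------------------------------------------------------------------


def run_compare(
    vcf_path: str | Path,
    panel_path: str | Path,
    segments_bed: str | Path,
    chromosome_lengths: Mapping[str, int],
    outdir: str | Path,
    params: ScanParams | None = None,
) -> ProvenanceReport:
    """Classify the largest introgressed segment's SNPs against a strain panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or ScanParams()
    segments = [
        s for s in read_bed(segments_bed) if s.classification == "introgressed"
    ]
    if not segments:
        raise ValueError(f"{segments_bed}: no introgressed segments to compare")
    segment = max(segments, key=lambda s: s.length)
    panel = read_strain_panel(panel_path)
    panel_chroms = set(map(str, panel.sites["chromosome"].unique()))
    if panel.n_sites and segment.chromosome not in panel_chroms:
        raise ValueError(
            f"panel covers chromosome(s) {sorted(panel_chroms)} but the "
            f"largest segment is on {segment.chromosome}"
        )

    calls = read_vcf(vcf_path)
    filtered, _ = apply_quality_filters(calls, params)
    het = select_het_nonref(filtered)
    sites = het[
        (het["chromosome"] == segment.chromosome)
        & (het["position"] >= segment.start)
        & (het["position"] <= segment.end)
    ].reset_index(drop=True)

    report = compare_to_panel(
        sites, panel,
        chromosome_length=int(chromosome_lengths[segment.chromosome]),
        params=params,
    )
    report.sites.to_csv(outdir / "provenance.tsv", sep="\t", index=False)
    report.similarity.to_csv(outdir / "similarity.tsv", sep="\t", index=False)
    report.track.to_frame(
        int(chromosome_lengths[segment.chromosome])
    ).to_csv(outdir / "private_density.tsv", sep="\t", index=False)
    (outdir / "compare_summary.txt").write_text(report.summary() + "\n")
    _write_manifest(
        outdir,
        "compare",
        {"scan": _params_dict(params),
         "segment": {"chromosome": segment.chromosome,
                     "start": segment.start, "end": segment.end}},
        {"vcf": vcf_path, "panel": panel_path, "segments": segments_bed},
    )
    return report


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------


def _fisher_row(table: ContingencyTable, comparison: str, seed: int = 0) -> dict:
    total = int(table.counts.sum())
    if table.counts.shape == (2, 2) or total <= MAX_ENUMERATION_TOTAL:
        res = fisher_exact(table)
        return {
            "test": "fisher_exact",
            "comparison": comparison,
            "statistic": res.point_prob,
            "df": float("nan"),
            "p_value": res.p_value,
            "note": f"{table.counts.shape[0]}x{table.counts.shape[1]}, total {total}",
        }
    mc = monte_carlo_exact(table, seed=seed)
    return {
        "test": "monte_carlo_exact",
        "comparison": comparison,
        "statistic": float("nan"),
        "df": float("nan"),
        "p_value": mc.p_value,
        "note": (
            f"{table.counts.shape[0]}x{table.counts.shape[1]}, total {total}; "
            f"95% CI [{mc.ci_low:.4f}, {mc.ci_high:.4f}], {mc.n_draws} draws"
        ),
    }


def run_stats(
    outdir: str | Path,
    cohort_path: str | Path | None = None,
    qpcr_path: str | Path | None = None,
    target_gene: str = "Rspo1",
    reference_gene: str = "Hprt1",
    calibrator_group: str = "+/+",
    seed: int = 0,
) -> pd.DataFrame:
    """Exact tests on cohort tables plus ddCt/Welch on expression tables.

    Writes one consolidated report (``stats_report.tsv``) with columns
    ``test, comparison, statistic, df, p_value, note``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []

    if cohort_path is not None:
        cohort = pd.read_csv(cohort_path, sep="\t")
        n_in = len(cohort)
        cohort = cohort.dropna(subset=["genotype", "phenotypic_sex"])
        if len(cohort) < n_in:
            log.warning("dropped %d cohort row(s) with missing fields", n_in - len(cohort))
        sex_table = ContingencyTable.from_frame(cohort, "genotype", "phenotypic_sex")
        rows.append(_fisher_row(sex_table, "genotype x phenotypic_sex", seed))
        if "gonad_category" in cohort.columns:
            gonad = cohort.dropna(subset=["gonad_category"])
            gonad_table = ContingencyTable.from_frame(
                gonad, "genotype", "gonad_category"
            )
            rows.append(_fisher_row(gonad_table, "genotype x gonad_category", seed))

    fc_result = None
    if qpcr_path is not None:
        qpcr = pd.read_csv(qpcr_path, sep="\t")
        fc_result = ddct_fold_change(
            qpcr, target_gene, reference_gene, calibrator_group
        )
        for r in fc_result.per_group.itertuples(index=False):
            rows.append(
                {
                    "test": "ddct_fold_change",
                    "comparison": f"{target_gene}: {r.group} vs {calibrator_group}",
                    "statistic": r.fold_change,
                    "df": float("nan"),
                    "p_value": float("nan"),
                    "note": f"ddCt {r.ddct:.4f}, n {r.n}",
                }
            )
        for group in fc_result.per_group["group"]:
            if group == calibrator_group:
                continue
            wt = welch_t(
                fc_result.relative_quantities(group),
                fc_result.relative_quantities(calibrator_group),
            )
            rows.append(
                {
                    "test": "welch_t",
                    "comparison": (
                        f"{target_gene} rel. quantity: {group} vs {calibrator_group}"
                    ),
                    "statistic": wt.statistic,
                    "df": wt.df,
                    "p_value": wt.p_value,
                    "note": "two-tailed",
                }
            )

    report = pd.DataFrame(
        rows, columns=["test", "comparison", "statistic", "df", "p_value", "note"]
    )
    report.to_csv(outdir / "stats_report.tsv", sep="\t", index=False)
    if fc_result is not None:
        fc_result.per_sample.to_csv(
            outdir / "relative_quantities.tsv", sep="\t", index=False
        )
    _write_manifest(
        outdir,
        "stats",
        {"target_gene": target_gene, "reference_gene": reference_gene,
         "calibrator_group": calibrator_group, "seed": seed},
        {"cohort": cohort_path, "qpcr": qpcr_path},
    )
    return report


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------


def run_demo(outdir: str | Path, seed: int = 0) -> dict:
    """One-command synthetic demo: simulate, discover, compare, stats.

    Returns a dictionary of headline results (largest segment, widest gap,
    top strain, fold change) and writes ``demo_summary.txt``.
    """
    outdir = Path(outdir)
    paths = run_simulate(outdir / "inputs", seed=seed)
    genome = pd.read_csv(paths["genome"], sep="\t", dtype={"chromosome": str})
    lengths = dict(zip(genome["chromosome"], genome["length"].astype(int)))

    scan_result = run_discover(paths["vcf"], lengths, outdir / "discover")
    report = run_compare(
        paths["vcf"], paths["panel"], outdir / "discover" / "segments.bed",
        lengths, outdir / "compare",
    )
    stats_report = run_stats(
        outdir / "stats",
        cohort_path=paths["cohort"],
        qpcr_path=paths["qpcr"],
        seed=seed,
    )

    segment = scan_result.largest_segment()
    gaps = scan_result.devoid_gaps()
    span_start, span_count = (
        densest_span(report.track) if report.track is not None else (None, None)
    )
    headline = {
        "seed": seed,
        "largest_segment": None
        if segment is None
        else {
            "chromosome": segment.chromosome,
            "start_bp": segment.start,
            "end_bp": segment.end,
            "length_mb": round(segment.length / 1e6, 2),
            "n_snps": segment.n_supporting_snps,
        },
        "widest_devoid_gap_mb": round(gaps[0].width / 1e6, 2) if gaps else None,
        "n_private": report.n_private,
        "n_shared": report.n_shared,
        "top_strain": report.top_strain,
        "densest_private_span_start_mb": (
            None if span_start is None else span_start / 1e6
        ),
    }
    fold_rows = stats_report[stats_report["test"] == "ddct_fold_change"]
    non_cal = fold_rows[~fold_rows["comparison"].str.contains("\\+/\\+ vs")]
    if not non_cal.empty:
        headline["qpcr_fold_change"] = round(float(non_cal["statistic"].iloc[0]), 3)

    summary = [
        "Synthetic demo pipeline",
        "=======================",
        scan_result.summary(),
        "",
        report.summary(),
        "",
        "Statistics report:",
        stats_report.to_string(index=False),
        "",
        "Headline: " + json.dumps(headline, sort_keys=True),
    ]
    (outdir / "demo_summary.txt").write_text("\n".join(summary) + "\n")
    return headline
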