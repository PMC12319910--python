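"""End-to-end orchestration: timeseries → gradients → dispersion → inference.

The analysis follows the study design it emulates: a group gradient
template is built from the average connectivity matrix of *all* scans
(patients ON, patients OFF, controls), every scan's gradients are aligned
to that template and labeled, the 3-D manifold dispersion metrics are
computed per scan, and the paired ON/OFF comparisons (max-statistic
permutation families, network shift tests, regional tests, KS distribution
comparisons, the state × dose mixed model, and optional spin-permutation
map associations) are run on the patient pairs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .embedding import (
    GRADIENT_AXES,
    GradientTemplate,
    build_group_template,
    gradients_from_scan,
    label_gradients,
    procrustes_align,
)
from .inference import (
    InteractionResult,
    KSResult,
    PermutationResult,
    SpinResult,
    bh_fdr,
    delta_map,
    interaction_family,
    ks_compare,
    maxstat_family,
    spin_correlate,
    spin_rotations,
)
from .io import (
    CohortTable,
    file_checksum,
    read_timeseries,
    write_eigen_table,
    write_gradients,
    write_manifest,
)
from .manifold import ManifoldEmbedding, dispersion_summary, network_mean_scores
from .parcellation import ParcelScheme, YEO7_NETWORKS

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "analyze_cohort", "run_full_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    """Everything the pipeline computes, as in-memory tables and results."""

    template: GradientTemplate
    aligned: dict  # scan_id -> labeled GradientSet
    dispersion: pd.DataFrame  # long: scan_id, subject, condition, metric, value
    between_tests: list = field(default_factory=list)  # PermutationResult
    within_tests: list = field(default_factory=list)
    network_shift_tests: list = field(default_factory=list)
    regional: pd.DataFrame | None = None
    ks_tests: list = field(default_factory=list)  # KSResult
    interactions: list = field(default_factory=list)  # InteractionResult
    delta_maps: dict = field(default_factory=dict)  # axis -> (P,) array
    spin_tests: list = field(default_factory=list)  # SpinResult

    def permutation_table(self) -> pd.DataFrame:
        rows = [
            {
                "family": fam,
                "metric": r.metric,
                "t": r.t,
                "p_uncorrected": r.p_uncorrected,
                "p_fwe": r.p_fwe,
                "n_permutations": r.n_permutations,
            }
            for fam, results in (
                ("between_dispersion", self.between_tests),
                ("within_dispersion", self.within_tests),
                ("network_shift", self.network_shift_tests),
            )
            for r in results
        ]
        return pd.DataFrame(rows)


def _stage(name: str, scan: str | None = None):
    where = f" [{scan}]" if scan else ""
    logger.info("stage: %s%s", name, where)


def analyze_cohort(
    scans,
    scheme: ParcelScheme,
    doses: pd.DataFrame,
    config: RunConfig | None = None,
    expression_maps: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory scans.

    ``scans`` is any iterable of :class:`~funcgrad.synthetic.ScanTimeseries`
    where patient scans carry condition "ON"/"OFF" (paired by subject) and
    control scans carry "control". ``doses`` has columns subject, DDE.
    ``expression_maps`` (optional) is a parcel × gene DataFrame tested
    against the ON-minus-OFF gradient change maps with spin nulls.
    """
    config = config or RunConfig()
    scans = list(scans)
    if not scans:
        raise PipelineError("no scans supplied")

    _stage("group template")
    template = build_group_template(
        scans,
        threshold_fraction=config.threshold_fraction,
        alpha=config.alpha,
        n_components=config.n_components,
    )
    reference_axes = template.gradients.scores[:, :3]

    _stage("individual gradients + alignment")
    aligned: dict[str, object] = {}
    manifolds: dict[str, ManifoldEmbedding] = {}
    for scan in scans:
        try:
            grads = gradients_from_scan(
                scan,
                threshold_fraction=config.threshold_fraction,
                alpha=config.alpha,
                n_components=config.n_components,
            )
            grads = procrustes_align(grads, template, n_components=config.n_aligned)
            grads = label_gradients(grads, reference_axes)
        except Exception as exc:
            raise PipelineError(f"stage 'gradients' failed for scan {scan.scan_id}: {exc}") from exc
        aligned[scan.scan_id] = grads
        manifolds[scan.scan_id] = ManifoldEmbedding.from_gradients(grads, scheme, scan.scan_id)

    _stage("dispersion metrics")
    meta = {s.scan_id: s for s in scans}
    long_rows = []
    for scan_id, emb in manifolds.items():
        tab = dispersion_summary(emb).to_long()
        tab.insert(1, "subject", meta[scan_id].subject)
        tab.insert(2, "condition", meta[scan_id].condition)
        long_rows.append(tab)
    dispersion = pd.concat(long_rows, ignore_index=True)

    result = PipelineResult(template=template, aligned=aligned, dispersion=dispersion)

    pairs = sorted(
        {s.subject for s in scans if s.condition == "ON"}
        & {s.subject for s in scans if s.condition == "OFF"}
    )
    if len(pairs) < 3:
        logger.warning("fewer than 3 ON/OFF pairs: skipping paired inference")
        return result

    def _metric_matrix(condition: str, metrics: list[str]) -> np.ndarray:
        sub = dispersion[dispersion["condition"] == condition].pivot_table(
            index="subject", columns="metric", values="value"
        )
        return sub.loc[pairs, metrics].to_numpy()

    between_metrics = [f"between_{a}_{b}" for a, b in ParcelScheme.network_pairs()]
    within_metrics = [f"within_{n}" for n in YEO7_NETWORKS]

    _stage("dispersion permutation tests")
    result.between_tests = maxstat_family(
        _metric_matrix("ON", between_metrics),
        _metric_matrix("OFF", between_metrics),
        between_metrics,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    result.within_tests = maxstat_family(
        _metric_matrix("ON", within_metrics),
        _metric_matrix("OFF", within_metrics),
        within_metrics,
        n_perm=config.n_perm,
        seed=config.seed + 1,
    )

    _stage("network shift tests")
    shift_metrics, shift_on, shift_off = [], [], []
    means = {
        scan_id: network_mean_scores(g, scheme) for scan_id, g in aligned.items()
    }
    for axis in GRADIENT_AXES:
        for net in YEO7_NETWORKS:
            shift_metrics.append(f"{axis}_{net}")
    for cond, store in (("ON", shift_on), ("OFF", shift_off)):
        for sub in pairs:
            scan_id = next(
                s.scan_id for s in scans if s.subject == sub and s.condition == cond
            )
            tab = means[scan_id]
            store.append([tab.loc[net, axis] for axis in GRADIENT_AXES for net in YEO7_NETWORKS])
    result.network_shift_tests = maxstat_family(
        np.asarray(shift_on),
        np.asarray(shift_off),
        shift_metrics,
        n_perm=config.n_perm,
        seed=config.seed + 2,
    )

    _stage("regional tests")
    on_sets = {
        s.subject: aligned[s.scan_id] for s in scans if s.condition == "ON" and s.subject in pairs
    }
    off_sets = {
        s.subject: aligned[s.scan_id] for s in scans if s.condition == "OFF" and s.subject in pairs
    }
    regional_rows = []
    for gi, axis in enumerate(GRADIENT_AXES):
        on_mat = np.vstack([on_sets[s].axis_scores(axis) for s in pairs])
        off_mat = np.vstack([off_sets[s].axis_scores(axis) for s in pairs])
        fam = maxstat_family(
            on_mat,
            off_mat,
            [str(p) for p in scheme.parcel_ids],
            n_perm=config.n_perm,
            seed=config.seed + 3 + gi,
        )
        for r in fam:
            regional_rows.append(
                {
                    "gradient": axis,
                    "parcel_id": r.metric,
                    "t": r.t,
                    "p_uncorrected": r.p_uncorrected,
                    "p_fwe": r.p_fwe,
                }
            )
    result.regional = pd.DataFrame(regional_rows)

    _stage("KS distribution comparisons")
    ks_raw = []
    for axis in GRADIENT_AXES:
        pooled_on = np.concatenate([on_sets[s].axis_scores(axis) for s in pairs])
        pooled_off = np.concatenate([off_sets[s].axis_scores(axis) for s in pairs])
        ks_raw.append(ks_compare(pooled_on, pooled_off, gradient=axis))
    adj = bh_fdr([k.p_value for k in ks_raw])
    result.ks_tests = [
        KSResult(k.gradient, k.d_statistic, k.p_value, float(a))
        for k, a in zip(ks_raw, adj)
    ]

    _stage("state x dose interaction models")
    if (
        doses is not None
        and len(doses)
        and doses["DDE"].nunique() > 1
        and len(pairs) >= 6
    ):
        tables = {}
        for metric in between_metrics:
            sub = dispersion[
                (dispersion["metric"] == metric)
                & (dispersion["condition"].isin(["ON", "OFF"]))
                & (dispersion["subject"].isin(pairs))
            ]
            tables[metric] = sub.rename(columns={"condition": "state"})[
                ["subject", "state", "value"]
            ]
        result.interactions = interaction_family(tables, doses)
    else:
        logger.warning("no usable dose table: skipping interaction models")

    _stage("gradient change maps")
    for axis in GRADIENT_AXES:
        result.delta_maps[axis] = delta_map(on_sets, off_sets, gradient=axis)

    if expression_maps is not None:
        _stage("spin-permutation map associations")
        rotations = spin_rotations(scheme, config.n_rotations, seed=config.seed + 10)
        raw = []
        for axis in GRADIENT_AXES:
            for gene in expression_maps.columns:
                raw.append(
                    spin_correlate(
                        expression_maps[gene].to_numpy(),
                        result.delta_maps[axis],
                        rotations,
                        map_name=f"delta_{axis}_x_{gene}",
                        seed=config.seed + 10,
                    )
                )
        adj = bh_fdr([r.p_spin for r in raw])
        result.spin_tests = [
            SpinResult(r.map_name, r.rho, r.p_spin, r.n_rotations, r.seed, float(a))
            for r, a in zip(raw, adj)
        ]
    return result


def run_full_pipeline(
    cohort: CohortTable,
    scheme: ParcelScheme,
    config: RunConfig | None = None,
    out_dir=None,
    expression_maps: pd.DataFrame | None = None,
) -> PipelineResult:
    """File-based entry point: read scans, analyze, write result tables.

    Outputs under ``out_dir``: the template gradients and spectrum, per-scan
    aligned gradient tables, the tidy dispersion table, all statistics
    tables, the change maps, and a JSON manifest with the configuration and
    output checksums sufficient to re-run bit-identically.
    """
    config = config or RunConfig()
    cohort.validate_files()
    scans = []
    for row in cohort.table.itertuples():
        scans.append(
            read_timeseries(
                cohort.resolve(row.path),
                scheme=scheme,
                scan_id=row.scan_id,
                subject=row.subject,
                condition=row.condition,
            )
        )
    result = analyze_cohort(
        scans, scheme, cohort.doses(), config, expression_maps=expression_maps
    )
    if out_dir is not None:
        _write_outputs(result, scheme, config, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, scheme, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "gradients").mkdir(exist_ok=True)
    write_gradients(result.template.gradients, out / "template_gradients.tsv")
    write_eigen_table(result.template.gradients, out / "template_spectrum.tsv")
    for scan_id, grads in result.aligned.items():
        write_gradients(grads, out / "gradients" / f"{scan_id}.tsv")
    result.dispersion.to_csv(out / "dispersion.tsv", sep="\t", index=False)
    result.permutation_table().to_csv(out / "permutation_tests.tsv", sep="\t", index=False)
    if result.regional is not None:
        result.regional.to_csv(out / "regional_tests.tsv", sep="\t", index=False)
    if result.ks_tests:
        pd.DataFrame(
            [
                {"gradient": k.gradient, "D": k.d_statistic, "p": k.p_value, "p_fdr": k.p_fdr}
                for k in result.ks_tests
            ]
        ).to_csv(out / "ks_tests.tsv", sep="\t", index=False)
    if result.interactions:
        pd.DataFrame(
            [
                {
                    "metric": r.metric,
                    "F": r.f_statistic,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p": r.p_value,
                    "p_fdr": r.p_fdr,
                    **{f"beta_{k}": v for k, v in r.estimates.items()},
                }
                for r in result.interactions
            ]
        ).to_csv(out / "interaction_tests.tsv", sep="\t", index=False)
    if result.delta_maps:
        frame = pd.DataFrame(result.delta_maps)
        frame.insert(0, "parcel_id", list(scheme.parcel_ids))
        frame.to_csv(out / "delta_maps.tsv", sep="\t", index=False)
    if result.spin_tests:
        pd.DataFrame(
            [
                {
                    "test": r.map_name,
                    "rho": r.rho,
                    "p_spin": r.p_spin,
                    "p_fdr": r.p_fdr,
                    "n_rotations": r.n_rotations,
                }
                for r in result.spin_tests
            ]
        ).to_csv(out / "spin_tests.tsv", sep="\t", index=False)
    outputs = {
        p.name: file_checksum(p)
        for p in sorted(out.glob("*.tsv"))
    }
    write_manifest(out / "manifest.json", config.to_dict(), outputs)
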