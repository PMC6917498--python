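"""Tidy-table I/O and the end-to-end analysis driver.

All tables are plain CSV with documented headers; configuration echoes are
JSON.  ``run_all`` chains the eight stages — simulate (or ingest), motion QC,
subtyping, connectivity, edge-wise group inference, model comparison,
brain-behavior correlation, and power analysis — writing every intermediate
table plus a manifest recording parameters, per-stage seeds, and content
hashes.  One global seed deterministically spawns per-stage substreams, so a
rerun with an identical configuration reproduces every stochastic output
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .brain_behavior import (
    bootstrap_ci,
    compare_correlations,
    robust_partial_correlation,
)
from .cohort import (
    ALL_GROUPS,
    Cohort,
    CohortConfig,
    ComponentTimeSeries,
    MotionTrace,
    SubjectRecord,
    generate_cohort,
)
from .connectivity import ConnectivityConfig, compute_edge_vectors
from .exceptions import ConfigurationError, GeoconnError, ValidationError
from .group_stats import fdr_bh, fit_edge_glm, permutation_pairwise
from .model_selection import compare_models
from .power import analytic_power, empirical_power, min_detectable_d
from .subtyping import build_design

__all__ = [
    "RunConfig",
    "read_subjects",
    "write_subjects",
    "write_timeseries",
    "read_timeseries",
    "write_motion",
    "read_motion",
    "run_all",
]

logger = logging.getLogger("geoconn")

SUBJECT_COLUMNS = [
    "subject_id", "group", "sex", "age_scan_months", "age_et_months",
    "pct_geo", "ados_sa", "mean_fd", "mean_dvars",
]


# ---------------------------------------------------------------------------
# tidy-table readers/writers


def write_subjects(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in SUBJECT_COLUMNS})
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


def read_subjects(path) -> list[SubjectRecord]:
    """Read the tidy subject table, validating labels and ranges.

    Unknown columns are ignored with a warning (lenient-read policy); unknown
    group labels and out-of-range values are rejected with the offending line
    number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns and c != "mean_dvars"]
    required = ["subject_id", "group", "sex", "age_scan_months"]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise ValidationError(f"{path}: missing required column(s) {absent}")
    extra = [c for c in df.columns if c not in SUBJECT_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)

    def opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    sex=str(row["sex"]),
                    age_scan_months=float(row["age_scan_months"]),
                    age_et_months=opt(row, "age_et_months"),
                    pct_geo=opt(row, "pct_geo"),
                    ados_sa=opt(row, "ados_sa"),
                    mean_fd=opt(row, "mean_fd"),
                    mean_dvars=opt(row, "mean_dvars"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i + 2}: {exc}") from exc
    return records


def write_timeseries(ts: ComponentTimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.component_labels)).to_csv(path, index=False)


def read_timeseries(path, subject_id: str, repetition_time: float = 2.5) -> ComponentTimeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    return ComponentTimeSeries(
        subject_id=subject_id,
        values=df.to_numpy(dtype=float),
        component_labels=list(df.columns),
        repetition_time=repetition_time,
    )


MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_rad", "rot_y_rad", "rot_z_rad"]


def write_motion(trace: MotionTrace, path) -> None:
    pd.DataFrame(trace.params, columns=MOTION_COLUMNS).to_csv(path, index=False)


def read_motion(path, subject_id: str) -> MotionTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return MotionTrace(subject_id=subject_id, params=df[MOTION_COLUMNS].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# run configuration and driver


@dataclass
class RunConfig:
    """End-to-end run: either a simulation config or paths to real tables."""

    cohort: CohortConfig | None = None
    subjects_path: str | None = None
    timeseries_dir: str | None = None
    motion_dir: str | None = None
    out_dir: str = "geoconn_out"
    seed: int = 0
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    schemes: tuple[str, ...] = ("case_control", "subtype", "transdiagnostic")
    omnibus_scheme: str = "subtype"
    fdr_q: float = 0.05
    n_perm: int = 10000
    n_boot: int = 10000
    cv_folds: int = 5
    behavior_edge: tuple[str, str] = ("DMN", "OTC")
    behavior_groups: tuple[str, str] = ("GeoPref ASD", "nonGeo ASD")
    power_n1: int = 16
    power_n2: int = 55
    power_alpha: float = 0.05
    power_target: float = 0.80
    power_nexp: int = 100000
    log_level: int = logging.INFO

    def validate(self) -> None:
        simulated = self.cohort is not None
        ingested = self.subjects_path is not None
        if simulated == ingested:
            raise ConfigurationError(
                "provide exactly one of a simulation config or input paths"
            )
        if ingested and (self.timeseries_dir is None or self.motion_dir is None):
            raise ConfigurationError("ingestion needs timeseries_dir and motion_dir")


def _hash_obj(obj) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = json.dumps(obj, default=default, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write every intermediate table.

    Returns a report bundle (dict of DataFrames/objects); writes CSVs and a
    manifest.json under ``config.out_dir``.  Any stage failure aborts with the
    stage name and cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ["simulate", "qc", "subtype", "connectivity", "group_diff",
             "model_compare", "brain_behavior", "power"],
            np.random.SeedSequence(config.seed).spawn(8),
        )
    }
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config_hash": _hash_obj(dataclasses.asdict(config)),
        "stages": [],
        "outputs": {},
    }
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise GeoconnError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
            logger.info("stage %s complete", name)

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.cohort is not None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seeds["simulate"])
            state["cohort"] = generate_cohort(cohort_cfg)
            (out / "config_echo.json").write_text(
                json.dumps(dataclasses.asdict(cohort_cfg), default=str, indent=2)
            )
        else:
            records = read_subjects(config.subjects_path)
            ts = [
                read_timeseries(
                    Path(config.timeseries_dir) / f"{r.subject_id}_timeseries.csv",
                    r.subject_id,
                )
                for r in records
            ]
            motion = [
                read_motion(
                    Path(config.motion_dir) / f"{r.subject_id}_motion.csv", r.subject_id
                )
                for r in records
            ]
            state["cohort"] = Cohort(records, ts, motion)

    @stage("qc")
    def _qc():
        cohort: Cohort = state["cohort"]
        rows = []
        for rec, ts, tr in zip(cohort.records, cohort.timeseries, cohort.motion):
            summ = qc_mod.framewise_displacement(tr)
            _, mean_dv = qc_mod.dvars(ts)
            rec.mean_fd = summ.mean_fd
            rec.mean_dvars = mean_dv
            rows.append(
                {"subject_id": rec.subject_id, "group": rec.group,
                 "mean_fd": summ.mean_fd, "mean_dvars": mean_dv}
            )
        qc_df = pd.DataFrame(rows)
        f, dfs, p = qc_mod.qc_group_balance(qc_df["mean_fd"], qc_df["group"])
        bundle["qc"] = qc_df
        bundle["qc_balance"] = {"F": f, "df": dfs, "p": p}
        qc_df.to_csv(out / "qc.csv", index=False)
        write_subjects(cohort.records, out / "subjects.csv")

    @stage("subtype")
    def _subtype():
        cohort: Cohort = state["cohort"]
        designs = {s: build_design(cohort.records, s) for s in config.schemes}
        state["designs"] = designs
        rows = []
        for s, d in designs.items():
            for sid, lab in d.labels.items():
                rows.append({"scheme": s, "subject_id": sid, "label": lab})
        labels_df = pd.DataFrame(rows)
        bundle["designs"] = designs
        labels_df.to_csv(out / "labels.csv", index=False)

    @stage("connectivity")
    def _connectivity():
        cohort: Cohort = state["cohort"]
        evs = compute_edge_vectors(cohort.timeseries, config.connectivity)
        state["edge_vectors"] = evs
        long = []
        for ev in evs:
            for (ci, cj), v in zip(ev.labels, ev.values):
                long.append(
                    {"subject_id": ev.subject_id, "comp_i": ci, "comp_j": cj, "zvalue": v}
                )
        edges_df = pd.DataFrame(long)
        bundle["edges"] = edges_df
        edges_df.to_csv(out / "edges.csv", index=False)

    @stage("group_diff")
    def _group_diff():
        cohort: Cohort = state["cohort"]
        design = state["designs"][config.omnibus_scheme]
        rec_by_id = {r.subject_id: r for r in cohort.records}
        evs = state["edge_vectors"]
        ids = [ev.subject_id for ev in evs if ev.subject_id in design.labels]
        labels = [design.labels[i] for i in ids]
        covars = pd.DataFrame(
            {
                "age_scan_months": [rec_by_id[i].age_scan_months for i in ids],
                "sex_male": [1.0 if rec_by_id[i].sex == "M" else 0.0 for i in ids],
            }
        )
        ev_by_id = {ev.subject_id: ev for ev in evs}
        edge_names = evs[0].labels
        rows = []
        for e_idx, edge in enumerate(edge_names):
            y = np.array([ev_by_id[i].values[e_idx] for i in ids])
            fit = fit_edge_glm(
                y, labels, covars,
                continuous=config.omnibus_scheme == "transdiagnostic", edge=edge,
            )
            rows.append(
                {"comp_i": edge[0], "comp_j": edge[1], "F": fit.omnibus_F,
                 "df1": fit.df[0], "df2": fit.df[1], "p": fit.p_value,
                 "partial_eta_sq": fit.partial_eta_sq}
            )
        omnibus = pd.DataFrame(rows)
        reject, adj = fdr_bh(omnibus["p"].to_numpy(), q=config.fdr_q)
        omnibus["fdr_q"] = adj
        omnibus["significant"] = reject
        bundle["omnibus"] = omnibus
        omnibus.to_csv(out / "omnibus.csv", index=False)

        # pairwise permutation follow-up on surviving edges
        pair_rows = []
        uniq = sorted({str(v) for v in labels})
        surviving = [tuple(r) for r in omnibus.loc[reject, ["comp_i", "comp_j"]].to_numpy()]
        rng = np.random.default_rng(stage_seeds["group_diff"])
        for edge in surviving:
            e_idx = edge_names.index(edge)
            y = np.array([ev_by_id[i].values[e_idx] for i in ids])
            edge_ps = []
            for a_i in range(len(uniq)):
                for b_i in range(a_i + 1, len(uniq)):
                    pc = permutation_pairwise(
                        y, labels, uniq[a_i], uniq[b_i], covars,
                        n_perm=config.n_perm,
                        seed=int(rng.integers(2**31)),
                        edge=edge,
                    )
                    edge_ps.append(pc)
            _, qvals = fdr_bh([pc.perm_p for pc in edge_ps], q=config.fdr_q)
            for pc, qv in zip(edge_ps, qvals):
                pc.fdr_q = float(qv)
                pair_rows.append(
                    {"comp_i": edge[0], "comp_j": edge[1], "group_a": pc.group_a,
                     "group_b": pc.group_b, "cohens_d": pc.cohens_d,
                     "perm_p": pc.perm_p, "fdr_q": pc.fdr_q, "n_perm": pc.n_perm}
                )
        pairwise = pd.DataFrame(
            pair_rows,
            columns=["comp_i", "comp_j", "group_a", "group_b", "cohens_d",
                     "perm_p", "fdr_q", "n_perm"],
        )
        bundle["pairwise"] = pairwise
        pairwise.to_csv(out / "pairwise.csv", index=False)

    @stage("model_compare")
    def _model_compare():
        cohort: Cohort = state["cohort"]
        evs = state["edge_vectors"]
        edge_names = evs[0].labels
        rows = []
        targets = [e for e in edge_names if "DMN" in e] or edge_names
        for edge in targets:
            e_idx = edge_names.index(edge)
            series = pd.Series(
                {ev.subject_id: ev.values[e_idx] for ev in evs}
            )
            report = compare_models(
                series, cohort.records, schemes=config.schemes,
                k=config.cv_folds, seed=stage_seeds["model_compare"], edge=edge,
            )
            for s, fit in report.fits.items():
                rows.append(
                    {"comp_i": edge[0], "comp_j": edge[1], "scheme": s,
                     "aic": fit.aic, "delta_aic": fit.delta_aic,
                     "support": fit.support, "mape_mean": fit.mape_mean,
                     "n_subjects": report.n_subjects}
                )
        comparison = pd.DataFrame(rows)
        bundle["model_comparison"] = comparison
        comparison.to_csv(out / "model_comparison.csv", index=False)

    @stage("brain_behavior")
    def _brain_behavior():
        cohort: Cohort = state["cohort"]
        evs = state["edge_vectors"]
        edge_names = evs[0].labels
        edge = tuple(config.behavior_edge)
        if edge not in edge_names:
            edge = (edge[1], edge[0])
        e_idx = edge_names.index(edge)
        ev_by_id = {ev.subject_id: ev for ev in evs}
        rows = []
        results = []
        rng = np.random.default_rng(stage_seeds["brain_behavior"])
        for grp in config.behavior_groups:
            recs = [r for r in cohort.records if r.group == grp and r.ados_sa is not None]
            e = np.array([ev_by_id[r.subject_id].values[e_idx] for r in recs])
            b = np.array([r.ados_sa for r in recs])
            age = np.array([r.age_scan_months for r in recs])
            res = robust_partial_correlation(e, b, age, group=grp, edge=edge)
            lo, hi = bootstrap_ci(
                e, b, age, n_boot=config.n_boot, seed=int(rng.integers(2**31))
            )
            res.ci_low, res.ci_high, res.n_boot = lo, hi, config.n_boot
            results.append(res)
            rows.append(
                {"group": grp, "comp_i": edge[0], "comp_j": edge[1], "r": res.r,
                 "p": res.p_value, "n": res.n, "ci_low": lo, "ci_high": hi,
                 "n_boot": config.n_boot}
            )
        if len(results) == 2:
            z, p = compare_correlations(
                results[0].r, results[0].n, results[1].r, results[1].n
            )
            bundle["bb_difference"] = {"z": z, "p": p}
        bb = pd.DataFrame(rows)
        bundle["brain_behavior"] = bb
        bb.to_csv(out / "brain_behavior.csv", index=False)

    @stage("power")
    def _power():
        d_min = min_detectable_d(
            config.power_n1, config.power_n2, config.power_alpha, config.power_target
        )
        sim = empirical_power(
            d_min, config.power_n1, config.power_n2, config.power_alpha,
            config.power_nexp, seed=stage_seeds["power"],
        )
        power_df = pd.DataFrame(
            [
                {"method": "analytic", "d": d_min, "n1": config.power_n1,
                 "n2": config.power_n2, "alpha": config.power_alpha,
                 "power": analytic_power(d_min, config.power_n1, config.power_n2,
                                          config.power_alpha)},
                {"method": "simulation", "d": d_min, "n1": config.power_n1,
                 "n2": config.power_n2, "alpha": config.power_alpha,
                 "power": sim.power_hat},
            ]
        )
        bundle["power"] = power_df
        power_df.to_csv(out / "power.csv", index=False)

    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
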