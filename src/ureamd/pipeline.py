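"""Pipeline orchestration and cross-protein aggregation.

``run_pipeline`` drives the per-protein analysis battery from a single config
(YAML file or dict): it loads a condition trajectory and a native-state
reference trajectory, runs the requested analysis stages, writes per-frame
metric CSVs and a deterministic ``summary.json`` whose headline numbers are
averages +/- sd over the last part of the trajectory (default 10 ns).
``aggregate_groups`` pools per-protein summaries into fold-group means, and
``condition_deltas`` forms condition-minus-water differences.
"""

from __future__ import annotations

import json
import logging
import os
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import contacts as ck
from . import dynamics as dyn
from . import hbonds as hb
from . import metrics as sm
from . import solvation as sv
from .system import load_topology, load_trajectory, classify_system

__all__ = [
    "run_pipeline",
    "aggregate_groups",
    "condition_deltas",
    "load_scop_groups",
    "DEFAULT_PARAMETERS",
]

logger = logging.getLogger("ureamd")

DEFAULT_PARAMETERS = {
    "contact_cutoff": 3.5,
    "min_seq_sep": 3,
    "native_occupancy_threshold": 0.80,
    "opening_shift_threshold_ns": 0.1,
    "fss_cutoff": 5.0,
    "bulk_cutoff": 6.0,
    "hbond_dist_cutoff": 3.50,
    "hbond_angle_cutoff_deg": 120.0,
    "hbond_min_occupancy_ns": 0.5,
    "sasa_probe": 1.4,
    "sasa_n_points": 960,
    "structure_index_mode": "mean",
    "summary_window_ns": 10.0,
    "residence_min_long_ns": 1.0,
}

ALL_ANALYSES = ("metrics", "contacts", "solvation", "hbonds", "dynamics")


def _window_stats(values: np.ndarray, times: np.ndarray, window_ns: float):
    t_end = times[-1]
    mask = times >= t_end - window_ns
    v = np.asarray(values, dtype=float)[mask]
    return {"mean": float(np.mean(v)), "sd": float(np.std(v)),
            "n_frames": int(mask.sum())}


def _write_series(out_dir, name, series: sm.MetricSeries):
    df = pd.DataFrame({"time_ns": series.times, "value": series.values})
    df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)


def run_pipeline(config) -> dict:
    """Run the configured analyses; returns the summary dict (also written
    as ``summary.json``).  ``config`` is a YAML path or a mapping with keys
    topology, trajectory, reference_trajectory, dt_ns, output_dir, analyses
    and an optional ``parameters`` override block."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    missing = [k for k in ("topology", "trajectory", "output_dir") if k not in config]
    if missing:
        raise ValueError(f"missing required config keys: {missing}")
    params = dict(DEFAULT_PARAMETERS)
    params.update(config.get("parameters", {}))
    analyses = tuple(config.get("analyses", ALL_ANALYSES))
    out_dir = config["output_dir"]
    os.makedirs(out_dir, exist_ok=True)

    handler = logging.FileHandler(os.path.join(out_dir, "pipeline.log"))
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, params, analyses, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config, params, analyses, out_dir) -> dict:
    import ureamd

    dt = config.get("dt_ns")
    logger.info("ureamd %s; parameters: %s", ureamd.__version__,
                json.dumps(params, sort_keys=True))
    system = classify_system(load_topology(config["topology"]),
                             config.get("classification"))
    traj = _stage("load trajectory", load_trajectory,
                  config["trajectory"], system, dt)
    ref_traj = None
    if config.get("reference_trajectory"):
        ref_traj = _stage("load reference", load_trajectory,
                          config["reference_trajectory"], system, dt)
    window = params["summary_window_ns"]
    summary: dict = {"parameters": params, "analyses": list(analyses),
                     "n_frames": traj.n_frames,
                     "duration_ns": traj.duration_ns}
    native_frame = (ref_traj.coordinates[0] if ref_traj is not None
                    else traj.coordinates[0])

    s2_series_vals = s3 = None
    if "metrics" in analyses:
        prot_heavy = system.protein_heavy_indices()
        rmsd = _stage("rmsd", sm.rmsd_series, traj, native_frame, prot_heavy)
        rg = _stage("radgyr", sm.rg_series, system=system, traj=traj)
        _write_series(out_dir, "rmsd", rmsd)
        _write_series(out_dir, "radgyr", rg)
        summary["rmsd"] = _window_stats(rmsd.values, rmsd.times, window)
        summary["radgyr"] = _window_stats(rg.values, rg.times, window)
        ca = [i for i, a in enumerate(system.atoms)
              if a.name == "CA" and system.protein_atom_mask[i]]
        if len(ca) >= 16:
            tm = np.array([sm.tm_score(native_frame[ca],
                                       traj.coordinates[f][ca])
                           for f in range(traj.n_frames)])
            _write_series(out_dir, "tmscore",
                          sm.MetricSeries("TMscore", tm, traj.times, "score"))
            summary["tmscore"] = _window_stats(tm, traj.times, window)
        sasa_vals, polar_vals, apolar_vals = [], [], []
        for f in range(traj.n_frames):
            areas = sm.sasa(traj.coordinates[f], system,
                            probe=params["sasa_probe"],
                            n_points=params["sasa_n_points"])
            total, polar, apolar, _ = sm.sasa_partition(areas, system)
            sasa_vals.append(total)
            polar_vals.append(polar)
            apolar_vals.append(apolar)
        for name, vals in (("sasa", sasa_vals), ("sasa_polar", polar_vals),
                           ("sasa_apolar", apolar_vals)):
            _write_series(out_dir, name,
                          sm.MetricSeries(name, np.array(vals), traj.times,
                                          "Angstrom^2"))
            summary[name] = _window_stats(np.array(vals), traj.times, window)
        native_ss = sm.assign_ss(native_frame, system)
        ss = sm.assign_ss_series(traj, system)
        s2_vals = np.array([sm.s2_index(ss[f], native_ss)
                            for f in range(traj.n_frames)])
        s2_series_vals = s2_vals
        _write_series(out_dir, "s2",
                      sm.MetricSeries("S2", s2_vals, traj.times, "fraction"))
        summary["s2"] = _window_stats(s2_vals, traj.times, window)

    if "contacts" in analyses:
        ref_for_native = ref_traj if ref_traj is not None else traj
        ref_tl = _stage("reference contacts", ck.contact_timeline,
                        ref_for_native, system,
                        cutoff=params["contact_cutoff"],
                        min_seq_sep=params["min_seq_sep"])
        native = ck.native_contact_set(ref_tl,
                                       params["native_occupancy_threshold"])
        tl = _stage("contacts", ck.contact_timeline, traj, system,
                    cutoff=params["contact_cutoff"],
                    min_seq_sep=params["min_seq_sep"])
        s3 = ck.s3_series(tl, native)
        _write_series(out_dir, "s3", s3)
        summary["s3"] = _window_stats(s3.values, s3.times, window)
        summary["n_native_contacts"] = len(native)
        ostats = ck.opening_stats(tl, native)
        pd.DataFrame({"res_i": [p[0] for p in ostats.pairs],
                      "res_j": [p[1] for p in ostats.pairs],
                      "n_open": ostats.n_open,
                      "mean_open_ns": ostats.mean_open_ns,
                      "total_open_ns": ostats.total_open_ns}).to_csv(
            os.path.join(out_dir, "opening_stats.csv"), index=False)
        lost = ck.lost_time_per_residue(tl, native)
        pd.DataFrame({"residue": list(lost), "lost_pct": list(lost.values())}
                     ).to_csv(os.path.join(out_dir, "lost_time.csv"), index=False)
        if s2_series_vals is not None:
            mode = params["structure_index_mode"]
            si = np.array([sm.structure_index(a, b, mode) for a, b in
                           zip(s2_series_vals, s3.values)])
            _write_series(out_dir, "structure_index",
                          sm.MetricSeries("structure_index", si, traj.times,
                                          "fraction"))
            summary["structure_index"] = _window_stats(si, traj.times, window)
            summary["structure_index_mode"] = mode

    if "solvation" in analyses:
        has_solvent = bool(system.solvent_molecules())
        if has_solvent:
            assignment = _stage("shells", sv.shell_assign_series, traj, system,
                                fss_cutoff=params["fss_cutoff"],
                                bulk_cutoff=params["bulk_cutoff"])
            try:
                ratios = sv.shell_ratio_series(assignment, traj.times)
                pd.DataFrame({"time_ns": ratios.times,
                              "fss_ratio": ratios.fss_ratio,
                              "bulk_ratio": ratios.bulk_ratio}).to_csv(
                    os.path.join(out_dir, "shell_ratios.csv"), index=False)
                summary["fss_water_urea_ratio"] = {"mean": ratios.fss_mean,
                                                   "sd": ratios.fss_sd}
                summary["bulk_water_urea_ratio"] = {"mean": ratios.bulk_mean,
                                                    "sd": ratios.bulk_sd}
            except ValueError as exc:
                logger.warning("shell ratios skipped: %s", exc)
            for species in ("urea", "water"):
                if not system.solvent_molecules(species=species):
                    continue
                events = sv.residence_events(traj, system, species=species,
                                             cutoff=params["contact_cutoff"])
                durations = [e.duration_ns for e in events]
                summary[f"{species}_residence"] = {
                    "n_events": len(events),
                    "mean_ns": float(np.mean(durations)) if durations else 0.0,
                    "max_ns": float(np.max(durations)) if durations else 0.0,
                }
            try:
                coeffs, flagged = sv.cc_uw(traj, system,
                                           cutoff=params["contact_cutoff"])
                summary["cc_uw"] = {str(k): (None if np.isnan(v) else v)
                                    for k, v in sorted(coeffs.items())}
            except ValueError as exc:
                logger.warning("CC_UW skipped: %s", exc)

    if "hbonds" in analyses and system.solvent_molecules():
        try:
            records = _stage("hbonds", hb.hbond_occupancy, traj, system,
                             min_occupancy_ns=params["hbond_min_occupancy_ns"],
                             dist_cutoff=params["hbond_dist_cutoff"],
                             angle_cutoff_deg=params["hbond_angle_cutoff_deg"])
            pd.DataFrame([{"donor": r.key.donor, "acceptor": r.key.acceptor,
                           "donor_side": r.key.donor_side,
                           "protein_part": r.key.protein_part,
                           "total_ns": r.total_ns, "longest_ns": r.longest_ns,
                           "retained": r.retained} for r in records]).to_csv(
                os.path.join(out_dir, "hbonds.csv"), index=False)
            summary["hbond_partition"] = hb.hbond_partition(records)
        except ValueError as exc:
            logger.warning("hbond stage skipped: %s", exc)

    if "dynamics" in analyses:
        rmsf_per_res = _stage("rmsf", dyn.rmsf, traj, system)
        pd.DataFrame({"residue": list(rmsf_per_res),
                      "rmsf": list(rmsf_per_res.values())}).to_csv(
            os.path.join(out_dir, "rmsf.csv"), index=False)
        summary["rmsf_mean"] = float(np.mean(list(rmsf_per_res.values())))
        for species in ("urea", "water"):
            if not system.solvent_molecules(species=species):
                continue
            max_lag = traj.duration_ns / 2.0
            lags = np.linspace(0, max_lag, 21)[1:]
            curve = dyn.msd_curve(traj, system, species, lags)
            fit = dyn.diffusion_coefficient(curve)
            pd.DataFrame({"lag_ns": curve.lags_ns, "msd_A2": curve.msd,
                          "n_samples": curve.n_samples}).to_csv(
                os.path.join(out_dir, f"msd_{species}.csv"), index=False)
            summary[f"diffusion_{species}"] = {
                "D_A2_per_ns": fit.D, "r_squared": fit.r_squared,
                "flagged": fit.flagged}

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1,
                  default=lambda o: o.item() if hasattr(o, "item") else str(o))
    return summary


def _stage(name, fn, *args, **kwargs):
    try:
        logger.info("stage %s", name)
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# cross-protein aggregation

def aggregate_groups(per_protein_summaries: dict, labels: dict,
                     metrics=None) -> pd.DataFrame:
    """Group means +/- sd of per-protein scalar metrics.

    ``per_protein_summaries`` maps protein name -> summary dict (as returned
    by :func:`run_pipeline`); ``labels`` maps protein name -> group label.
    Metrics default to every key with a ``mean`` entry.
    """
    rows = []
    for prot, summ in per_protein_summaries.items():
        if prot not in labels:
            raise ValueError(f"no group label for protein {prot!r}")
        for key, val in summ.items():
            if metrics is not None and key not in metrics:
                continue
            if isinstance(val, dict) and "mean" in val:
                rows.append({"protein": prot, "group": labels[prot],
                             "metric": key, "value": val["mean"]})
            elif isinstance(val, (int, float)) and metrics is not None:
                rows.append({"protein": prot, "group": labels[prot],
                             "metric": key, "value": float(val)})
    if not rows:
        raise ValueError("no aggregatable metrics found")
    df = pd.DataFrame(rows)
    agg = df.groupby(["group", "metric"])["value"].agg(
        mean="mean", sd=lambda x: float(np.std(x)), n="count").reset_index()
    return agg


def condition_deltas(summary_condition: dict, summary_water: dict) -> dict:
    """(condition - water) differences for every shared scalar metric."""
    out = {}
    for key, val in summary_condition.items():
        ref = summary_water.get(key)
        if isinstance(val, dict) and "mean" in val and isinstance(ref, dict):
            out[key] = val["mean"] - ref["mean"]
    return out


def load_scop_groups() -> pd.DataFrame:
    """Convenience PDB-code -> fold-group table for the 30 reference folds."""
    with resources.files("ureamd.data").joinpath("scop_groups.csv").open() as fh:
        return pd.read_csv(fh)
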