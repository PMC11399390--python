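"""Experiment orchestration, session file I/O, and population statistics.

Ties the analysis stages into the three experiment designs: a baseline
square session (GLM classification), the square/L-shape geometry
manipulation (globality index and inserted-wall firing change), and the
A1/AB/A2 cue-duplication experiment (bidirectionality and cue-modulation
indices). All stochastic stages derive their seeds from the run seed, so
a run is fully reproducible.

Session file set: tracking as ``tracking.csv`` (header ``t,x,y,hd``;
seconds, cm, degrees), one ``<cell>_spikes.csv`` per cell (header ``t``),
and a ``session.yaml`` with the arena tag and session label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu, wilcoxon

from .arena import l_arena, square_arena
from .glm import GLMConfig, classify_cell
from .localglobal import globality_for_cell
from .maps import occupancy_ratemap, wall_proximity_change
from .session import Session, SpikeTrain, Trajectory, compute_covariates
from .synth import CellSpec, make_cue_experiment, make_synthetic_session
from .tuning import (bidirectionality_index, fit_bidirectional_von_mises,
                     angular_tuning_curve, modulation_indices)

__all__ = [
    "RunConfig", "PopulationReport", "run_experiment",
    "read_session", "write_session", "write_report",
]

PUBLICATION_SHUFFLES = {"classify": 400, "symmetry": 100}


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    experiment: str                    # "baseline" | "geometry" | "cue"
    seed: int = 0
    duration_s: float = 1200.0
    cell_specs: dict = field(default_factory=dict)
    n_shuffles_classify: int = 400
    n_shuffles_symmetry: int = 100
    alpha: float = 0.05
    modulation_fraction: float = 0.5   # cue experiment
    n_repeats: int = 1                 # independent simulated animals/pairs
    glm: GLMConfig = field(default_factory=GLMConfig)

    def __post_init__(self):
        if self.experiment not in ("baseline", "geometry", "cue"):
            raise ValueError(f"unknown experiment {self.experiment!r}")

    @property
    def reduced_shuffles(self) -> bool:
        return (self.n_shuffles_classify < PUBLICATION_SHUFFLES["classify"]
                or self.n_shuffles_symmetry < PUBLICATION_SHUFFLES["symmetry"])

    def hash(self) -> str:
        spec_repr = {k: repr(v) for k, v in sorted(self.cell_specs.items())}
        payload = json.dumps({
            "experiment": self.experiment, "seed": self.seed,
            "duration_s": self.duration_s, "specs": spec_repr,
            "shuffles": [self.n_shuffles_classify, self.n_shuffles_symmetry],
            "alpha": self.alpha, "mod": self.modulation_fraction,
            "repeats": self.n_repeats,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PopulationReport:
    """Per-cell metric tables plus population-level tests and provenance."""

    tables: dict                       # name -> DataFrame
    tests: dict                        # name -> {statistic, p, n, sided, kind}
    config_hash: str
    seed: int
    reduced_shuffles: bool
    errors: dict = field(default_factory=dict)


def _paired_test(a, b, name, sided="two-sided"):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 5 or np.allclose(a[ok], b[ok]):
        return {"name": name, "statistic": float("nan"), "p": float("nan"),
                "n": int(ok.sum()), "sided": sided, "kind": "signed-rank"}
    res = wilcoxon(a[ok], b[ok], alternative=sided, zero_method="zsplit")
    return {"name": name, "statistic": float(res.statistic),
            "p": float(res.pvalue), "n": int(ok.sum()), "sided": sided,
            "kind": "signed-rank"}


def _unpaired_test(a, b, name, sided="two-sided"):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        return {"name": name, "statistic": float("nan"), "p": float("nan"),
                "n": [len(a), len(b)], "sided": sided, "kind": "rank-sum"}
    res = mannwhitneyu(a, b, alternative=sided)
    return {"name": name, "statistic": float(res.statistic),
            "p": float(res.pvalue), "n": [len(a), len(b)], "sided": sided,
            "kind": "rank-sum"}


# ---------------------------------------------------------------------------
# experiments

def _run_baseline(config: RunConfig):
    rows, errors = [], {}
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(config.n_repeats)
    glm_cfg = GLMConfig(n_shuffles=config.n_shuffles_classify,
                        alpha=config.alpha)
    for rep, rseed in enumerate(seeds):
        sseed = int(rseed.generate_state(1)[0] % (2 ** 31))
        syn = make_synthetic_session(square_arena(), config.duration_s,
                                     config.cell_specs, sseed, label="Square1")
        for name in syn.session.cells:
            try:
                cls = classify_cell(syn.session, name, glm_cfg, seed=sseed + 1,
                                    covariates=syn.covariates)
                rows.append({
                    "repeat": rep, "cell": name,
                    "true_class": syn.specs[name].cell_class,
                    "selected": (",".join(cls.selected)
                                 if isinstance(cls.selected, tuple) else cls.selected),
                    "is_eb": cls.is_eb, "is_hd": cls.is_hd,
                    "bearing_mvl": cls.bearing_mvl,
                    "bearing_peak_hz": cls.bearing_peak_hz,
                    "hd_mvl": cls.hd_mvl,
                })
            except Exception as exc:       # isolate per-cell failures
                errors[f"rep{rep}/{name}"] = repr(exc)
    return {"classification": pd.DataFrame(rows)}, {}, errors


def _run_geometry(config: RunConfig):
    rows, errors = [], {}
    ss = np.random.SeedSequence(config.seed)
    for rep, rseed in enumerate(ss.spawn(config.n_repeats)):
        s1, s2 = (int(s.generate_state(1)[0] % (2 ** 31)) for s in rseed.spawn(2))
        sq = make_synthetic_session(square_arena(), config.duration_s,
                                    config.cell_specs, s1, label="Square1")
        lsh = make_synthetic_session(l_arena(), config.duration_s,
                                     config.cell_specs, s2, label="L")
        for name in sq.session.cells:
            try:
                g_sq = globality_for_cell(sq.session, name, config.glm,
                                          covariates=sq.covariates)
                g_l = globality_for_cell(lsh.session, name, config.glm,
                                         covariates=lsh.covariates)
                m_sq = occupancy_ratemap(sq.session, name)
                m_l = occupancy_ratemap(lsh.session, name)
                near, far = wall_proximity_change(m_sq, m_l, lsh.session.arena)
                rows.append({
                    "repeat": rep, "cell": name,
                    "true_class": sq.specs[name].cell_class,
                    "gi_square": g_sq.gi, "gi_l": g_l.gi,
                    "delta_gi": g_l.gi - g_sq.gi,
                    "near_wall_delta": near, "far_wall_delta": far,
                })
            except Exception as exc:
                errors[f"rep{rep}/{name}"] = repr(exc)
    df = pd.DataFrame(rows)
    tests = {}
    if len(df) >= 5:
        tests["delta_gi_vs_zero"] = _paired_test(df["delta_gi"],
                                                 np.zeros(len(df)),
                                                 "delta GI square->L vs 0")
        tests["near_vs_far_wall_delta"] = _paired_test(df["near_wall_delta"],
                                                       df["far_wall_delta"],
                                                       "near vs far inserted-wall change")
    return {"globality": df}, tests, errors


def _run_cue(config: RunConfig):
    rows, errors = [], {}
    ss = np.random.SeedSequence(config.seed)
    for rep, rseed in enumerate(ss.spawn(config.n_repeats)):
        sessions = make_cue_experiment(config.cell_specs,
                                       int(rseed.generate_state(1)[0] % (2 ** 31)),
                                       duration_s=config.duration_s,
                                       modulation_fraction=config.modulation_fraction)
        covs = {lbl: syn.covariates for lbl, syn in sessions.items()}
        for name in sessions["A1"].session.cells:
            try:
                bi = {lbl: bidirectionality_index(syn.session, name, covs[lbl])
                      for lbl, syn in sessions.items()}
                a1 = sessions["A1"]
                counts_a1 = a1.session.cells[name].binned_counts(a1.session.n_frames)
                pfd_a1 = angular_tuning_curve(covs["A1"].hd, counts_a1,
                                              valid=covs["A1"].valid).pfd
                ab = sessions["AB"]
                counts_ab = ab.session.cells[name].binned_counts(ab.session.n_frames)
                curve_ab = angular_tuning_curve(covs["AB"].hd, counts_ab,
                                                valid=covs["AB"].valid)
                fit = fit_bidirectional_von_mises(curve_ab, "upright")
                mi_a, mi_b = modulation_indices(fit, pfd_a1)
                rows.append({
                    "repeat": rep, "cell": name,
                    "bi_a1": bi["A1"], "bi_ab": bi["AB"], "bi_a2": bi["A2"],
                    "delta_bi_ab": bi["AB"] - bi["A1"],
                    "delta_bi_a2": bi["A2"] - bi["A1"],
                    "mi_a": mi_a, "mi_b": mi_b,
                })
            except Exception as exc:
                errors[f"rep{rep}/{name}"] = repr(exc)
    df = pd.DataFrame(rows)
    tests = {}
    if len(df) >= 5:
        tests["bi_ab_vs_a1"] = _paired_test(df["bi_ab"], df["bi_a1"],
                                            "BI in AB vs A1")
        tests["bi_ab_vs_a2"] = _paired_test(df["bi_ab"], df["bi_a2"],
                                            "BI in AB vs A2")
        tests["mi_a_vs_mi_b"] = _paired_test(df["mi_a"], df["mi_b"],
                                             "cue-A vs cue-B modulation")
    return {"cue": df}, tests, errors


def run_experiment(config: RunConfig) -> PopulationReport:
    """Execute the stage graph for one experiment configuration.

    Per-cell failures are recorded and do not abort the run. The report
    is deterministic given the config (including its seed).
    """
    runner = {"baseline": _run_baseline, "geometry": _run_geometry,
              "cue": _run_cue}[config.experiment]
    tables, tests, errors = runner(config)
    return PopulationReport(tables, tests, config.hash(), config.seed,
                            config.reduced_shuffles, errors)


# ---------------------------------------------------------------------------
# session file I/O

def write_session(session: Session, out_dir) -> None:
    """Write a session as the plain-text file set (CSV + YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj = session.trajectory
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y, "hd": traj.hd}).to_csv(
        out / "tracking.csv", index=False, float_format="%.9f")
    for name, st in session.cells.items():
        pd.DataFrame({"t": st.spike_times}).to_csv(
            out / f"{name}_spikes.csv", index=False, float_format="%.9f")
    meta = {"arena": session.arena.shape_tag, "label": session.label,
            "cells": sorted(session.cells),
            "units": {"t": "s", "x": "cm", "y": "cm", "hd": "deg"}}
    (out / "session.yaml").write_text(yaml.safe_dump(meta))


def read_session(in_dir) -> tuple[Session, dict]:
    """Read a session file set; returns ``(session, qc)``.

    ``qc`` counts tracking rows outside the arena polygon (excluded
    downstream via the covariate validity mask) and spikes past the end
    of the session (dropped). Malformed rows raise with line numbers.
    """
    src = Path(in_dir)
    meta = yaml.safe_load((src / "session.yaml").read_text())
    arena = {"square": square_arena, "L": l_arena}[meta["arena"]]()
    df = pd.read_csv(src / "tracking.csv")
    expected = ["t", "x", "y", "hd"]
    if list(df.columns) != expected:
        raise ValueError(f"tracking.csv: expected header {expected}, got {list(df.columns)}")
    bad = df.index[df.isna().any(axis=1) | ~np.isfinite(df).all(axis=1)]
    if len(bad):
        raise ValueError(f"tracking.csv: malformed rows at lines {[int(b) + 2 for b in bad[:10]]}")
    traj = Trajectory(df["t"].to_numpy(), df["x"].to_numpy(),
                      df["y"].to_numpy(), df["hd"].to_numpy())
    outside = int((~arena.contains(traj.x, traj.y)).sum())
    duration = traj.duration
    cells, dropped = {}, {}
    for name in meta["cells"]:
        sdf = pd.read_csv(src / f"{name}_spikes.csv")
        if list(sdf.columns) != ["t"]:
            raise ValueError(f"{name}_spikes.csv: expected header ['t']")
        st = sdf["t"].to_numpy(float)
        keep = (st >= 0) & (st < duration)
        dropped[name] = int((~keep).sum())
        cells[name] = SpikeTrain(st[keep])
    session = Session(arena, traj, cells, label=meta.get("label", ""))
    return session, {"tracking_rows_outside": outside, "spikes_dropped": dropped}


def write_report(report: PopulationReport, out_dir) -> None:
    """Write the population report: one TSV per table plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# config={report.config_hash} seed={report.seed} "
              f"reduced_shuffles={report.reduced_shuffles}\n")
    for name, df in report.tables.items():
        path = out / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    summary = {"config_hash": report.config_hash, "seed": report.seed,
               "reduced_shuffles": report.reduced_shuffles,
               "tests": report.tests, "errors": report.errors}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
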