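"""End-to-end pipeline: sweep -> mapping -> uniqueness -> whisking demo.

Each stage logs its timing and record counts (converged / discarded /
excluded), writes its artifacts into the output directory, and the resolved
configuration is saved next to them so any run can be reproduced from its
own output directory and seed alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from .config import RunConfig
from .errors import WhiskmapError

log = logging.getLogger("whiskmap")


def build_whisker(cfg: RunConfig):
    from . import geometry

    w = cfg.whisker
    if w.points_file:
        from .geometry import MaterialParams

        mat = MaterialParams(w.youngs_modulus_gpa, w.poisson_ratio,
                             w.base_radius_um, w.taper_ratio)
        return geometry.load_whisker_points(w.points_file, mat, w.n_nodes)
    return geometry.build_gamma_like_whisker(
        arc_length_mm=w.arc_length_mm, taper_ratio=w.taper_ratio,
        base_radius_um=w.base_radius_um, quad_coeff=w.quad_coeff,
        oop_cubic_coeff=w.oop_cubic_coeff, n_nodes=w.n_nodes,
        youngs_modulus_gpa=w.youngs_modulus_gpa,
        poisson_ratio=w.poisson_ratio)


def build_table(cfg: RunConfig, whisker):
    from .elastica import reachable_space
    from .mapping import build_grid

    g = cfg.grid
    grid = build_grid((g.r_min_mm, g.r_max_mm), g.r_step_mm,
                      (g.theta_min_deg, g.theta_max_deg), g.theta_step_deg,
                      (g.phi_min_deg, g.phi_max_deg), g.phi_step_deg)
    return reachable_space(whisker, grid, cone_deg=g.cone_deg)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    A stage failure is logged with context and downstream stages are skipped
    (WhiskmapError is re-raised so callers can exit non-zero).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "resolved_config.yaml")
    stages = {}

    def stage(name):
        def deco(fn):
            stages[name] = fn
            return fn

        return deco

    state = {}

    @stage("sweep")
    def _sweep():
        state["whisker"] = build_whisker(cfg)
        from .geometry import save_whisker_points

        save_whisker_points(state["whisker"], out / "whisker.csv")
        table = build_table(cfg, state["whisker"])
        state["table"] = table
        df = table.df
        log.info("sweep: %d grid points, %d converged, %d discarded, "
                 "%d excluded (small deflection)", len(df),
                 int(df["converged"].sum()),
                 int((~df["converged"]).sum()),
                 int((df["converged"] & df["excluded_small_deflection"]).sum()))
        table.save_csv(out / "mapping.csv")
        table.save_hdf5(out / "mapping.h5")

    @stage("uniqueness")
    def _uniqueness():
        if not cfg.uniqueness.run:
            return
        from .io import save_reports_json
        from .uniqueness import UniquenessThresholds, uniqueness_survey

        u = cfg.uniqueness
        thr = UniquenessThresholds(u.median_r_mm, u.median_angle_deg,
                                   u.eps_sig, u.eps_cp_mm)
        base = cfg.child_seed("uniqueness")
        reports = uniqueness_survey(state["table"], region=u.region,
                                    thresholds=thr,
                                    seeds=tuple(base + i for i in range(u.n_seeds)),
                                    min_records=u.min_records)
        n_unique = sum(r.verdict == "unique" for r in reports)
        log.info("uniqueness: %d/20 triplets unique in region %s",
                 n_unique, u.region)
        save_reports_json(reports, out / "uniqueness.json")
        state["reports"] = reports

    @stage("demo")
    def _demo():
        if not cfg.whisk.run:
            return
        from .io import save_trajectory_csv
        from .mapping import TripletSpec
        from .whisking import (PegModel, WhiskParams, lowpass_basepose,
                               reconstruct_peg, synth_whisk_trial,
                               trial_to_signals)

        w = cfg.whisk
        peg = PegModel(w.peg_x_mm, w.peg_y_mm, w.peg_diameter_mm)
        params = WhiskParams(amplitude_deg=w.amplitude_deg,
                             frequency_hz=w.frequency_hz, n_cycles=w.n_cycles,
                             elevation_amp_deg=w.elevation_amp_deg,
                             basepoint_jitter_mm=w.basepoint_jitter_mm,
                             angle_jitter_deg=w.angle_jitter_deg,
                             slip_max_deg=w.slip_max_deg)
        traj = synth_whisk_trial(state["whisker"], peg, params,
                                 seed=cfg.child_seed("whisk"))
        traj = lowpass_basepose(traj, w.cutoff_hz)
        save_trajectory_csv(traj, out / "trajectory.csv")
        signals = trial_to_signals(traj, state["whisker"],
                                   cone_deg=cfg.grid.cone_deg)
        signals.to_csv(out / "trial_signals.csv", index=False)
        spec = TripletSpec(tuple(w.triplet.split(",")))
        rec = reconstruct_peg(signals, traj, state["table"], spec)
        rec.frames.to_csv(out / "reconstruction.csv", index=False)
        log.info("demo: %d contact frames, %d reconstructed, "
                 "median radial error %.2f mm, median angular error %.2f mm",
                 int(traj.in_contact.sum()), rec.n_frames,
                 rec.median_radial_error_mm, rec.median_angular_error_mm)
        state["signals"] = signals
        state["trajectory"] = traj

    @stage("sensitivity")
    def _sensitivity():
        if not cfg.sensitivity.run:
            return
        from .io import save_sensitivity_json
        from .sensitivity import jacobian_field, signal_envelope, trim_and_bin

        env = None
        if not cfg.sensitivity.full_table_envelope and "signals" in state:
            sig = state["signals"]
            sig = sig[sig["in_contact"] & sig["converged"]]
            if len(sig) >= 10:
                env = signal_envelope(sig, pad=0.0)
        field = jacobian_field(state["table"], envelope=env)
        if env is not None and field.n_probes < 300:
            # behavioral envelope holds too few table samples at this grid
            # resolution; fall back to the full-table envelope
            log.info("sensitivity: only %d probes in the behavioral envelope;"
                     " using the full-table envelope", field.n_probes)
            field = jacobian_field(state["table"], envelope=None)
        binned = trim_and_bin(field, n_bins=cfg.sensitivity.n_bins,
                              trim=cfg.sensitivity.trim)
        save_sensitivity_json(binned, out / "sensitivity.json")
        log.info("sensitivity: %d probes, method=%s", field.n_probes,
                 field.metadata["interpolation"])

    order = ["sweep", "uniqueness", "demo", "sensitivity"]
    for name in order:
        t0 = time.time()
        try:
            stages[name]()
        except WhiskmapError:
            log.exception("stage %s failed; skipping downstream stages", name)
            raise
        log.info("stage %s finished in %.1f s", name, time.time() - t0)
    (out / "run_summary.json").write_text(json.dumps(
        {"stages": order, "seed": cfg.seed}, indent=2))
    return out
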