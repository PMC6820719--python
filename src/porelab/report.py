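"""Comparative quantities and the pipeline orchestrator.

Mutant-vs-wild-type comparisons are reported three ways at once: the signed
percent change 100*(mutant - wt)/wt, the fold change mutant/wt (the two are
linked by fold = 1 + percent/100, asserted on every table row), and a
rendered narrative string ("decreased by 21%") with the percent rounded
half-away-from-zero to an integer — full precision stays in the numeric
columns. Translocation speed is expressed as dwell time per base, and the
diameter-dwell relation is summarised by Pearson (on a chosen transform) and
Spearman rank correlations.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .events import capture_rate, detect_events, fit_dwell_exponential
from .geometry import diameter_at_region, slice_radius_profile
from .io import ResultsTable, write_trace, write_trajectory
from .synthetic import (
    ChannelSpec,
    DriftDiffusionSpec,
    TraceSpec,
    gen_channel_structure,
    gen_current_trace,
    gen_ion_trajectory,
)
from .transport import compute_species_currents, density_profile, selectivity_ratio

__all__ = [
    "percent_change",
    "render_change",
    "fold_change",
    "per_base_time",
    "diameter_dwell_correlation",
    "comparison_table",
    "build_report",
    "DEFAULT_REPORT_CONFIG",
]

VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def percent_change(mutant: float, wt: float) -> float:
    """Signed relative change, 100 * (mutant - wt) / wt."""
    if wt == 0:
        raise InputError("percent change undefined for wt = 0")
    return 100.0 * (mutant - wt) / wt


def render_change(pct: float) -> str:
    """Narrative rendering with the magnitude rounded half-away-from-zero."""
    mag = math.floor(abs(pct) + 0.5)
    if mag == 0:
        return "unchanged"
    word = "increased" if pct > 0 else "decreased"
    return f"{word} by {mag}%"


def fold_change(mutant: float, wt: float) -> float:
    """mutant / wt."""
    if wt == 0:
        raise InputError("fold change undefined for wt = 0")
    return mutant / wt


def per_base_time(dwell_ms: float, n_bases: int) -> float:
    """Translocation time per base, dwell / n_bases (ms/base)."""
    if n_bases < 1:
        raise InputError("n_bases must be >= 1")
    return dwell_ms / n_bases


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def diameter_dwell_correlation(pairs, transform: str = "log-dwell") -> dict:
    """Pearson (on the chosen transform) and Spearman r for (diameter, dwell).

    ``transform="log-dwell"`` correlates diameter with ln(dwell), apt when
    dwell varies over decades; ``"linear"`` uses raw values. Spearman is the
    headline statistic since a monotone relation is the claim being tested.
    """
    pairs = [(float(d), float(t)) for d, t in pairs]
    if len(pairs) < 3:
        raise InputError("need >= 3 (diameter, dwell) pairs")
    d = np.array([p[0] for p in pairs])
    t = np.array([p[1] for p in pairs])
    if np.ptp(d) == 0 or np.ptp(t) == 0:
        return {"pearson_r": float("nan"), "spearman_r": float("nan"),
                "n": len(pairs), "constant_column": True}
    if transform == "log-dwell":
        if np.any(t <= 0):
            raise InputError("log-dwell transform needs positive dwell times")
        y = np.log(t)
    elif transform == "linear":
        y = t
    else:
        raise InputError(f"unknown transform {transform!r}")
    pear = stats.pearsonr(d, y).statistic
    spear = stats.spearmanr(d, t).statistic
    return {"pearson_r": float(pear), "spearman_r": float(spear),
            "n": len(pairs), "constant_column": False,
            "transform": transform}


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------

def comparison_table(rows, provenance=None) -> ResultsTable:
    """Build a ComparisonTable from (label, wt, mutant, units) rows.

    Each output row carries percent change, fold change and the narrative
    rendering; the identity fold = 1 + percent/100 is asserted per row.
    """
    out = []
    for label, wt, mutant, units in rows:
        pct = percent_change(mutant, wt)
        fold = fold_change(mutant, wt)
        assert np.isclose(fold, 1.0 + pct / 100.0, rtol=1e-12, atol=1e-12)
        out.append({
            "label": label, "wt_value": wt, "mutant_value": mutant,
            "percent_change": pct, "fold_change": fold,
            "rendered": render_change(pct), "units": units,
        })
    prov = {"operation": "comparison_table", "version": VERSION}
    prov.update(provenance or {})
    return ResultsTable(df=pd.DataFrame(out), provenance=prov)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

DEFAULT_REPORT_CONFIG = {
    "seed": 0,
    "channel": {"knots": [[0.0, 8.0], [50.0, 3.0], [100.0, 8.0]],
                "wall_atom_spacing_A": 2.0, "water_number_density": 3.0},
    "ions": {"n_ions_per_species": 50, "diffusion_A2_per_ps": 0.02,
             "mobility": 0.01, "field_mv_per_A": 1.5,
             "duration_ps": 4000.0, "frame_interval_ps": 20.0},
    "trace": {"open_current_pa": 61.5, "noise_sd_pa": 1.2,
              "event_rate_hz": 20.0, "dwell_mean_s": 2e-3,
              "blockade_depth": 0.5, "duration_s": 10.0,
              "sampling_rate_hz": 100000.0, "voltage_mv": 100.0},
    "mutant_trace": {"open_current_pa": 48.4, "noise_sd_pa": 1.2,
                     "event_rate_hz": 20.0, "dwell_mean_s": 8e-3,
                     "blockade_depth": 0.5, "duration_s": 10.0,
                     "sampling_rate_hz": 100000.0, "voltage_mv": 100.0},
    "regions_z": [25.0, 50.0, 75.0],
    "detection": {"k_sigma": 5.0, "min_dwell_s": 5e-5},
}


def build_report(config: dict | str | Path | None = None,
                 outdir: str | Path = "porelab_report") -> dict:
    """Run the full synthetic pipeline and write a provenance-carrying bundle.

    One call regenerates every table — radius profile, region diameters,
    per-species currents, ion densities, event tables, dwell/capture fits and
    the wt-vs-mutant comparison — deterministically for a fixed seed
    (reruns are byte-identical). Returns the paths written.
    """
    if config is None:
        config = DEFAULT_REPORT_CONFIG
    elif isinstance(config, (str, Path)):
        import tomllib
        with open(config, "rb") as fh:
            config = tomllib.load(fh)
    cfg = {**DEFAULT_REPORT_CONFIG, **config}
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _prov(op, **extra):
        p = {"operation": op, "version": VERSION, "seed": seed}
        p.update(extra)
        return p

    # --- geometry ---------------------------------------------------------
    channel = ChannelSpec(
        knots=[tuple(k) for k in cfg["channel"]["knots"]],
        wall_atom_spacing_A=cfg["channel"]["wall_atom_spacing_A"],
        water_number_density=cfg["channel"]["water_number_density"],
    )
    _, filled = gen_channel_structure(channel, seed=seed)
    profile = slice_radius_profile(filled, frames=[0])
    prof_df = pd.DataFrame({
        "z_A": profile.z_centers,
        "radius_mean_A": profile.radius_mean,
        "radius_sd_A": profile.radius_sd,
        "n_frames": profile.n_frames,
    })
    paths["profile"] = outdir / "profile.csv"
    ResultsTable(prof_df, _prov("slice_radius_profile")).to_csv(paths["profile"])

    diam_rows = []
    for z in cfg["regions_z"]:
        mean, sd = diameter_at_region(profile, z)
        diam_rows.append({"z_A": z, "diameter_mean_A": mean, "diameter_sd_A": sd})
    paths["diameters"] = outdir / "diameters.csv"
    ResultsTable(pd.DataFrame(diam_rows),
                 _prov("diameter_at_region", window_A=3.0)
                 ).to_csv(paths["diameters"])

    # --- transport --------------------------------------------------------
    ion_spec = DriftDiffusionSpec(seed=seed, **cfg["ions"])
    traj = gen_ion_trajectory(ion_spec, channel)
    est = compute_species_currents(traj)
    cur_df = pd.DataFrame([{
        "i_total_pa": est.i_total_pa, "i_k_pa": est.i_k_pa,
        "i_cl_pa": est.i_cl_pa, "sd_pa": est.sd_pa,
        "selectivity_cl": selectivity_ratio(est),
        "voltage_mv": est.voltage_mv, "n_frames": est.n_frames,
    }])
    paths["current"] = outdir / "current.csv"
    ResultsTable(cur_df, _prov("compute_species_currents")).to_csv(paths["current"])

    dens_rows = []
    for sp in ("K", "CL"):
        dens = density_profile(traj, sp, profile, step_ps=traj.dt_ps)
        for z, m, s in zip(dens.z_centers, dens.density_mean, dens.density_sd):
            dens_rows.append({"species": sp, "z_A": z,
                              "density_mean_A3": m, "density_sd_A3": s})
    paths["density"] = outdir / "density.csv"
    ResultsTable(pd.DataFrame(dens_rows),
                 _prov("density_profile", resolution_A=1.0)
                 ).to_csv(paths["density"])

    # --- events -----------------------------------------------------------
    kin_rows = []
    comparisons = []
    taus = {}
    for name, key in (("wt", "trace"), ("mutant", "mutant_trace")):
        tspec = TraceSpec(seed=seed, **cfg[key])
        trace, _ = gen_current_trace(tspec)
        events = detect_events(trace, **cfg["detection"])
        if name == "wt":
            ev_df = events.df.copy()
            ev_df.insert(0, "label", name)
            paths["events"] = outdir / "events.csv"
            ResultsTable(ev_df, _prov("detect_events", **cfg["detection"])
                         ).to_csv(paths["events"])
        dwell = fit_dwell_exponential(events, seed=seed)
        cap = capture_rate(events)
        taus[name] = dwell.tau_s
        kin_rows.append({
            "label": name, "n_events": events.n_events,
            "tau_ms": dwell.tau_s * 1e3,
            "tau_ci_lo_ms": dwell.ci_s[0] * 1e3,
            "tau_ci_hi_ms": dwell.ci_s[1] * 1e3,
            "tau_on_s": cap.tau_on_s, "f_hz": cap.f_hz,
            "i0_pa": events.i0_pa,
            "mean_ires_over_i0": float(events.df["ires_over_i0"].mean()),
        })
        comparisons.append((name, tspec))
    paths["kinetics"] = outdir / "kinetics.csv"
    ResultsTable(pd.DataFrame(kin_rows), _prov("event_kinetics")
                 ).to_csv(paths["kinetics"])

    wt_spec, mut_spec = comparisons[0][1], comparisons[1][1]
    table = comparison_table(
        [
            ("open_current", wt_spec.open_current_pa,
             mut_spec.open_current_pa, "pA"),
            ("dwell_tau", taus["wt"] * 1e3, taus["mutant"] * 1e3, "ms"),
        ],
        provenance=_prov("comparison_table"),
    )
    paths["comparisons"] = outdir / "comparisons.csv"
    table.to_csv(paths["comparisons"])

    # raw synthetic inputs for reuse
    paths["trajectory"] = outdir / "trajectory.tsv"
    write_trajectory(traj, paths["trajectory"])
    wt_trace, _ = gen_current_trace(TraceSpec(seed=seed, **cfg["trace"]))
    paths["trace"] = outdir / "trace.tsv"
    write_trace(wt_trace, paths["trace"])
    return paths
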