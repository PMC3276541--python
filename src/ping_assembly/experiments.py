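"""Config-driven reproduction of the figure-level computational studies.

Each experiment id names one study family:

========  ===================================================================
id        study
========  ===================================================================
fig3      breakdown of strong PING as E-to-I synapses weaken (homogeneous,
          sparse, and heterogeneous 80E/20I networks; 1:1 → 2:1 entrainment)
fig4      rhythmicity γ as a function of mean E-to-I conductance (sweep)
fig6      homogeneous I-to-E weakening: the rhythm locks ever more slowly
fig7      the same with heterogeneity: slow-locking regimes break outright
fig8      ten-fold stronger inhibition barely sharpens E-volleys
fig9      γ as a function of mean I-to-E conductance (sweep)
fig10     reduced 20E+1I network: locked rhythm and its breakdown
fig12     fixed-point locking curves and existence for the reduced network
fig13     assembly-size breakdown with stochastic background (80I/320E)
fig15     spatial network: breakdown as the driven-patch radius ρ shrinks
fig16     the same with network size doubled, synapse strengths halved
fig17     synchrony σ versus ρ for both spatial network sizes
fig18     breakdown as connectivity becomes too local (length constant ℓ)
========  ===================================================================

Every run writes a JSON manifest with the fully resolved parameter set and
seed; ``run_from_manifest`` re-executes a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ping_assembly import metrics as met
from ping_assembly import network_builder as nb
from ping_assembly.locking import (
    ReducedNetworkSpec,
    once_per_cycle_fraction,
    simulate_reduced,
    solve_locking_selfconsistent,
)
from ping_assembly.simulator import run_simulation

__all__ = ["ExperimentConfig", "run_experiment", "sweep", "run_from_manifest",
           "EXPERIMENT_IDS", "DEFAULTS"]


# --- parameter families ------------------------------------------------------
# One dict per figure family: the package's reference conditions. Conductance
# densities are population means Ḡ in mS/cm², drives in µA/cm².

DEFAULTS: dict[str, dict] = {
    "fig3": {
        "n_e": 80, "n_i": 20, "gbar_ie": 0.2, "gbar_ii": 0.05,
        "drive_e": 1.6, "drive_i": 0.0, "het_pct": 15.0, "p": 0.5,
        "drive_i_spread": 0.1, "gei_panels": {"A": 0.25, "B": 0.08, "C": 0.04},
        "rows": ["homog", "sparse", "het"], "duration": 400.0, "dt": 0.02,
        "band": (25.0, 100.0), "transient": 100.0,
    },
    "fig4": {"sweep_of": "fig3", "row": "het",
             "values": [0.02, 0.04, 0.06, 0.08, 0.10, 0.12], "replicates": 2},
    "fig6": {
        "n_e": 80, "n_i": 20, "gbar_ei": 0.25, "gbar_ii": 0.2,
        "drive_e": 1.6, "drive_i": 0.0,
        "gie_panels": {"A": 0.2, "B": 0.05, "C": 0.02},
        "duration": 400.0, "dt": 0.02, "band": (25.0, 100.0),
        "transient": 100.0, "tight_std_ms": 2.0,
    },
    "fig7": {"like": "fig6", "het_pct": 10.0, "p_ei": 0.5},
    "fig8": {"like": "fig7", "gie_panels": {"A": 0.2, "B": 2.0}},
    "fig9": {"sweep_of": "fig7",
             "values": [0.01, 0.02, 0.05, 0.1, 0.15, 0.2], "replicates": 2},
    "fig10": {"gie_panels": {"A": 0.3, "B": 0.15, "C": 0.05},
              "duration": 600.0, "dt": 0.02, "transient": 300.0,
              "band": (25.0, 100.0)},
    "fig12": {"like": "fig10", "n_s": 150},
    "fig13": {
        "n_e": 320, "n_i": 80, "p": 0.5,
        "gbar_ei": 0.4, "gbar_ie": 0.3, "gbar_ii": 0.15,
        "drive_e": 1.5, "drive_i": 0.0,
        "poisson_rate": 20.0, "poisson_g": 0.05,
        "n_panels": {"A": 200, "B": 100, "C": 50, "D": 0, "E": 50},
        "triple_panel": "E", "duration": 400.0, "dt": 0.02,
        "band": (25.0, 100.0), "kainate_band": (25.0, 50.0),
        "transient": 100.0,
    },
    "fig15": {
        "n_e": 320, "n_i": 80, "ell": 0.25, "strength_scale": 1.0,
        "gbar_ei": 0.4, "gbar_ie": 0.3, "gbar_ii": 0.15,
        "drive_e": 1.5, "rho_panels": {"A": 0.5, "B": 0.35, "C": 0.25, "D": 0.18},
        "duration": 400.0, "dt": 0.02, "band": (25.0, 100.0), "transient": 100.0,
    },
    "fig16": {"like": "fig15", "n_e": 640, "n_i": 160},
    "fig17": {"sweep_of": "fig15", "values": [0.5, 0.4, 0.3, 0.25, 0.2],
              "replicates": 2},
    "fig18": {"like": "fig15",
              "panels": {"A": {"ell": 0.25, "strength_scale": 1.0},
                         "B": {"ell": 0.10, "strength_scale": 1.0},
                         "C": {"ell": 0.10, "strength_scale": 3.0}},
              "rho": 0.5},
}

EXPERIMENT_IDS = tuple(DEFAULTS)

#: mean of exp(−d/ℓ) over random point pairs in the unit disk at ℓ = 0.25,
#: used to convert target Ḡ into per-synapse strengths for spatial networks.
_PBAR_REF = 0.085
_ELL_REF = 0.25


@dataclass
class ExperimentConfig:
    """A named study plus overrides, seed and output directory."""

    experiment: str
    overrides: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.experiment not in DEFAULTS:
            raise ValueError(
                f"unknown experiment id {self.experiment!r}; "
                f"valid ids: {', '.join(EXPERIMENT_IDS)}")

    def resolved(self) -> dict:
        base = dict(DEFAULTS[self.experiment])
        while "like" in base:
            parent = dict(DEFAULTS[base.pop("like")])
            parent.update(base)
            base = parent
        base.update(self.overrides)
        return base


def _subseed(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(2 ** 31))


def _standard_metrics(res, params, transient=None):
    tr = params.get("transient", 100.0) if transient is None else transient
    dur = res.duration
    band = tuple(params.get("band", (25.0, 100.0)))
    sp_e = res.population_spikes("E")
    sp_i = res.population_spikes("I")
    post = lambda s: s[s[:, 1] >= tr] if s.size else s
    out = {
        "gamma": met.rhythmicity_gamma(res.s_bar, res.dt, band=band, transient=tr).gamma,
        "f_e": met.mean_population_frequency(post(sp_e), res.n_e, (tr, dur)),
        "f_i": met.mean_population_frequency(post(sp_i), res.n_i, (tr, dur)),
    }
    ev = met.detect_volleys(post(sp_e), dur)
    iv = met.detect_volleys(post(sp_i), dur)
    out["n_e_volleys"] = int(ev.times.size)
    out["n_i_volleys"] = int(iv.times.size)
    out["e_volley_width"] = float(ev.widths.mean()) if ev.widths.size else np.nan
    try:
        out["entrainment"] = met.entrainment_ratio(ev, iv)
    except ValueError:
        out["entrainment"] = None
    return out


def _maybe_plot(res, name, params, order=None):
    outdir = params.get("_artifacts")
    if outdir is None:
        return
    from ping_assembly import plotting
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plotting.plot_raster(res, outdir / f"raster_{name}.svg", order=order, title=name)
    plotting.plot_sbar_spectrum(res, outdir / f"sbar_{name}.svg",
                                band=tuple(params.get("band", (25.0, 100.0))),
                                transient=params.get("transient", 100.0))


# --- family builders ---------------------------------------------------------

def _fig3_network(params, row, gei, seed):
    n_e, n_i = params["n_e"], params["n_i"]
    gii = params["gbar_ii"]
    if row == "homog":
        net = nb.build_all_to_all(n_e, n_i, gei, params["gbar_ie"], gii)
        drive_e = np.full(n_e, params["drive_e"])
        drive_i = np.full(n_i, params["drive_i"])
    elif row == "sparse":
        net = nb.build_random_network(n_e, n_i, {"ei": params["p"]}, gei,
                                      params["gbar_ie"], gii, seed=_subseed(seed, 11))
        drive_e = np.full(n_e, params["drive_e"])
        drive_i = np.full(n_i, params["drive_i"])
    elif row in ("het", "J"):
        include_ii = row != "J"
        net = nb.build_random_network(n_e, n_i, params["p"], gei,
                                      params["gbar_ie"], gii if include_ii else 0.0,
                                      include_ii=include_ii, seed=_subseed(seed, 11))
        drive_e = nb.make_heterogeneous_drives(n_e, params["drive_e"],
                                               params["het_pct"], seed=_subseed(seed, 12))
        center = 0.4 if row == "J" else params["drive_i"]
        rng = np.random.default_rng(_subseed(seed, 13))
        drive_i = rng.uniform(center - params["drive_i_spread"],
                              center + params["drive_i_spread"], n_i)
    else:
        raise ValueError(f"unknown fig3 row {row!r}")
    return net, nb.DriveSpec(drive_e=drive_e, drive_i=drive_i, seed=seed)


def _run_fig3(params, seed):
    rows = params["rows"]
    results = {}
    for row in rows:
        for panel, gei in params["gei_panels"].items():
            net, dr = _fig3_network(params, row, gei, seed)
            res = run_simulation(net, dr, duration=params["duration"],
                                 dt=params["dt"], seed=_subseed(seed, hash(row + panel) % 1000))
            m = _standard_metrics(res, params)
            m["gbar_ei"] = gei
            _maybe_plot(res, f"{row}_{panel}", params)
            results[f"{row}/{panel}"] = m
    return results


def _fig67_network(params, gie, seed, heterogeneous):
    n_e, n_i = params["n_e"], params["n_i"]
    if heterogeneous:
        net = nb.build_random_network(n_e, n_i, {"ei": params["p_ei"]},
                                      params["gbar_ei"], gie, params["gbar_ii"],
                                      seed=_subseed(seed, 21))
        drive_e = nb.make_heterogeneous_drives(n_e, params["drive_e"],
                                               params["het_pct"], seed=_subseed(seed, 22))
    else:
        net = nb.build_all_to_all(n_e, n_i, params["gbar_ei"], gie, params["gbar_ii"])
        drive_e = np.full(n_e, params["drive_e"])
    dr = nb.DriveSpec(drive_e=drive_e, drive_i=np.full(n_i, params["drive_i"]), seed=seed)
    return net, dr


def _cycles_to_synchrony(res, tight_std_ms=2.0, transient=0.0):
    """Number of I-volley cycles before per-cycle E-spike dispersion stays
    below ``tight_std_ms``; None if it never does."""
    sp_i = res.population_spikes("I")
    sp_e = res.population_spikes("E")
    iv = met.detect_volleys(sp_i[sp_i[:, 1] >= transient], res.duration)
    t_i = iv.times
    if t_i.size < 3:
        return None
    stds = []
    for k in range(t_i.size - 1):
        sel = sp_e[(sp_e[:, 1] >= t_i[k]) & (sp_e[:, 1] < t_i[k + 1])][:, 1]
        stds.append(np.std(sel) if sel.size > 5 else np.inf)
    stds = np.asarray(stds)
    ok = stds <= tight_std_ms
    for k in range(ok.size):
        if ok[k:].all():
            return k
    return None


def _run_fig67(params, seed, heterogeneous):
    results = {}
    for panel, gie in params["gie_panels"].items():
        net, dr = _fig67_network(params, gie, seed, heterogeneous)
        res = run_simulation(net, dr, duration=params["duration"],
                             dt=params["dt"], seed=_subseed(seed, 31 + ord(panel)))
        m = _standard_metrics(res, params)
        m["gbar_ie"] = gie
        m["cycles_to_sync"] = _cycles_to_synchrony(res, params.get("tight_std_ms", 2.0))
        _maybe_plot(res, panel, params)
        results[panel] = m
    return results


def _run_fig10(params, seed):
    results = {}
    for panel, gie in params["gie_panels"].items():
        spec = ReducedNetworkSpec(g_ie=gie)
        res = simulate_reduced(spec, duration=params["duration"],
                               dt=params["dt"], seed=_subseed(seed, 41 + ord(panel)))
        m = _standard_metrics(res, params, transient=params["transient"])
        m["g_ie"] = gie
        m["once_per_cycle"] = once_per_cycle_fraction(res, transient=params["transient"])
        _maybe_plot(res, panel, params)
        results[panel] = m
    return results


def _run_fig12(params, seed):
    from ping_assembly.locking import locking_map
    results = {}
    for panel, gie in params["gie_panels"].items():
        sol = solve_locking_selfconsistent(ReducedNetworkSpec(g_ie=gie),
                                           n_s=params["n_s"])
        if params.get("_artifacts") is not None:
            from ping_assembly import plotting
            spec = ReducedNetworkSpec(g_ie=gie)
            curves = locking_map(spec.drives, gie, n_s=60)
            outdir = Path(params["_artifacts"])
            outdir.mkdir(parents=True, exist_ok=True)
            plotting.plot_locking_curves(curves, outdir / f"locking_{panel}.svg",
                                         P=sol.period)
        results[panel] = {
            "g_ie": gie, "exists": sol.exists, "period": sol.period,
            "s_min": float(np.nanmin(sol.s)) if np.any(~np.isnan(sol.s)) else None,
            "s_max": float(np.nanmax(sol.s)) if np.any(~np.isnan(sol.s)) else None,
        }
    return results


def _fig13_network(params, seed, gbar_ei=None):
    net = nb.build_random_network(
        params["n_e"], params["n_i"], params["p"],
        gbar_ei if gbar_ei is not None else params["gbar_ei"],
        params["gbar_ie"], params["gbar_ii"], seed=_subseed(seed, 51))
    return net


def _run_fig13(params, seed):
    results = {}
    for panel, n_driven in params["n_panels"].items():
        gei = params["gbar_ei"] * (3.0 if panel == params.get("triple_panel") else 1.0)
        net = _fig13_network(params, seed, gbar_ei=gei)
        drive_e = np.zeros(params["n_e"])
        drive_e[:n_driven] = params["drive_e"]
        dr = nb.DriveSpec(drive_e=drive_e, drive_i=np.full(params["n_i"], params["drive_i"]),
                          poisson_rate=params["poisson_rate"], poisson_g=params["poisson_g"],
                          driven_idx=np.arange(n_driven), seed=seed)
        res = run_simulation(net, dr, duration=params["duration"], dt=params["dt"],
                             seed=_subseed(seed, 61 + ord(panel)))
        m = _standard_metrics(res, params)
        m["gamma_kainate"] = met.rhythmicity_gamma(
            res.s_bar, res.dt, band=tuple(params["kainate_band"]),
            transient=params["transient"]).gamma
        m["n_driven"] = n_driven
        _maybe_plot(res, panel, params)
        results[panel] = m
    return results


def _spatial_strengths(params):
    """Per-synapse strengths hitting the target Ḡ at the reference geometry."""
    scale = params.get("strength_scale", 1.0)
    n_e, n_i = params["n_e"], params["n_i"]
    g_ei = params["gbar_ei"] / (n_e * _PBAR_REF) * scale
    g_ie = params["gbar_ie"] / (n_i * _PBAR_REF) * scale
    g_ii = params["gbar_ii"] / (n_i * _PBAR_REF) * scale
    return g_ei, g_ie, g_ii


def _run_spatial_panel(params, rho, ell, scale, seed):
    p = dict(params)
    p["strength_scale"] = scale
    g_ei, g_ie, g_ii = _spatial_strengths(p)
    net, lay = nb.build_spatial_network(params["n_e"], params["n_i"], ell,
                                        g_ei, g_ie, g_ii, rho=rho,
                                        seed=_subseed(seed, 71))
    idx = nb.select_driven_patch(lay, rho)
    drive_e = np.zeros(params["n_e"])
    drive_e[idx] = params["drive_e"]
    dr = nb.DriveSpec(drive_e=drive_e, drive_i=np.zeros(params["n_i"]),
                      driven_idx=idx, seed=seed)
    res = run_simulation(net, dr, layout=lay, duration=params["duration"],
                         dt=params["dt"], seed=_subseed(seed, 72))
    # raster ordering: E-cells sorted by distance from the disk center
    order = np.argsort(np.hypot(lay.pos_e[:, 0], lay.pos_e[:, 1]))
    _maybe_plot(res, f"rho{rho}_ell{ell}", params, order=order)
    m = _standard_metrics(res, params)
    sp_e = res.population_spikes("E")
    patch = sp_e[np.isin(sp_e[:, 0].astype(int), idx)]
    patch = patch[patch[:, 1] >= params["transient"]]
    try:
        m["sigma"] = met.synchrony_measure(patch, res.duration)
    except ValueError:
        m["sigma"] = np.nan
    m["rho"] = rho
    m["ell"] = ell
    m["n_driven"] = int(idx.size)
    return m


def _run_fig15(params, seed):
    return {panel: _run_spatial_panel(params, rho, params["ell"],
                                      params.get("strength_scale", 1.0),
                                      seed + 7 * ord(panel))
            for panel, rho in params["rho_panels"].items()}


def _run_fig16(params, seed):
    # doubled cell counts, halved per-synapse strengths (Ḡ preserved)
    p = dict(params)
    return {panel: _run_spatial_panel(p, rho, p["ell"], p.get("strength_scale", 1.0),
                                      seed + 7 * ord(panel))
            for panel, rho in p["rho_panels"].items()}


def _run_fig18(params, seed):
    return {panel: _run_spatial_panel(params, params["rho"], sub["ell"],
                                      sub["strength_scale"], seed + 7 * ord(panel))
            for panel, sub in params["panels"].items()}


_RUNNERS = {
    "fig3": _run_fig3,
    "fig6": lambda p, s: _run_fig67(p, s, heterogeneous=False),
    "fig7": lambda p, s: _run_fig67(p, s, heterogeneous=True),
    "fig8": lambda p, s: _run_fig67(p, s, heterogeneous=True),
    "fig10": _run_fig10,
    "fig12": _run_fig12,
    "fig13": _run_fig13,
    "fig15": _run_fig15,
    "fig16": _run_fig16,
    "fig18": _run_fig18,
}


def _sweep_param_and_runner(params):
    """For sweep-style ids (fig4, fig9, fig17): the swept path and base id."""
    base_id = params["sweep_of"]
    if base_id == "fig3":
        return base_id, "gei"
    if base_id == "fig7":
        return base_id, "gie"
    if base_id == "fig15":
        return base_id, "rho"
    raise ValueError(f"no sweep defined over {base_id}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one named study; returns the metrics dict and writes
    artifacts (manifest, metrics JSON, per-panel plots) when an output
    directory is configured."""
    params = config.resolved()
    if config.outdir is not None:
        params["_artifacts"] = str(Path(config.outdir) / "figures")
    if config.experiment in _RUNNERS:
        results = _RUNNERS[config.experiment](params, config.seed)
    elif "sweep_of" in params:
        results = _run_builtin_sweep(config, params)
    else:  # pragma: no cover - registry and DEFAULTS are kept in sync
        raise ValueError(f"no runner for {config.experiment}")

    payload = {"experiment": config.experiment, "seed": config.seed,
               "results": results}
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        resolved_public = {k: v for k, v in params.items() if not k.startswith("_")}
        manifest = {"experiment": config.experiment, "seed": config.seed,
                    "overrides": _jsonable(config.overrides),
                    "resolved": _jsonable(resolved_public)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "metrics.json").write_text(json.dumps(_jsonable(results), indent=2))
    return payload


def _run_builtin_sweep(config, params):
    base_id, name = _sweep_param_and_runner(params)
    rows = []
    for v in params["values"]:
        for rep in range(params["replicates"]):
            seed = _subseed(config.seed, 1000 + rep)
            if base_id == "fig3":
                sub = ExperimentConfig(base_id, overrides={
                    "rows": [params.get("row", "het")],
                    "gei_panels": {"X": v}, **{k: params[k] for k in params
                                               if k in DEFAULTS["fig3"]}},
                    seed=seed)
            elif base_id == "fig7":
                sub = ExperimentConfig(base_id, overrides={"gie_panels": {"X": v}},
                                       seed=seed)
            else:  # fig15 ρ sweep
                sub = ExperimentConfig(base_id, overrides={"rho_panels": {"X": v}},
                                       seed=seed)
            out = run_experiment(sub)
            (_, m), = out["results"].items()
            rows.append({name: v, "replicate": rep, "seed": seed, **m})
    return {"table": rows}


def sweep(config: ExperimentConfig, parameter: str, values, replicates: int = 1) -> pd.DataFrame:
    """Run ``config`` once per (value, replicate), overriding ``parameter``
    (a ``/``-separated path into the resolved parameter dict), and return a
    long-format table of all panel metrics."""
    rows = []
    for v in values:
        for rep in range(replicates):
            overrides = dict(config.overrides)
            _set_path(overrides, parameter, v)
            sub = ExperimentConfig(config.experiment, overrides=overrides,
                                   seed=_subseed(config.seed, 5000 + rep))
            out = run_experiment(sub)
            for panel, m in out["results"].items():
                if panel == "table":
                    continue
                rows.append({"value": v, "replicate": rep, "panel": panel,
                             **{k: val for k, val in m.items()}})
    return pd.DataFrame(rows)


def _set_path(overrides: dict, path: str, value) -> None:
    keys = path.split("/")
    d = overrides
    for k in keys[:-1]:
        d = d.setdefault(k, {})
    d[keys[-1]] = value


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_from_manifest(path) -> dict:
    """Re-execute a run from its manifest; identical inputs reproduce
    identical outputs."""
    manifest = json.loads(Path(path).read_text())
    cfg = ExperimentConfig(manifest["experiment"],
                           overrides=manifest.get("overrides", {}),
                           seed=manifest["seed"])
    return run_experiment(cfg)
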