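"""CSV / YAML readers and writers for the pipeline's file formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emu import TracerSpec
from .fluxes import FluxVector
from .measurements import LabelingExperiment, MeasurementSet, MidMeasurement
from .physiology import GrowthSeries


def _parse_positions(text) -> tuple[int, ...] | None:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return None
    text = str(text)
    if "-" in text:
        lo, hi = text.split("-")
        return tuple(range(int(lo), int(hi) + 1))
    return tuple(int(x) for x in text.split(","))


def _format_positions(positions) -> str:
    if positions is None:
        return ""
    positions = list(positions)
    if positions == list(range(positions[0], positions[-1] + 1)) \
            and len(positions) > 1:
        return f"{positions[0]}-{positions[-1]}"
    return ",".join(map(str, positions))


def mids_to_frame(measurements: MeasurementSet) -> pd.DataFrame:
    rows = []
    for exp in measurements.experiments:
        for m in exp.mids:
            for shift, (frac, sd) in enumerate(zip(m.fractions, m.sd)):
                rows.append({"experiment": exp.id, "metabolite": m.metabolite,
                             "fragment_positions": _format_positions(m.positions),
                             "mass_shift": shift, "fraction": frac, "sd": sd})
    return pd.DataFrame(rows)


def write_mid_csv(measurements: MeasurementSet, path):
    mids_to_frame(measurements).to_csv(path, index=False)


def read_mid_csv(path, tracers: dict[str, dict[str, TracerSpec]] | None = None,
                 effluxes: dict[str, tuple[float, float]] | None = None,
                 ) -> MeasurementSet:
    """Read the long-format MID CSV (one row per isotopolog).

    ``tracers`` maps experiment-id prefixes (the part before ``/``) to
    tracer maps; omitted experiments get no tracer (unlabeled).
    """
    df = pd.read_csv(path)
    experiments = []
    for exp_id, g in df.groupby("experiment", sort=False):
        mids = []
        key = (str(exp_id).split("/", 1)[0], str(exp_id))
        tr = {}
        if tracers:
            tr = tracers.get(key[1], tracers.get(key[0], {}))
        for (met, pos), gg in g.groupby(["metabolite", "fragment_positions"],
                                        sort=False, dropna=False):
            gg = gg.sort_values("mass_shift")
            mids.append(MidMeasurement(
                met, gg["fraction"].to_numpy(), gg["sd"].to_numpy(),
                _parse_positions(pos)))
        experiments.append(LabelingExperiment(str(exp_id), tr, mids))
    return MeasurementSet(experiments, dict(effluxes or {}))


def write_flux_csv(fluxes: FluxVector, path, ci=None, sd=None):
    ci, sd = ci or {}, sd or {}
    rows = []
    for rid, v in fluxes.net.items():
        lo, hi = ci.get(rid, (np.nan, np.nan))
        rows.append({"reaction": rid, "net": v,
                     "exchange": fluxes.exchange.get(rid, 0.0),
                     "ci_lo": lo, "ci_hi": hi, "sd": sd.get(rid, np.nan)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_flux_csv(path) -> FluxVector:
    df = pd.read_csv(path)
    net = dict(zip(df["reaction"], df["net"].astype(float)))
    exchange = {}
    if "exchange" in df.columns:
        exchange = {r: float(e) for r, e in zip(df["reaction"], df["exchange"])
                    if np.isfinite(e) and e != 0.0}
    return FluxVector(net, exchange)


def read_tracer_yaml(path) -> dict[str, TracerSpec]:
    """Tracer config: ``{substrate: {purity: [...], unlabeled_weight: w}}``."""
    spec = yaml.safe_load(Path(path).read_text())
    out = {}
    for sub, cfg in spec.items():
        out[sub] = TracerSpec(sub, tuple(float(p) for p in cfg["purity"]),
                              float(cfg.get("unlabeled_weight", 0.0)))
    return out


def write_growth_csv(series: GrowthSeries, path):
    rows = []
    for i, t in enumerate(series.time_h):
        rows.append({"time_h": t, "od600": series.od600[i],
                     "compound": "", "conc_mM": np.nan})
    for compound, conc in series.concentrations.items():
        for i, t in enumerate(series.time_h):
            rows.append({"time_h": t, "od600": np.nan,
                         "compound": compound, "conc_mM": conc[i]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_csv(path, conversion: float | None = None) -> GrowthSeries:
    df = pd.read_csv(path)
    od = df[df["od600"].notna()].sort_values("time_h")
    conc = {}
    for compound, g in df[df["conc_mM"].notna()].groupby("compound"):
        if compound == "":
            continue
        conc[compound] = g.sort_values("time_h")["conc_mM"].to_numpy()
    return GrowthSeries(od["time_h"].to_numpy(), od["od600"].to_numpy(),
                        conc, conversion)


def write_pools_csv(pools: dict[str, float], path):
    pd.DataFrame({"metabolite": list(pools), "pool_umol_gcdw":
                  list(pools.values())}).to_csv(path, index=False)


def read_pools_csv(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return dict(zip(df["metabolite"], df["pool_umol_gcdw"].astype(float)))


def write_trajectory_csv(traj, path):
    rows = []
    for met, mids in traj.mids.items():
        for i, t in enumerate(traj.time_s):
            for shift, frac in enumerate(mids[i]):
                rows.append({"time_s": t, "metabolite": met,
                             "mass_shift": shift, "fraction": frac})
    pd.DataFrame(rows).to_csv(path, index=False)
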