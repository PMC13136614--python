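"""Readers and writers for the exchanged file formats.

Process data travel as four tidy CSV files:

* ``measurements.csv`` — batch_id, time_d, analyte, value, unit
* ``feeds.csv``        — batch_id, time_d, stream, volume_ml
* ``compositions.csv`` — stream, analyte, conc_g_per_l
* ``groups.csv``       — batch_id, media_group

Analyte names come from the controlled vocabulary (the 24-analyte panel plus
``vcd``, ``viability`` and ``volume``).  Metabolic networks are read/written
as SBML Level 3 with the FBC package through COBRApy.  Run manifests record
the configuration hash, seed and package version next to every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cobra.io import read_sbml_model, write_sbml_model

from . import __version__
from .network import MetabolicNetwork
from .records import ALL_ANALYTES, FeedEvent, ProcessRecord, SampleEvent

logger = logging.getLogger(__name__)

CONTROL_VARIABLES = ("vcd", "viability", "volume")
VALID_ANALYTES = set(ALL_ANALYTES) | set(CONTROL_VARIABLES)

EXPECTED_UNITS = {**{a: "g/l" for a in ALL_ANALYTES},
                  "vcd": "1e6 cells/ml", "viability": "fraction",
                  "volume": "ml"}


class ValidationError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValidationError(f"{name} is missing columns {sorted(missing)}")


def read_process_data(measurements, feeds, compositions, groups,
                      sample_volume_ml: float = 0.0) -> list[ProcessRecord]:
    """Assemble :class:`ProcessRecord` objects from the four-file dialect."""
    meas = pd.read_csv(measurements)
    feed = pd.read_csv(feeds)
    comp = pd.read_csv(compositions)
    grp = pd.read_csv(groups)
    _require_columns(meas, ["batch_id", "time_d", "analyte", "value", "unit"],
                     "measurements")
    _require_columns(feed, ["batch_id", "time_d", "stream", "volume_ml"],
                     "feeds")
    _require_columns(comp, ["stream", "analyte", "conc_g_per_l"],
                     "compositions")
    _require_columns(grp, ["batch_id", "media_group"], "groups")

    for i, row in meas.iterrows():
        if row["analyte"] not in VALID_ANALYTES:
            raise ValidationError(
                f"measurements row {i}: unknown analyte {row['analyte']!r}")
        if row["time_d"] < 0:
            raise ValidationError(f"measurements row {i}: negative time")
        expected = EXPECTED_UNITS[row["analyte"]]
        if str(row["unit"]) != expected:
            raise ValidationError(
                f"measurements row {i}: unit {row['unit']!r} for "
                f"{row['analyte']!r}, expected {expected!r}")
    for i, row in feed.iterrows():
        if row["volume_ml"] < 0:
            raise ValidationError(f"feeds row {i}: negative volume_ml")

    compositions_map: dict[str, dict[str, float]] = {}
    for _, row in comp.iterrows():
        compositions_map.setdefault(row["stream"], {})[row["analyte"]] = \
            float(row["conc_g_per_l"])
    for _, row in feed.iterrows():
        if row["stream"] not in compositions_map:
            raise ValidationError(
                f"no composition for fed stream {row['stream']!r}")

    groups_map = dict(zip(grp["batch_id"], grp["media_group"].astype(int)))
    records = []
    for batch_id, sub in meas.groupby("batch_id", sort=True):
        if not sub["time_d"].is_monotonic_increasing:
            logger.warning("unsorted times for batch %s; sorting", batch_id)
        wide = sub.pivot_table(index="time_d", columns="analyte",
                               values="value").sort_index()
        for col in ("vcd", "viability", "volume"):
            if col not in wide.columns:
                raise ValidationError(f"batch {batch_id}: missing {col!r}")
        times = wide.index.to_numpy(dtype=float)
        analyte_cols = [a for a in ALL_ANALYTES if a in wide.columns]
        events = [FeedEvent(float(r["time_d"]), r["stream"],
                            float(r["volume_ml"]))
                  for _, r in feed[feed["batch_id"] == batch_id].iterrows()]
        samples = [SampleEvent(float(t), sample_volume_ml)
                   for t in times if t > 0] if sample_volume_ml > 0 else []
        records.append(ProcessRecord(
            batch_id=str(batch_id),
            media_group=int(groups_map.get(batch_id, 0)),
            times_d=times,
            concentrations=wide[analyte_cols],
            vcd=wide["vcd"].to_numpy(dtype=float),
            viability=wide["viability"].to_numpy(dtype=float),
            volume_ml=wide["volume"].to_numpy(dtype=float),
            feed_events=sorted(events, key=lambda e: e.time_d),
            sample_events=samples,
            feed_compositions=compositions_map,
        ))
    return records


def write_process_data(records: list[ProcessRecord], out_dir) -> dict[str, Path]:
    """Write records in the four-file dialect; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m_rows, f_rows, c_rows, g_rows = [], [], [], []
    streams_done = set()
    for rec in records:
        for i, t in enumerate(rec.times_d):
            for a in rec.analytes:
                m_rows.append((rec.batch_id, t, a,
                               rec.concentrations.iloc[i][a], "g/l"))
            m_rows.append((rec.batch_id, t, "vcd", rec.vcd[i],
                           "1e6 cells/ml"))
            m_rows.append((rec.batch_id, t, "viability", rec.viability[i],
                           "fraction"))
            m_rows.append((rec.batch_id, t, "volume", rec.volume_ml[i], "ml"))
        for e in rec.feed_events:
            f_rows.append((rec.batch_id, e.time_d, e.stream, e.volume_ml))
        for stream, comp in rec.feed_compositions.items():
            if stream not in streams_done:
                streams_done.add(stream)
                for a, v in comp.items():
                    c_rows.append((stream, a, v))
        g_rows.append((rec.batch_id, rec.media_group))
    paths = {
        "measurements": out / "measurements.csv",
        "feeds": out / "feeds.csv",
        "compositions": out / "compositions.csv",
        "groups": out / "groups.csv",
    }
    pd.DataFrame(m_rows, columns=["batch_id", "time_d", "analyte", "value",
                                  "unit"]).to_csv(paths["measurements"],
                                                  index=False)
    pd.DataFrame(f_rows, columns=["batch_id", "time_d", "stream",
                                  "volume_ml"]).to_csv(paths["feeds"],
                                                       index=False)
    pd.DataFrame(c_rows, columns=["stream", "analyte", "conc_g_per_l"]
                 ).to_csv(paths["compositions"], index=False)
    pd.DataFrame(g_rows, columns=["batch_id", "media_group"]
                 ).to_csv(paths["groups"], index=False)
    return paths


# --------------------------------------------------------------------------
# SBML
# --------------------------------------------------------------------------

def read_sbml(path) -> MetabolicNetwork:
    """Read an SBML L3/FBC constraint-based model.

    Models without flux-bound annotations get COBRA's (-1000, 1000) defaults
    (a warning is logged); a missing objective is an error.
    """
    model = read_sbml_model(str(path))
    if not any(r.objective_coefficient != 0 for r in model.reactions):
        raise ValidationError(f"model {model.id!r} has no objective reaction")
    return MetabolicNetwork(model)


def write_sbml(network: MetabolicNetwork, path) -> None:
    write_sbml_model(network.model, str(path))


# --------------------------------------------------------------------------
# configuration and manifests
# --------------------------------------------------------------------------

KNOWN_CONFIG_KEYS = {
    "seed", "synthetic", "growth", "ode", "reduction", "pcdfba", "twin",
    "units",
}


def load_run_config(path) -> dict:
    """Schema-light YAML run configuration; unknown top-level keys rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed: int, extra=None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(cfg), "seed": int(seed),
                "version": __version__}
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_rate_ensembles(ensembles, out_dir) -> tuple[Path, Path]:
    """Long-format trajectory CSV plus a mean/p5/p95 summary CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long_rows, sum_rows = [], []
    for ens in ensembles:
        for k, traj in enumerate(ens.trajectories):
            for t, v in zip(ens.times, traj):
                long_rows.append((ens.batch, ens.analyte, k, t, v))
        for t, m, lo, hi in zip(ens.times, ens.mean, ens.p5, ens.p95):
            sum_rows.append((ens.batch, ens.analyte, t, m, lo, hi))
    p1 = out / "rate_trajectories.csv"
    p2 = out / "rate_summary.csv"
    pd.DataFrame(long_rows, columns=["batch", "analyte", "traj_id", "time_d",
                                     "rate"]).to_csv(p1, index=False)
    pd.DataFrame(sum_rows, columns=["batch", "analyte", "time_d", "mean",
                                    "p5", "p95"]).to_csv(p2, index=False)
    return p1, p2


def write_tidy_result(result, out_path) -> Path:
    """Simulation result as tidy (time, variable, value) CSV."""
    rows = []
    for col in result.concentrations.columns:
        for t, v in zip(result.times, result.concentrations[col].values):
            rows.append((t, col, v))
    for name, arr in (("vcd", getattr(result, "vcd", None)),
                      ("mu", getattr(result, "mu", None)),
                      ("volume_ml", getattr(result, "volume", None))):
        if arr is not None and np.ndim(arr) == 1 and len(arr) == len(result.times):
            for t, v in zip(result.times, arr):
                rows.append((t, name, v))
    path = Path(out_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["time_d", "variable", "value"]
                 ).to_csv(path, index=False)
    return path
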