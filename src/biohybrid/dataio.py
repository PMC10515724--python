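"""On-disk dataset formats (plain CSV + JSON) and run configuration.

A dataset bundle is a directory of five CSV files plus a JSON metadata file:

* ``measurements.csv`` — wide: experiment_id, time_h, one column per species
  (empty cell = missing measurement)
* ``sigmas.csv`` — same layout; per-point measurement SDs
* ``feeds.csv`` — long: experiment_id, stream_id, t_start_h, t_end_h, rate
* ``compositions.csv`` — experiment_id, stream_id, one column per species
* ``initial_states.csv`` — experiment_id, V0, one column per species
* ``roster.csv`` — species, cmax, unit
* ``meta.json`` — provenance (generator seed or "external"), volume maximum

Numbers are serialized at full precision with a deterministic column order,
so writing the same bundle twice is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Experiment, ExperimentDataset
from .errors import SchemaError
from .mechanistic import FeedStream, SpeciesSet

__all__ = ["write_dataset", "read_dataset", "load_run_config"]

_FILES = (
    "measurements.csv",
    "sigmas.csv",
    "feeds.csv",
    "compositions.csv",
    "initial_states.csv",
    "roster.csv",
    "meta.json",
)


def write_dataset(dataset: ExperimentDataset, path: str | Path) -> Path:
    """Serialize a bundle to a directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sp = dataset.species
    cols = list(sp.names)

    meas_rows, sig_rows, feed_rows, comp_rows, init_rows = [], [], [], [], []
    for exp in dataset.experiments:
        for ti, t in enumerate(exp.times):
            meas_rows.append([exp.id, t, *exp.values[ti]])
            sig_rows.append([exp.id, t, *exp.sigmas[ti]])
        for si, stream in enumerate(exp.streams):
            sid = f"s{si + 1}"
            for a, b, r in stream.schedule:
                feed_rows.append([exp.id, sid, a, b, r])
            comp_rows.append([exp.id, sid, *stream.c_in])
        init_rows.append([exp.id, exp.v0, *exp.c0])

    def frame(rows, lead):
        return pd.DataFrame(rows, columns=[*lead, *cols])

    frame(meas_rows, ["experiment_id", "time_h"]).to_csv(
        path / "measurements.csv", index=False, float_format="%.17g"
    )
    frame(sig_rows, ["experiment_id", "time_h"]).to_csv(
        path / "sigmas.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        feed_rows, columns=["experiment_id", "stream_id", "t_start_h", "t_end_h", "rate"]
    ).to_csv(path / "feeds.csv", index=False, float_format="%.17g")
    frame(comp_rows, ["experiment_id", "stream_id"]).to_csv(
        path / "compositions.csv", index=False, float_format="%.17g"
    )
    frame(init_rows, ["experiment_id", "V0"]).to_csv(
        path / "initial_states.csv", index=False, float_format="%.17g"
    )
    units = sp.units or ("",) * sp.n
    pd.DataFrame(
        {"species": cols, "cmax": sp.cmax, "unit": list(units)}
    ).to_csv(path / "roster.csv", index=False, float_format="%.17g")

    meta = {"xv_name": sp.xv_name}
    meta.update(dataset.provenance)
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def _read_csv(path):
    # round_trip parsing: full-precision floats survive write->read exactly
    return pd.read_csv(path, float_precision="round_trip")


def _require_columns(df: pd.DataFrame, needed: list[str], fname: str):
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing columns {missing}")


def read_dataset(path: str | Path) -> ExperimentDataset:
    """Load and validate a bundle directory written by :func:`write_dataset`.

    Schema violations are reported with the file and cell that caused them.
    Missing measurements (empty cells) are allowed and excluded from every
    residual count.
    """
    path = Path(path)
    for f in _FILES:
        if not (path / f).exists():
            raise SchemaError(f"bundle at {path} is missing {f}")

    meta = json.loads((path / "meta.json").read_text())
    roster = _read_csv(path / "roster.csv")
    _require_columns(roster, ["species", "cmax"], "roster.csv")
    names = tuple(str(s) for s in roster["species"])
    units = (
        tuple(str(u) if isinstance(u, str) else "" for u in roster["unit"])
        if "unit" in roster.columns
        else None
    )
    try:
        species = SpeciesSet(
            names, roster["cmax"].to_numpy(float), units, meta.get("xv_name", "Xv")
        )
    except Exception as exc:
        raise SchemaError(f"roster.csv: {exc}") from exc

    meas = _read_csv(path / "measurements.csv")
    sig = _read_csv(path / "sigmas.csv")
    feeds = _read_csv(path / "feeds.csv")
    comps = _read_csv(path / "compositions.csv")
    inits = _read_csv(path / "initial_states.csv")
    _require_columns(meas, ["experiment_id", "time_h"], "measurements.csv")
    _require_columns(sig, ["experiment_id", "time_h"], "sigmas.csv")
    _require_columns(
        feeds, ["experiment_id", "stream_id", "t_start_h", "t_end_h", "rate"], "feeds.csv"
    )
    _require_columns(comps, ["experiment_id", "stream_id"], "compositions.csv")
    _require_columns(inits, ["experiment_id", "V0"], "initial_states.csv")

    for fname, df in (("measurements.csv", meas), ("sigmas.csv", sig),
                      ("compositions.csv", comps), ("initial_states.csv", inits)):
        lead = {"experiment_id", "time_h", "stream_id", "V0"}
        for col in df.columns:
            if col not in lead and col not in names:
                raise SchemaError(f"{fname}: column {col!r} names an unknown species")
        for nm in names:
            if nm not in df.columns:
                raise SchemaError(f"{fname}: species column {nm!r} is missing")

    experiments = []
    for exp_id, group in meas.groupby("experiment_id", sort=False):
        exp_id = str(exp_id)
        g = group.sort_values("time_h")
        times = g["time_h"].to_numpy(float)
        values = g[list(names)].to_numpy(float)
        sg = sig[sig["experiment_id"].astype(str) == exp_id].sort_values("time_h")
        if len(sg) != len(g) or not np.allclose(sg["time_h"].to_numpy(float), times):
            raise SchemaError(f"sigmas.csv: rows for experiment {exp_id} do not mirror measurements")
        sigmas = sg[list(names)].to_numpy(float)

        init_row = inits[inits["experiment_id"].astype(str) == exp_id]
        if len(init_row) != 1:
            raise SchemaError(f"initial_states.csv: need exactly one row for {exp_id}")
        c0 = init_row[list(names)].to_numpy(float)[0]
        v0 = float(init_row["V0"].iloc[0])

        streams = []
        fsub = feeds[feeds["experiment_id"].astype(str) == exp_id]
        for sid, seg in fsub.groupby("stream_id", sort=False):
            crow = comps[
                (comps["experiment_id"].astype(str) == exp_id)
                & (comps["stream_id"].astype(str) == str(sid))
            ]
            if len(crow) != 1:
                raise SchemaError(
                    f"compositions.csv: need exactly one row for ({exp_id}, {sid})"
                )
            c_in = crow[list(names)].to_numpy(float)[0]
            seg = seg.sort_values("t_start_h")
            schedule = tuple(
                (row.t_start_h, row.t_end_h, row.rate) for row in seg.itertuples()
            )
            try:
                streams.append(FeedStream(c_in, schedule, name=str(sid)))
            except Exception as exc:
                raise SchemaError(f"feeds.csv: stream ({exp_id}, {sid}): {exc}") from exc
        try:
            experiments.append(
                Experiment(exp_id, times, values, sigmas, c0, v0, tuple(streams))
            )
        except Exception as exc:
            raise SchemaError(f"experiment {exp_id}: {exc}") from exc

    provenance = {k: v for k, v in meta.items() if k != "xv_name"}
    return ExperimentDataset(species, experiments, provenance)


def load_run_config(path: str | Path) -> dict:
    """Strictly validated YAML/JSON run configuration."""
    import yaml

    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: run config must be a mapping")
    allowed = {
        "structure", "hidden", "activation", "trainer", "iterations", "adam",
        "lmm", "substep", "volume_input", "partitions", "n_test", "seed",
        "noise_fraction",
    }
    unknown = set(cfg) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg
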