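"""CSV/TSV readers and writers for every pipeline artifact.

All tables are plain text with a header row; provenance (package version,
seed, configuration hash) travels in ``#``-prefixed comment lines that every
reader skips.  Layouts:

* traces: long format ``complex_id,bin,intensity`` plus a ground-truth
  sidecar ``complex_id,n_fluorophores,bleach_bins`` (bleach bins
  semicolon-joined);
* step histogram: ``steps,occurrences``;
* gel lanes: ``lane_id,probe,position,intensity,is_background``;
* splicing: ``condition,replicate,s57,s56,s67``;
* isotherm: ``protein_nM,fraction_bound``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import BindingIsotherm
from .exceptions import SchemaError
from .footprint import LaneProfile
from .smtirf import IntensityTrace, StepCountHistogram

__all__ = [
    "write_traces",
    "read_traces",
    "read_trace_truth",
    "write_histogram",
    "read_histogram",
    "write_lanes",
    "read_lanes",
    "write_splicing",
    "read_splicing",
    "write_isotherm",
    "read_isotherm",
    "file_sha256",
]


def _provenance(extra: dict | None = None) -> str:
    fields = {"tool": f"ptbquant {__version__}"}
    if extra:
        fields.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in fields.items())


def _write_csv(df: pd.DataFrame, path, extra: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance(extra))
        df.to_csv(fh, index=False)


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# -- traces -----------------------------------------------------------------

def write_traces(traces, truths, path, truth_path, extra: dict | None = None) -> None:
    rows = [
        {"complex_id": t.complex_id, "bin": b, "intensity": v}
        for t in traces
        for b, v in enumerate(t.intensities)
    ]
    _write_csv(pd.DataFrame(rows, columns=["complex_id", "bin", "intensity"]), path, extra)
    truth_df = pd.DataFrame(
        [
            {
                "complex_id": tr.complex_id,
                "n_fluorophores": tr.n_fluorophores,
                "bleach_bins": ";".join(map(str, tr.bleach_bins)),
            }
            for tr in truths
        ],
        columns=["complex_id", "n_fluorophores", "bleach_bins"],
    )
    _write_csv(truth_df, truth_path, extra)


def read_traces(path, bin_ms: float = 200.0) -> list[IntensityTrace]:
    df = _read_csv(path, {"complex_id", "bin", "intensity"})
    traces = []
    for cid, grp in df.groupby("complex_id", sort=True):
        grp = grp.sort_values("bin")
        traces.append(IntensityTrace(str(cid), grp["intensity"].to_numpy(), bin_ms))
    return traces


def read_trace_truth(path) -> dict[str, int]:
    df = _read_csv(path, {"complex_id", "n_fluorophores"})
    return dict(zip(df["complex_id"].astype(str), df["n_fluorophores"].astype(int)))


# -- step histogram ---------------------------------------------------------

def write_histogram(hist: StepCountHistogram, path, extra: dict | None = None) -> None:
    df = pd.DataFrame(
        [{"steps": i, "occurrences": c} for i, c in sorted(hist.counts.items())]
    )
    _write_csv(df, path, extra)


def read_histogram(path) -> StepCountHistogram:
    df = _read_csv(path, {"steps", "occurrences"})
    return StepCountHistogram(dict(zip(df["steps"].astype(int), df["occurrences"].astype(int))))


# -- gel lanes --------------------------------------------------------------

def write_lanes(lanes, path, extra: dict | None = None) -> None:
    rows = [
        {
            "lane_id": lane.lane_id,
            "probe": lane.probe,
            "position": p,
            "intensity": v,
            "is_background": int(p in lane.background_ids),
        }
        for lane in lanes
        for p, v in sorted(lane.bands.items())
    ]
    _write_csv(pd.DataFrame(rows), path, extra)


def read_lanes(path) -> dict[str, LaneProfile]:
    df = _read_csv(path, {"lane_id", "probe", "position", "intensity", "is_background"})
    lanes: dict[str, LaneProfile] = {}
    for lid, grp in df.groupby("lane_id", sort=True):
        lanes[str(lid)] = LaneProfile(
            lane_id=str(lid),
            probe=str(grp["probe"].iloc[0]),
            bands=dict(zip(grp["position"].astype(int), grp["intensity"].astype(float))),
            background_ids=frozenset(
                grp.loc[grp["is_background"] == 1, "position"].astype(int)
            ),
        )
    return lanes


# -- splicing ---------------------------------------------------------------

def write_splicing(rows: pd.DataFrame, path, extra: dict | None = None) -> None:
    required = {"condition", "replicate", "s57", "s56", "s67"}
    if not required <= set(rows.columns):
        raise SchemaError(f"splicing table needs columns {sorted(required)}")
    _write_csv(rows, path, extra)


def read_splicing(path) -> pd.DataFrame:
    return _read_csv(path, {"condition", "replicate", "s57", "s56", "s67"})


# -- binding ----------------------------------------------------------------

def write_isotherm(iso: BindingIsotherm, path, extra: dict | None = None) -> None:
    df = pd.DataFrame(
        {"protein_nM": iso.protein_nM, "fraction_bound": iso.fraction_bound}
    )
    meta = {"rna_nM": iso.rna_nM}
    if extra:
        meta.update(extra)
    _write_csv(df, path, meta)


def read_isotherm(path, rna_nM: float = 3.0) -> BindingIsotherm:
    df = _read_csv(path, {"protein_nM", "fraction_bound"})
    return BindingIsotherm(
        protein_nM=df["protein_nM"].to_numpy(),
        fraction_bound=df["fraction_bound"].to_numpy(),
        rna_nM=rna_nM,
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
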