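"""CSV schemas and readers/writers for assay, velocity, and track tables.

All tables are plain CSV with units embedded in the column names:

* assay:    ``species, temperature_c, ph, pair_id, tech_rep, n_scored, n_fertilized``
* velocity: ``sample_id, temperature_c, ph, velocity_um_s, motile_flag`` (one
  row per tracked sperm)
* tracks:   ``track_id, frame, x_um, y_um`` with the frame rate in a
  ``# frame_rate_hz=...`` comment on the first line

Readers validate schemas up front and report the offending row on bad counts;
``aggregate_assay`` implements the fixed aggregation order: per technical
replicate, fertilization proportion = n_fertilized / n_scored; technical
replicates are then averaged within each biological replicate (male–female
pair), and treatment summaries average biological replicates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import SpermTrack, VelocitySample
from .synthetic import FertAssayRecord
from .tpc import TPCDataset

__all__ = [
    "ASSAY_COLUMNS",
    "VELOCITY_COLUMNS",
    "TRACK_COLUMNS",
    "write_assay_csv",
    "read_assay_csv",
    "write_velocity_csv",
    "read_velocity_csv",
    "write_track_csv",
    "read_track_csv",
    "aggregate_assay",
    "assay_tpc_dataset",
    "velocity_tpc_datasets",
]

ASSAY_COLUMNS = ["species", "temperature_c", "ph", "pair_id", "tech_rep",
                 "n_scored", "n_fertilized"]
VELOCITY_COLUMNS = ["sample_id", "temperature_c", "ph", "velocity_um_s", "motile_flag"]
TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")


def write_assay_csv(records, path) -> Path:
    path = Path(path)
    df = pd.DataFrame([{
        "species": r.species, "temperature_c": r.temperature, "ph": r.ph,
        "pair_id": r.pair_id, "tech_rep": r.tech_rep,
        "n_scored": r.n_scored, "n_fertilized": r.n_fertilized,
    } for r in records], columns=ASSAY_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_assay_csv(path) -> list[FertAssayRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, ASSAY_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        for col in ("n_scored", "n_fertilized", "tech_rep"):
            val = row[col]
            if not float(val).is_integer():
                raise ValueError(f"{path} row {i + 2}: {col}={val} is not integral")
        if row["n_fertilized"] > row["n_scored"]:
            raise ValueError(
                f"{path} row {i + 2}: n_fertilized={row['n_fertilized']} exceeds "
                f"n_scored={row['n_scored']}")
        records.append(FertAssayRecord(
            species=str(row["species"]), temperature=float(row["temperature_c"]),
            ph=float(row["ph"]), pair_id=str(row["pair_id"]),
            tech_rep=int(row["tech_rep"]), n_scored=int(row["n_scored"]),
            n_fertilized=int(row["n_fertilized"]),
        ))
    return records


def write_velocity_csv(samples, path) -> Path:
    path = Path(path)
    rows = []
    for s in samples:
        for v in s.velocities:
            rows.append({
                "sample_id": s.sample_id, "temperature_c": s.temperature,
                "ph": "" if s.ph is None else s.ph,
                "velocity_um_s": float(v),
                "motile_flag": int(v > s.motility_threshold),
            })
    pd.DataFrame(rows, columns=VELOCITY_COLUMNS).to_csv(path, index=False)
    return path


def read_velocity_csv(path, motility_threshold: float | None = None) -> list[VelocitySample]:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, VELOCITY_COLUMNS, path)
    if (df["velocity_um_s"] < 0).any():
        bad = int(df.index[df["velocity_um_s"] < 0][0]) + 2
        raise ValueError(f"{path} row {bad}: negative velocity")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        v = grp["velocity_um_s"].to_numpy(dtype=float)
        thr = motility_threshold
        if thr is None:
            from .kinematics import DEFAULT_MOTILITY_THRESHOLD as thr  # noqa: N813
        motile = v[v > thr]
        ph = grp["ph"].iloc[0]
        samples.append(VelocitySample(
            sample_id=str(sid),
            temperature=float(grp["temperature_c"].iloc[0]),
            ph=None if pd.isna(ph) else float(ph),
            velocities=v,
            motile_fraction=float(np.mean(v > thr)),
            mean_vcl=float(motile.mean()) if motile.size else 0.0,
            all_immotile=motile.size == 0,
            motility_threshold=float(thr),
        ))
    return samples


def write_track_csv(tracks, path) -> Path:
    path = Path(path)
    frame_rates = {t.frame_rate for t in tracks}
    if len(frame_rates) != 1:
        raise ValueError("all tracks in one file must share a frame rate")
    rows = []
    for t in tracks:
        for frame, (x, y) in enumerate(t.points):
            rows.append({"track_id": t.track_id, "frame": frame, "x_um": x, "y_um": y})
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={frame_rates.pop():g}\n")
        pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(fh, index=False)
    return path


def read_track_csv(path, frame_rate: float | None = None) -> list[SpermTrack]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# frame_rate_hz="):
            frame_rate = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if frame_rate is None:
        raise ValueError(f"{path}: frame rate not in header; pass frame_rate=")
    _check_columns(df, TRACK_COLUMNS, path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        tracks.append(SpermTrack(track_id=str(tid), frame_rate=frame_rate, points=pts))
    return tracks


def aggregate_assay(records) -> pd.DataFrame:
    """Biological-replicate fertilization proportions.

    One row per (species, temperature, pH, pair): the mean over technical
    replicates of per-replicate proportions n_fertilized / n_scored.
    """
    df = pd.DataFrame([{
        "species": r.species, "temperature_c": r.temperature, "ph": r.ph,
        "pair_id": r.pair_id, "proportion": r.proportion,
    } for r in records])
    if df.empty:
        raise ValueError("no assay records to aggregate")
    out = (df.groupby(["species", "temperature_c", "ph", "pair_id"], sort=True)
             ["proportion"].mean().reset_index()
             .rename(columns={"proportion": "fertilization_proportion"}))
    return out


def assay_tpc_dataset(records, trait_name: str = "fertilization") -> TPCDataset:
    """TPC dataset of biological-replicate fertilization proportions."""
    agg = aggregate_assay(records)
    return TPCDataset(
        trait_name=trait_name,
        temperature=agg["temperature_c"].to_numpy(),
        rate=agg["fertilization_proportion"].to_numpy(),
        replicate_id=agg["pair_id"].to_numpy(),
    )


def velocity_tpc_datasets(samples) -> tuple[TPCDataset, TPCDataset]:
    """(velocity, motility) TPC datasets, one point per sample."""
    temps = np.array([s.temperature for s in samples])
    ids = np.array([s.sample_id for s in samples])
    vel = TPCDataset("velocity", temps,
                     np.array([s.mean_vcl for s in samples]), ids)
    mot = TPCDataset("motility", temps,
                     np.array([s.motile_fraction for s in samples]), ids)
    return vel, mot
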