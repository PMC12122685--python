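"""Readers and writers for the documented plain-text formats.

Formats
-------
trajectory CSV   t_s,x_cm,y_cm            (+ ``# key=value`` header lines)
event-log CSV    window_id,state,start_s,end_s
trial CSV        animal,session,trial,arm,pellets,quinine_flag,exclusion
cell CSV         animal,hemisphere,level,x_um,y_um
outline JSON     {animal, hemisphere, level, group, outline_um, lesion_um}
matrix CSV       plain comma-separated numbers (maps, components)

Every writer records the generator seed (when known) in a ``#`` header
comment; readers skip comment lines.  Floats are written with a fixed
"%.6g" format so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arenas import ArenaSpec, checking_platform, epm, open_field
from .rigt import TrialRecord
from .spatial import StriatalSection
from .states import StateEventLog
from .trajectory import Trajectory

FLOAT_FMT = "%.6g"

_ARENAS = {
    "open_field": open_field,
    "epm": epm,
    "checking_platform": checking_platform,
}


def _header_lines(meta: dict) -> list[str]:
    return [f"# {k}={meta[k]}" for k in sorted(meta) if np.isscalar(meta[k])]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    path = Path(path)
    meta = {"arena": traj.arena.kind, **traj.meta}
    lines = _header_lines(meta)
    lines.append("t_s,x_cm,y_cm")
    for t, x, y in zip(traj.t, traj.x, traj.y):
        lines.append(f"{FLOAT_FMT % t},{FLOAT_FMT % x},{FLOAT_FMT % y}")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory_csv(path, arena: ArenaSpec | None = None) -> Trajectory:
    path = Path(path)
    meta: dict = {}
    rows = []
    for ln in path.read_text().splitlines():
        if ln.startswith("#"):
            key, _, val = ln[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            continue
        if not ln or ln.startswith("t_s"):
            continue
        rows.append([float(v) for v in ln.split(",")])
    if arena is None:
        kind = meta.get("arena", "open_field")
        if kind not in _ARENAS:
            raise ValueError(f"{path}: unknown arena kind {kind!r}")
        arena = _ARENAS[kind]()
    data = np.asarray(rows)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns t_s,x_cm,y_cm")
    return Trajectory(data[:, 0], data[:, 1], data[:, 2], arena, meta)


def write_event_log_csv(logs: list[StateEventLog], path, seed=None) -> None:
    lines = [] if seed is None else [f"# seed={seed}"]
    lines.append("window_id,state,start_s,end_s")
    for log in logs:
        for state, start, end in log.events:
            lines.append(
                f"{log.window_id},{state},{FLOAT_FMT % start},{FLOAT_FMT % end}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_log_csv(path) -> list[StateEventLog]:
    from .states import parse_event_log

    rows = []
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("#") or not ln or ln.startswith("window_id"):
            continue
        wid, state, start, end = ln.split(",")
        rows.append((wid, state, float(start), float(end)))
    return parse_event_log(rows)


def write_trials_csv(records: list[TrialRecord], path, seed=None) -> None:
    lines = [] if seed is None else [f"# seed={seed}"]
    lines.append("animal,session,trial,arm,pellets,quinine_flag,exclusion")
    for r in records:
        lines.append(
            f"{r.animal},{r.session},{r.trial},{r.arm},{r.pellets},"
            f"{int(r.quinine)},{r.exclusion}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trials_csv(path) -> list[TrialRecord]:
    records = []
    for i, ln in enumerate(Path(path).read_text().splitlines()):
        if ln.startswith("#") or not ln or ln.startswith("animal,"):
            continue
        parts = ln.split(",")
        if len(parts) != 7:
            raise ValueError(f"{path}: malformed row {i}: {ln!r}")
        animal, session, trial, arm, pellets, quinine, excl = parts
        records.append(
            TrialRecord(
                animal, int(session), int(trial), arm, int(pellets),
                bool(int(quinine)), excl,
            )
        )
    return records


def write_sections(sections: list[StriatalSection], cells_path, outlines_path,
                   seed=None) -> None:
    lines = [] if seed is None else [f"# seed={seed}"]
    lines.append("animal,hemisphere,level,x_um,y_um")
    outlines = []
    for s in sections:
        for x, y in s.cells:
            lines.append(
                f"{s.animal},{s.hemisphere},{FLOAT_FMT % s.level},"
                f"{FLOAT_FMT % x},{FLOAT_FMT % y}"
            )
        outlines.append(
            {
                "animal": s.animal,
                "hemisphere": s.hemisphere,
                "level": s.level,
                "group": s.group,
                "outline_um": np.round(s.outline, 3).tolist(),
                "lesion_um": (
                    np.round(s.lesion, 3).tolist() if s.lesion is not None else None
                ),
            }
        )
    Path(cells_path).write_text("\n".join(lines) + "\n")
    Path(outlines_path).write_text(json.dumps(outlines, indent=None, sort_keys=True))


def read_sections(cells_path, outlines_path) -> list[StriatalSection]:
    cells: dict[tuple, list] = {}
    for i, ln in enumerate(Path(cells_path).read_text().splitlines()):
        if ln.startswith("#") or not ln or ln.startswith("animal,"):
            continue
        animal, hemi, level, x, y = ln.split(",")
        cells.setdefault((animal, hemi, float(level)), []).append(
            (float(x), float(y))
        )
    sections = []
    for rec in json.loads(Path(outlines_path).read_text()):
        key = (rec["animal"], rec["hemisphere"], float(rec["level"]))
        sections.append(
            StriatalSection(
                animal=rec["animal"],
                hemisphere=rec["hemisphere"],
                level=float(rec["level"]),
                outline=np.asarray(rec["outline_um"], float),
                cells=np.asarray(cells.get(key, []), float).reshape(-1, 2),
                lesion=(
                    np.asarray(rec["lesion_um"], float)
                    if rec.get("lesion_um") is not None
                    else None
                ),
                group=rec.get("group", ""),
            )
        )
    return sections


def write_matrix_csv(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, float), fmt=FLOAT_FMT, delimiter=",")


def read_matrix_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def load_params_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: parameter file must map names to values")
    return out


def render_map_png(array: np.ndarray, path, title: str = "", symmetric=False) -> None:
    """Small matplotlib rendering of a map for visual QC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    arr = np.asarray(array, float)
    if symmetric:
        v = np.nanmax(np.abs(arr)) or 1.0
        im = ax.imshow(arr, origin="lower", cmap="RdBu_r", vmin=-v, vmax=v)
    else:
        im = ax.imshow(arr, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
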