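"""Domain types for ultrafiltration-HPLC screens.

A screen compares three incubation conditions of the same extract:

* ``blank`` -- extract incubated without the enzyme source; peak areas
  measure non-specific retention on the ultrafiltration membrane (A_b).
* ``experimental`` -- extract incubated with the enzyme source; areas
  include specifically bound ligand (A_a).
* ``control`` -- extract incubated with the enzyme source after the
  active site of one expected target was blocked with a competitive
  probe; areas reveal displaceable binding at that target (A_c).

This module holds the chromatogram/peak containers, the screen design
manifest binding runs to those roles, and plain-text readers/writers.
Time is always minutes, detector signal mAU, peak area mAU*min.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GROUPS",
    "Chromatogram",
    "Peak",
    "PeakTable",
    "ScreenDesign",
    "ValidationError",
    "ChromatogramParseError",
    "read_chromatogram",
    "write_chromatogram",
    "read_design",
    "write_design",
    "read_peak_table",
    "write_peak_table",
]

GROUPS = ("blank", "experimental", "control")

#: uniform-grid tolerance, minutes
_GRID_ATOL = 1e-9


class ValidationError(ValueError):
    """An object violates a structural invariant of the screen design."""


class ChromatogramParseError(ValueError):
    """A chromatogram file could not be parsed; names the offending line."""


@dataclass(frozen=True)
class Chromatogram:
    """A uniformly sampled detector trace for one run.

    Parameters
    ----------
    run_id : str
        Unique identifier of the run within a screen.
    group : {'blank', 'experimental', 'control'}
        Role of the run in the three-condition design.
    control_target : str
        Target whose probe was used to block its active site; required
        exactly when ``group == 'control'``, empty otherwise.
    time : ndarray
        Strictly increasing, uniform grid in minutes.
    signal : ndarray
        Detector response in mAU, same length as ``time``.
    """

    run_id: str
    group: str
    control_target: str
    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "signal", signal)
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}")
        if (self.group == "control") != bool(self.control_target):
            raise ValidationError(
                "control_target must be set if and only if group is 'control' "
                f"(got group={self.group!r}, control_target={self.control_target!r})"
            )
        if time.ndim != 1 or signal.ndim != 1 or time.shape != signal.shape:
            raise ValidationError("time and signal must be 1-D of equal length")
        if time.size < 2:
            raise ValidationError("chromatogram needs at least 2 samples")
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise ValidationError("non-monotone time")
        if np.ptp(steps) > _GRID_ATOL:
            raise ValidationError("time grid is not uniform")

    @property
    def sampling_interval(self) -> float:
        """Grid step in minutes."""
        return float(self.time[1] - self.time[0])

    def with_signal(self, signal: np.ndarray) -> "Chromatogram":
        """Copy of this chromatogram with the signal replaced."""
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass(frozen=True)
class Peak:
    """One detected, baseline-corrected chromatographic peak."""

    apex_rt: float
    start_rt: float
    end_rt: float
    height: float  # mAU
    area: float  # mAU*min

    def __post_init__(self):
        if not (self.start_rt < self.apex_rt < self.end_rt):
            raise ValidationError(
                f"peak bounds must satisfy start < apex < end, got "
                f"({self.start_rt}, {self.apex_rt}, {self.end_rt})"
            )
        if self.area < 0 or self.height < 0:
            raise ValidationError("peak area and height must be non-negative")


@dataclass(frozen=True)
class PeakTable:
    """Peaks of one run, sorted by apex retention time, non-overlapping."""

    run_id: str
    group: str
    control_target: str
    peaks: tuple[Peak, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}")
        if (self.group == "control") != bool(self.control_target):
            raise ValidationError(
                "control_target must be set if and only if group is 'control'"
            )
        for prev, cur in zip(self.peaks, self.peaks[1:]):
            if cur.apex_rt < prev.apex_rt:
                raise ValidationError("peaks must be sorted by apex_rt")
            if cur.start_rt < prev.end_rt:
                raise ValidationError(
                    f"overlapping peaks: [{prev.start_rt}, {prev.end_rt}] and "
                    f"[{cur.start_rt}, {cur.end_rt}]"
                )

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class ScreenDesign:
    """Manifest binding runs to the three-condition design.

    Exactly one blank run, exactly one experimental run, and exactly one
    control run per target.
    """

    targets: tuple[str, ...]
    probe_of: Mapping[str, str]
    runs: tuple[tuple[str, str, str], ...]  # (run_id, group, control_target)
    chromatogram_paths: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "probe_of", dict(self.probe_of))
        object.__setattr__(self, "runs", tuple(tuple(r) for r in self.runs))
        object.__setattr__(
            self, "chromatogram_paths", dict(self.chromatogram_paths)
        )
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("duplicate target identifiers")
        run_ids = [r[0] for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            raise ValidationError("run_ids must be unique")
        missing_probes = [t for t in self.targets if t not in self.probe_of]
        if missing_probes:
            raise ValidationError(f"targets without a probe: {missing_probes}")
        n_blank = n_exp = 0
        controls: dict[str, int] = {t: 0 for t in self.targets}
        for run_id, group, ctl in self.runs:
            if group not in GROUPS:
                raise ValidationError(
                    f"unknown group label {group!r} for run {run_id!r}"
                )
            if group == "control":
                if not ctl:
                    raise ValidationError(
                        f"control run {run_id!r} must name its blocked target"
                    )
                if ctl not in controls:
                    raise ValidationError(
                        f"control run {run_id!r} names unknown target {ctl!r}"
                    )
                controls[ctl] += 1
            else:
                if ctl:
                    raise ValidationError(
                        f"non-control run {run_id!r} must not name a target"
                    )
                if group == "blank":
                    n_blank += 1
                else:
                    n_exp += 1
        if n_blank != 1:
            raise ValidationError("exactly one blank run required")
        if n_exp != 1:
            raise ValidationError("exactly one experimental run required")
        bad = [t for t, n in controls.items() if n != 1]
        if bad:
            raise ValidationError(
                f"each target requires exactly one control run; violated for {bad}"
            )

    @property
    def blank_run(self) -> str:
        return next(r for r, g, _ in self.runs if g == "blank")

    @property
    def experimental_run(self) -> str:
        return next(r for r, g, _ in self.runs if g == "experimental")

    def control_run(self, target: str) -> str:
        for run_id, group, ctl in self.runs:
            if group == "control" and ctl == target:
                return run_id
        raise KeyError(target)


# ---------------------------------------------------------------------------
# Chromatogram files: 2-column CSV/TSV, optional '#' comments, optional header


def read_chromatogram(
    path: str | Path,
    run_id: str,
    group: str,
    control_target: str = "",
) -> Chromatogram:
    """Read a two-column (time, signal) delimited text file.

    The delimiter (comma or tab) is auto-detected; ``#`` comment lines
    and a single non-numeric header line are skipped.  The time grid
    must be strictly increasing and uniform -- non-uniform grids are
    rejected, never resampled.
    """
    path = Path(path)
    times: list[float] = []
    signals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) != 2:
                raise ChromatogramParseError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                t, s = float(fields[0]), float(fields[1])
            except ValueError:
                if not times and lineno <= 2:  # header line
                    continue
                raise ChromatogramParseError(
                    f"{path.name}:{lineno}: malformed row {line!r}"
                ) from None
            times.append(t)
            signals.append(s)
    if len(times) < 2:
        raise ChromatogramParseError(
            f"{path.name}: fewer than 2 data rows"
        )
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ChromatogramParseError(
            f"{path.name}: non-monotone time near row {bad + 1} "
            f"(t={t[bad]:g} followed by t={t[bad + 1]:g})"
        )
    try:
        return Chromatogram(run_id, group, control_target, t, np.asarray(signals))
    except ValidationError as exc:
        raise ChromatogramParseError(f"{path.name}: {exc}") from exc


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    """Write a chromatogram as a two-column CSV with a header line."""
    with open(path, "w") as fh:
        fh.write(f"# run_id={chrom.run_id} group={chrom.group}")
        if chrom.control_target:
            fh.write(f" control_target={chrom.control_target}")
        fh.write("\ntime_min,signal_mAU\n")
        for t, s in zip(chrom.time, chrom.signal):
            fh.write(f"{t:.6f},{s:.6f}\n")


# ---------------------------------------------------------------------------
# Design manifest (YAML or JSON): keys targets, probes, runs


def read_design(path: str | Path) -> ScreenDesign:
    """Read and validate a screen design manifest (YAML or JSON)."""
    path = Path(path)
    with open(path) as fh:
        raw = fh.read()
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise ValidationError(f"{path.name}: manifest must be a mapping")
    for key in ("targets", "probes", "runs"):
        if key not in data:
            raise ValidationError(f"{path.name}: missing key {key!r}")
    runs = []
    paths = {}
    for entry in data["runs"]:
        run_id = str(entry["run_id"])
        runs.append(
            (run_id, str(entry["group"]), str(entry.get("control_target") or ""))
        )
        if "path" in entry:
            paths[run_id] = str(entry["path"])
    return ScreenDesign(
        targets=tuple(str(t) for t in data["targets"]),
        probe_of={str(k): str(v) for k, v in data["probes"].items()},
        runs=tuple(runs),
        chromatogram_paths=paths,
    )


def write_design(design: ScreenDesign, path: str | Path) -> None:
    """Write a design manifest as YAML."""
    data = {
        "targets": list(design.targets),
        "probes": dict(design.probe_of),
        "runs": [
            {
                "run_id": run_id,
                "group": group,
                **({"control_target": ctl} if ctl else {}),
                **(
                    {"path": design.chromatogram_paths[run_id]}
                    if run_id in design.chromatogram_paths
                    else {}
                ),
            }
            for run_id, group, ctl in design.runs
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Peak tables: CSV with one row per peak (or a JSON mirror)

_PEAK_COLUMNS = [
    "run_id",
    "group",
    "control_target",
    "apex_rt",
    "start_rt",
    "end_rt",
    "height",
    "area",
]


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write a peak table as CSV (``.json`` path writes the JSON mirror)."""
    path = Path(path)
    rows = [
        {
            "run_id": table.run_id,
            "group": table.group,
            "control_target": table.control_target,
            "apex_rt": p.apex_rt,
            "start_rt": p.start_rt,
            "end_rt": p.end_rt,
            "height": p.height,
            "area": p.area,
        }
        for p in table.peaks
    ]
    if path.suffix == ".json":
        meta = {
            "run_id": table.run_id,
            "group": table.group,
            "control_target": table.control_target,
            "peaks": [
                {k: r[k] for k in _PEAK_COLUMNS[3:]} for r in rows
            ],
        }
        path.write_text(json.dumps(meta, indent=1))
        return
    df = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
    header_only = df.empty
    with open(path, "w") as fh:
        if header_only:
            fh.write(",".join(_PEAK_COLUMNS) + "\n")
            fh.write(f"#empty run_id={table.run_id} group={table.group} "
                     f"control_target={table.control_target}\n")
        else:
            df.to_csv(fh, index=False, float_format="%.9f")


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak table written by :func:`write_peak_table`."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        peaks = tuple(
            Peak(p["apex_rt"], p["start_rt"], p["end_rt"], p["height"], p["area"])
            for p in data["peaks"]
        )
        return PeakTable(
            data["run_id"], data["group"], data.get("control_target", ""), peaks
        )
    text = path.read_text()
    meta = None
    for line in text.splitlines():
        if line.startswith("#empty"):
            meta = dict(kv.split("=", 1) for kv in line[7:].split())
    df = pd.read_csv(io.StringIO(text), comment="#")
    if df.empty:
        if meta is None:
            raise ValidationError(f"{path.name}: empty table without metadata")
        return PeakTable(meta["run_id"], meta["group"], meta["control_target"], ())
    run_ids = df["run_id"].unique()
    if len(run_ids) != 1:
        raise ValidationError(f"{path.name}: multiple run_ids in one table")
    df = df.sort_values("apex_rt")
    ctl = df["control_target"].iloc[0]
    ctl = "" if pd.isna(ctl) else str(ctl)
    peaks = tuple(
        Peak(
            float(r.apex_rt),
            float(r.start_rt),
            float(r.end_rt),
            float(r.height),
            float(r.area),
        )
        for r in df.itertuples()
    )
    return PeakTable(str(run_ids[0]), str(df["group"].iloc[0]), ctl, peaks)
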