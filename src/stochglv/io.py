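"""Reading and writing the package's plain-text formats.

Abundance series travel as tab-separated text: a header row with ``time``
followed by species labels, then one row per time point.  Blueprints and
run settings are YAML mappings of scalar keys, so every artifact can be
re-created from its sidecar config and seed alone.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .experiments import CommunityBlueprint
from .simulate import AbundanceSeries

__all__ = [
    "write_abundance_table",
    "read_abundance_table",
    "write_blueprint",
    "read_blueprint",
    "write_sidecar",
]


def write_abundance_table(series: AbundanceSeries, path: str | Path) -> None:
    """Write a series as TSV: time column, one column per species."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["time", *series.species_labels])
        for t, row in zip(series.times, series.values):
            w.writerow([repr(float(t)), *[repr(float(v)) for v in row]])


def read_abundance_table(path: str | Path) -> AbundanceSeries:
    """Read a TSV abundance table, validating shape, signs and uniform spacing.

    The first column is time (or an integer index); remaining columns are
    species abundances.  Malformed input raises ``ValueError`` naming the
    offending line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file")
        labels = [h.strip() for h in header[1:]]
        if not labels:
            raise ValueError(f"{path}: header must name a time column and at least one species")
        times, rows = [], []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != len(labels) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(labels) + 1} columns, found {len(rec)}"
                )
            try:
                vals = [float(v) for v in rec]
            except ValueError:
                bad = next(i for i, v in enumerate(rec) if not _is_float(v))
                raise ValueError(f"{path}:{lineno}: non-numeric value {rec[bad]!r} in column {bad + 1}")
            for col, v in enumerate(vals[1:], start=2):
                if v < 0:
                    raise ValueError(f"{path}:{lineno}: negative abundance in column {col}")
            times.append(vals[0])
            rows.append(vals[1:])
    if len(rows) < 1:
        raise ValueError(f"{path}: no data rows")
    times = np.asarray(times)
    if times.size >= 2:
        steps = np.diff(times)
        if np.any(np.abs(steps - steps[0]) > 1e-6 * max(abs(steps[0]), 1e-300)):
            bad = int(np.argmax(np.abs(steps - steps[0]) > 1e-6 * abs(steps[0]))) + 3
            raise ValueError(f"{path}: non-uniform time spacing near line {bad}")
    return AbundanceSeries(times=times, values=np.asarray(rows), species_labels=labels,
                           metadata={"source": str(path)})


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_blueprint(bp: CommunityBlueprint, path: str | Path) -> None:
    data = dataclasses.asdict(bp)
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
        elif isinstance(v, np.ndarray):
            data[k] = v.tolist()
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_blueprint(path: str | Path) -> CommunityBlueprint:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: blueprint config must be a mapping")
    known = {f.name for f in dataclasses.fields(CommunityBlueprint)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown blueprint keys {sorted(unknown)}")
    for k in ("growth_band", "self_interaction_range"):
        if k in data and isinstance(data[k], list):
            data[k] = tuple(data[k])
    return CommunityBlueprint(**data)


def write_sidecar(path: str | Path, settings: dict) -> None:
    """Record the settings and seed that produced an output artifact."""
    clean = {}
    for k, v in settings.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            v = v.item()
        elif isinstance(v, tuple):
            v = list(v)
        clean[k] = v
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=False))
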