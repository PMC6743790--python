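"""File formats: tidy assay CSVs, kinetic-matrix JSON, report TSVs, YAML configs.

The canonical internal orientation is fraction *uncleaved* (the quantity
the rate law integrates).  Real mass-spectrometry readouts quantify the
*cleaved* barcode; ``orientation="cleaved"`` converts v -> 1 - v at the
boundary so everything downstream stays in one convention.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .design import FamilyAssignment, SelectionTrace
from .evaluate import RmseReport
from .kinetics import KineticMatrix, ParameterError, ShapeError, Timecourse
from .simulate import MixtureAssay, ParamRanges, SimConfig, SingleAssay

__all__ = [
    "ValidationError",
    "ASSAY_COLUMNS",
    "read_assay_table",
    "read_single_assays",
    "read_mixture_assay",
    "write_single_assays",
    "write_mixture_assay",
    "write_kinetic_matrix",
    "read_kinetic_matrix",
    "write_rmse_report",
    "write_selection_trace",
    "write_family_assignment",
    "load_config",
    "save_config",
    "config_to_dict",
    "write_manifest",
]

ASSAY_COLUMNS = ("protease_id", "substrate_id", "time_minutes", "value")


class ValidationError(ValueError):
    """An input file violates the format contract."""


def read_assay_table(path, orientation: str = "uncleaved") -> pd.DataFrame:
    """Read and validate a tidy assay CSV.

    Expected header: ``protease_id,substrate_id,time_minutes,value``.
    Returns a frame with a ``fraction_uncleaved`` column, sorted by
    (protease, substrate, time).  Row numbers in error messages refer to
    lines of the CSV file (header is line 1).
    """
    if orientation not in ("uncleaved", "cleaved"):
        raise ValidationError(f"orientation must be 'uncleaved' or 'cleaved', got {orientation!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    lines = df.index.to_numpy() + 2  # header occupies line 1
    values = df["value"].to_numpy(dtype=float)
    bad = (values < 0) | (values > 1) | ~np.isfinite(values)
    if bad.any():
        rows = lines[bad][:5].tolist()
        raise ValidationError(
            f"{path}: 'value' outside [0, 1] at line(s) {rows}"
        )
    times = df["time_minutes"].to_numpy(dtype=float)
    if (times < 0).any():
        rows = lines[times < 0][:5].tolist()
        raise ValidationError(f"{path}: negative time_minutes at line(s) {rows}")
    dup = df.duplicated(subset=["protease_id", "substrate_id", "time_minutes"])
    if dup.any():
        rows = lines[dup.to_numpy()][:5].tolist()
        raise ValidationError(
            f"{path}: duplicate (protease, substrate, time) triples at line(s) {rows}"
        )
    out = df.copy()
    out["fraction_uncleaved"] = 1.0 - values if orientation == "cleaved" else values
    out = out.sort_values(
        ["protease_id", "substrate_id", "time_minutes"], kind="stable"
    ).reset_index(drop=True)
    return out


def _assays_from_frame(df: pd.DataFrame) -> list[SingleAssay]:
    assays = []
    for (prot, sub), grp in df.groupby(["protease_id", "substrate_id"], sort=True):
        assays.append(
            SingleAssay(
                protease=str(prot),
                substrate=str(sub),
                timecourse=Timecourse(
                    grp["time_minutes"].to_numpy(dtype=float),
                    grp["fraction_uncleaved"].to_numpy(dtype=float),
                ),
            )
        )
    return assays


def read_single_assays(path, orientation: str = "uncleaved") -> list[SingleAssay]:
    return _assays_from_frame(read_assay_table(path, orientation))


def read_mixture_assay(path, orientation: str = "uncleaved") -> MixtureAssay:
    """Read a mixture assay CSV; ``protease_id`` holds the mixture label."""
    df = read_assay_table(path, orientation)
    mixtures = df["protease_id"].unique()
    if len(mixtures) != 1:
        raise ValidationError(
            f"{path}: a mixture table must have exactly one protease_id, got {list(mixtures)}"
        )
    substrates = list(dict.fromkeys(df["substrate_id"].astype(str)))
    times = np.sort(df["time_minutes"].unique().astype(float))
    Y = np.empty((len(substrates), times.size))
    pivot = df.set_index(["substrate_id", "time_minutes"])["fraction_uncleaved"]
    for i, s in enumerate(substrates):
        for q, t in enumerate(times):
            try:
                Y[i, q] = pivot.loc[(s, t)]
            except KeyError:
                raise ValidationError(
                    f"{path}: missing value for substrate {s!r} at t={t}"
                ) from None
    return MixtureAssay(substrates=tuple(substrates), times=times, Y=Y)


def write_single_assays(assays: Sequence[SingleAssay], path) -> None:
    rows = []
    for a in assays:
        for t, y in zip(a.timecourse.times, a.timecourse.values):
            rows.append((a.protease, a.substrate, t, y))
    # %.17g guarantees exact float64 round-trips through text
    pd.DataFrame(rows, columns=list(ASSAY_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_mixture_assay(mix: MixtureAssay, path, mixture_id: str = "mixture") -> None:
    rows = []
    for i, s in enumerate(mix.substrates):
        for q, t in enumerate(mix.times):
            rows.append((mixture_id, s, t, mix.Y[i, q]))
    pd.DataFrame(rows, columns=list(ASSAY_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_kinetic_matrix(km: KineticMatrix, path) -> None:
    """Serialise a kinetic matrix as JSON (lossless float round-trip)."""
    cells = {
        s: {
            p: {
                "V": km.V[i, j],
                "K": km.K[i, j],
                "n": km.n[i, j],
                "beta": km.beta[i, j],
            }
            for j, p in enumerate(km.proteases)
        }
        for i, s in enumerate(km.substrates)
    }
    payload = {
        "substrates": list(km.substrates),
        "proteases": list(km.proteases),
        "params": cells,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_kinetic_matrix(path) -> KineticMatrix:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"{path}: malformed JSON ({e})") from None
    try:
        substrates = list(payload["substrates"])
        proteases = list(payload["proteases"])
        cells = payload["params"]
    except (KeyError, TypeError) as e:
        raise ValidationError(f"{path}: missing top-level key {e}") from None
    M, N = len(substrates), len(proteases)
    arrays = {name: np.empty((M, N)) for name in ("V", "K", "n", "beta")}
    for i, s in enumerate(substrates):
        for j, p in enumerate(proteases):
            try:
                cell = cells[s][p]
                for name in arrays:
                    arrays[name][i, j] = float(cell[name])
            except (KeyError, TypeError):
                raise ValidationError(
                    f"{path}: missing or malformed cell for ({s!r}, {p!r})"
                ) from None
    try:
        return KineticMatrix(tuple(substrates), tuple(proteases), **arrays)
    except (ParameterError, ShapeError) as e:
        raise ValidationError(f"{path}: {e}") from None


def write_rmse_report(report: RmseReport, tsv_path, json_path=None) -> None:
    pd.DataFrame(
        {"id": report.ids, "rmse": report.per_protease}
    ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {
                    "overall": report.overall,
                    "per_id": dict(zip(report.ids, report.per_protease.tolist())),
                    "P": report.P,
                },
                indent=1,
            )
        )


def write_selection_trace(trace: SelectionTrace, path) -> None:
    trace.to_frame().to_csv(path, sep="\t", index=False)


def write_family_assignment(fa: FamilyAssignment, path, linkage_path=None) -> None:
    pd.DataFrame(
        {"protease": list(fa.labels), "family": list(fa.labels.values())}
    ).to_csv(path, sep="\t", index=False)
    if linkage_path is not None:
        pd.DataFrame({"merge_height": fa.linkage_heights}).to_csv(
            linkage_path, sep="\t", index=False
        )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["times"] = list(config.times)
    d["calibration_times"] = list(config.calibration_times)
    d["alpha_range"] = list(config.alpha_range)
    d["param_ranges"] = {
        k: list(v) for k, v in dataclasses.asdict(config.param_ranges).items()
    }
    return d


def load_config(path) -> SimConfig:
    """Build a SimConfig from a YAML mapping of field names to values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = dict(raw)
    for key in ("times", "calibration_times"):
        if key in kwargs:
            kwargs[key] = tuple(float(t) for t in kwargs[key])
    if "alpha_range" in kwargs:
        kwargs["alpha_range"] = tuple(float(x) for x in kwargs["alpha_range"])
    if "param_ranges" in kwargs:
        pr = kwargs["param_ranges"]
        kwargs["param_ranges"] = ParamRanges(
            **{k: tuple(float(x) for x in v) for k, v in pr.items()}
        )
    try:
        return SimConfig(**kwargs)
    except (ParameterError, TypeError) as e:
        raise ValidationError(f"{path}: {e}") from None


def save_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def write_manifest(path, command: str, seed, config: SimConfig | None, **options) -> None:
    """Record what produced a set of outputs: tool version, seed, config echo."""
    from . import __version__

    payload = {
        "tool": "protdeconv",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config_to_dict(config) if config is not None else None,
        "options": options,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
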