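"""Plain-text readers/writers for the pipeline's data formats.

Tabular inputs are CSV with ``#key=value`` metadata header lines;
alignments are FASTA; discrete trajectories are one integer per line,
one file per trajectory.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InvalidParameterError
from .synthetic import (BindingIsotherm, DiscreteTrajectorySet, DispersionCurve,
                        FeatureTrajectory, KineticTrace, MeltCurve, MultipleAlignment)

__all__ = [
    "write_csv_with_meta", "read_csv_with_meta",
    "write_trace", "read_trace",
    "write_melt", "read_melt",
    "write_isotherm", "read_isotherm",
    "write_cpmg", "read_cpmg",
    "write_dtrajs", "read_dtrajs",
    "write_features", "read_features",
    "write_alignment", "read_alignment",
]


def write_csv_with_meta(df: pd.DataFrame, meta: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, index=False)


def read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return df, meta


def write_trace(trace: KineticTrace, path) -> None:
    meta = {"mode": trace.mode, "allotype": trace.allotype,
            "dm_conc": trace.dm_conc, "temperature": trace.temperature}
    write_csv_with_meta(pd.DataFrame({"time": trace.times, "signal": trace.signal}),
                        meta, path)


def read_trace(path) -> KineticTrace:
    df, meta = read_csv_with_meta(path)
    return KineticTrace(times=df["time"].to_numpy(), signal=df["signal"].to_numpy(),
                        mode=meta.get("mode", "dissociation"),
                        allotype=meta.get("allotype", ""),
                        dm_conc=float(meta.get("dm_conc", 0) or 0),
                        temperature=float(meta.get("temperature", 37) or 37))


def write_melt(curve: MeltCurve, path) -> None:
    write_csv_with_meta(pd.DataFrame({"temperature": curve.temperatures,
                                      "fluorescence": curve.fluorescence}),
                        {"allotype": curve.allotype}, path)


def read_melt(path) -> MeltCurve:
    df, meta = read_csv_with_meta(path)
    return MeltCurve(temperatures=df["temperature"].to_numpy(),
                     fluorescence=df["fluorescence"].to_numpy(),
                     allotype=meta.get("allotype", ""))


def write_isotherm(iso: BindingIsotherm, path) -> None:
    write_csv_with_meta(pd.DataFrame({"receptor_conc": iso.receptor_concs,
                                      "fraction_bound": iso.fraction_bound}),
                        {"probe_conc": iso.probe_conc, "temperature": iso.temperature},
                        path)


def read_isotherm(path) -> BindingIsotherm:
    df, meta = read_csv_with_meta(path)
    return BindingIsotherm(receptor_concs=df["receptor_conc"].to_numpy(),
                           fraction_bound=df["fraction_bound"].to_numpy(),
                           probe_conc=float(meta["probe_conc"]),
                           temperature=float(meta.get("temperature", 298.15)))


def write_cpmg(curve: DispersionCurve, path) -> None:
    write_csv_with_meta(pd.DataFrame({"freq": curve.freqs, "r2eff": curve.r2eff}),
                        {"t_cpmg": curve.t_cpmg, "group_id": curve.group_id}, path)


def read_cpmg(path) -> DispersionCurve:
    df, meta = read_csv_with_meta(path)
    return DispersionCurve(freqs=df["freq"].to_numpy(), r2eff=df["r2eff"].to_numpy(),
                           t_cpmg=float(meta.get("t_cpmg", 0.04)),
                           group_id=meta.get("group_id", ""))


def write_dtrajs(dtrajs: DiscreteTrajectorySet, directory, prefix: str = "dtraj") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, traj in enumerate(dtrajs.trajectories):
        p = directory / f"{prefix}_{i:03d}.txt"
        np.savetxt(p, traj, fmt="%d")
        paths.append(p)
    return paths


def read_dtrajs(paths, n_states: int | None = None,
                frame_stride: float = 1.0) -> DiscreteTrajectorySet:
    trajs = [np.loadtxt(p, dtype=np.int64, ndmin=1) for p in paths]
    if not trajs:
        raise InvalidParameterError("no trajectory files given")
    if n_states is None:
        n_states = int(max(t.max() for t in trajs)) + 1
    return DiscreteTrajectorySet(trajectories=trajs, n_states=n_states,
                                 frame_stride=frame_stride)


def write_features(feat: FeatureTrajectory, path) -> None:
    cols = feat.feature_names or [f"f{i}" for i in range(feat.data.shape[1])]
    pd.DataFrame(feat.data, columns=cols).to_csv(path, index=False)


def read_features(path, frame_stride: float = 1.0) -> FeatureTrajectory:
    df = pd.read_csv(path)
    return FeatureTrajectory(data=df.to_numpy(dtype=float), frame_stride=frame_stride,
                             feature_names=list(df.columns))


def write_alignment(aln: MultipleAlignment, path) -> None:
    Path(path).write_text(aln.to_fasta())


def read_alignment(path) -> MultipleAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidParameterError(f"no sequences in {path}")
    return MultipleAlignment(sequences=[str(r.seq).upper() for r in records],
                             identifiers=[r.id for r in records])
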