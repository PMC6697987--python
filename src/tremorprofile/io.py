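"""CSV/JSON schemas, configuration, and table <-> object conversion.

All tables are plain CSV.  Null amplitudes are encoded as empty fields —
never ``NA`` or ``0`` — since zero is a legal amplitude.  Every run can emit
a resolved-config copy next to its outputs so results are reproducible from
the artefacts alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .kinematics import AnalysisWindow, MovementRecording
from .profiling import CharacteristicVector, MeasurementVector
from .spectral import SpectralConfig

__all__ = [
    "PipelineConfig",
    "read_recording_csv",
    "read_annotations_csv",
    "read_amplitude_table",
    "write_amplitude_table",
    "amplitude_table_to_vectors",
    "read_cohort_scores",
    "write_change_table",
    "write_eval_table",
    "profile_to_json",
    "profile_from_json",
]

AMPLITUDE_COLUMNS = [
    "subject_id",
    "day_id",
    "instance_id",
    "parameter_id",
    "log_ata",
    "n_reps_used",
    "f_T_mean",
]

ANNOTATION_COLUMNS = [
    "subject_id",
    "day_id",
    "instance_id",
    "start_s",
    "end_s",
    "label",
]

SCORE_COLUMNS = ["subject_id", "visit", "ftmtrs_a", "ftmtrs_b", "ftmtrs_c"]

CHANGE_COLUMNS = [
    "subject_id",
    "day_p",
    "day_q",
    "metric_id",
    "variant",
    "N",
    "d_raw_1",
    "d_raw_2",
    "denom",
    "d_adj",
]


@dataclass
class PipelineConfig:
    """Resolved configuration for an end-to-end run.

    Every field has a documented default matching the analysis constants:
    the 2-10 Hz tremor band, the 1.5 s minimum window, Welch settings, the
    natural-log amplitude scale, the 2..15 joint-count range and the
    absolute-value variability denominator.
    """

    fs: float = 100.0
    band_lo: float = 2.0
    band_hi: float = 10.0
    min_window_s: float = 1.5
    welch_seg_seconds: float = 1.0
    welch_overlap: float = 0.5
    welch_max_df: float = 0.25
    log_base: str = "e"
    zscore_hand: bool = True
    n_min: int = 2
    n_max: int = 15
    denominator_mode: str = "absolute"
    seed: int = 0

    def spectral(self) -> SpectralConfig:
        return SpectralConfig(
            seg_seconds=self.welch_seg_seconds,
            overlap=self.welch_overlap,
            max_df=self.welch_max_df,
            band=(self.band_lo, self.band_hi),
            min_window_s=self.min_window_s,
        )

    @property
    def n_range(self) -> Tuple[int, ...]:
        return tuple(range(self.n_min, self.n_max + 1))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Load from a flat key-value YAML file; unknown keys raise."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _infer_kind(channel: str) -> str:
    name = channel.rsplit(".", 1)[-1].lower()
    for prefix, kind in (
        ("accel_", "acceleration_"),
        ("gyro_", "angular_velocity_"),
    ):
        if name.startswith(prefix):
            return kind + name[len(prefix):]
    return "joint_angle"


def read_recording_csv(
    path: Union[str, Path],
    fs: float,
    subject_id: str = "",
    day_id: str = "",
    instance_id: int = 1,
) -> MovementRecording:
    """Read one recording CSV: optional ``t`` column then one column per channel.

    Channel kinds are inferred from the column suffix: ``*.accel_{x,y,z}``
    are accelerations, ``*.gyro_{x,y,z}`` angular velocities, everything
    else a joint angle.  Identity defaults may be overridden by the file
    name convention ``<subject>_<day>_<instance>.csv``.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if not subject_id:
        parts = path.stem.split("_")
        if len(parts) >= 3:
            subject_id, day_id = parts[0], parts[1]
            try:
                instance_id = int(parts[2])
            except ValueError:
                instance_id = 1
    channels = {
        col: frame[col].to_numpy(dtype=float)
        for col in frame.columns
        if col != "t"
    }
    kinds = {name: _infer_kind(name) for name in channels}
    return MovementRecording(
        subject_id=subject_id or path.stem,
        day_id=day_id or "day1",
        instance_id=instance_id,
        fs=fs,
        channels=channels,
        kinds=kinds,
    )


def write_recording_csv(recording: MovementRecording, path: Union[str, Path]) -> None:
    t = np.arange(recording.n_samples) / recording.fs
    frame = pd.DataFrame({"t": t})
    for name, series in recording.channels.items():
        frame[name] = series
    frame.to_csv(path, index=False)


def read_annotations_csv(
    path: Union[str, Path],
) -> Dict[Tuple[str, str, int], List[AnalysisWindow]]:
    """Annotation CSV -> windows keyed by (subject, day, instance)."""
    frame = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    out: Dict[Tuple[str, str, int], List[AnalysisWindow]] = {}
    for row in frame.itertuples(index=False):
        key = (str(row.subject_id), str(row.day_id), int(row.instance_id))
        out.setdefault(key, []).append(
            AnalysisWindow(
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                label="" if pd.isna(row.label) else str(row.label),
            )
        )
    return out


def write_annotations_csv(
    annotations: Dict[Tuple[str, str, int], List[AnalysisWindow]],
    path: Union[str, Path],
) -> None:
    rows = []
    for (subject, day, inst), windows in sorted(annotations.items()):
        for w in windows:
            rows.append(
                {
                    "subject_id": subject,
                    "day_id": day,
                    "instance_id": inst,
                    "start_s": w.start_s,
                    "end_s": w.end_s,
                    "label": w.label,
                }
            )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def write_amplitude_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write an amplitude table; null log-amplitudes become empty fields."""
    missing = set(AMPLITUDE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"amplitude table missing columns: {sorted(missing)}")
    table[AMPLITUDE_COLUMNS].to_csv(path, index=False, na_rep="")


def read_amplitude_table(path: Union[str, Path]) -> pd.DataFrame:
    table = pd.read_csv(
        path, dtype={"subject_id": str, "day_id": str, "parameter_id": str}
    )
    missing = set(AMPLITUDE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"amplitude table missing columns: {sorted(missing)}")
    return table


def amplitude_table_to_vectors(
    table: pd.DataFrame, params: Optional[Sequence[str]] = None
) -> Dict[str, List[MeasurementVector]]:
    """Pivot a long amplitude table into per-subject measurement vectors.

    ``params`` fixes the parameter order; by default the sorted set of
    parameter ids present in the table.  Absent (subject, day, instance,
    parameter) combinations and empty ``log_ata`` fields both become nulls.
    """
    if params is None:
        params = sorted(table["parameter_id"].unique())
    params = tuple(params)
    index = {p: j for j, p in enumerate(params)}
    out: Dict[str, List[MeasurementVector]] = {}
    grouped = table.groupby(["subject_id", "day_id", "instance_id"], sort=True)
    for (subject, day, inst), group in grouped:
        values = np.full(len(params), np.nan)
        for row in group.itertuples(index=False):
            j = index.get(str(row.parameter_id))
            if j is not None and not pd.isna(row.log_ata):
                values[j] = float(row.log_ata)
        out.setdefault(str(subject), []).append(
            MeasurementVector(
                subject_id=str(subject),
                day_id=str(day),
                instance_id=int(inst),
                params=params,
                values=values,
            )
        )
    return out


def read_cohort_scores(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(SCORE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort scores CSV missing columns: {sorted(missing)}")
    return frame


def write_change_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.reindex(columns=CHANGE_COLUMNS).to_csv(path, index=False, na_rep="")


def write_eval_table(results, path: Union[str, Path]) -> None:
    rows = [
        {
            "metric_id": r.metric_id,
            "reference": r.reference,
            "N": r.N,
            "rho2": r.rho2,
            "rho_sign": r.rho_sign,
            "p": r.p,
            "pFDR": r.pFDR,
            "n_points": r.n_points,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["metric_id", "reference", "N", "rho2", "rho_sign", "p", "pFDR", "n_points"],
    ).to_csv(path, index=False, na_rep="")


def profile_to_json(a_c: CharacteristicVector) -> dict:
    return {
        "subject_id": a_c.subject_id,
        "params": list(a_c.params),
        "values": [None if np.isnan(v) else float(v) for v in a_c.values],
        "m": [int(m) for m in a_c.m],
        "variant": a_c.variant,
    }


def profile_from_json(data: dict) -> CharacteristicVector:
    return CharacteristicVector(
        subject_id=data["subject_id"],
        params=tuple(data["params"]),
        values=np.array(
            [np.nan if v is None else float(v) for v in data["values"]], dtype=float
        ),
        m=np.asarray(data["m"], dtype=int),
        variant=data.get("variant", "plain"),
    )


def write_profiles_json(
    profiles: Dict[str, CharacteristicVector], path: Union[str, Path]
) -> None:
    Path(path).write_text(
        json.dumps(
            {s: profile_to_json(p) for s, p in sorted(profiles.items())}, indent=1
        )
    )


def read_profiles_json(path: Union[str, Path]) -> Dict[str, CharacteristicVector]:
    data = json.loads(Path(path).read_text())
    return {s: profile_from_json(p) for s, p in data.items()}
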