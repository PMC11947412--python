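"""File formats: load-case CSV, apparatus / registration / surface configs.

Tracks travel as plain CSV with a ``#``-prefixed metadata header block and a
mandatory column header; floats are written with ``repr`` so a write → read
round trip is bitwise exact.  The dialect is fixed: comma separator, decimal
point.  Configuration objects (ligament apparatus, frame registration,
contact surface, run config) travel as YAML/JSON mappings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .contact import CondyleSurface, ContactParams, ContactSurface
from .jcs import JCSCoordinates, pose_from_jcs
from .ligament import LigamentApparatus, LigamentLawParams, LigamentStrand
from .transfer import (CHANNELS, FrameRegistration, LoadCaseTrack,
                       SourceRecording)

__all__ = [
    "LoadCaseFormatError", "read_load_case_csv", "write_load_case_csv",
    "read_recording_csv", "write_recording_csv",
    "load_apparatus", "save_apparatus",
    "load_registration", "save_registration",
    "load_surface", "save_surface", "RunConfig",
]

_RECORDING_COLUMNS = ("time_s", "fe_deg", "ad_deg", "ei_deg", "ml_mm",
                      "ap_mm", "is_mm", "fx_N", "fy_N", "fz_N",
                      "mx_Nm", "my_Nm", "mz_Nm")


class LoadCaseFormatError(ValueError):
    """Malformed load-case file (message carries the offending line)."""


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_float(tok: str, lineno: int, path) -> float:
    try:
        return float(tok)
    except ValueError:
        hint = ""
        if "," in tok:
            hint = (" — the value contains a comma; this reader expects "
                    "the comma-separated, decimal-point dialect")
        raise LoadCaseFormatError(
            f"{path}:{lineno}: cannot parse {tok!r} as a number{hint}") from None


def _read_table(path, required_columns) -> tuple[dict, dict[str, np.ndarray]]:
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if ";" in line:
                raise LoadCaseFormatError(
                    f"{path}:{lineno}: semicolon found — this looks like the "
                    "semicolon/comma-decimal CSV dialect; expected comma "
                    "separator with decimal points")
            toks = [t.strip() for t in line.split(",")]
            if header is None:
                header = toks
                missing = [c for c in required_columns if c not in header]
                if missing:
                    raise LoadCaseFormatError(
                        f"{path}: missing required column(s) "
                        f"{', '.join(missing)}")
                continue
            if len(toks) != len(header):
                raise LoadCaseFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(toks)}")
            rows.append([_parse_float(t, lineno, path) for t in toks])
    if header is None or not rows:
        raise LoadCaseFormatError(f"{path}: no data rows found")
    data = np.asarray(rows)
    cols = {name: data[:, i].copy() for i, name in enumerate(header)}
    return meta, cols


def write_load_case_csv(track: LoadCaseTrack, path) -> None:
    """Write a track; floats use repr so the round trip is bitwise."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# adl={track.adl}\n")
        fh.write(f"# frequency_hz={_fmt(track.frequency_hz)}\n")
        fh.write(f"# frame={track.meta.get('frame', 'grood_suntay')}\n")
        for k, v in track.meta.items():
            if k != "frame":
                fh.write(f"# {k}={v}\n")
        fh.write("time_s," + ",".join(CHANNELS) + "\n")
        for i in range(track.n_samples):
            vals = [track.time_s[i]] + [track.channels[c][i] for c in CHANNELS]
            fh.write(",".join(_fmt(v) for v in vals) + "\n")


def read_load_case_csv(path) -> LoadCaseTrack:
    meta, cols = _read_table(path, ("time_s",) + CHANNELS)
    if "adl" not in meta or "frequency_hz" not in meta:
        raise LoadCaseFormatError(
            f"{path}: metadata header must declare adl=... and "
            "frequency_hz=...")
    parsed_meta = {k: v for k, v in meta.items()
                   if k not in ("adl", "frequency_hz")}
    for k, v in list(parsed_meta.items()):
        if v in ("True", "False"):
            parsed_meta[k] = v == "True"
    try:
        track = LoadCaseTrack(meta["adl"], cols["time_s"],
                              {c: cols[c] for c in CHANNELS},
                              float(meta["frequency_hz"]), parsed_meta)
    except ValueError as exc:
        raise LoadCaseFormatError(f"{path}: {exc}") from exc
    return track


def write_recording_csv(rec: SourceRecording, path) -> None:
    """Serialise a source recording (pose as JCS components + tibial-frame
    wrench)."""
    from .jcs import jcs_from_pose
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# adl={rec.adl}\n")
        fh.write(f"# frequency_hz={_fmt(rec.frequency_hz)}\n")
        fh.write(f"# frame={rec.frame_id}\n")
        fh.write(f"# side={rec.side}\n")
        fh.write(",".join(_RECORDING_COLUMNS) + "\n")
        t = np.asarray(rec.time_s, dtype=float)
        for i in range(rec.n_samples):
            c = jcs_from_pose(rec.pose(i))
            vals = [t[i], c.flexion_deg, c.adduction_deg, c.internal_rot_deg,
                    c.ml_mm, c.ap_mm, c.is_mm, *rec.force_N[i],
                    *rec.moment_Nm[i]]
            fh.write(",".join(_fmt(v) for v in vals) + "\n")


def read_recording_csv(path) -> SourceRecording:
    meta, cols = _read_table(path, _RECORDING_COLUMNS)
    n = cols["time_s"].size
    rotations = np.empty((n, 3, 3))
    translations = np.empty((n, 3))
    side = meta.get("side", "right")
    for i in range(n):
        pose = pose_from_jcs(JCSCoordinates(
            flexion_deg=cols["fe_deg"][i], adduction_deg=cols["ad_deg"][i],
            internal_rot_deg=cols["ei_deg"][i], ml_mm=cols["ml_mm"][i],
            ap_mm=cols["ap_mm"][i], is_mm=cols["is_mm"][i]), side)
        rotations[i] = pose.rotation
        translations[i] = pose.translation
    return SourceRecording(
        adl=meta.get("adl", "unknown"), time_s=cols["time_s"],
        rotations=rotations, translations=translations,
        force_N=np.column_stack([cols["fx_N"], cols["fy_N"], cols["fz_N"]]),
        moment_Nm=np.column_stack([cols["mx_Nm"], cols["my_Nm"],
                                   cols["mz_Nm"]]),
        frame_id=meta.get("frame", "source"), side=side,
        frequency_hz=float(meta.get("frequency_hz", 1.0)))


# -- config objects ----------------------------------------------------------

def save_apparatus(app: LigamentApparatus, path) -> None:
    doc = {
        "toe_strain": app.law.toe_strain,
        "strain_model": app.law.strain_model,
        "strands": [
            {"name": s.name, "group": s.group,
             "origin_mm": [float(v) for v in s.origin_mm],
             "insertion_mm": [float(v) for v in s.insertion_mm],
             "stiffness_N_per_strain": s.stiffness_N_per_strain,
             "reference_strain": s.reference_strain}
            for s in app.strands],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_apparatus(path) -> LigamentApparatus:
    """Read an apparatus YAML/JSON.

    Strand stiffness may be given as ``stiffness_N_per_strain`` or as
    ``stiffness_N_per_percent`` (converted, ×100), since parameter tables in
    the literature use both conventions.
    """
    doc = yaml.safe_load(Path(path).read_text())
    law = LigamentLawParams(toe_strain=doc.get("toe_strain", 0.03),
                            strain_model=doc.get("strain_model",
                                                 "blankevoort"))
    strands = []
    for item in doc["strands"]:
        if "stiffness_N_per_strain" in item:
            k = float(item["stiffness_N_per_strain"])
        elif "stiffness_N_per_percent" in item:
            k = float(item["stiffness_N_per_percent"]) * 100.0
        else:
            raise ValueError(
                f"strand {item.get('name')!r}: no stiffness given")
        strands.append(LigamentStrand(
            name=item["name"], group=item["group"],
            origin_mm=np.asarray(item["origin_mm"], dtype=float),
            insertion_mm=np.asarray(item["insertion_mm"], dtype=float),
            stiffness_N_per_strain=k,
            reference_strain=float(item["reference_strain"])))
    return LigamentApparatus(tuple(strands), law)


def save_registration(reg: FrameRegistration, path) -> None:
    from scipy.spatial.transform import Rotation as _Rot
    rotvec = _Rot.from_matrix(reg.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    axis = (rotvec / np.linalg.norm(rotvec)).tolist() if angle > 0 \
        else [1.0, 0.0, 0.0]
    doc = {"rotation_axis": axis, "rotation_deg": angle,
           "origin_shift_mm": [float(v) for v in reg.origin_shift_mm],
           "source_frame": reg.source_frame,
           "target_frame": reg.target_frame}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_registration(path) -> FrameRegistration:
    doc = yaml.safe_load(Path(path).read_text())
    return FrameRegistration.from_axis_angle(
        axis=doc["rotation_axis"], angle_deg=float(doc["rotation_deg"]),
        origin_shift_mm=doc.get("origin_shift_mm", (0, 0, 0)),
        source_frame=doc.get("source_frame", "source"),
        target_frame=doc.get("target_frame", "target"))


def save_surface(surface: ContactSurface, path) -> None:
    def cond(c: CondyleSurface) -> dict:
        d = {"sphere_center_femoral_mm": [float(v) for v in
                                          c.sphere_center_femoral_mm],
             "sphere_radius_mm": c.sphere_radius_mm}
        if c.is_dish:
            d["dish_center_tibial_mm"] = [float(v) for v in
                                          c.dish_center_tibial_mm]
            d["dish_radius_mm"] = c.dish_radius_mm
        return d
    doc = {"medial": cond(surface.medial), "lateral": cond(surface.lateral)}
    Path(path).write_text(json.dumps(doc, indent=2))


def load_surface(path) -> ContactSurface:
    doc = json.loads(Path(path).read_text())

    def cond(d: dict) -> CondyleSurface:
        return CondyleSurface(
            sphere_center_femoral_mm=np.asarray(
                d["sphere_center_femoral_mm"], dtype=float),
            sphere_radius_mm=float(d["sphere_radius_mm"]),
            dish_center_tibial_mm=(np.asarray(d["dish_center_tibial_mm"],
                                              dtype=float)
                                   if "dish_center_tibial_mm" in d else None),
            dish_radius_mm=d.get("dish_radius_mm"))

    return ContactSurface(medial=cond(doc["medial"]),
                          lateral=cond(doc["lateral"]))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    track_path: str | None = None
    apparatus_path: str | None = None
    registration_path: str | None = None
    surface_path: str | None = None
    output_dir: str = "out"
    seed: int = 0
    adl: str = "level_walking"
    n_samples: int = 100
    extension_fraction: float = 0.15
    strain_model: str = "blankevoort"
    target_body_weight_kg: float = 75.0
    reference_body_weight_kg: float = 75.0
    contact_stiffness: float = 5000.0
    contact_exponent: float = 1.0
    cycles: int = 2
    variant: str = "none"            # none | resect:<group> | stiffen:<group>:<f>
    force_tol_N: float = 0.5
    moment_tol_Nm: float = 0.05
    extra: dict = field(default_factory=dict)

    def contact_params(self) -> ContactParams:
        return ContactParams(stiffness=self.contact_stiffness,
                             exponent=self.contact_exponent)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)
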