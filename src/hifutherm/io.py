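"""Serialization: YAML scenario configs, HDF5 artifacts, CSV logs/reports."""

from __future__ import annotations

import dataclasses
import json
from io import StringIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .reconstruct import TemperatureField
from .student import StudentConfig, StudentModel
from .synthdata import (
    FieldSequence,
    HeatingScenario,
    ModalityImageSequence,
)
from .teacher import EncoderParams, TeacherArtifacts, TeacherConfig

__all__ = [
    "save_scenario_yaml", "load_scenario_yaml",
    "save_sequences", "load_sequences",
    "export_probe_log",
    "save_teacher", "load_teacher",
    "save_student", "load_student",
    "save_field", "load_field", "render_field_png",
    "export_profiles",
]


def save_scenario_yaml(scenario: HeatingScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_listify(scenario.to_dict()), fh, sort_keys=False)


def load_scenario_yaml(path) -> HeatingScenario:
    with open(path) as fh:
        return HeatingScenario.from_dict(yaml.safe_load(fh))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_sequences(path, field: FieldSequence,
                   images: ModalityImageSequence | None = None) -> None:
    """One HDF5 file: /frames, /times, /probes, /modalities + scenario attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=field.frames, compression="gzip")
        f.create_dataset("times", data=field.times)
        f.create_dataset("probes", data=field.probe_readings)
        f.attrs["scenario_yaml"] = yaml.safe_dump(_listify(field.scenario.to_dict()))
        if images is not None:
            f.create_dataset("modalities", data=images.images, compression="gzip")
            f.attrs["modality_names"] = json.dumps(list(images.modality_names))
            f.attrs["noise_params"] = json.dumps(list(images.noise_params))
            f.attrs["render_seed"] = images.seed


def load_sequences(path):
    """Returns (FieldSequence, ModalityImageSequence | None)."""
    with h5py.File(path, "r") as f:
        scenario = HeatingScenario.from_dict(yaml.safe_load(f.attrs["scenario_yaml"]))
        field = FieldSequence(frames=f["frames"][:], times=f["times"][:],
                              probe_readings=f["probes"][:], scenario=scenario)
        images = None
        if "modalities" in f:
            images = ModalityImageSequence(
                images=f["modalities"][:],
                modality_names=tuple(json.loads(f.attrs["modality_names"])),
                noise_params=tuple(json.loads(f.attrs["noise_params"])),
                seed=int(f.attrs["render_seed"]),
            )
    return field, images


def export_probe_log(field: FieldSequence, path) -> None:
    """CSV probe log: columns time_s, TC1..TCP."""
    cols = {"time_s": field.times}
    for p in range(field.probe_readings.shape[1]):
        cols[f"TC{p + 1}"] = field.probe_readings[:, p]
    pd.DataFrame(cols).to_csv(path, index=False)


def _write_config(group, cfg) -> None:
    group.attrs["config_json"] = json.dumps(dataclasses.asdict(cfg))


def save_teacher(art: TeacherArtifacts, path) -> None:
    with h5py.File(path, "w") as f:
        for m, enc in enumerate(art.encoders):
            g = f.create_group(f"encoder_{m}")
            g.attrs["modality"] = enc.modality
            for i, (W, b) in enumerate(enc.layers):
                g.create_dataset(f"W{i}", data=W)
                g.create_dataset(f"b{i}", data=b)
        f.create_dataset("Z", data=art.Z)
        f.create_dataset("D", data=art.D)
        f.create_dataset("singular_values", data=art.singular_values)
        for m, R in enumerate(art.ridge_maps):
            f.create_dataset(f"ridge_map_{m}", data=R)
        f.create_dataset("head_w", data=art.head_w)
        f.create_dataset("patch_mean", data=art.patch_mean)
        f.create_dataset("patch_std", data=art.patch_std)
        f.attrs["head_b"] = art.head_b
        f.attrs["label_mean"] = art.label_mean
        f.attrs["label_std"] = art.label_std
        f.attrs["seed"] = art.seed
        f.attrs["train_fingerprint"] = art.train_fingerprint
        f.attrs["modality_names"] = json.dumps(list(art.modality_names))
        _write_config(f, art.config)
        f.attrs["log_json"] = art.log.to_json(orient="split")


def load_teacher(path) -> TeacherArtifacts:
    with h5py.File(path, "r") as f:
        encoders = []
        m = 0
        while f"encoder_{m}" in f:
            g = f[f"encoder_{m}"]
            layers = []
            i = 0
            while f"W{i}" in g:
                layers.append((g[f"W{i}"][:], g[f"b{i}"][:]))
                i += 1
            encoders.append(EncoderParams(layers, modality=str(g.attrs["modality"])))
            m += 1
        ridge = []
        while f"ridge_map_{len(ridge)}" in f:
            ridge.append(f[f"ridge_map_{len(ridge)}"][:])
        cfg_d = json.loads(f.attrs["config_json"])
        cfg_d["lambdas"] = tuple(cfg_d["lambdas"])
        art = TeacherArtifacts(
            encoders=encoders,
            Z=f["Z"][:], D=f["D"][:],
            singular_values=f["singular_values"][:],
            ridge_maps=ridge,
            head_w=f["head_w"][:], head_b=float(f.attrs["head_b"]),
            patch_mean=f["patch_mean"][:], patch_std=f["patch_std"][:],
            label_mean=float(f.attrs["label_mean"]),
            label_std=float(f.attrs["label_std"]),
            config=TeacherConfig(**cfg_d),
            seed=int(f.attrs["seed"]),
            log=pd.read_json(StringIO(str(f.attrs["log_json"])), orient="split"),
            train_fingerprint=str(f.attrs["train_fingerprint"]),
            modality_names=tuple(json.loads(f.attrs["modality_names"])),
        )
    art.freeze()
    return art


def save_student(model: StudentModel, path) -> None:
    """Single-file student: the prior is embedded so inference is standalone."""
    with h5py.File(path, "w") as f:
        for i, (W, b) in enumerate(model.mlp):
            f.create_dataset(f"W{i}", data=W)
            f.create_dataset(f"b{i}", data=b)
        f.create_dataset("conv_kernel", data=model.conv_kernel)
        f.create_dataset("map_W", data=model.map_W)
        f.create_dataset("map_b", data=model.map_b)
        f.create_dataset("head_w", data=model.head_w)
        f.create_dataset("prior", data=model.prior)
        if model.prior_source is not None:
            f.create_dataset("prior_source", data=model.prior_source)
        f.attrs.update({
            "conv_bias": float(model.conv_bias),
            "head_b": float(model.head_b),
            "combine_rule": model.combine_rule,
            "target_modality": model.target_modality,
            "patch_mean": model.patch_mean, "patch_std": model.patch_std,
            "label_mean": model.label_mean, "label_std": model.label_std,
            "seed": model.seed, "distilled": model.distilled,
            "teacher_fingerprint": model.teacher_fingerprint,
            "train_fingerprint": model.train_fingerprint,
        })
        if model.log is not None:
            f.attrs["log_json"] = model.log.to_json(orient="split")


def load_student(path) -> StudentModel:
    with h5py.File(path, "r") as f:
        mlp = []
        i = 0
        while f"W{i}" in f:
            mlp.append((f[f"W{i}"][:], f[f"b{i}"][:]))
            i += 1
        model = StudentModel(
            mlp=mlp,
            conv_kernel=f["conv_kernel"][:],
            conv_bias=np.array(float(f.attrs["conv_bias"])),
            map_W=f["map_W"][:], map_b=f["map_b"][:],
            head_w=f["head_w"][:], head_b=np.array(float(f.attrs["head_b"])),
            prior_source=f["prior_source"][:] if "prior_source" in f else None,
            prior=f["prior"][:],
            combine_rule=str(f.attrs["combine_rule"]),
            target_modality=str(f.attrs["target_modality"]),
            patch_mean=float(f.attrs["patch_mean"]),
            patch_std=float(f.attrs["patch_std"]),
            label_mean=float(f.attrs["label_mean"]),
            label_std=float(f.attrs["label_std"]),
            seed=int(f.attrs["seed"]),
            distilled=bool(f.attrs["distilled"]),
            log=(pd.read_json(StringIO(str(f.attrs["log_json"])), orient="split")
                 if "log_json" in f.attrs else None),
            teacher_fingerprint=str(f.attrs["teacher_fingerprint"]),
            train_fingerprint=str(f.attrs["train_fingerprint"]),
        )
    return model


def save_field(fld: TemperatureField, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("field", data=fld.grid)
        f.create_dataset("coverage", data=fld.coverage)
        f.attrs["spacing_mm"] = fld.spacing_mm
        f.attrs["normalized"] = fld.normalized
        if fld.vmin is not None:
            f.attrs["vmin"] = fld.vmin
            f.attrs["vmax"] = fld.vmax


def load_field(path) -> TemperatureField:
    with h5py.File(path, "r") as f:
        return TemperatureField(
            grid=f["field"][:], coverage=f["coverage"][:],
            spacing_mm=float(f.attrs["spacing_mm"]),
            normalized=bool(f.attrs["normalized"]),
            vmin=float(f.attrs["vmin"]) if "vmin" in f.attrs else None,
            vmax=float(f.attrs["vmax"]) if "vmax" in f.attrs else None,
        )


def render_field_png(fld: TemperatureField, path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = fld.grid.shape
    extent = (0, w * fld.spacing_mm, h * fld.spacing_mm, 0)
    fig, ax = plt.subplots(figsize=(4.2, 4))
    im = ax.imshow(fld.grid, cmap="inferno", extent=extent)
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("axial (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax,
                 label="normalized" if fld.normalized else "temperature (degC)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def export_profiles(profiles, path) -> None:
    """CSV with axis, position_mm, value rows for both focal cuts."""
    df = pd.concat([
        pd.DataFrame({"axis": "axial", "position_mm": profiles.axial_positions,
                      "value": profiles.axial_values}),
        pd.DataFrame({"axis": "lateral", "position_mm": profiles.lateral_positions,
                      "value": profiles.lateral_values}),
    ])
    df.to_csv(path, index=False)
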