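"""Dataset import/export, the canonical HDF5 store, and experiment runs.

The canonical on-disk format is one HDF5 file holding a group per
recording (``recordings/00000/signals`` in mV, channels x frames) with the
sampling rate and labels as attributes, and a ``manifest`` JSON attribute
at the root.  Synthetic and imported real data share this layout, so
downstream code cannot tell them apart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .grid import ElectrodeGrid, IntensityMap, Recording, image_stack, difference_stack
from .preprocess import apply_pipeline, validate_pipeline, ConfigurationError
from .voting import FramePredictions, SplitSpec, split, vote_curve, SEGMENT

__all__ = [
    "DatasetManifest",
    "SchemaError",
    "save_dataset",
    "load_dataset",
    "import_matfile",
    "export_matfile",
    "run_experiment",
    "PRESETS",
]

log = logging.getLogger("semgimg")


class SchemaError(ValueError):
    """A source file does not contain the expected variables."""


@dataclass
class DatasetManifest:
    """Summary metadata validated against the stored recordings."""

    name: str
    rows: int
    cols: int
    fs: float
    subjects: list[int]
    gestures: list[int]
    trials: list[int]
    rectified: bool = False
    source_format: str = "synthetic"

    def validate(self, recordings: Sequence[Recording]) -> None:
        if not recordings:
            raise ValueError("manifest cannot describe an empty dataset")
        n_ch = self.rows * self.cols
        for rec in recordings:
            if rec.n_channels != n_ch:
                raise ValueError(
                    f"recording has {rec.n_channels} channels, manifest grid "
                    f"{self.rows}x{self.cols} expects {n_ch}"
                )
            if rec.fs != self.fs:
                raise ValueError("sampling rate mismatch between manifest and data")
        if set(r.subject for r in recordings) - set(self.subjects):
            raise ValueError("recordings contain subjects absent from the manifest")

    @classmethod
    def describe(
        cls, recordings: Sequence[Recording], grid: ElectrodeGrid, name: str = "dataset",
        source_format: str = "synthetic",
    ) -> "DatasetManifest":
        return cls(
            name=name,
            rows=grid.rows,
            cols=grid.cols,
            fs=recordings[0].fs,
            subjects=sorted({r.subject for r in recordings}),
            gestures=sorted({r.gesture for r in recordings}),
            trials=sorted({r.trial for r in recordings}),
            rectified=all(r.rectified for r in recordings),
            source_format=source_format,
        )


def save_dataset(
    path, recordings: Sequence[Recording], manifest: DatasetManifest
) -> None:
    import h5py

    manifest.validate(recordings)
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(asdict(manifest))
        grp = f.create_group("recordings")
        for i, rec in enumerate(recordings):
            g = grp.create_group(f"{i:05d}")
            g.create_dataset("signals", data=rec.signals)
            g.attrs.update(
                fs=rec.fs,
                subject=rec.subject,
                gesture=rec.gesture,
                trial=rec.trial,
                session=rec.session,
                rectified=rec.rectified,
            )


def load_dataset(path) -> tuple[list[Recording], DatasetManifest]:
    import h5py

    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs or "recordings" not in f:
            raise SchemaError("not a canonical dataset file (missing manifest/recordings)")
        manifest = DatasetManifest(**json.loads(f.attrs["manifest"]))
        recordings = []
        for key in sorted(f["recordings"]):
            g = f["recordings"][key]
            recordings.append(
                Recording(
                    np.array(g["signals"]),
                    fs=float(g.attrs["fs"]),
                    subject=int(g.attrs["subject"]),
                    gesture=int(g.attrs["gesture"]),
                    trial=int(g.attrs["trial"]),
                    session=int(g.attrs["session"]),
                    rectified=bool(g.attrs["rectified"]),
                )
            )
    manifest.validate(recordings)
    return recordings, manifest


# ------------------------------------------------------------------ MAT files

#: Default variable mapping for MAT-file import.  Real archives differ in
#: naming, so importers are driven entirely by this mapping config.
DEFAULT_MAT_MAPPING = {
    "signals": "data",  # channels x frames or frames x channels
    "fs": "fs",
    "subject": "subject",
    "gesture": "gesture",
    "trial": "trial",
    "session": "session",
    "transpose": False,  # set when the source stores frames x channels
    "scale_to_mv": 1.0,
    "rectified": False,
}


def _load_mat(path) -> dict[str, Any]:
    from scipy.io import loadmat

    try:
        raw = loadmat(path)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        # MAT v7.3 files are HDF5 containers.
        import h5py

        out: dict[str, Any] = {}
        with h5py.File(path, "r") as f:
            for k in f:
                out[k] = np.array(f[k]).T  # v7.3 stores column-major
        return out
    except (ValueError, OSError) as exc:
        raise SchemaError(f"unreadable MAT file {path}: {exc}") from exc


def import_matfile(path, mapping: dict[str, Any] | None = None) -> Recording:
    """Read one recording from a MAT-file (v5/v7 or HDF5-based v7.3).

    ``mapping`` names the source variables and declares layout/scaling; see
    :data:`DEFAULT_MAT_MAPPING`.  Scalar metadata absent from the file may
    be given directly in the mapping (e.g. ``{"trial": 3}``).
    """
    cfg = dict(DEFAULT_MAT_MAPPING)
    cfg.update(mapping or {})
    variables = _load_mat(path)
    key = cfg["signals"]
    if key not in variables:
        raise SchemaError(f"MAT file {path} has no variable {key!r}")
    signals = np.asarray(variables[key], dtype=np.float64)
    if cfg["transpose"]:
        signals = signals.T
    signals = signals * cfg["scale_to_mv"]

    def meta(name: str, default: int = 0) -> float:
        src = cfg[name]
        if isinstance(src, str):
            if src in variables:
                return float(np.asarray(variables[src]).ravel()[0])
            return default
        return float(src)

    return Recording(
        signals,
        fs=meta("fs", 1000),
        subject=int(meta("subject")),
        gesture=int(meta("gesture")),
        trial=int(meta("trial")),
        session=int(meta("session")),
        rectified=bool(cfg["rectified"]),
    )


def export_matfile(path, rec: Recording) -> None:
    """Write a recording to a MAT-file with the default variable names."""
    from scipy.io import savemat

    savemat(
        path,
        {
            "data": rec.signals,
            "fs": rec.fs,
            "subject": rec.subject,
            "gesture": rec.gesture,
            "trial": rec.trial,
            "session": rec.session,
        },
    )


# ------------------------------------------------------------ experiment runs

#: Named grids used by the experiment protocols.
GRIDS = {
    "8x16": ElectrodeGrid(8, 16),
    "7x24": ElectrodeGrid(7, 24),
    "1x10": ElectrodeGrid(1, 10),
}

PRESETS: dict[str, dict[str, Any]] = {
    # Within-subject odd/even trials on an 8x16 grid at 1000 Hz, ConvNet on
    # instantaneous images, voting windows 1 / 40 / 150 frames + segment.
    "exp1-dba": {
        "dataset": {"kind": "hdf5", "path": None},
        "grid": "8x16",
        "preprocess": [{"name": "remove_powerline"}],
        "classifier": {"kind": "convnet"},
        "protocol": {"protocol": "odd_even"},
        "windows": [1, 40, 150, SEGMENT],
    },
    # Classical baselines on raw instantaneous vectors, training frames
    # decimated by 9.
    "exp2-baselines": {
        "dataset": {"kind": "hdf5", "path": None},
        "grid": "8x16",
        "preprocess": [{"name": "remove_powerline"}],
        "classifier": {"kind": "rf", "train_downsample_factor": 9},
        "protocol": {"protocol": "odd_even"},
        "windows": [1, 40, 150, SEGMENT],
    },
    # Session-wise leave-one-trial-out on a 7x24 grid at 2048 Hz with 3x3
    # spatial median filtering and test-time batch-norm recalibration.
    "exp3-csl": {
        "dataset": {"kind": "hdf5", "path": None},
        "grid": "7x24",
        "preprocess": [{"name": "bandpass", "low": 20.0, "high": 380.0}],
        "spatial_median": True,
        "classifier": {"kind": "convnet", "recalibrate_bn": True},
        "protocol": {"protocol": "leave_one_trial_out", "per": "session"},
        "windows": [1, 307, 350, 758, SEGMENT],
    },
    # Sparse 1x10 grid, first-two-thirds trials train.
    "exp4-ninapro": {
        "dataset": {"kind": "hdf5", "path": None},
        "grid": "1x10",
        "preprocess": [{"name": "downsample", "target_fs": 100.0}],
        "classifier": {"kind": "convnet"},
        "protocol": {"protocol": "two_thirds"},
        "windows": [1, 20, 28, SEGMENT],
    },
    # Self-contained end-to-end demo on synthetic data.
    "synthetic-demo": {
        "dataset": {
            "kind": "synthetic",
            "n_gestures": 4,
            "trials_per_gesture": 6,
            "fs": 1000.0,
            "duration": 0.15,
            "snr": 5.0,
        },
        "grid": "8x16",
        "preprocess": [],
        "classifier": {"kind": "convnet", "epochs": 6, "lr_drop_epochs": [4, 5]},
        "protocol": {"protocol": "odd_even"},
        "windows": [1, 40, SEGMENT],
    },
}


def _load_config_dataset(config: dict, grid: ElectrodeGrid, seed: int) -> list[Recording]:
    ds = config["dataset"]
    if ds["kind"] == "synthetic":
        from .synthetic import SyntheticSpec, generate

        params = {k: v for k, v in ds.items() if k != "kind"}
        params.setdefault("seed", seed)
        spec = SyntheticSpec(grid=grid, **params)
        return generate(spec)
    if ds["kind"] == "hdf5":
        if not ds.get("path"):
            raise ConfigurationError(
                "config requires dataset.path pointing at a canonical HDF5 store"
            )
        recordings, _ = load_dataset(ds["path"])
        return recordings
    raise ConfigurationError(f"unknown dataset kind {ds['kind']!r}")


def _features(
    recordings: Sequence[Recording],
    grid: ElectrodeGrid,
    imap: IntensityMap,
    representation: str,
    use_spatial_median: bool = False,
) -> list[np.ndarray]:
    """Per-recording feature arrays: image stacks or raw vectors."""
    out = []
    for rec in recordings:
        if representation == "vector":
            out.append(rec.signals.T.copy())
            continue
        stack = image_stack(rec, grid, imap)
        if use_spatial_median:
            from scipy.ndimage import median_filter

            stack = median_filter(stack, size=(1, 3, 3), mode="reflect")
        if representation == "difference":
            stack = difference_stack(stack)
        out.append(stack)
    return out


def _fit_predict(
    config: dict,
    grid: ElectrodeGrid,
    imap: IntensityMap,
    train: Sequence[Recording],
    test: Sequence[Recording],
    seed: int,
) -> list[FramePredictions]:
    """Train the configured classifier on one fold and predict the test fold."""
    clf = dict(config.get("classifier", {"kind": "convnet"}))
    kind = clf.pop("kind", "convnet")
    gestures = sorted({r.gesture for r in train})
    remap = {g: i for i, g in enumerate(gestures)}
    n_classes = len(gestures)
    use_median = bool(config.get("spatial_median", False))

    if kind == "convnet":
        from .convnet import ConvNet, ConvNetSpec, TrainSpec

        representation = clf.pop("representation", "image")
        recal = clf.pop("recalibrate_bn", False)
        arch_keys = {
            "n_conv_layers", "n_filters", "kernel", "n_local_layers",
            "dense_units", "dropout_p", "dropout_layers",
        }
        arch = {k: clf.pop(k) for k in list(clf) if k in arch_keys}
        if "dense_units" in arch:
            arch["dense_units"] = tuple(arch["dense_units"])
        if "lr_drop_epochs" in clf:
            clf["lr_drop_epochs"] = tuple(clf["lr_drop_epochs"])
        train_spec = TrainSpec(seed=seed, **clf)
        x_tr = _features(train, grid, imap, representation, use_median)
        x_te = _features(test, grid, imap, representation, use_median)
        images = np.concatenate(x_tr, axis=0)
        labels = np.concatenate(
            [np.full(len(x), remap[r.gesture]) for x, r in zip(x_tr, train)]
        )
        model = ConvNet(
            ConvNetSpec((grid.rows, grid.cols, 1), n_classes, **arch), seed=seed
        )
        model.fit(images, labels, train_spec)
        if recal:
            model.recalibrate_bn(np.concatenate(x_te, axis=0))
        preds = []
        for x, rec in zip(x_te, test):
            probs = model.predict_proba(x)
            preds.append(
                FramePredictions(
                    probs,
                    label=remap.get(rec.gesture, -1),
                    subject=rec.subject,
                    trial=rec.trial,
                    session=rec.session,
                )
            )
        return preds

    # classical baselines on raw instantaneous vectors
    from .baselines import BaselineSpec, fit_baseline, predict_baseline

    factor = clf.pop("train_downsample_factor", 1)
    spec = BaselineSpec(
        kind=kind, hyperparameters=clf, train_downsample_factor=factor, seed=seed
    )
    x_tr = _features(train, grid, imap, "vector")
    x_te = _features(test, grid, imap, "vector")
    vectors = np.concatenate(x_tr, axis=0)
    labels = np.concatenate(
        [np.full(len(x), remap[r.gesture]) for x, r in zip(x_tr, train)]
    )
    fitted = fit_baseline(spec, vectors, labels)
    preds = []
    for x, rec in zip(x_te, test):
        probs = predict_baseline(fitted, x)
        preds.append(
            FramePredictions(
                probs,
                label=remap.get(rec.gesture, -1),
                subject=rec.subject,
                trial=rec.trial,
                session=rec.session,
            )
        )
    return preds


def run_experiment(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute one experiment config end to end and write a results bundle.

    The bundle contains ``config.json`` (echo, with the effective seed),
    ``results.csv`` (one row per subject x window) and ``summary.json``.
    Identical config + seed reproduce identical files.
    """
    config = json.loads(json.dumps(config))  # deep copy, JSON-typed
    if seed is not None:
        config["seed"] = seed
    config.setdefault("seed", 0)
    seed = int(config["seed"])

    validate_pipeline(config.get("preprocess", []))
    clf = config.get("classifier", {"kind": "convnet"})
    if clf.get("kind", "convnet") != "convnet" and clf.get("recalibrate_bn"):
        raise ConfigurationError("recalibrate_bn applies only to the convnet")

    grid = GRIDS[config["grid"]] if isinstance(config.get("grid"), str) else config["grid"]
    imap = IntensityMap(**config.get("intensity_map", {}))
    log.info("loading dataset: %s", config["dataset"].get("kind"))
    recordings = _load_config_dataset(config, grid, seed)
    log.info("preprocessing %d recordings", len(recordings))
    recordings = [apply_pipeline(r, config.get("preprocess", [])) for r in recordings]

    folds = split(recordings, SplitSpec(**config["protocol"]))
    all_preds: list[FramePredictions] = []
    for i, (train, test) in enumerate(folds):
        log.info("fold %d/%d: %d train / %d test recordings", i + 1, len(folds), len(train), len(test))
        all_preds.extend(_fit_predict(config, grid, imap, train, test, seed))

    windows = config.get("windows", [1, SEGMENT])
    results = vote_curve(all_preds, windows)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.json", "w") as f:
        json.dump(config, f, indent=2, sort_keys=True)
    import pandas as pd

    rows = [
        {"window": str(r.window), "subject": s, "accuracy": a}
        for r in results
        for s, a in r.per_subject.items()
    ]
    pd.DataFrame(rows).to_csv(out_dir / "results.csv", index=False)
    summary = {
        "seed": seed,
        "n_recordings": len(recordings),
        "windows": {
            str(r.window): {"mean": r.mean, "std": r.std} for r in results
        },
    }
    with open(out_dir / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    log.info("results written to %s", out_dir)
    return summary
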