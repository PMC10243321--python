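"""File formats, run configuration and the end-to-end pipeline.

Portal images travel as 16-bit grayscale TIFF with a JSON sidecar carrying
the grid; dose planes and TDM maps as compressed ``.npz`` archives with the
same sidecar convention; histories and reports as CSV.  A ``RunConfig``
bundles every knob of a run, round-trips through YAML, and hashes to a
stable identifier that stamps all artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import DoseDistribution, GridSpec, PortalImage
from .gamma_metrics import GammaCriteria
from .model import UNet, UNetSpec, TDMLayer
from .preprocessing import NormalizationFactors
from .synthetic_beams import SimulatorConfig, desk_config, paper_config
from .training import TrainingConfig

__all__ = [
    "RunConfig",
    "read_portal_image",
    "write_portal_image",
    "read_dose",
    "write_dose",
    "write_dicom_rt_dose",
    "save_checkpoint",
    "load_checkpoint",
    "run_pipeline",
]

log = logging.getLogger("portaldose")


# ---------------------------------------------------------------------------
# portal images: 16-bit TIFF + JSON sidecar


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_meta(path: Path, grid: GridSpec, **extra) -> None:
    meta = {"n_pixels": grid.n_pixels, "pixel_pitch": grid.pixel_pitch, **extra}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _read_meta(path: Path) -> dict:
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing grid metadata sidecar for {path}")
    return json.loads(side.read_text())


def write_portal_image(path, mpi: PortalImage, **extra) -> None:
    path = Path(path)
    tifffile.imwrite(path, mpi.values)
    _write_meta(path, mpi.grid, **extra)


def read_portal_image(path) -> PortalImage:
    path = Path(path)
    values = tifffile.imread(path)
    if values.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit grayscale TIFF, got dtype {values.dtype}")
    meta = _read_meta(path)
    return PortalImage(values, GridSpec(meta["n_pixels"], meta["pixel_pitch"]))


# ---------------------------------------------------------------------------
# dose planes: compressed npz + JSON sidecar


def write_dose(path, dose: DoseDistribution, **extra) -> None:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez_compressed(path, values=dose.values)
    _write_meta(path, dose.grid, unit=dose.unit, **extra)


def read_dose(path) -> DoseDistribution:
    path = Path(path)
    meta = _read_meta(path)
    if meta.get("unit") != "Gy":
        raise ValueError(f"{path}: dose archive must carry unit 'Gy'")
    with np.load(path) as archive:
        values = archive["values"]
    return DoseDistribution(values, GridSpec(meta["n_pixels"], meta["pixel_pitch"]))


def write_dicom_rt_dose(path, dose: DoseDistribution) -> None:
    """Write-only convenience export of a dose plane as DICOM RT Dose."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    scale = dose.values.max() / 65534 if dose.values.max() > 0 else 1.0
    pixels = np.round(dose.values / scale).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.dataset.FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = pydicom.uid.RTDoseStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = float(scale)
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [dose.grid.pixel_pitch, dose.grid.pixel_pitch]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything one pipeline run needs; presets 'desk' and 'paper'."""

    preset: str = "desk"
    simulator: SimulatorConfig = None
    unet: UNetSpec = field(default_factory=UNetSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    gamma: GammaCriteria = field(default_factory=GammaCriteria)
    n_train: int = 40
    n_validation: int = 10
    n_test: int = 10
    gamma_subsample: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulator is None:
            factory = {"desk": desk_config, "paper": paper_config}.get(self.preset)
            if factory is None:
                raise ValueError(f"unknown preset {self.preset!r}")
            self.simulator = factory(seed=self.seed)
        if self.preset == "paper":
            # mirror the full-scale data design
            self.n_train, self.n_validation, self.n_test = 119, 30, 37

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulator"]["grid"] = asdict(self.simulator.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulator"))
        sim["grid"] = GridSpec(**sim.pop("grid"))
        sim["horn_coeffs"] = tuple(sim["horn_coeffs"])
        sim["epid_radial_response_coeffs"] = tuple(sim["epid_radial_response_coeffs"])
        return cls(
            simulator=SimulatorConfig(**sim),
            unet=UNetSpec(**d.pop("unet")),
            training=TrainingConfig(**d.pop("training")),
            gamma=GammaCriteria(**d.pop("gamma")),
            **d,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# model checkpoints


def save_checkpoint(
    directory,
    network: UNet,
    tdm: TDMLayer | None,
    norm: NormalizationFactors,
    grid: GridSpec,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "weights.npz",
        **{f"p{i:03d}": v for i, v in enumerate(network.state_dict())},
    )
    meta = {
        "unet_spec": asdict(network.spec),
        "norm": asdict(norm),
        "grid": {"n_pixels": grid.n_pixels, "pixel_pitch": grid.pixel_pitch},
        "has_tdm": tdm is not None,
        "tdm_provenance": tdm.provenance if tdm is not None else None,
    }
    (directory / "checkpoint.json").write_text(json.dumps(meta, indent=1))
    if tdm is not None:
        np.savez_compressed(directory / "tdm.npz", values=tdm.values)


def load_checkpoint(directory):
    """Returns (network, tdm_or_None, norm, grid)."""
    from .model import build_unet

    directory = Path(directory)
    meta = json.loads((directory / "checkpoint.json").read_text())
    spec = UNetSpec(**meta["unet_spec"])
    network = build_unet(spec, seed=0)
    with np.load(directory / "weights.npz") as archive:
        state = [archive[k] for k in sorted(archive.files)]
    network.load_state_dict(state)
    tdm = None
    if meta["has_tdm"]:
        with np.load(directory / "tdm.npz") as archive:
            tdm = TDMLayer(archive["values"], provenance=meta["tdm_provenance"] or "")
    norm = NormalizationFactors(**meta["norm"])
    grid = GridSpec(**meta["grid"])
    return network, tdm, norm, grid


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """simulate -> preprocess -> two-step train -> evaluate, one seed ledger.

    Writes the config, checkpoint, history CSV and study report into
    ``out_dir`` and returns a summary dict.  Every artifact is stamped with
    the config hash; stage boundaries are logged.
    """
    from .evaluation import compare_variants
    from .synthetic_beams import generate_dataset
    from .training import FoldSplit, prepare_dataset, two_step_train

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    config.to_yaml(out / "config.yaml")
    log.info("[%s] simulate: %d beams", chash, config.n_train + config.n_validation + config.n_test)

    n_total = config.n_train + config.n_validation + config.n_test
    pairs, calibration = generate_dataset(n_total, config.simulator, seed=config.seed)
    dataset = prepare_dataset(pairs, calibration)
    fold = FoldSplit(
        fold_id=0,
        train=np.arange(config.n_train),
        validation=np.arange(config.n_train, config.n_train + config.n_validation),
        test=np.arange(config.n_train + config.n_validation, n_total),
    )
    log.info("[%s] two-step training", chash)
    result = two_step_train(dataset, fold, config.training, config.unet)
    result.history.to_dataframe().assign(config_hash=chash).to_csv(
        out / "history.csv", index=False
    )
    save_checkpoint(out / "checkpoint", result.network, result.tdm, dataset.norm, dataset.grid)

    log.info("[%s] evaluate on %d held-out beams", chash, len(fold.test))
    control = [pairs[i] for i in fold.test]
    report = compare_variants(
        control,
        result.stage1_network,
        (result.network, result.tdm),
        dataset.norm,
        config.gamma,
        subsample=config.gamma_subsample,
        bootstrap_seed=config.seed,
    )
    report.rows.assign(config_hash=chash).to_csv(out / "report_rows.csv", index=False)
    report.aggregates.to_csv(out / "report_aggregates.csv")

    tdm_rows = report.rows[report.rows.variant == "unet_tdm"]
    summary = {
        "config_hash": chash,
        "mean_gamma": float(tdm_rows.mean_gamma.mean()),
        "passing_rate": float(tdm_rows.passing_rate.mean()),
        "n_test_beams": int(len(tdm_rows)),
    }
    log.info("[%s] done: mean gamma %.3f, passing %.2f%%", chash,
             summary["mean_gamma"], summary["passing_rate"])
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
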