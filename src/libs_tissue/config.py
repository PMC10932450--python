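"""Pipeline configuration: wavelength grid, bin catalog, generator model.

A single YAML file describes one reproducible pipeline setup.  A versioned
default ships with the package (``data/default_config.yaml``) holding the
published class calibration table, the 15-bin catalog and the synthetic
grid.  ``PipelineConfig`` round-trips losslessly through YAML, and its
``config_hash`` pins a run to an exact configuration in the run manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .core import BinCatalog, TissueClass, ValidationError, default_catalog
from .synth import DEFAULT_COUNTS, ClassIntensityModel

__all__ = ["GridSpec", "PipelineConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform wavelength grid of the (synthetic) spectrometer."""

    lo_nm: float = 500.0
    hi_nm: float = 850.0
    step_nm: float = 0.1

    def __post_init__(self) -> None:
        if not (self.lo_nm < self.hi_nm) or self.step_nm <= 0:
            raise ValidationError(f"invalid grid {self}")

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.hi_nm - self.lo_nm) / self.step_nm)) + 1
        return self.lo_nm + self.step_nm * np.arange(n)

    def to_dict(self) -> dict:
        return {"lo_nm": self.lo_nm, "hi_nm": self.hi_nm, "step_nm": self.step_nm}


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run."""

    grid: GridSpec
    catalog: BinCatalog
    model: ClassIntensityModel
    counts: dict[TissueClass, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    baseline_percentile: float = 5.0
    pca_reference_count: int = 50
    representative_k: int = 50
    version: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.baseline_percentile < 50):
            raise ValidationError("baseline_percentile must lie in (0, 50)")
        if self.pca_reference_count < 0 or self.representative_k < 1:
            raise ValidationError("invalid pca_reference_count / representative_k")

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "grid": self.grid.to_dict(),
            "catalog": self.catalog.to_dict(),
            "preprocess": {"baseline_percentile": self.baseline_percentile},
            "generator": self.model.to_dict(),
            "counts": {t.value: n for t, n in self.counts.items()},
            "pca": {
                "reference_count": self.pca_reference_count,
                "representative_k": self.representative_k,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(
            grid=GridSpec(**data["grid"]),
            catalog=BinCatalog.from_dict(data["catalog"]),
            model=ClassIntensityModel.from_dict(data["generator"]),
            counts={TissueClass(k): int(v) for k, v in data.get("counts", {}).items()},
            baseline_percentile=float(
                data.get("preprocess", {}).get("baseline_percentile", 5.0)
            ),
            pca_reference_count=int(data.get("pca", {}).get("reference_count", 50)),
            representative_k=int(data.get("pca", {}).get("representative_k", 50)),
            version=int(data.get("version", 1)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def default_config() -> PipelineConfig:
    """The packaged default configuration (published calibration, 15 bins)."""
    text = resources.files("libs_tissue").joinpath("data/default_config.yaml").read_text()
    cfg = PipelineConfig.from_dict(yaml.safe_load(text))
    # The packaged catalog must be the canonical 15-bin default.
    if cfg.catalog != default_catalog():
        raise ValidationError("packaged default catalog is out of sync with core.default_catalog")
    return cfg
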