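"""Pipeline configuration: validated, JSON round-trippable, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MovieConfig(_StrictModel):
    duration_s: float = Field(240.0, gt=0)
    frame_rate_hz: float = Field(8.0, gt=0)
    pixel_size_um: float = Field(0.5, gt=0)
    snr: float = Field(10.0, gt=0)
    basal_diameter_um: float = Field(20.0, gt=0)
    dilation_fraction: float = Field(0.15, ge=0)
    dilation_tau_s: float = Field(1.5, gt=0)


class PenetratingConfig(_StrictModel):
    n_frames: int = Field(8, ge=1)
    a_px: float = Field(10.0, gt=0)
    b_px: float = Field(5.0, gt=0)
    rotate: bool = True
    snr: float = Field(5.0, gt=0)
    pixel_size_um: float = Field(0.5, gt=0)


class LinescanConfig(_StrictModel):
    velocity_mm_s: float = 2.0
    n_lines: int = Field(1024, ge=128)
    pixel_size_um: float = Field(0.5, gt=0)
    line_rate_hz: float = Field(2000.0, gt=0)
    snr: float = Field(5.0, gt=0)
    min_separability: float = Field(0.5, ge=0, le=1)


class LocomotionConfig(_StrictModel):
    duration_s: float = Field(240.0, gt=0)
    sample_rate_hz: float = Field(1000.0, gt=0)
    bouts_s: list[tuple[float, float]] = [
        (20.0, 28.0), (50.0, 62.0), (85.0, 97.0),
        (120.0, 133.0), (155.0, 168.0), (193.0, 207.0),
    ]
    peak_speed_cm_s: float = Field(3.0, gt=0)
    noise_sd_cm_s: float = Field(0.1, ge=0)
    accel_threshold: float = Field(1e-5, gt=0)


class LFPConfig(_StrictModel):
    duration_s: float = Field(40.0, gt=0)
    sample_rate_hz: float = Field(20000.0, gt=0)
    gamma_gain: float = Field(2.0, gt=0)
    line_amp_uv: float = Field(20.0, ge=0)


class PhotometryConfig(_StrictModel):
    duration_s: float = Field(900.0, gt=0)
    sample_rate_hz: float = Field(1200.0, gt=0)
    tau1_s: float = Field(30.0, gt=0)
    tau2_s: float = Field(300.0, gt=0)
    attenuation_coeff: float = Field(0.3, ge=0)
    noise_sd: float = Field(0.1, ge=0)
    n_gfp_animals: int = Field(3, ge=1)


class CohortConfig(_StrictModel):
    gamma: float = -0.25
    sigma_animal: float = Field(0.05, ge=0)
    sigma_resid: float = Field(0.05, ge=0)
    n_animals: int = Field(6, ge=2)
    vessels_per_animal: int = Field(5, ge=1)
    baseline_mean_um: float = Field(20.0, gt=0)
    n_groups: int = Field(6, ge=1)


class PipelineConfig(_StrictModel):
    """Top-level configuration for the end-to-end synthetic demonstration."""

    seed: int = 1
    outdir: str = "vasopipe_out"
    movie: MovieConfig = MovieConfig()
    penetrating: PenetratingConfig = PenetratingConfig()
    linescan: LinescanConfig = LinescanConfig()
    locomotion: LocomotionConfig = LocomotionConfig()
    lfp: LFPConfig = LFPConfig()
    photometry: PhotometryConfig = PhotometryConfig()
    cohort: CohortConfig = CohortConfig()

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.model_dump_json(indent=2) + "\n")
        return path
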