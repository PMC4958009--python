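"""Validated pipeline configuration (YAML-loadable, unknown keys rejected)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with defaults.

    Preprocessing: ``median_window`` (odd px), ``pde_iterations`` /
    ``pde_conductance`` / ``pde_dt`` (anisotropic diffusion),
    ``se_shape`` / ``se_size`` (structuring element), ``use_top_hat``
    (top-hat instead of opening), ``majority_n``, ``binarize_method``.
    Backbone: KDE bandwidth, ridge step, density-threshold fraction,
    spur pruning. Boundary: ``alpha`` (None = Otsu along perpendicular
    profiles), marching cap. Spines: area/gap gates and model paths.
    """

    # i/o
    input: str | None = None
    output_dir: str = "spineridge_out"
    seed: int = 0
    pixel_size_um: float = 0.24
    # preprocessing
    median_window: int = 3
    pde_iterations: int = 0
    pde_conductance: float = 0.1
    pde_dt: float = 0.2
    se_shape: str = "disk"
    se_size: int = 2
    use_top_hat: bool = False
    majority_n: int = 4
    spine_majority_n: int = 2
    binarize_method: str = "otsu"
    fixed_threshold: float = 0.5
    # backbone
    bandwidth_px: float = 3.0
    ridge_step: float = 1.5
    theta_fraction: float = 0.1
    spur_max_len: float = 15.0
    junction_radius: float | None = None
    max_samples: int = 20000
    min_branch_px: float = 25.0
    # boundary
    alpha: float | None = None
    max_halfwidth: float = 20.0
    sigma_d: float = 2.0
    # spines
    min_area: int = 4
    max_gap: float = 2.0
    boundary_margin_px: float = 1.5
    min_protrusion_px: float = 1.0
    binary_model: str | None = None
    multiclass_model: str | None = None
    # classifiers
    c1: float = 1.0
    c2: float = 1.0
    gamma_k: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError("config YAML must be a mapping")
        return cls.from_dict(data)

    def validate(self):
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValidationError("median_window must be odd and >= 3")
        if self.bandwidth_px <= 0 or self.ridge_step <= 0:
            raise ValidationError("bandwidth_px and ridge_step must be positive")
        if not (0 <= self.theta_fraction < 1):
            raise ValidationError("theta_fraction must lie in [0, 1)")
        if self.alpha is not None and not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.min_area < 1:
            raise ValidationError("min_area must be >= 1")
        return self

    def to_dict(self) -> dict:
        return asdict(self)
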