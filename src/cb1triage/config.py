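"""YAML run configuration with strict schema validation.

Unknown keys are rejected (a typo in a threshold name must not silently
fall back to a default), and every threshold echoed here ends up in the
run manifest so a run can be reproduced bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TriageBlock(_Strict):
    mw_range: tuple[float, float] = (350.0, 500.0)
    clogp_range: tuple[float, float] = (3.0, 5.0)
    top_n: int = Field(default=300_000, ge=1)
    cluster_tc: float = Field(default=0.5, gt=0.0, le=1.0)
    novelty_tc: float = Field(default=0.36, gt=0.0, le=1.0)
    analog_tc: float = Field(default=0.5, gt=0.0, le=1.0)
    fingerprint_bits: int = Field(default=2048, ge=64)
    fingerprint_radius: int = Field(default=2, ge=1)

    def to_triage_config(self):
        from .triage import TriageConfig

        return TriageConfig(
            mw_range=self.mw_range,
            clogp_range=self.clogp_range,
            top_n=self.top_n,
            cluster_tc=self.cluster_tc,
            novelty_tc=self.novelty_tc,
            analog_tc=self.analog_tc,
            fingerprint_bits=self.fingerprint_bits,
            fingerprint_radius=self.fingerprint_radius,
        )


class SimulateBlock(_Strict):
    n_molecules: int = Field(default=1000, ge=1)
    n_chemotype_clusters: int = Field(default=8, ge=1)
    fraction_knownlike: float = Field(default=0.25, ge=0.0, le=1.0)
    mw_range: tuple[float, float] = (350.0, 500.0)
    clogp_range: tuple[float, float] = (3.0, 5.0)


class PoseBlock(_Strict):
    contact_cutoff: float = Field(default=3.5, gt=0.0)
    anchor_residues: list[str] = ["S383", "T201", "H178"]


class PharmBlock(_Strict):
    radioligand_conc_nM: float = Field(default=0.75, ge=0.0)
    radioligand_kd_nM: float = Field(default=2.0, gt=0.0)
    hit_threshold_percent: float = 50.0
    mode: str = "agonist"


class PKBlock(_Strict):
    n_lambda_points: int = Field(default=3, ge=3)
    lambda_mode: str = "last-points"
    protein_conc_mg_ml: float = Field(default=0.42, gt=0.0)


class WindowBlock(_Strict):
    analgesic_assays: list[str] = []
    side_effect_assays: list[str] = []


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "cb1triage_out"
    log_level: str = "INFO"
    triage: TriageBlock = TriageBlock()
    simulate: SimulateBlock = SimulateBlock()
    pose: PoseBlock = PoseBlock()
    pharm: PharmBlock = PharmBlock()
    pk: PKBlock = PKBlock()
    window: WindowBlock = WindowBlock()


def validate_config(path: str | Path, required: list[str] | None = None) -> RunConfig:
    """Load and schema-check a YAML config; unknown keys are rejected.

    ``required`` names blocks that must be present explicitly in the file
    for the requested subcommand (defaults alone are not accepted there).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for block in required or []:
        if block not in raw:
            raise ConfigError(f"{path}: missing required block {block!r}")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        lines = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"{path}: {lines}") from exc
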