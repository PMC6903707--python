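"""Configuration objects for cohort simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass
class SimulationConfig:
    """Parameters of the synthetic case-control cohort generator.

    The defaults encode the cohort the analysis assumes: ~4.9% diagnosed
    type 2 diabetes prevalence, 57 independent BMI instruments jointly
    explaining r^2 ~= 0.013 of BMI, a disease polygenic score with AUC ~= 0.66
    for case status, ~16.8% family-history prevalence, and a causal effect of
    BMI on diabetes odds of exp(theta) per kg/m^2.
    """

    n_individuals: int = 50_000
    seed: int = 0
    n_instruments: int = 57
    instrument_freqs: Optional[Sequence[float]] = None  # drawn U(0.05, 0.5) if None
    target_instrument_r2: float = 0.013
    causal_log_or_per_bmi_unit: float = math.log(1.3)
    target_prevalence: float = 0.049
    target_prs_auc: float = 0.66
    target_fh_prevalence: float = 0.168
    fh_heritable_share: float = 0.4
    shared_env_liability_share: float = 0.1
    confounder_effect_bmi: float = 1.0
    confounder_effect_logit: float = 0.2
    liability_logit_effect: float = 0.9
    shared_env_bmi_effect: float = 1.0
    bmi_mean: float = 27.4
    bmi_sd: float = 4.8
    n_pcs: int = 10
    other_label_fraction: float = 0.01
    genotype_missing_rate: float = 0.005
    bad_variant_missing_rate: float = 0.15
    bad_variant_index: int = 0
    case_metformin_rate: float = 0.567  # 7,923 / 13,982
    case_insulin_rate: float = 0.150  # 2,094 / 13,982
    prs_auc_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.n_individuals < 100:
            raise ValueError("n_individuals must be >= 100")
        if self.n_instruments < 1:
            raise ValueError("n_instruments must be >= 1")
        for name in (
            "target_instrument_r2",
            "target_prevalence",
            "target_prs_auc",
            "target_fh_prevalence",
            "fh_heritable_share",
            "shared_env_liability_share",
            "other_label_fraction",
            "genotype_missing_rate",
            "bad_variant_missing_rate",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0 or (v == 0.0 and name in ("other_label_fraction", "genotype_missing_rate"))):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.fh_heritable_share + self.shared_env_liability_share >= 1.0:
            raise ValueError("fh_heritable_share + shared_env_liability_share must be < 1")
        if self.instrument_freqs is not None:
            freqs = list(self.instrument_freqs)
            if len(freqs) != self.n_instruments:
                raise ValueError("instrument_freqs length must equal n_instruments")
            if not all(0.0 < f < 1.0 for f in freqs):
                raise ValueError("instrument allele frequencies must lie strictly inside (0, 1)")
        if self.bmi_sd <= 0:
            raise ValueError("bmi_sd must be positive")
        remaining = self.bmi_sd**2 - (
            self.target_instrument_r2 * self.bmi_sd**2
            + self.confounder_effect_bmi**2
            + self.shared_env_bmi_effect**2
        )
        if remaining <= 0:
            raise ValueError(
                "BMI variance budget exhausted: instrument, confounder and shared-environment "
                "components exceed bmi_sd^2"
            )

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        if d["instrument_freqs"] is not None:
            d["instrument_freqs"] = list(map(float, d["instrument_freqs"]))
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            try:
                d = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    d = json.load(fh)
        if "seed" not in d:
            raise ValueError("simulation config JSON must specify 'seed'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration (simulate a cohort or load files)."""

    mode: str = "simulate"  # "simulate" | "files"
    simulation: Optional[SimulationConfig] = None
    cohort_path: Optional[str] = None
    genotypes_path: Optional[str] = None
    weights_path: Optional[str] = None
    output_dir: str = "bmimr_output"
    seed: int = 0
    max_missing: float = 0.1
    min_hwe_midp: float = 1e-20
    n_quantiles: int = 50
    match_ratio: float = 4.5
    match_bins: int = 10
    stratifications: Sequence[str] = field(
        default_factory=lambda: ("overall", "bmi", "family_history", "prs_tertile", "medication")
    )

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files":
            missing = [
                name
                for name in ("cohort_path", "genotypes_path", "weights_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(f"files mode requires paths: {missing}")
        elif self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
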