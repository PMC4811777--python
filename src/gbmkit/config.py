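"""Run configuration: defaults, YAML loading, range validation, seeding.

One flat key-value configuration drives every stage; CLI flags override file
values, and the fully resolved configuration is written next to the outputs
so a run can be reproduced from its own artifacts. Per-stage seeds are
derived deterministically from the single master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "derive_seed"]

STAGES = ("simulate", "normalize", "subtype", "cnv", "cohort")


@dataclass
class RunConfig:
    """All stage parameters with their defaults.

    Numeric defaults follow the pipeline's documented conventions: 1.5-fold
    deregulation threshold, 0.996 duplicate-correlation floor, B=1000
    bootstrap replicates at a 5% tail, 1 Mb GC windows and 1 Mb minimum
    reported CNV length, SD-undo multiple 3.
    """

    # expression
    glog_c: float = 0.0
    fold_threshold: float = 1.5
    min_corr: float = 0.996
    reference_condition: str = "wt"
    primary_condition: str = "p53"
    secondary_condition: str = "atmin_p53"
    # subtype
    metric: str = "spearman"
    B: int = 1000
    tail_level: float = 0.05
    scheme: str = "bootstrap"
    assignment: str = "relative"
    pooled_null: bool = False
    min_mapped_fraction: float = 0.5
    # cnv
    window_bp: int = 1_000_000
    min_length_bp: int = 1_000_000
    alpha: float = 0.01
    n_perm: int = 100
    min_markers: int = 5
    undo_sd: float = 3.0
    state_thresholds: tuple = (-1.0, -0.3, 0.3, 0.9)
    per_chromosome_wave: bool = False
    # cohort
    exact_cutoff: int = 12
    # simulation
    sim_n_genes: int = 2000
    sim_n_tech_dups: int = 2
    sim_noise_sd: float = 0.1
    sim_n_planted: int = 50
    sim_planted_logfc: float = 1.0
    sim_signature_genes: int = 60
    sim_chrom_lengths: dict = field(
        default_factory=lambda: {"1": 100_000_000, "2": 80_000_000}
    )
    sim_marker_spacing: int = 50_000
    sim_wave_coefficient: float = 0.5
    sim_lrr_noise_sd: float = 0.15
    sim_cohort_n: int = 200
    sim_cohort_effect: float = 1.0
    sim_mutant_fraction: float = 0.3
    # global
    seed: int = 0
    # paths (None means "use the simulated inputs in the run directory")
    expression_path: str | None = None
    annotation_path: str | None = None
    centroids_path: str | None = None
    gene_map_path: str | None = None
    marker_path: str | None = None
    cohort_path: str | None = None

    def validate(self) -> list[str]:
        """Range checks for every parameter; returns violations (empty = valid)."""
        v: list[str] = []
        if self.glog_c < 0:
            v.append(f"glog_c must be >= 0 (got {self.glog_c})")
        if self.fold_threshold <= 1:
            v.append(f"fold_threshold must be > 1 (got {self.fold_threshold})")
        if not 0 < self.min_corr <= 1:
            v.append(f"min_corr must be in (0, 1] (got {self.min_corr})")
        if self.metric not in ("spearman", "pearson", "euclidean"):
            v.append(f"metric must be spearman|pearson|euclidean (got {self.metric})")
        if self.B < 1:
            v.append(f"B must be >= 1 (got {self.B})")
        if not 0 < self.tail_level < 1:
            v.append(f"tail_level must be in (0, 1) (got {self.tail_level})")
        if self.scheme not in ("bootstrap", "permutation"):
            v.append(f"scheme must be bootstrap|permutation (got {self.scheme})")
        if self.assignment not in ("relative", "raw"):
            v.append(f"assignment must be relative|raw (got {self.assignment})")
        if self.window_bp <= 0:
            v.append(f"window_bp must be > 0 (got {self.window_bp})")
        if self.min_length_bp < 0:
            v.append(f"min_length_bp must be >= 0 (got {self.min_length_bp})")
        if not 0 < self.alpha < 1:
            v.append(f"alpha must be in (0, 1) (got {self.alpha})")
        if self.n_perm < 1:
            v.append(f"n_perm must be >= 1 (got {self.n_perm})")
        if self.min_markers < 2:
            v.append(f"min_markers must be >= 2 (got {self.min_markers})")
        if self.undo_sd < 0:
            v.append(f"undo_sd must be >= 0 (got {self.undo_sd})")
        thresholds = tuple(self.state_thresholds)
        if len(thresholds) != 4 or any(
            b <= a for a, b in zip(thresholds[:-1], thresholds[1:])
        ):
            v.append(
                "state_thresholds must be 4 strictly increasing cut points "
                f"(got {thresholds})"
            )
        if self.exact_cutoff < 2:
            v.append(f"exact_cutoff must be >= 2 (got {self.exact_cutoff})")
        if not 0 < self.sim_mutant_fraction < 1:
            v.append(
                f"sim_mutant_fraction must be in (0, 1) (got {self.sim_mutant_fraction})"
            )
        if self.sim_noise_sd < 0 or self.sim_lrr_noise_sd < 0:
            v.append("simulation noise SDs must be >= 0")
        if self.seed < 0:
            v.append(f"seed must be >= 0 (got {self.seed})")
        return v

    def to_dict(self) -> dict:
        out = asdict(self)
        out["state_thresholds"] = list(self.state_thresholds)
        return out

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config file (optional) and apply keyword overrides."""
    data: dict = {}
    if path is not None:
        try:
            loaded = yaml.safe_load(Path(path).read_text())
        except OSError as exc:
            raise ValueError(f"cannot read config file {path}: {exc}") from exc
        if loaded:
            data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(**data)
    if "state_thresholds" in data:
        config.state_thresholds = tuple(data["state_thresholds"])
    return config


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, STAGES.index(stage) if stage in STAGES else hash(stage) % 97])
    return int(ss.generate_state(1)[0] % (2**31))
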