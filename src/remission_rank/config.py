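"""Study-wide configuration.

All numeric constants of the pipeline live in one dataclass so a run is
fully described by (inputs, config, seed).  Defaults are the published
protocol values; everything is overridable from a YAML/``key: value`` file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class StudyConfig:
    """Pipeline constants.

    Parameters
    ----------
    maf_min
        Minimum minor allele frequency for a SNP to pass QC.
    hwe_p_min
        Hardy-Weinberg exact-test p-value below which a SNP is excluded.
    snp_miss_max, sample_miss_max
        Maximum tolerated missing-genotype rate for SNPs and samples.
    seed_k
        Number of lowest-p scan SNPs used to seed the network expansion.
    ld_r2_max
        Squared-correlation threshold above which two candidate SNPs are
        considered linked; the higher-p member of the pair is pruned.
    p_max
        Association p-value ceiling for candidate SNPs.
    gower_threshold
        Gower similarity above which two patients count as redundant.
    hidden_units, weight_decay, max_iterations
        Neural-network architecture and training constants.
    outer_folds, inner_folds, inner_repeats
        Nested cross-validation geometry; the number of forward-selection
        runs is ``outer_folds * inner_folds * inner_repeats``.
    delta_auc
        Minimum test-AUC improvement for a feature to be accepted during
        forward selection.
    min_total_clinical, min_total_snp, min_per_outer
        Finalization rule: a feature is kept when selected at least
        ``min_per_outer`` times in every outer fold and at least
        ``min_total_*`` times over all runs.
    score_cutoff
        Network output score at or above which a patient is classified
        as a remitter.
    rng_seed
        Master seed; every random substream is derived from it.
    """

    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    snp_miss_max: float = 0.10
    sample_miss_max: float = 0.10
    seed_k: int = 200
    ld_r2_max: float = 0.8
    p_max: float = 0.2
    gower_threshold: float = 0.925
    hidden_units: int = 3
    weight_decay: float = 1.0
    max_iterations: int = 1000
    outer_folds: int = 5
    inner_folds: int = 5
    inner_repeats: int = 5
    delta_auc: float = 0.01
    min_total_clinical: int = 45
    min_total_snp: int = 5
    min_per_outer: int = 1
    score_cutoff: float = 0.5
    snp_phase_mode: str = "forward"  # "forward" | "single"
    # Hobohm tie-break order; configurable because the protocol only states
    # that missing-rich patients are preferentially removed.
    hobohm_tiebreak: tuple = ("degree", "missing", "id")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("maf_min", 0.0, 0.5), ("hwe_p_min", 0.0, 1.0),
            ("snp_miss_max", 0.0, 1.0), ("sample_miss_max", 0.0, 1.0),
            ("ld_r2_max", 0.0, 1.0), ("p_max", 0.0, 1.0),
            ("gower_threshold", 0.0, 1.0), ("delta_auc", 0.0, 1.0),
            ("score_cutoff", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("seed_k", "hidden_units", "max_iterations",
                     "outer_folds", "inner_folds", "inner_repeats",
                     "min_total_clinical", "min_total_snp", "min_per_outer"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.snp_phase_mode not in ("forward", "single"):
            raise ValueError("snp_phase_mode must be 'forward' or 'single'")

    @property
    def n_selection_runs(self) -> int:
        return self.outer_folds * self.inner_folds * self.inner_repeats

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hobohm_tiebreak"] = list(self.hobohm_tiebreak)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hobohm_tiebreak" in d:
            d = {**d, "hobohm_tiebreak": tuple(d["hobohm_tiebreak"])}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
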