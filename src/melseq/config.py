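"""YAML run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .effects import MIX, SCENARIOS
from .events import Subgroup, n_named_lines
from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config"]

_KNOWN_KEYS = {
    "subgroup", "sequence", "scenario", "horizon_years", "dt", "seed",
    "cohort_csv", "generate", "hr_table", "life_table", "start_age",
    "male_fraction", "output_dir", "psa", "families",
}


@dataclass
class RunConfig:
    subgroup: Subgroup = field(default_factory=lambda: Subgroup(False, "favorable"))
    sequence: list = field(default_factory=lambda: [MIX])
    scenario: str = "base"
    horizon_years: float | None = None
    dt: float = 1.0 / 12
    seed: int = 0
    cohort_csv: str | None = None
    generate: dict | None = None     # GeneratorSpec overrides
    hr_table: str = "builtin"        # path or "builtin"
    life_table: str = "builtin"
    start_age: float = 60.0
    male_fraction: float = 0.56
    output_dir: str = "melseq-run"
    psa_n_iter: int = 1000
    families: tuple | None = None     # candidate families for transition fits

    def validate(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"scenario: unknown value {self.scenario!r} "
                f"(expected one of {SCENARIOS})")
        L = n_named_lines(self.subgroup.braf)
        if len(self.sequence) > L:
            raise ConfigError(
                f"sequence: {len(self.sequence)} lines named but the "
                f"{'BRAF-mutant' if self.subgroup.braf else 'wild-type'} "
                f"model has only {L} treatment lines")
        if self.dt <= 0:
            raise ConfigError("dt: must be positive")
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ConfigError("horizon_years: must be positive when set")
        if not (0 <= self.male_fraction <= 1):
            raise ConfigError("male_fraction: must be in [0, 1]")
        if self.cohort_csv is not None and self.generate is not None:
            raise ConfigError("cohort_csv/generate: specify only one source")
        return self


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
    kwargs = {}
    if "subgroup" in raw:
        sg = raw.pop("subgroup")
        try:
            kwargs["subgroup"] = Subgroup(bool(sg["braf"]), sg["prognostic"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"subgroup: {exc}") from None
    if "sequence" in raw:
        seq = raw.pop("sequence")
        kwargs["sequence"] = [seq] if isinstance(seq, str) else list(seq)
    if "families" in raw:
        fams = raw.pop("families")
        kwargs["families"] = tuple(
            fams.split(",") if isinstance(fams, str) else fams)
    if "psa" in raw:
        psa = raw.pop("psa") or {}
        kwargs["psa_n_iter"] = int(psa.get("n_iter", 1000))
    kwargs.update(raw)
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    return cfg.validate()
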