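"""Global pipeline configuration: every threshold in one place.

Defaults are the published operating points: ddG tolerance cutoffs of
2.1 kcal/mol (crystal structures) and 1.6 kcal/mol (AlphaFold2 models),
model gates of mean motif pLDDT > 65 and interaction energy < -5 kcal/mol,
allele-frequency defaults 10^-4.1 (autosomal recessive / no disease) and
10^-4.28 (autosomal dominant), and a symmetric final-score verdict cutoff
tau = 0.5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .variants import AD_DEFAULT_AF, AR_DEFAULT_AF


@dataclass
class PipelineConfig:
    ddg_threshold_pdb: float = 2.1  # kcal/mol
    ddg_threshold_af2: float = 1.6  # kcal/mol
    plddt_min: float = 65.0
    energy_max: float = -5.0  # kcal/mol
    af_default_ar: float = AR_DEFAULT_AF
    af_default_ad: float = AD_DEFAULT_AF
    final_tau: float = 0.5
    sasa_relative_cutoff: float = 0.25
    conservation_rule: str = "p0-minimum"
    seed: int = 0
    max_iterations: int = 20
    extra: dict = field(default_factory=dict)

    @property
    def ddg_thresholds(self) -> dict[str, float]:
        return {"pdb": self.ddg_threshold_pdb, "af2": self.ddg_threshold_af2}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        unknown = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(unknown)
        return cfg
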