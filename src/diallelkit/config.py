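"""Pipeline configuration and study-scale defaults.

The default configuration emulates a 10-parent eggplant half diallel
(nine cultivated accessions plus one wild-relative accession) evaluated in
three complete blocks for eleven fruit biochemical, colour and browning
traits, genotyped at several thousand biallelic SNPs.  The per-trait
variance components were chosen to give the additive-dominant structure
typical of such trials: GCA variance dominating SCA variance for every
trait (Baker ratios well above 0.75), sizeable residual noise, and weak
block effects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .design import DiallelDesign
from .simulate import TruthParams

#: Default parent labels: nine cultivated eggplant accessions and one
#: wild-relative accession (``INS2``), which anchors the wide crosses.
DEFAULT_PARENTS = (
    "MM1597", "DH621", "AN-S-26", "H15", "A0416",
    "IVIA-371", "ASI-S-1", "MEL1", "MEL5", "INS2",
)
DEFAULT_WILD = "INS2"

#: Per-trait generative parameters (mu, sigma2_g, sigma2_s, sigma2_block,
#: sigma2_e).  Units follow the trait definitions: percent for DryMatter and
#: AreaPct, mg/g dry weight for Phenolics and CGA, CIELAB units for the
#: colour traits, activity units for PPO.
DEFAULT_TRAIT_PARAMS: dict[str, dict[str, float]] = {
    "DryMatter": dict(mu=9.53, sigma2_g=0.253, sigma2_s=1.613, sigma2_block=0.007, sigma2_e=1.81),
    "Phenolics": dict(mu=10.96, sigma2_g=1.355, sigma2_s=3.680, sigma2_block=0.300, sigma2_e=7.31),
    "CGA": dict(mu=2.82, sigma2_g=0.010, sigma2_s=0.090, sigma2_block=0.0, sigma2_e=0.30),
    "AreaPct": dict(mu=72.30, sigma2_g=10.861, sigma2_s=35.310, sigma2_block=0.0, sigma2_e=30.48),
    "L0": dict(mu=81.47, sigma2_g=2.754, sigma2_s=3.750, sigma2_block=0.657, sigma2_e=5.63),
    "a0": dict(mu=-2.91, sigma2_g=0.464, sigma2_s=0.720, sigma2_block=0.044, sigma2_e=1.60),
    "b0": dict(mu=18.10, sigma2_g=5.117, sigma2_s=5.580, sigma2_block=0.515, sigma2_e=4.56),
    "DW0": dict(mu=26.34, sigma2_g=6.634, sigma2_s=7.310, sigma2_block=1.115, sigma2_e=8.08),
    "PPO": dict(mu=2.16, sigma2_g=0.208, sigma2_s=1.013, sigma2_block=0.0, sigma2_e=0.81),
    "DB": dict(mu=3.47, sigma2_g=0.976, sigma2_s=4.873, sigma2_block=0.0, sigma2_e=2.60),
    "CD": dict(mu=5.52, sigma2_g=2.189, sigma2_s=7.603, sigma2_block=0.0, sigma2_e=4.61),
}


def default_divergence(parent_ids, wild_parent: str | None,
                       within: float = 0.25, wild: float = 0.45) -> np.ndarray:
    """Target pairwise GD matrix: cultivated pairs vs crosses with the wild parent."""
    p = len(parent_ids)
    d = np.full((p, p), within)
    np.fill_diagonal(d, 0.0)
    if wild_parent is not None and wild_parent in parent_ids:
        w = list(parent_ids).index(wild_parent)
        d[w, :] = wild
        d[:, w] = wild
        d[w, w] = 0.0
    return d


@dataclass
class PipelineConfig:
    """Everything needed for one deterministic end-to-end run."""

    seed: int = 42
    parents: tuple[str, ...] = DEFAULT_PARENTS
    blocks: int = 3
    wild_parent: str | None = DEFAULT_WILD
    trait_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_PARAMS.items()})
    n_markers: int = 7335
    divergence_within: float = 0.25
    divergence_wild: float = 0.45
    missing_rate: float = 0.02
    db_formula: str = "lightness_drop"
    baker_mode: str = "ms"
    ibs_mode: str = "shared_allele"
    entanglement_L: float = 1.5
    dependent_trait: str = "CGA"

    def __post_init__(self):
        self.parents = tuple(str(x) for x in self.parents)
        if self.wild_parent is not None and self.wild_parent not in self.parents:
            raise ValueError(
                f"wild_parent {self.wild_parent!r} is not among the parents")
        for trait, pars in self.trait_params.items():
            for key in ("sigma2_g", "sigma2_s", "sigma2_block", "sigma2_e"):
                if pars.get(key, 0.0) < 0:
                    raise ValueError(f"{trait}: {key} must be non-negative")

    @property
    def design(self) -> DiallelDesign:
        return DiallelDesign(self.parents, blocks=self.blocks)

    @property
    def traits(self) -> list[str]:
        return list(self.trait_params)

    def truth_for(self, trait: str) -> TruthParams:
        pars = self.trait_params[trait]
        return TruthParams(
            mu=pars.get("mu", 0.0),
            sigma2_g=pars.get("sigma2_g", 0.0),
            sigma2_s=pars.get("sigma2_s", 0.0),
            sigma2_block=pars.get("sigma2_block", 0.0),
            sigma2_e=pars.get("sigma2_e", 0.0),
        )

    def trait_seed(self, trait: str) -> int:
        """Fixed per-trait substream: stable under trait-list reordering."""
        h = hashlib.sha256(f"{self.seed}:{trait}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def snp_seed(self) -> int:
        h = hashlib.sha256(f"{self.seed}:snps".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def divergence_matrix(self) -> np.ndarray:
        return default_divergence(self.parents, self.wild_parent,
                                  self.divergence_within, self.divergence_wild)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "parents": list(self.parents),
            "blocks": self.blocks,
            "wild_parent": self.wild_parent,
            "trait_params": {k: dict(v) for k, v in self.trait_params.items()},
            "n_markers": self.n_markers,
            "divergence_within": self.divergence_within,
            "divergence_wild": self.divergence_wild,
            "missing_rate": self.missing_rate,
            "db_formula": self.db_formula,
            "baker_mode": self.baker_mode,
            "ibs_mode": self.ibs_mode,
            "entanglement_L": self.entanglement_L,
            "dependent_trait": self.dependent_trait,
        }

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "parents" in d:
            d["parents"] = tuple(d["parents"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
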