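"""Run configuration: enzymes, primers, thresholds, statistical settings.

Enzyme and primer definitions are data, not code: they live in a YAML file
(packaged defaults in ``data/defaults.yaml``) so that a user can swap in a
different enzyme or real laboratory primers without touching the logic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .assay import Marker, PrimerPair, RestrictionEnzyme
from .errors import ConfigError


@dataclass
class RunConfig:
    enzymes: dict[str, RestrictionEnzyme]
    marker_enzymes: dict[Marker, str]
    primers: dict[Marker, PrimerPair]
    visibility_threshold: int = 100
    band_tolerance: float = 0.05
    max_product_length: int = 5000
    scan_both_strands: bool = True
    confirmation_identity: float = 0.98
    bootstrap_replicates: int = 1000
    seed: int = 1234
    confidence_level: float = 0.95
    excluded_states: frozenset[str] = frozenset({"IL", "NV", "NY", "TX"})
    trade_years: tuple[int, int] = (2019, 2021)

    def __post_init__(self) -> None:
        if self.visibility_threshold < 0:
            raise ConfigError("visibility_threshold must be >= 0")
        if not 0 <= self.band_tolerance < 1:
            raise ConfigError("band_tolerance must be in [0, 1)")
        if not 0 < self.confidence_level < 1:
            raise ConfigError("confidence_level must be in (0, 1)")
        if not 0 < self.confirmation_identity <= 1:
            raise ConfigError("confirmation_identity must be in (0, 1]")
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError("seed must be an integer")
        for marker, name in self.marker_enzymes.items():
            if name not in self.enzymes:
                raise ConfigError(
                    f"marker {marker.value} mapped to unknown enzyme {name!r}"
                )

    def enzyme_for(self, marker: Marker) -> RestrictionEnzyme:
        return self.enzymes[self.marker_enzymes[marker]]

    def primer_for(self, marker: Marker) -> PrimerPair:
        return self.primers[marker]

    def to_dict(self) -> dict:
        return {
            "enzymes": {
                name: {"recognition": e.recognition, "cut_offset": e.cut_offset}
                for name, e in sorted(self.enzymes.items())
            },
            "marker_enzymes": {
                m.value: name for m, name in sorted(self.marker_enzymes.items())
            },
            "primers": {
                m.value: {
                    "name": p.name,
                    "forward": p.forward,
                    "reverse": p.reverse,
                    "max_mismatch": p.max_mismatch,
                }
                for m, p in sorted(self.primers.items())
            },
            "assay": {
                "visibility_threshold": self.visibility_threshold,
                "band_tolerance": self.band_tolerance,
                "max_product_length": self.max_product_length,
                "scan_both_strands": self.scan_both_strands,
            },
            "classify": {"confirmation_identity": self.confirmation_identity},
            "survey": {
                "bootstrap_replicates": self.bootstrap_replicates,
                "seed": self.seed,
                "confidence_level": self.confidence_level,
                "excluded_states": sorted(self.excluded_states),
            },
            "trade": {"years": list(self.trade_years)},
        }

    def config_hash(self) -> str:
        """Stable digest of the full configuration, embedded in reports."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            enzymes = {
                name: RestrictionEnzyme(
                    name=name,
                    recognition=spec["recognition"],
                    cut_offset=int(spec["cut_offset"]),
                )
                for name, spec in raw["enzymes"].items()
            }
            marker_enzymes = {
                Marker(m): name for m, name in raw["marker_enzymes"].items()
            }
            primers = {
                Marker(m): PrimerPair(
                    name=spec["name"],
                    forward=spec["forward"],
                    reverse=spec["reverse"],
                    max_mismatch=int(spec.get("max_mismatch", 0)),
                )
                for m, spec in raw["primers"].items()
            }
            assay = raw.get("assay", {})
            classify = raw.get("classify", {})
            survey = raw.get("survey", {})
            trade = raw.get("trade", {})
            return cls(
                enzymes=enzymes,
                marker_enzymes=marker_enzymes,
                primers=primers,
                visibility_threshold=int(assay.get("visibility_threshold", 100)),
                band_tolerance=float(assay.get("band_tolerance", 0.05)),
                max_product_length=int(assay.get("max_product_length", 5000)),
                scan_both_strands=bool(assay.get("scan_both_strands", True)),
                confirmation_identity=float(
                    classify.get("confirmation_identity", 0.98)
                ),
                bootstrap_replicates=int(survey.get("bootstrap_replicates", 1000)),
                seed=survey.get("seed", 1234),
                confidence_level=float(survey.get("confidence_level", 0.95)),
                excluded_states=frozenset(
                    survey.get("excluded_states", ["IL", "NV", "NY", "TX"])
                ),
                trade_years=tuple(trade.get("years", [2019, 2021])),
            )
        except ConfigError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"configuration file {path} is not a mapping")
        return cls.from_dict(raw)


def default_config() -> RunConfig:
    """The packaged default configuration."""
    text = resources.files("eelid.data").joinpath("defaults.yaml").read_text()
    return RunConfig.from_dict(yaml.safe_load(text))
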