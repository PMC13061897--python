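"""Experimental design and planted ground truth for the generators."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np


def stable_int(label: str) -> int:
    """Deterministic 64-bit integer derived from a string label."""
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:8], "big")


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Generator keyed by (seed, label) so per-sample streams are stable."""
    return np.random.default_rng([seed, stable_int(label)])


def sample_label(focal: str, partner: str, day: int, replicate: int) -> str:
    """Canonical sample id: ``FOCAL-PARTNER_d<day>_r<rep>``."""
    return f"{focal}-{partner}_d{day}_r{replicate}"


def parse_sample_label(label: str) -> tuple[str, str, int, int]:
    pair, d, r = label.split("_")
    focal, partner = pair.split("-")
    return focal, partner, int(d[1:]), int(r[1:])


@dataclass
class SyntheticDesign:
    """Strains x partners x days x replicates layout of the experiment."""

    strains: list[str] = field(default_factory=lambda: ["A", "B", "C", "D"])
    days: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("strains must be non-empty")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strains must be unique")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (t-tests require it)")

    def pairs(self) -> list[tuple[str, str]]:
        """All ordered (focal, partner) pairings, including self-pairings."""
        return [(x, y) for x in self.strains for y in self.strains]

    def sample_labels(self) -> list[str]:
        return [
            sample_label(x, y, d, r)
            for (x, y) in self.pairs()
            for d in self.days
            for r in range(1, self.replicates + 1)
        ]


@dataclass
class PlantedFeature:
    """A metabolite feature planted with a known producer."""

    producer: str
    partner: str | None
    log2fc: float
    diffusible: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc) or self.log2fc == 0:
            raise ValueError("planted log2fc must be finite and nonzero")

    def affects(self, focal: str, partner: str) -> bool:
        """Does this feature's planted effect apply to sample focal-partner?"""
        if self.diffusible:
            return self.producer in (focal, partner)
        return focal == self.producer and partner == self.partner


@dataclass
class PlantedDE:
    """A gene planted as differentially expressed in one pairing."""

    strain: str
    partner: str
    days: tuple[int, int]  # inclusive day range
    log2fc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc) or self.log2fc == 0:
            raise ValueError("planted log2fc must be finite and nonzero")

    def affects(self, focal: str, partner: str, day: int) -> bool:
        return (
            focal == self.strain
            and partner == self.partner
            and self.days[0] <= day <= self.days[1]
        )


@dataclass
class ColonyDisk:
    cx: float
    cy: float
    radius: float

    @property
    def area_px(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for parameter-recovery tests."""

    producer_features: dict[str, PlantedFeature] = field(default_factory=dict)
    de_genes: dict[str, PlantedDE] = field(default_factory=dict)
    colony_truth: dict[str, list[ColonyDisk]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            producer_features={k: PlantedFeature(**v) for k, v in d["producer_features"].items()},
            de_genes={
                k: PlantedDE(v["strain"], v["partner"], tuple(v["days"]), v["log2fc"])
                for k, v in d["de_genes"].items()
            },
            colony_truth={
                k: [ColonyDisk(**c) for c in v] for k, v in d["colony_truth"].items()
            },
        )
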