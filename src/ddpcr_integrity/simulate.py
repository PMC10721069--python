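"""Generative simulator of duplex droplet dPCR experiments.

Droplet occupancy is Poisson: a droplet receives ``k ~ Poisson(lambda)``
template molecules, and each molecule is independently one of three
species — 5'-only, 3'-only, or intact (both targets).  A droplet is
positive on a channel when at least one of its molecules carries that
channel's target.  The simulator produces the four-category counts the
instrument would report, for mixture/dilution study designs: two stocks
(an intact-like and a fragmented-like template population) mixed at a
grid of molecule fractions and diluted over a concentration grid, with
replicate wells.

Two built-in designs mirror published validation studies: a plasmid
(pAAV) study with expected integrities 0-100% over 12 dilutions spanning
8-5000 copies/uL, and an rAAV study mixing a heterogeneous vector prep
(84% intact) with a 0%-intact prep, at 4 dilutions over 62-498 copies/uL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .models import (
    DEFAULT_DROPLET_VOLUME_NL,
    DropletCounts,
    SpeciesProbabilities,
    copies_per_ul_to_lambda,
    expected_category_probabilities,
)

__all__ = [
    "StockSpec",
    "MixtureDesign",
    "SimulatedWell",
    "species_from_mixture",
    "simulate_well",
    "simulate_experiment",
    "paav_design",
    "raav_design",
    "design_from_yaml",
    "design_to_yaml",
]

PAAV_DILUTIONS = (8, 16, 31, 63, 125, 250, 500, 1000, 2000, 3000, 4000, 5000)
RAAV_DILUTIONS = (62, 124, 249, 498)  # 4 points, geometric over 62-498 copies/uL


@dataclass(frozen=True)
class StockSpec:
    """A template stock: the fraction of intact molecules and, among the
    partial molecules, the fraction that are 5'-only."""

    name: str
    integrity_fraction: float
    partial_split_t1: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.integrity_fraction <= 1.0:
            raise ValueError("integrity_fraction must be in [0, 1]")
        if not 0.0 <= self.partial_split_t1 <= 1.0:
            raise ValueError("partial_split_t1 must be in [0, 1]")

    @property
    def species(self) -> SpeciesProbabilities:
        partial = 1.0 - self.integrity_fraction
        return SpeciesProbabilities(
            p_t1_only=partial * self.partial_split_t1,
            p_t2_only=partial * (1.0 - self.partial_split_t1),
        )


@dataclass(frozen=True)
class MixtureDesign:
    """Declarative description of a mixture/dilution study.

    One well is simulated per (mix fraction x dilution x replicate).
    ``mix_fractions`` are molecule fractions of the first (intact-like)
    stock; the expected integrity of a sample is the molecule-weighted
    average of the stocks' integrity fractions.
    """

    stocks: tuple[StockSpec, StockSpec]
    mix_fractions: tuple[float, ...]
    dilution_copies_per_ul: tuple[float, ...]
    droplets_per_well: int = 20000
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    replicates: int = 2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stocks) != 2:
            raise ValueError("exactly two stocks required")
        if any(not 0.0 <= f <= 1.0 for f in self.mix_fractions):
            raise ValueError("mix fractions must be in [0, 1]")
        if any(c <= 0 for c in self.dilution_copies_per_ul):
            raise ValueError("dilutions must be positive")
        if self.droplets_per_well <= 0 or self.droplet_volume_nl <= 0:
            raise ValueError("droplets_per_well and droplet_volume_nl must be positive")
        if self.replicates < 0:
            raise ValueError("replicates must be non-negative")

    def expected_integrity(self, intact_fraction: float) -> float:
        a, b = self.stocks
        return (
            intact_fraction * a.integrity_fraction
            + (1.0 - intact_fraction) * b.integrity_fraction
        )

    def sample_ids(self) -> list[str]:
        return [
            f"int{round(100 * self.expected_integrity(f)):03d}"
            for f in self.mix_fractions
        ]

    @property
    def n_wells(self) -> int:
        return len(self.mix_fractions) * len(self.dilution_copies_per_ul) * self.replicates


@dataclass(frozen=True)
class SimulatedWell:
    """One simulated well plus its ground truth."""

    sample: str
    replicate: int
    dilution_copies_per_ul: float
    species: SpeciesProbabilities
    lam: float
    counts: DropletCounts
    well_index: int
    master_seed: int


def species_from_mixture(
    stocks: Sequence[StockSpec], intact_fraction: float
) -> SpeciesProbabilities:
    """Molecule-weighted average of two stocks' species distributions."""
    if not 0.0 <= intact_fraction <= 1.0:
        raise ValueError("intact_fraction must be in [0, 1]")
    a, b = stocks
    wa, wb = intact_fraction, 1.0 - intact_fraction
    return SpeciesProbabilities(
        p_t1_only=wa * a.species.p_t1_only + wb * b.species.p_t1_only,
        p_t2_only=wa * a.species.p_t2_only + wb * b.species.p_t2_only,
    ).validate_generative()


def simulate_well(
    lam: float,
    species: SpeciesProbabilities,
    droplets: int,
    seed,
    mode: str = "category",
) -> DropletCounts:
    """Simulate the four category counts of one well.

    ``mode="category"`` draws a single multinomial over the exact
    category probabilities.  ``mode="per_molecule"`` draws a Poisson
    molecule count per droplet, assigns each molecule a species, and
    classifies the droplet by the union of targets present.  The two
    modes sample the same distribution; ``category`` is the fast default.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if droplets <= 0:
        raise ValueError("droplets must be positive")
    species.validate_generative()
    rng = np.random.default_rng(seed)
    if mode == "category":
        probs = expected_category_probabilities(lam, species)
        nd, n1, n2, nn = rng.multinomial(droplets, probs)
    elif mode == "per_molecule":
        ks = rng.poisson(lam, size=droplets)
        nn = int(np.sum(ks == 0))
        nd = n1 = n2 = 0
        p = (species.p_t1_only, species.p_t2_only, max(species.p_full, 0.0))
        for k in np.unique(ks):
            if k == 0:
                continue
            m = rng.multinomial(int(k), p, size=int(np.sum(ks == k)))
            has1 = (m[:, 0] + m[:, 2]) > 0
            has2 = (m[:, 1] + m[:, 2]) > 0
            nd += int(np.sum(has1 & has2))
            n1 += int(np.sum(has1 & ~has2))
            n2 += int(np.sum(~has1 & has2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DropletCounts(int(nd), int(n1), int(n2), int(nn))


def simulate_experiment(
    design: MixtureDesign, mode: str = "category"
) -> list[SimulatedWell]:
    """Simulate every well of a design.

    Wells are enumerated sample-major (sample, then dilution, then
    replicate); well i is seeded with ``SeedSequence([master_seed, i])``
    so any single well is reproducible in isolation.
    """
    wells: list[SimulatedWell] = []
    idx = 0
    for frac, sample_id in zip(design.mix_fractions, design.sample_ids()):
        species = species_from_mixture(design.stocks, frac)
        for dilution in design.dilution_copies_per_ul:
            lam = copies_per_ul_to_lambda(dilution, design.droplet_volume_nl)
            for rep in range(1, design.replicates + 1):
                seed = np.random.SeedSequence([design.master_seed, idx])
                counts = simulate_well(
                    lam, species, design.droplets_per_well, seed, mode
                )
                wells.append(
                    SimulatedWell(
                        sample=sample_id,
                        replicate=rep,
                        dilution_copies_per_ul=float(dilution),
                        species=species,
                        lam=lam,
                        counts=counts,
                        well_index=idx,
                        master_seed=design.master_seed,
                    )
                )
                idx += 1
    return wells


def paav_design(master_seed: int = 0, include_zero: bool = True) -> MixtureDesign:
    """Plasmid-study template: intact (100%) and double-digest (0%,
    symmetric partials) stocks mixed to expected integrities
    {0, 8, 18, 29, 43, 60, 82, 100}%, 12 dilutions over 8-5000 copies/uL,
    2 replicates, 20,000 droplets of 0.85 nL per well."""
    fracs = (0.0, 0.08, 0.18, 0.29, 0.43, 0.60, 0.82, 1.0)
    if not include_zero:
        fracs = fracs[1:]
    return MixtureDesign(
        stocks=(
            StockSpec("intact-digest", 1.0, 0.5),
            StockSpec("double-digest", 0.0, 0.5),
        ),
        mix_fractions=fracs,
        dilution_copies_per_ul=tuple(float(x) for x in PAAV_DILUTIONS),
        droplets_per_well=20000,
        replicates=2,
        master_seed=master_seed,
    )


def raav_design(master_seed: int = 0, gfp_partial_split_t1: float = 0.5) -> MixtureDesign:
    """rAAV-study template: a heterogeneous vector prep (84% intact)
    mixed with a 0%-intact prep (5'-only molecules) to expected
    integrities {0, 5, 10, 21, 42, 63, 84}%, 4 dilutions over 62-498
    copies/uL, 6 replicate experiments.

    Expected integrities depend only on the intact fractions, not on the
    partial split of the heterogeneous stock (a free design parameter).
    """
    return MixtureDesign(
        stocks=(
            StockSpec("AAV-intact-like", 0.84, gfp_partial_split_t1),
            StockSpec("AAV-fragmented-like", 0.0, 1.0),
        ),
        mix_fractions=(0.0, 5 / 84, 10 / 84, 0.25, 0.5, 0.75, 1.0),
        dilution_copies_per_ul=tuple(float(x) for x in RAAV_DILUTIONS),
        droplets_per_well=20000,
        replicates=6,
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# Plain-text design config
# ---------------------------------------------------------------------------

def design_from_yaml(path) -> MixtureDesign:
    """Load a :class:`MixtureDesign` from a YAML file (keys mirror the
    dataclass fields; stocks as a list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    stocks = tuple(
        StockSpec(
            name=s["name"],
            integrity_fraction=float(s["integrity_fraction"]),
            partial_split_t1=float(s.get("partial_split_t1", 0.5)),
        )
        for s in raw["stocks"]
    )
    return MixtureDesign(
        stocks=stocks,  # type: ignore[arg-type]
        mix_fractions=tuple(float(x) for x in raw["mix_fractions"]),
        dilution_copies_per_ul=tuple(float(x) for x in raw["dilution_copies_per_ul"]),
        droplets_per_well=int(raw.get("droplets_per_well", 20000)),
        droplet_volume_nl=float(raw.get("droplet_volume_nl", DEFAULT_DROPLET_VOLUME_NL)),
        replicates=int(raw.get("replicates", 2)),
        master_seed=int(raw.get("master_seed", 0)),
    )


def design_to_yaml(design: MixtureDesign, path) -> None:
    data = {
        "stocks": [
            {
                "name": s.name,
                "integrity_fraction": s.integrity_fraction,
                "partial_split_t1": s.partial_split_t1,
            }
            for s in design.stocks
        ],
        "mix_fractions": list(design.mix_fractions),
        "dilution_copies_per_ul": list(design.dilution_copies_per_ul),
        "droplets_per_well": design.droplets_per_well,
        "droplet_volume_nl": design.droplet_volume_nl,
        "replicates": design.replicates,
        "master_seed": design.master_seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
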