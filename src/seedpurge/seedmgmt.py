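"""Breeder-seed purge planning under a recessive-lethal allele and selfing.

The model: the population selfs; mutant homozygotes are albino and die
before reproducing; heterozygous carriers look wild-type. With carrier
(heterozygote) frequency h among parents, selfed bulk progeny contain a
fraction a = h/4 of albinos, so an observed albino incidence a implies
h = 4a and a mutant allele frequency q = h/2 = 2a — always above the
incidence itself whenever a > 0. Among the surviving (green) progeny the
carrier frequency next generation is h' = (h/2) / (1 - h/4): the allele
decays towards loss but is never eliminated by selection alone. Retaining
only plants genotyped homozygous wild-type (G) removes it in one step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PopulationState:
    """Carrier frequency and expected albino incidence at one generation."""

    generation: int
    h: float  # heterozygote frequency among (surviving) parents
    a: float  # expected albino incidence among their bulked selfed progeny

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("h must be in [0, 1]")


@dataclass(frozen=True)
class PurgePlan:
    """Partition of genotyped plants into retained (G only) and discarded."""

    retained: tuple[str, ...]
    discarded: tuple[str, ...]
    counts: dict[str, int]

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def carrier_estimate_from_incidence(a: float) -> tuple[float, float]:
    """(h, q) from albino incidence: h = 4a carriers, q = 2a allele frequency."""
    if not (0.0 <= a <= 0.25):
        raise ValueError("albino incidence above 0.25 is impossible under the model")
    return 4.0 * a, 2.0 * a


def progeny_albino_incidence(h: float) -> float:
    """Expected albino fraction in bulked selfed progeny of a population with
    carrier frequency h (each carrier family segregates 3 green : 1 albino)."""
    if not (0.0 <= h <= 1.0):
        raise ValueError("h must be in [0, 1]")
    return h / 4.0


def selfing_recurrence(h_t: float) -> float:
    """Next-generation carrier frequency among survivors: (h/2) / (1 - h/4)."""
    if not (0.0 <= h_t <= 1.0):
        raise ValueError("h must be in [0, 1]")
    return (h_t / 2.0) / (1.0 - h_t / 4.0)


def project_generations(h0: float, generations: int) -> pd.DataFrame:
    """Carrier frequency and expected incidence over selfing generations."""
    states = [PopulationState(0, h0, progeny_albino_incidence(h0))]
    h = h0
    for g in range(1, generations + 1):
        h = selfing_recurrence(h)
        states.append(PopulationState(g, h, progeny_albino_incidence(h)))
    return pd.DataFrame(
        {
            "generation": [s.generation for s in states],
            "h": [s.h for s in states],
            "expected_incidence": [s.a for s in states],
        }
    )


def purge(genotypes: Iterable[tuple[str, str]]) -> PurgePlan:
    """Retain exactly the homozygous wild-type (G) plants.

    ``genotypes`` is an iterable of (plant_id, genotype) with genotype in
    {G, H, A} (anything else counts as ambiguous and is discarded).
    """
    retained, discarded = [], []
    counts: dict[str, int] = {}
    for plant_id, g in genotypes:
        counts[g] = counts.get(g, 0) + 1
        (retained if g == "G" else discarded).append(plant_id)
    return PurgePlan(tuple(retained), tuple(discarded), counts)


def simulate_progeny_albinos(
    h: float, n_seeds: int, rng: Optional[np.random.Generator] = None
) -> int:
    """Number of albino seedlings among n_seeds bulked selfed progeny."""
    rng = rng or np.random.default_rng()
    p = progeny_albino_incidence(h)
    return int(rng.binomial(n_seeds, p)) if p > 0 else 0
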