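"""Bootstrap pseudo-study generation.

The survey treats the full cohort as the gold standard and generates
small "studies" by sampling participants with replacement.  A
counter-based seed hierarchy (master seed -> per-(size, replicate) child
seed) makes any single pseudo-study reproducible in isolation.  For the
prediction level, a fixed holdout test set is split off once and shared
by every study so their scores are comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "StudySample",
    "split_holdout",
    "draw_bootstrap_studies",
    "child_rng",
    "DEFAULT_SIZES",
    "DEFAULT_N_BOOT",
]

DEFAULT_SIZES = (20, 40, 60, 80, 100)
DEFAULT_N_BOOT = 100


@dataclass
class StudyDesign:
    """Plan for a bootstrap survey: who, how many, how often."""

    population_ids: np.ndarray
    sizes: tuple = DEFAULT_SIZES
    n_boot: int = DEFAULT_N_BOOT
    seed: int = 0
    holdout_fraction: float = 0.2

    def __post_init__(self):
        self.population_ids = np.asarray(self.population_ids)
        self.sizes = tuple(int(s) for s in self.sizes)
        if any(s < 2 for s in self.sizes):
            raise ValueError("every study size must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")

    def to_json(self, path) -> None:
        payload = {
            "population_ids": self.population_ids.tolist(),
            "sizes": list(self.sizes),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "holdout_fraction": self.holdout_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StudyDesign":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            population_ids=np.asarray(payload["population_ids"]),
            sizes=tuple(payload["sizes"]),
            n_boot=payload["n_boot"],
            seed=payload["seed"],
            holdout_fraction=payload["holdout_fraction"],
        )


@dataclass
class StudySample:
    """One pseudo-study: a with-replacement draw from the population."""

    size: int
    replicate_index: int
    member_ids: np.ndarray

    def __post_init__(self):
        self.member_ids = np.asarray(self.member_ids)
        if len(self.member_ids) != self.size:
            raise ValueError("member count must equal the study size")


def child_rng(master_seed: int, size: int, replicate: int) -> np.random.Generator:
    """Deterministic per-(size, replicate) generator under a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), int(size), int(replicate))))


def split_holdout(population_ids, holdout_fraction: float, seed: int):
    """Split the population into disjoint, exhaustive train/test id sets.

    The same seeded split (hence the same test set) is reused for every
    study size and replicate downstream.
    """
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError("holdout_fraction must lie in (0, 1)")
    population_ids = np.asarray(population_ids)
    n = len(population_ids)
    n_test = int(round(n * holdout_fraction))
    if n_test < 1 or n_test >= n:
        raise ValueError("population too small for the requested holdout split")
    perm = np.random.default_rng(seed).permutation(n)
    test_ids = population_ids[np.sort(perm[:n_test])]
    train_ids = population_ids[np.sort(perm[n_test:])]
    return train_ids, test_ids


def draw_bootstrap_studies(design: StudyDesign) -> list:
    """Draw ``n_boot`` with-replacement samples at every study size.

    Each (size, replicate) pair gets its own child generator, so any
    study can be re-drawn in isolation from the master seed.
    """
    population = design.population_ids
    if len(population) == 0:
        raise ValueError("empty population")
    samples = []
    for size in design.sizes:
        for rep in range(design.n_boot):
            rng = child_rng(design.seed, size, rep)
            members = population[rng.integers(0, len(population), size=size)]
            samples.append(StudySample(size=size, replicate_index=rep,
                                       member_ids=members))
    return samples


def samples_to_tsv(samples, path) -> None:
    rows = [
        {"size": s.size, "replicate": s.replicate_index, "member_id": m}
        for s in samples
        for m in s.member_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
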