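"""Seed-gene selection: per-contrast significance filtering and Venn intersection.

A dataset contributes one significance list per contrast (each tissue plus a
pooled "diagnosis" contrast); the dataset's seed set is the intersection of
all its contrast lists, and seed sets are unioned across datasets.  A second,
stricter cutoff can then be re-applied, keeping genes significant at the
tighter level in every contrast of at least one dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Selected seed symbols with the provenance of each contributing contrast."""

    symbols: frozenset[str]
    provenance: list[tuple[str, str, float]] = field(default_factory=list)  # (dataset, contrast, alpha)
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.symbols)


def select_sdegs(de: pd.DataFrame, alpha: float) -> set[str]:
    """Genes with p strictly below alpha in a differential-expression table."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    mask = de["p"] < alpha
    return set(de.index[mask])


def venn_overlap(sets: Sequence[set[str]]) -> tuple[set[str], dict[str, int]]:
    """Core intersection plus the size of every Venn region for 2-4 sets.

    Region keys are membership bitstrings, e.g. ``"1011"`` = in sets 1, 3, 4
    but not 2.  Region sizes sum to the size of the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"venn_overlap supports 2-4 sets, got {len(sets)}")
    sets = [set(s) for s in sets]
    universe = set().union(*sets)
    regions: dict[str, int] = {
        "".join(bits): 0
        for bits in product("01", repeat=len(sets))
        if "1" in bits
    }
    for sym in universe:
        key = "".join("1" if sym in s else "0" for s in sets)
        regions[key] += 1
    core = set.intersection(*sets)
    return core, regions


def combine_seed_sets(sets: Sequence[SeedSet]) -> SeedSet:
    """Union of seed sets with duplicates removed; provenance concatenated."""
    if not sets:
        raise ValueError("need at least one seed set")
    symbols = frozenset().union(*(s.symbols for s in sets))
    provenance = [p for s in sets for p in s.provenance]
    alpha = max(s.alpha for s in sets)
    return SeedSet(symbols, provenance, alpha)


def dataset_seed_set(
    dataset: str,
    contrast_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> SeedSet:
    """Intersection core of a dataset's per-contrast significance lists."""
    if not contrast_tables:
        raise ValueError("no contrasts supplied")
    per_contrast = {c: select_sdegs(de, alpha) for c, de in contrast_tables.items()}
    core = set.intersection(*per_contrast.values())
    for c, s in per_contrast.items():
        logger.info("%s/%s: %d SDEGs at alpha=%g", dataset, c, len(s), alpha)
    logger.info("%s: %d seed genes in the %d-way intersection", dataset, len(core), len(per_contrast))
    return SeedSet(
        frozenset(core),
        [(dataset, c, alpha) for c in sorted(contrast_tables)],
        alpha,
    )


def select_seed_genes(
    datasets: Mapping[str, Mapping[str, pd.DataFrame]],
    alpha: float = 0.05,
    tighten_alpha: float | None = 0.01,
) -> SeedSet:
    """Full seed-selection procedure across datasets.

    1. per dataset: intersect the contrast lists at ``alpha``;
    2. union the dataset cores;
    3. if ``tighten_alpha`` is given, keep only genes significant at that
       level in *every* contrast of at least one dataset.
    """
    cores = [dataset_seed_set(name, tabs, alpha) for name, tabs in datasets.items()]
    combined = combine_seed_sets(cores)
    if tighten_alpha is None:
        return combined
    tight = set()
    for name, tabs in datasets.items():
        tight |= set.intersection(*(select_sdegs(de, tighten_alpha) for de in tabs.values()))
    final = frozenset(combined.symbols & tight)
    logger.info(
        "seed tightening: %d at alpha=%g -> %d at alpha=%g",
        len(combined.symbols), alpha, len(final), tighten_alpha,
    )
    provenance = combined.provenance + [
        (name, c, tighten_alpha) for name, tabs in datasets.items() for c in sorted(tabs)
    ]
    return SeedSet(final, provenance, tighten_alpha)


def write_seeds(seeds: SeedSet, path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(seeds.symbols):
            fh.write(sym + "\n")


def read_seeds(path) -> SeedSet:
    """One symbol per line."""
    with open(path) as fh:
        symbols = frozenset(
            line.strip().upper() for line in fh if line.strip()
        )
    return SeedSet(symbols, [("file", str(path), float("nan"))])
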