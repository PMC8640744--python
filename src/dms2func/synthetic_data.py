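"""Seeded generators of DMS-like fixtures.

A synthetic landscape assigns each sequence a fitness of the form
``g(sum of additive effects + sum of pairwise epistatic terms) + noise``.
Additive effects are per (position, letter) with wild-type letters fixed at
zero; an epistatic pair (i, j, eps) contributes eps whenever both positions
are mutated.  Noise is a deterministic function of (seed, sequence) so that
fitness is a pure function of the sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from dms2func.alphabet import AA20, AA20_INDEX
from dms2func.sequence_data import (
    DMSDataset,
    Substitution,
    Variant,
    WildType,
    apply_variant,
)

NONLINEARITIES = {
    "identity": lambda t: t,
    "sigmoid": lambda t: 1.0 / (1.0 + np.exp(-t)),
}


@dataclass
class LandscapeSpec:
    """Defaults are desk-scale but rich enough that nonlinear models beat
    linear regression: with L=10 and 5 planted pairs, a few-thousand-variant
    sample covers every pair with enough examples to learn from."""

    L: int = 10
    n_epistatic_pairs: int = 5
    epistasis_magnitude: float = 2.0
    additive_sd: float = 1.0
    noise_sd: float = 0.05
    nonlinearity: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nonlinearity not in NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass
class Landscape:
    """A realized fitness landscape: wild type, additive table, planted pairs."""

    spec: LandscapeSpec
    wild_type: WildType
    additive: np.ndarray  # (L, 20); wild-type letters have effect 0
    pairs: list[tuple[int, int, float]]  # 0-based position pairs + magnitude

    def fitness(self, seq: str) -> float:
        return landscape_fitness(self, seq)


def build_landscape(spec: LandscapeSpec) -> Landscape:
    """Draw a wild type, additive effects, and epistatic pairs from the seed."""
    rng = np.random.default_rng(spec.seed)
    wt_letters = rng.choice(list(AA20), size=spec.L)
    wt = WildType(id=f"synthetic_L{spec.L}_seed{spec.seed}", sequence="".join(wt_letters))
    additive = rng.normal(0.0, spec.additive_sd, size=(spec.L, 20))
    for i, aa in enumerate(wt.sequence):
        additive[i, AA20_INDEX[aa]] = 0.0
    n_pairs = min(spec.n_epistatic_pairs, spec.L * (spec.L - 1) // 2)
    all_pairs = [(i, j) for i in range(spec.L) for j in range(i + 1, spec.L)]
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_pairs)
    pairs = [
        (all_pairs[k][0], all_pairs[k][1], float(s * spec.epistasis_magnitude))
        for k, s in zip(chosen, signs)
    ]
    return Landscape(spec, wt, additive, pairs)


def _sequence_noise(seed: int, seq: str, sd: float) -> float:
    if sd == 0:
        return 0.0
    h = zlib.crc32(f"{seed}:{seq}".encode())
    return float(np.random.default_rng(h).normal(0.0, sd))


def landscape_fitness(landscape: Landscape, seq: str) -> float:
    """Deterministic fitness of a raw sequence under the landscape."""
    spec = landscape.spec
    wt_seq = landscape.wild_type.sequence
    if len(seq) != spec.L:
        raise ValueError("sequence length does not match landscape")
    total = 0.0
    mutated = np.zeros(spec.L, dtype=bool)
    for p, (a, w) in enumerate(zip(seq, wt_seq)):
        if a != w:
            mutated[p] = True
            total += landscape.additive[p, AA20_INDEX[a]]
    for i, j, eps in landscape.pairs:
        if mutated[i] and mutated[j]:
            total += eps
    g = NONLINEARITIES[spec.nonlinearity]
    return float(g(total)) + _sequence_noise(spec.seed, seq, spec.noise_sd)


def sample_dataset(
    landscape: Landscape,
    n_variants: int = 1500,
    max_mutations: int = 2,
    seed: int = 0,
    allow_full_enumeration: bool = False,
) -> DMSDataset:
    """Sample unique scored variants with 1..max_mutations substitutions.

    Raises if the requested count exceeds the variant space unless
    ``allow_full_enumeration`` is set, in which case all variants with a
    single mutation count budget are enumerated (only practical for tiny L).
    """
    wt = landscape.wild_type
    L = landscape.spec.L
    space = 0
    from math import comb

    for k in range(1, max_mutations + 1):
        space += comb(L, k) * 19**k
    if n_variants > space:
        if not allow_full_enumeration:
            raise ValueError(
                f"requested {n_variants} variants but only {space} exist "
                f"with <= {max_mutations} mutations"
            )
        n_variants = space
    rng = np.random.default_rng(seed)
    seen: set[frozenset[Substitution]] = set()
    variants: list[Variant] = []
    while len(variants) < n_variants:
        k = int(rng.integers(1, max_mutations + 1))
        positions = rng.choice(L, size=k, replace=False)
        subs = []
        for p in positions:
            wt_aa = wt.sequence[p]
            options = [a for a in AA20 if a != wt_aa]
            mut = options[int(rng.integers(len(options)))]
            subs.append(Substitution(int(p) + 1, wt_aa, mut))
        key = frozenset(subs)
        if key in seen:
            continue
        seen.add(key)
        v = Variant(key)
        variants.append(v.with_score(landscape.fitness(apply_variant(v, wt))))
    return DMSDataset(wt, variants)


@dataclass
class SimulatedCounts:
    """Raw input/selected counts paired with the variants that produced them."""

    variants: list[str]  # canonical variant strings, "" = wild type
    count_input: np.ndarray
    count_selected: np.ndarray


def simulate_read_counts(
    ds: DMSDataset,
    total_reads: int = 100_000,
    selection_strength: float = 1.0,
    seed: int = 0,
    wt_score: Optional[float] = None,
) -> SimulatedCounts:
    """Simulate a screening experiment from a scored dataset.

    Input counts are multinomial over a seeded Dirichlet abundance
    distribution; selected-set probabilities are proportional to the input
    frequency times a logistic survival probability of the score.  The wild
    type (empty variant string) is always included.  Both sets contain
    exactly ``total_reads`` reads.
    """
    rng = np.random.default_rng(seed)
    names = [""] + [v.to_string() for v in ds.variants if v.n_mutations > 0]
    if wt_score is None:
        wt_score = 0.0
    scores = np.array(
        [wt_score] + [v.score for v in ds.variants if v.n_mutations > 0], dtype=float
    )
    abundance = rng.dirichlet(np.ones(len(names)) * 5.0)
    count_input = rng.multinomial(total_reads, abundance)
    survival = 1.0 / (1.0 + np.exp(-selection_strength * scores))
    p_sel = abundance * survival
    p_sel = p_sel / p_sel.sum()
    count_selected = rng.multinomial(total_reads, p_sel)
    return SimulatedCounts(names, count_input, count_selected)


def default_landscape(seed: int = 0) -> Landscape:
    """The package's default desk-scale fixture landscape."""
    return build_landscape(LandscapeSpec(seed=seed))
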