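"""Ensemble-guided design of sequences at fixed Hamming distance n.

Random-restart hill climbing over the set of sequences exactly n mutations
from the wild type, maximizing the minimum predicted score over an ensemble
of trained models.  The move set exchanges one current mutation for another:
delete one substitution, then add any single substitution at a currently
unmutated position (including the vacated one, with a different letter),
which keeps the distance fixed at n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dms2func.alphabet import AA20
from dms2func.encoding import PropertyProjection, encode_batch
from dms2func.models import Model
from dms2func.sequence_data import Substitution, Variant, WildType


@dataclass
class DesignConfig:
    n: int
    ensemble: list[Model]
    proj: PropertyProjection
    restarts: int = 10
    seed: int = 0
    alphabet: str = AA20  # stop codon deliberately excluded

    def __post_init__(self) -> None:
        if not self.ensemble:
            raise ValueError("ensemble must contain at least one model")
        if self.n < 1:
            raise ValueError("n must be at least 1")


@dataclass
class DesignResult:
    sequence: str
    variant: Variant
    objective: float
    per_model: list[float]
    trajectories: list[list[float]] = field(repr=False)


def ensemble_min_objective(
    variants: list[Variant],
    wt: WildType,
    ensemble: list[Model],
    proj: PropertyProjection,
) -> np.ndarray:
    """min over models of the predicted score, for a batch of variants."""
    X = encode_batch(variants, wt, proj)
    preds = np.stack([m.predict(X) for m in ensemble])
    return preds.min(axis=0)


def random_n_mutant(
    wt: WildType, n: int, rng: np.random.Generator, alphabet: str = AA20
) -> Variant:
    """A uniformly random variant with exactly n mutated positions."""
    if n > len(wt):
        raise ValueError("n exceeds sequence length")
    if n == 0:
        return Variant()
    positions = rng.choice(len(wt), size=n, replace=False)
    subs = []
    for p in positions:
        wt_aa = wt.sequence[p]
        options = [a for a in alphabet if a != wt_aa]
        subs.append(Substitution(int(p) + 1, wt_aa, options[int(rng.integers(len(options)))]))
    return Variant(frozenset(subs))


def neighborhood(v: Variant, wt: WildType, alphabet: str = AA20) -> list[Variant]:
    """All distinct variants reachable by exchanging one mutation.

    Every neighbor is at Hamming distance exactly ``v.n_mutations`` from the
    wild type and differs from ``v``.  Returned in canonical (sorted variant
    string) order for deterministic tie-breaking.
    """
    neighbors: dict[str, Variant] = {}
    subs = v.sorted_substitutions()
    for removed in subs:
        remaining = [s for s in subs if s is not removed]
        occupied = {s.position for s in remaining}
        for pos in range(1, len(wt) + 1):
            if pos in occupied:
                continue
            wt_aa = wt.sequence[pos - 1]
            for letter in alphabet:
                if letter == wt_aa:
                    continue
                cand = Substitution(pos, wt_aa, letter)
                if cand == removed:
                    continue
                nb = Variant(frozenset(remaining + [cand]))
                neighbors[nb.to_string()] = nb
    return [neighbors[k] for k in sorted(neighbors)]


def hill_climb(cfg: DesignConfig, wt: WildType) -> DesignResult:
    """Random-restart hill climbing; returns the best local optimum found.

    Each restart starts from a random n-mutant and greedily moves to the best
    neighbor while it strictly improves the ensemble-min objective; ties in
    the argmax are broken by canonical variant order.  The result is the best
    final state over all restarts.
    """
    rng = np.random.default_rng(cfg.seed)
    best: Variant | None = None
    best_obj = -np.inf
    trajectories: list[list[float]] = []
    for _ in range(cfg.restarts):
        current = random_n_mutant(wt, cfg.n, rng, cfg.alphabet)
        cur_obj = float(
            ensemble_min_objective([current], wt, cfg.ensemble, cfg.proj)[0]
        )
        traj = [cur_obj]
        while True:
            nbrs = neighborhood(current, wt, cfg.alphabet)
            objs = ensemble_min_objective(nbrs, wt, cfg.ensemble, cfg.proj)
            k = int(np.argmax(objs))  # first max = lowest canonical order
            if objs[k] <= cur_obj:
                break
            current, cur_obj = nbrs[k], float(objs[k])
            traj.append(cur_obj)
        trajectories.append(traj)
        if cur_obj > best_obj:
            best, best_obj = current, cur_obj
    assert best is not None
    from dms2func.sequence_data import apply_variant

    X = encode_batch([best], wt, cfg.proj)
    per_model = [float(m.predict(X)[0]) for m in cfg.ensemble]
    return DesignResult(
        sequence=apply_variant(best, wt),
        variant=best,
        objective=best_obj,
        per_model=per_model,
        trajectories=trajectories,
    )
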