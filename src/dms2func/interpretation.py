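"""Model interpretation: integrated gradients, latent spaces, mutation scans.

Integrated gradients distribute the prediction difference f(x) - f(baseline)
over input features by integrating the gradient along the straight path from
the baseline (here the wild-type encoding) to the input.  The path integral
is approximated with a midpoint Riemann sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dms2func.alphabet import ALPHABET21
from dms2func.encoding import PropertyProjection, encode_batch, encode_variant
from dms2func.models import Model
from dms2func.sequence_data import Variant, WildType


def integrated_gradients(
    model: Model,
    x: np.ndarray,
    baseline: np.ndarray,
    steps: int = 100,
) -> np.ndarray:
    """Per-feature attributions for a single encoded variant (L x F array).

    attribution = (x - baseline) * mean of gradients at ``steps`` midpoints
    of the straight path from baseline to x.  For a linear model this equals
    w * (x - baseline) exactly, for any number of steps.
    """
    if x.shape != baseline.shape:
        raise ValueError("input and baseline must have the same shape")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    delta = x - baseline
    alphas = (np.arange(steps) + 0.5) / steps
    path = baseline[None] + alphas[:, None, None] * delta[None]
    grads = model.input_gradients(path)
    return delta * grads.mean(axis=0)


def position_attributions(attr: np.ndarray) -> np.ndarray:
    """Sum attributions over all features at each sequence position."""
    return attr.sum(axis=1)


def dataset_position_attributions(
    model: Model,
    variants: list[Variant],
    wt: WildType,
    proj: PropertyProjection,
    steps: int = 100,
) -> np.ndarray:
    """Per-position attributions summed over a set of variants.

    The wild-type encoding is the baseline for every variant, so this equals
    the sum of the individual per-variant position attribution vectors.
    """
    baseline = encode_variant(Variant(), wt, proj)
    total = np.zeros(len(wt))
    for v in variants:
        x = encode_variant(v, wt, proj)
        total += position_attributions(
            integrated_gradients(model, x, baseline, steps=steps)
        )
    return total


def latent_representations(model: Model, X: np.ndarray) -> np.ndarray:
    """Activations of the last internal layer before the output node.

    For the default convolutional architectures this is the 100-unit dense
    layer; dropout is disabled.
    """
    return model.latent(X)


@dataclass
class SingleMutantMatrix:
    """Predicted scores for every (position, letter) single mutant."""

    predictions: np.ndarray  # (L, len(alphabet))
    alphabet: str
    wild_type: WildType

    def wild_type_mask(self) -> np.ndarray:
        mask = np.zeros_like(self.predictions, dtype=bool)
        for p, aa in enumerate(self.wild_type.sequence):
            j = self.alphabet.find(aa)
            if j >= 0:
                mask[p, j] = True
        return mask

    @property
    def n_cells(self) -> int:
        return int(self.predictions.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.predictions,
            index=pd.RangeIndex(1, len(self.wild_type) + 1, name="position"),
            columns=list(self.alphabet),
        )


def single_mutant_matrix(
    model: Model,
    wt: WildType,
    proj: PropertyProjection,
    alphabet: str = ALPHABET21,
) -> SingleMutantMatrix:
    """Predict every single mutant over ``alphabet``; complete, no gaps.

    Cells at the wild-type letter hold the wild-type prediction.  Mutations
    never observed in training still get predictions — the matrix is defined
    by the model, not the data.
    """
    from dms2func.encoding import enumerate_single_mutants

    variants = enumerate_single_mutants(wt, alphabet)
    X = encode_batch(variants, wt, proj)
    preds = model.predict(X).reshape(len(wt), len(alphabet))
    return SingleMutantMatrix(preds, alphabet, wt)
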