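"""Per-residue feature encoding of protein variants.

Each residue is featurized with a length-21 one-hot vector (20 amino acids +
stop) concatenated with a low-dimensional PCA projection of per-amino-acid
physicochemical properties.  A full variant is the L x (21 + d) stack of its
residue feature vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from dms2func.alphabet import AA20, ALPHABET21, ALPHABET21_INDEX, STOP
from dms2func.sequence_data import Variant, WildType, apply_variant, validate_variant

DEFAULT_N_COMPONENTS = 19


def load_property_matrix(path: str | Path | None = None) -> pd.DataFrame:
    """Load an amino-acid property matrix from CSV.

    Rows are the 20 standard amino acids (column ``aa``), remaining columns
    are numeric properties.  Without a path, the packaged fixture table is
    loaded.
    """
    if path is None:
        with resources.files("dms2func").joinpath("data/aa_properties.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    if "aa" not in df.columns:
        raise ValueError("property matrix must have an 'aa' column")
    df = df.set_index("aa")
    if sorted(df.index) != sorted(AA20):
        raise ValueError("property matrix must have exactly the 20 standard amino acids")
    df = df.loc[list(AA20)]
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("property matrix contains non-finite entries")
    return df


@dataclass
class PropertyProjection:
    """Fitted PCA projection of amino-acid properties.

    ``vectors`` has one row per letter of the 21-letter alphabet (stop maps
    to the zero vector), d columns.
    """

    vectors: np.ndarray  # (21, d)
    mean: np.ndarray  # (P,)
    scale: np.ndarray  # (P,)
    explained_variance_ratio: np.ndarray  # (d,)
    property_names: list[str]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def vector(self, letter: str) -> np.ndarray:
        return self.vectors[ALPHABET21_INDEX[letter]]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.vectors,
            index=list(ALPHABET21),
            columns=[f"pc_{i+1}" for i in range(self.d)],
        )
        df.index.name = "aa"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PropertyProjection":
        df = pd.read_csv(path).set_index("aa")
        vectors = df.loc[list(ALPHABET21)].to_numpy(dtype=float)
        d = vectors.shape[1]
        return cls(
            vectors=vectors,
            mean=np.zeros(0),
            scale=np.zeros(0),
            explained_variance_ratio=np.full(d, np.nan),
            property_names=[],
        )


def fit_property_projection(
    props: pd.DataFrame, d: int = DEFAULT_N_COMPONENTS
) -> PropertyProjection:
    """PCA-project the standardized 20 x P property matrix down to d scores.

    Columns are standardized to zero mean / unit variance; zero-variance
    columns are dropped with a warning.  Because a mean-centered matrix with
    20 rows has rank at most 19, d = 19 always captures 100% of the variance.
    Component signs are fixed by making the largest-magnitude loading of each
    component positive.
    """
    X = props.to_numpy(dtype=float)
    names = list(props.columns)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    keep = scale > 0
    if not keep.any():
        raise ValueError("property matrix has zero total variance")
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance property columns: {dropped}")
        X, mean, scale = X[:, keep], mean[keep], scale[keep]
        names = [n for n, k in zip(names, keep) if k]
    if not 1 <= d <= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"d={d} out of range for a {X.shape[0]}x{X.shape[1]} property matrix"
        )
    Z = (X - mean) / scale
    # SVD of the centered, standardized matrix: scores are U * S.
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :d] * S[:d]
    loadings = Vt[:d]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(d):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    total_var = (S**2).sum()
    evr = S[:d] ** 2 / total_var
    vectors = np.vstack([scores, np.zeros((1, d))])  # stop codon -> zeros
    return PropertyProjection(
        vectors=vectors,
        mean=mean,
        scale=scale,
        explained_variance_ratio=evr,
        property_names=names,
    )


def _letter_features(proj: PropertyProjection) -> np.ndarray:
    """(21, 21 + d) table: one-hot block then projected property block."""
    eye = np.eye(len(ALPHABET21))
    return np.hstack([eye, proj.vectors])


def encode_sequence(seq: str, proj: PropertyProjection) -> np.ndarray:
    """Encode a raw sequence string as an L x (21 + d) matrix."""
    table = _letter_features(proj)
    try:
        idx = [ALPHABET21_INDEX[c] for c in seq]
    except KeyError as exc:
        raise ValueError(f"unknown letter {exc.args[0]!r} in sequence") from exc
    return table[idx]


def encode_variant(v: Variant, wt: WildType, proj: PropertyProjection) -> np.ndarray:
    """Encode one variant; rows at unmutated positions equal the wild-type rows."""
    validate_variant(v, wt)
    return encode_sequence(apply_variant(v, wt), proj)


def encode_batch(
    variants: list[Variant], wt: WildType, proj: PropertyProjection
) -> np.ndarray:
    """Encode many variants into an (N, L, 21 + d) array.

    Starts from the wild-type encoding and rewrites only mutated rows, which
    is much faster than per-variant sequence encoding for large batches.
    """
    table = _letter_features(proj)
    base = encode_sequence(wt.sequence, proj)
    out = np.repeat(base[None, :, :], len(variants), axis=0)
    for i, v in enumerate(variants):
        for s in v.substitutions:
            out[i, s.position - 1] = table[ALPHABET21_INDEX[s.mut_aa]]
    return out


def encode_sequences(
    seqs: list[str], proj: PropertyProjection, wt: WildType | None = None
) -> np.ndarray:
    """Encode raw sequences; with a wild type given, uses the fast row-rewrite path."""
    if wt is None:
        return np.stack([encode_sequence(s, proj) for s in seqs])
    table = _letter_features(proj)
    base = encode_sequence(wt.sequence, proj)
    out = np.repeat(base[None, :, :], len(seqs), axis=0)
    wt_seq = wt.sequence
    for i, s in enumerate(seqs):
        if len(s) != len(wt_seq):
            raise ValueError("sequence length differs from wild type")
        for p, (a, b) in enumerate(zip(s, wt_seq)):
            if a != b:
                out[i, p] = table[ALPHABET21_INDEX[a]]
    return out


def enumerate_single_mutants(wt: WildType, alphabet: str = AA20) -> list[Variant]:
    """All (position, letter) variants over an alphabet, position-major order.

    Cells where the letter equals the wild-type letter are represented by the
    wild-type variant (zero substitutions), so the list always has
    L x len(alphabet) entries.
    """
    from dms2func.sequence_data import Substitution

    out = []
    for pos in range(1, len(wt) + 1):
        wt_aa = wt.sequence[pos - 1]
        for letter in alphabet:
            if letter == wt_aa:
                out.append(Variant(frozenset()))
            else:
                out.append(Variant(frozenset([Substitution(pos, wt_aa, letter)])))
    return out
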