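"""Library-size vs. sequencing-read trade-off simulation.

Functional scores are wild-type-normalized natural-log enrichment ratios with
+0.5 pseudocounts computed from paired input (pre-screening) and selected
(post-screening) read counts.  ``resample_dataset`` draws a reduced library
and multinomial read samples from a base count table; ``run_grid`` trains a
model per resampled dataset and reports the mean test Pearson per grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from dms2func.encoding import PropertyProjection, encode_batch
from dms2func.experiments import TrainingConfig, evaluate, train
from dms2func.models import Model
from dms2func.sequence_data import DMSDataset, Variant, WildType, parse_variant

WT_LABEL = ""  # canonical variant string of the wild type


@dataclass
class ReadCountTable:
    """Per-variant input/selected read counts (nonnegative ints, unique variants)."""

    df: pd.DataFrame  # columns: variant, count_input, count_selected

    def __post_init__(self) -> None:
        required = {"variant", "count_input", "count_selected"}
        if not required <= set(self.df.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        if self.df["variant"].duplicated().any():
            raise ValueError("duplicate variants in count table")
        counts = self.df[["count_input", "count_selected"]].to_numpy()
        if (counts < 0).any():
            raise ValueError("negative read counts")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variants(self) -> list[str]:
        return self.df["variant"].tolist()

    @classmethod
    def from_arrays(cls, variants, count_input, count_selected) -> "ReadCountTable":
        return cls(
            pd.DataFrame(
                {
                    "variant": list(variants),
                    "count_input": np.asarray(count_input, dtype=int),
                    "count_selected": np.asarray(count_selected, dtype=int),
                }
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReadCountTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"variant": str})
        df["count_input"] = df["count_input"].astype(int)
        df["count_selected"] = df["count_selected"].astype(int)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def filter_counts(t: ReadCountTable, min_reads: int) -> ReadCountTable:
    """Keep variants with at least ``min_reads`` in BOTH input and selected sets."""
    m = (t.df["count_input"] >= min_reads) & (t.df["count_selected"] >= min_reads)
    return ReadCountTable(t.df[m].reset_index(drop=True))


def enrichment_score(t: ReadCountTable, wt_id: str = WT_LABEL) -> pd.Series:
    """Wild-type-normalized log enrichment ratio with +0.5 pseudocounts.

    score(v) = ln((sel_v + 0.5) / (inp_v + 0.5)) - ln((sel_wt + 0.5) / (inp_wt + 0.5))
    """
    wt_rows = t.df[t.df["variant"] == wt_id]
    if len(wt_rows) != 1:
        raise ValueError(f"wild type {wt_id!r} missing from count table")
    wt = wt_rows.iloc[0]
    wt_ratio = np.log((wt["count_selected"] + 0.5) / (wt["count_input"] + 0.5))
    ratios = np.log(
        (t.df["count_selected"] + 0.5) / (t.df["count_input"] + 0.5)
    )
    return pd.Series(
        (ratios - wt_ratio).to_numpy(), index=t.df["variant"], name="score"
    )


def resample_dataset(
    base: ReadCountTable,
    library_size: int,
    total_reads: int,
    seed: int = 0,
    include_wt: bool = True,
) -> ReadCountTable:
    """Uniformly sample a library and multinomially resample its reads.

    The library is a uniform without-replacement sample of ``library_size``
    base variants (the wild type is force-included so scores stay
    normalizable).  Reads are split between input and selected sets according
    to the base dataset's read fractions, then each set's reads are drawn from
    a multinomial proportional to the base counts restricted to the library.
    The sampled counts sum exactly to ``total_reads``.
    """
    if library_size < 1:
        raise ValueError("library must contain at least one variant")
    if library_size > len(base):
        raise ValueError(
            f"library size {library_size} exceeds base table of {len(base)}"
        )
    if total_reads < 1:
        raise ValueError("total_reads must be at least 1")
    rng = np.random.default_rng(seed)
    names = np.array(base.variants)
    chosen = rng.choice(len(base), size=library_size, replace=False)
    if include_wt and WT_LABEL in names:
        wt_idx = int(np.flatnonzero(names == WT_LABEL)[0])
        if wt_idx not in chosen:
            chosen[0] = wt_idx
    chosen = np.sort(chosen)

    inp = base.df["count_input"].to_numpy(dtype=float)
    sel = base.df["count_selected"].to_numpy(dtype=float)
    frac_input = inp.sum() / (inp.sum() + sel.sum())
    reads_input = int(round(total_reads * frac_input))
    reads_selected = total_reads - reads_input

    def draw(weights: np.ndarray, n: int) -> np.ndarray:
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        return rng.multinomial(n, weights / weights.sum())

    new_input = draw(inp[chosen], reads_input)
    new_selected = draw(sel[chosen], reads_selected)
    return ReadCountTable.from_arrays(names[chosen], new_input, new_selected)


@dataclass
class ResampleGrid:
    library_sizes: Sequence[int]
    total_reads: Sequence[int]
    replicates: int = 5
    seed: int = 0
    min_variants: int = 25

    @property
    def n_cells(self) -> int:
        return len(self.library_sizes) * len(self.total_reads)


def generate_grid_datasets(
    base: ReadCountTable, grid: ResampleGrid
) -> Iterator[tuple[int, int, int, ReadCountTable]]:
    """Yield (library_size, total_reads, replicate, table) over the full grid.

    ``grid.n_cells * grid.replicates`` datasets are produced in total.
    """
    counter = 0
    for lib in grid.library_sizes:
        for reads in grid.total_reads:
            for rep in range(grid.replicates):
                table = resample_dataset(
                    base, lib, reads, seed=grid.seed + counter
                )
                counter += 1
                yield lib, reads, rep, table


def sequenced_subset(t: ReadCountTable, keep_wt: bool = True) -> ReadCountTable:
    """Variants that received at least one read in either set.

    The wild type is kept regardless (scores are normalized against it), even
    in the unlucky draw where it received no reads.
    """
    m = (t.df["count_input"] + t.df["count_selected"]) > 0
    if keep_wt:
        m = m | (t.df["variant"] == WT_LABEL)
    return ReadCountTable(t.df[m].reset_index(drop=True))


def run_grid(
    base: ReadCountTable,
    wt: WildType,
    proj: PropertyProjection,
    grid: ResampleGrid,
    make_model: Callable[[int, int, int], Model],
    train_cfg: Optional[TrainingConfig] = None,
    n_test: int = 1000,
    true_scores: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Run the full resampling protocol and summarize per-cell performance.

    A global test set of ``n_test`` variants is drawn from the base table and
    excluded from every resampled library; test variants keep their "true"
    (non-resampled) scores.  Per cell, ``grid.replicates`` resampled datasets
    are scored, split 80/20 into train/tune, used to train a fresh model from
    ``make_model(L, in_features, seed)``, and evaluated on the global test
    set.  Cells in which any replicate ends up with fewer than
    ``grid.min_variants`` sequenced variants are marked excluded.

    Returns a data frame with one row per (library_size, total_reads) cell:
    columns ``library_size, total_reads, mean_pearson, excluded, n_datasets``.
    """
    if train_cfg is None:
        train_cfg = TrainingConfig(max_epochs=50, patience=10)
    base = filter_counts(base, 1)
    if true_scores is None:
        true_scores = enrichment_score(base)
    rng = np.random.default_rng(grid.seed)
    non_wt = [n for n in base.variants if n != WT_LABEL]
    if n_test >= len(non_wt):
        raise ValueError("test size exceeds available variants")
    test_names = set(
        rng.choice(np.array(non_wt), size=n_test, replace=False).tolist()
    )
    pool = ReadCountTable(
        base.df[~base.df["variant"].isin(test_names)].reset_index(drop=True)
    )
    test_variants = [parse_variant(n, wt) for n in sorted(test_names)]
    X_test = encode_batch(test_variants, wt, proj)
    y_test = true_scores.loc[sorted(test_names)].to_numpy()

    rows = []
    for lib in grid.library_sizes:
        for reads in grid.total_reads:
            pearsons, n_vars = [], []
            tables = []
            for rep in range(grid.replicates):
                cell_seed = grid.seed + hash((lib, reads, rep)) % (2**31)
                t = resample_dataset(pool, min(lib, len(pool)), reads, seed=cell_seed)
                t = sequenced_subset(t)
                tables.append((cell_seed, t))
                n_vars.append(len(t))
            if min(n_vars) < grid.min_variants:
                rows.append(
                    dict(
                        library_size=lib,
                        total_reads=reads,
                        mean_pearson=np.nan,
                        excluded=True,
                        n_datasets=grid.replicates,
                    )
                )
                continue
            for cell_seed, t in tables:
                scores = enrichment_score(t)
                names = [n for n in t.variants if n != WT_LABEL]
                variants = [parse_variant(n, wt) for n in names]
                X = encode_batch(variants, wt, proj)
                y = scores.loc[names].to_numpy()
                srng = np.random.default_rng(cell_seed)
                order = srng.permutation(len(names))
                n_tune = max(1, int(0.2 * len(names)))
                tune_idx, train_idx = order[:n_tune], order[n_tune:]
                model = make_model(len(wt), X.shape[2], cell_seed)
                train(
                    model,
                    X[train_idx],
                    y[train_idx],
                    X[tune_idx],
                    y[tune_idx],
                    train_cfg,
                )
                rep_eval = evaluate(y_test, model.predict(X_test))
                pearsons.append(rep_eval.pearson)
            rows.append(
                dict(
                    library_size=lib,
                    total_reads=reads,
                    mean_pearson=float(np.nanmean(pearsons)),
                    excluded=False,
                    n_datasets=grid.replicates,
                )
            )
    return pd.DataFrame(rows)
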