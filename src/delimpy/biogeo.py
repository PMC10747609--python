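"""Biogeographic concordance of delimited species with regionalization units.

Haplogroup occurrences across biogeographic subprovinces are tabulated into
a frequency matrix, subprovinces are ordered along a thermal gradient (mean
BIO11, the mean temperature of the coldest quarter), and a double k-means
split clusters haplogroups (rows, on their relative frequency profiles
across subprovinces) and subprovinces (columns, on their haplogroup
composition) simultaneously.  Repeating the split with independent seeds and
requiring an identical canonical partition every time mirrors the stability
check used with heatmap biclustering.  Agreement between the biogeographic
row clusters and molecular species hypotheses is scored with the Adjusted
Rand Index.

Morphological trait summaries (epidermal cell-length ratios, hair width,
hydathode counts) are reported per group with the adaxial/abaxial ratio
criterion (group mean in [1.5, 2.0]) that separates taxa in this complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from ._rand import derive_seed

OCC_COLUMNS = ["population_id", "subprovince", "haplogroup", "ploidy", "bio11"]
TRAIT_COLUMNS = ["adaxial_len", "abaxial_len", "hair_width", "hydathodes"]
ALLOWED_PLOIDY = {2, 4, 6}
RATIO_CRITERION = (1.5, 2.0)


def load_occurrences(path) -> pd.DataFrame:
    """Read and validate an occurrence CSV (one row per population)."""
    occ = pd.read_csv(path)
    return validate_occurrences(occ)


def validate_occurrences(occ: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OCC_COLUMNS if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if occ[["subprovince", "haplogroup"]].isna().any().any():
        raise ValueError("missing subprovince or haplogroup values")
    bad = set(occ["ploidy"].astype(int)) - ALLOWED_PLOIDY
    if bad:
        raise ValueError(f"ploidy values outside {sorted(ALLOWED_PLOIDY)}: {sorted(bad)}")
    return occ


@dataclass
class FrequencyMatrix:
    """Haplogroup x subprovince counts with row-normalized frequencies."""

    counts: pd.DataFrame  # rows: haplogroups, cols: subprovinces

    def __post_init__(self) -> None:
        zero = self.counts.index[self.counts.sum(axis=1) == 0]
        if len(zero):
            warnings.warn(f"haplogroups with zero occurrences dropped: {list(zero)}")
            self.counts = self.counts.drop(index=zero)

    @property
    def freqs(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    @property
    def haplogroups(self) -> list[str]:
        return [str(x) for x in self.counts.index]

    @property
    def subprovinces(self) -> list[str]:
        return [str(x) for x in self.counts.columns]

    def write_tsv(self, path) -> None:
        self.freqs.to_csv(path, sep="\t")


def build_frequency_matrix(
    occ: pd.DataFrame, col_order: list[str] | None = None
) -> FrequencyMatrix:
    """Tabulate haplogroup occurrences per subprovince.

    ``col_order`` (e.g. from :func:`thermal_order`) fixes the column order;
    by default columns follow the thermal gradient.
    """
    occ = validate_occurrences(occ)
    counts = pd.crosstab(occ["haplogroup"], occ["subprovince"])
    if col_order is None:
        col_order = thermal_order(occ)
    counts = counts.reindex(columns=col_order, fill_value=0)
    return FrequencyMatrix(counts)


def thermal_order(occ: pd.DataFrame) -> list[str]:
    """Subprovinces sorted by ascending mean BIO11 (coldest first)."""
    if occ["bio11"].isna().any():
        raise ValueError("bio11 missing for some occurrences")
    means = occ.groupby("subprovince")["bio11"].mean()
    return list(means.sort_index().sort_values(kind="stable").index)


@dataclass
class SplitConfig:
    k_rows: int = 3
    k_cols: int = 4
    repeats: int = 25
    seed: int = 0


@dataclass
class ConcordanceResult:
    row_partition: dict[str, int]
    col_partition: dict[str, int]
    consistent: bool
    ari_vs_species: float | None = None
    exact_match: bool | None = None


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance so partitions compare across runs."""
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


class DoubleKMeans(BaseEstimator):
    """Simultaneous k-means split of a frequency matrix by rows and columns.

    Rows (haplogroups) are clustered on their row-normalized frequency
    profiles; columns (subprovinces) on their column-normalized composition,
    transposed.  The split is repeated ``repeats`` times with seeds derived
    from ``random_state``; ``consistent_`` records whether every repeat
    returned the same canonical partition (the stability check).

    Attributes
    ----------
    row_labels_, col_labels_ : ndarray
    consistent_ : bool
    row_partition_, col_partition_ : dict name -> cluster id
    """

    def __init__(self, k_rows: int = 3, k_cols: int = 4, repeats: int = 25,
                 n_init: int = 10, random_state: int = 0):
        self.k_rows = k_rows
        self.k_cols = k_cols
        self.repeats = repeats
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        F = X if isinstance(X, FrequencyMatrix) else FrequencyMatrix(pd.DataFrame(X))
        n_r, n_c = F.counts.shape
        if not (1 <= self.k_rows <= n_r):
            raise ValueError(f"k_rows={self.k_rows} outside [1, {n_r}]")
        if not (1 <= self.k_cols <= n_c):
            raise ValueError(f"k_cols={self.k_cols} outside [1, {n_c}]")
        row_X = F.freqs.to_numpy()
        col_X = F.counts.div(F.counts.sum(axis=0), axis=1).T.to_numpy()
        row_runs, col_runs = [], []
        for r in range(self.repeats):
            rs = derive_seed(self.random_state, "double-kmeans", counter=r)
            km_r = KMeans(n_clusters=self.k_rows, n_init=self.n_init,
                          random_state=rs).fit(row_X)
            km_c = KMeans(n_clusters=self.k_cols, n_init=self.n_init,
                          random_state=rs + 1).fit(col_X)
            row_runs.append(_canonical(km_r.labels_))
            col_runs.append(_canonical(km_c.labels_))
        self.row_runs_ = row_runs
        self.col_runs_ = col_runs
        self.consistent_ = all(
            np.array_equal(row_runs[0], lr) for lr in row_runs
        ) and all(np.array_equal(col_runs[0], lc) for lc in col_runs)
        self.row_labels_ = row_runs[0]
        self.col_labels_ = col_runs[0]
        self.row_partition_ = dict(zip(F.haplogroups, map(int, self.row_labels_)))
        self.col_partition_ = dict(zip(F.subprovinces, map(int, self.col_labels_)))
        return self


def double_kmeans_split(
    F: FrequencyMatrix, cfg: SplitConfig,
    species_of_row: Mapping[str, str] | None = None,
) -> ConcordanceResult:
    """Run the repeated double split; optionally score rows against species."""
    dk = DoubleKMeans(k_rows=cfg.k_rows, k_cols=cfg.k_cols,
                      repeats=cfg.repeats, random_state=cfg.seed).fit(F)
    ari = exact = None
    if species_of_row is not None:
        ari, exact = partition_concordance(
            dk.row_partition_, {r: species_of_row[r] for r in F.haplogroups}
        )
    return ConcordanceResult(
        row_partition=dk.row_partition_,
        col_partition=dk.col_partition_,
        consistent=dk.consistent_,
        ari_vs_species=ari,
        exact_match=exact,
    )


def partition_concordance(
    part_a: Mapping[str, object], part_b: Mapping[str, object]
) -> tuple[float, bool]:
    """(Adjusted Rand Index, identical-up-to-relabeling) of two partitions."""
    if set(part_a) != set(part_b):
        raise ValueError("partitions are over different element sets")
    keys = sorted(part_a)
    a = [part_a[k] for k in keys]
    b = [part_b[k] for k in keys]
    ari = float(adjusted_rand_score(a, b))
    ia = _canonical(pd.factorize(np.asarray(a, dtype=object))[0])
    ib = _canonical(pd.factorize(np.asarray(b, dtype=object))[0])
    return ari, bool(np.array_equal(ia, ib))


def trait_group_summary(
    traits: pd.DataFrame, grouping: Mapping[str, str] | str = "group"
) -> pd.DataFrame:
    """Per-group summaries of the diagnostic leaf traits.

    ``traits`` needs ``individual_id``, the trait columns, and either a
    ``group`` column or an external ``grouping`` map.  The ratio criterion
    flags groups whose mean adaxial/abaxial cell-length ratio falls in
    [1.5, 2.0].
    """
    df = traits.copy()
    if isinstance(grouping, str):
        if grouping not in df.columns:
            raise ValueError(f"no grouping column {grouping!r}")
        df["_group"] = df[grouping]
    else:
        df["_group"] = df["individual_id"].map(dict(grouping))
        if df["_group"].isna().any():
            raise ValueError("grouping does not cover all individuals")
    if (df["adaxial_len"] <= 0).any() or (df["abaxial_len"] <= 0).any():
        raise ValueError("non-positive cell lengths")
    df["ratio"] = df["adaxial_len"] / df["abaxial_len"]
    rows = []
    for grp, sub in df.groupby("_group", sort=True):
        row = {"group": grp, "n": len(sub)}
        for col in ["ratio", "hair_width", "hydathodes"]:
            if col in sub:
                row[f"{col}_mean"] = sub[col].mean()
                row[f"{col}_min"] = sub[col].min() if len(sub) > 1 else np.nan
                row[f"{col}_max"] = sub[col].max() if len(sub) > 1 else np.nan
        lo, hi = RATIO_CRITERION
        row["ratio_criterion"] = bool(lo <= row["ratio_mean"] <= hi)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
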