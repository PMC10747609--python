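"""Barcode-gap automatic partitioning of a pairwise distance matrix.

Candidate species partitions are the states of a single-linkage merge
sequence: at threshold t the groups are exactly the connected components of
the graph joining pairs at distance <= t, which is the transitive-closure
logic behind barcode-gap delimitation.  Each candidate receives

* a probability of panmixia (p-value): a label-permutation test of the
  merge(s) that would collapse it (the joins pending at its threshold
  distance), asking whether the between-group distances are exchangeable
  with the pooled within-group distances — a low probability means the
  groups the candidate keeps apart are significantly non-panmictic, i.e.
  the partition sits on a real barcode gap,
* a relative gap width W = (d_next - d_cur) / d_next, the width of the
  distance interval over which the candidate persists relative to the
  distance at which it collapses (a dimensionless measure of the
  discontinuity between intra- and inter-group divergence),
* a threshold distance d_next, the distance at which it would collapse.

Per substitution model, candidates are ranked on the p-value (ascending) and
on W (descending); the asap-score is the average of the two ranks, lower
being better.  A reference threshold distance (default 0.0005
substitutions/site) flags candidates whose threshold exceeds typical
intrapopulation divergence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from ._rand import derive_seed
from .seqdata import MODELS, Alignment, DistanceMatrix, pairwise_distances

DEFAULT_REFERENCE_THRESHOLD = 5e-4
DEFAULT_N_PERM = 999


@dataclass
class MergeEvent:
    """One single-linkage merge: the joined groups and the join distance."""

    d_merge: float
    merged: tuple[frozenset, frozenset]
    groups_before: list[frozenset]
    groups_after: list[frozenset]


@dataclass
class PartitionCandidate:
    groups: list[frozenset]
    n_species: int
    d_cur: float
    d_next: float
    threshold_dist: float
    p_value: float
    W: float
    rank_p: float = math.nan
    rank_W: float = math.nan
    asap_score: float = math.nan
    above_reference: bool = False

    def labels(self, order: list[str]) -> np.ndarray:
        lab = {}
        for k, g in enumerate(self.groups):
            for m in g:
                lab[m] = k
        return np.array([lab[x] for x in order])

    def to_dict(self) -> dict:
        return {
            "groups": [sorted(g) for g in self.groups],
            "n_species": self.n_species,
            "d_cur": self.d_cur,
            "d_next": self.d_next,
            "threshold_dist": self.threshold_dist,
            "p_value": self.p_value,
            "W": self.W,
            "rank_p": self.rank_p,
            "rank_W": self.rank_W,
            "asap_score": self.asap_score,
            "above_reference": self.above_reference,
        }


def single_linkage_merges(dm: DistanceMatrix) -> list[MergeEvent]:
    """The full single-linkage merge sequence, all-singletons to one group."""
    n = dm.n
    if n < 2:
        return []
    Z = hierarchy.linkage(squareform(dm.D, checks=False), method="single")
    clusters: dict[int, frozenset] = {
        i: frozenset([lab]) for i, lab in enumerate(dm.labels)
    }
    current = [clusters[i] for i in range(n)]
    events: list[MergeEvent] = []
    for row_i, (a, b, d, _) in enumerate(Z):
        ga, gb = clusters[int(a)], clusters[int(b)]
        before = list(current)
        merged = ga | gb
        current = [g for g in current if g is not ga and g is not gb] + [merged]
        clusters[n + row_i] = merged
        events.append(MergeEvent(float(d), (ga, gb), before, list(current)))
    return events


def _split_stat(sub: np.ndarray, mask_a: np.ndarray) -> float:
    """mean(between) - mean(pooled within) for a boolean side assignment."""
    between = sub[np.ix_(mask_a, ~mask_a)]
    iu = np.triu_indices(sub.shape[0], k=1)
    same = mask_a[iu[0]] == mask_a[iu[1]]
    within = sub[iu][same]
    if within.size == 0:
        return math.nan
    return float(between.mean() - within.mean())


def panmixia_pvalue(
    dm: DistanceMatrix,
    group_a: frozenset,
    group_b: frozenset,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> float:
    """Permutation probability that two groups form one panmictic pool.

    The statistic is mean(between-group distances) minus mean(pooled
    within-group distances); labels are permuted within the union.  When the
    number of distinct splits of the union into the two group sizes is at
    most ``n_perm`` the test is exhaustive, otherwise Monte Carlo with the
    add-one estimator.  Two singletons have no within-group distances and
    return 1 by convention.
    """
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    union = sorted(group_a | group_b)
    na = len(group_a)
    if len(union) == 2:
        return 1.0
    idx = {lab: i for i, lab in enumerate(dm.labels)}
    sub = dm.D[np.ix_([idx[u] for u in union], [idx[u] for u in union])]
    m = len(union)
    obs_mask = np.array([u in group_a for u in union])
    s_obs = _split_stat(sub, obs_mask)

    n_splits = math.comb(m, na)
    if na * 2 == m:
        n_splits //= 2
    eps = 1e-12
    if n_splits <= n_perm:
        count = total = 0
        for combo in combinations(range(m), na):
            if na * 2 == m and 0 not in combo:
                continue  # each balanced split counted once
            mask = np.zeros(m, dtype=bool)
            mask[list(combo)] = True
            if _split_stat(sub, mask) >= s_obs - eps:
                count += 1
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        mask = np.zeros(m, dtype=bool)
        mask[rng.choice(m, size=na, replace=False)] = True
        if _split_stat(sub, mask) >= s_obs - eps:
            count += 1
    return (1 + count) / (n_perm + 1)


def _rel_gap(d_cur: float, d_next: float) -> float:
    """Gap width relative to the collapse distance.

    A barcode gap is a discontinuity between observed intra-group and
    inter-group divergence; a candidate whose largest applied merge distance
    is zero (nothing merged, or only identical sequences) exhibits no
    intra-group scale, so no gap can be claimed and W = 0.
    """
    if d_next <= 0 or d_cur <= 0:
        return 0.0
    return (d_next - d_cur) / d_next


def _candidates_from_merges(
    dm: DistanceMatrix,
    events: list[MergeEvent],
    n_perm: int,
    seed: int,
    reference_threshold: float,
) -> list[PartitionCandidate]:
    n = dm.n
    iu = np.triu_indices(n, k=1)
    all_pairs = dm.D[iu]
    mean_d = float(all_pairs.mean())
    max_d = float(all_pairs.max())
    if mean_d <= 0:
        # degenerate: all sequences identical
        return [
            PartitionCandidate(
                groups=[frozenset(dm.labels)], n_species=1,
                d_cur=0.0, d_next=0.0, threshold_dist=0.0,
                p_value=1.0, W=0.0, rank_p=1.0, rank_W=1.0, asap_score=1.0,
                above_reference=False,
            )
        ]

    # group merge events by distinct merge distance
    distinct: list[tuple[float, list[MergeEvent]]] = []
    for ev in events:
        if distinct and ev.d_merge == distinct[-1][0]:
            distinct[-1][1].append(ev)
        else:
            distinct.append((ev.d_merge, [ev]))

    # p-value per merge batch: does the pending join lump non-panmictic groups?
    batch_p: list[float] = []
    counter = 0
    for d, evs in distinct:
        pvals = []
        for ev in evs:
            pvals.append(
                panmixia_pvalue(dm, ev.merged[0], ev.merged[1], n_perm=n_perm,
                                seed=derive_seed(seed, "panmixia", counter=counter))
            )
            counter += 1
        batch_p.append(min(pvals))  # simultaneous merges: conservative minimum

    cands: list[PartitionCandidate] = []
    first_d = distinct[0][0] if distinct else max_d
    # all-singletons state; it would collapse at the first merge distance
    cands.append(
        PartitionCandidate(
            groups=[frozenset([lab]) for lab in dm.labels],
            n_species=n, d_cur=0.0, d_next=first_d, threshold_dist=first_d,
            p_value=batch_p[0] if batch_p else 1.0,
            W=_rel_gap(0.0, first_d),
        )
    )
    for j, (d, evs) in enumerate(distinct):
        d_next = distinct[j + 1][0] if j + 1 < len(distinct) else max_d
        # the single-group state has no pending merge: p = 1 by convention
        p_val = batch_p[j + 1] if j + 1 < len(distinct) else 1.0
        cands.append(
            PartitionCandidate(
                groups=list(evs[-1].groups_after),
                n_species=len(evs[-1].groups_after),
                d_cur=d, d_next=d_next, threshold_dist=d_next,
                p_value=p_val, W=_rel_gap(d, d_next),
            )
        )

    p = np.array([c.p_value for c in cands])
    W = np.array([c.W for c in cands])
    rank_p = rankdata(p, method="average")
    rank_W = rankdata(-W, method="average")
    for c, rp, rw in zip(cands, rank_p, rank_W):
        c.rank_p = float(rp)
        c.rank_W = float(rw)
        c.asap_score = (float(rp) + float(rw)) / 2.0
        c.above_reference = c.threshold_dist > reference_threshold
    # partitions whose threshold overpasses the reference distance (minimum
    # plausible interspecific divergence) outrank those that do not; within a
    # stratum, lower asap-score wins, then lower p, then fewer species
    cands.sort(
        key=lambda c: (not c.above_reference, c.asap_score, c.p_value,
                       c.n_species)
    )
    return cands


def asap_partition(
    dm: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    reference_threshold: float = DEFAULT_REFERENCE_THRESHOLD,
) -> list[PartitionCandidate]:
    """Ranked candidate partitions for one distance matrix."""
    events = single_linkage_merges(dm)
    return _candidates_from_merges(dm, events, n_perm, seed, reference_threshold)


def asap_delimit(
    aln: Alignment,
    models=("p", "JC69", "K80"),
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    reference_threshold: float = DEFAULT_REFERENCE_THRESHOLD,
) -> dict[str, list[PartitionCandidate]]:
    """Per-model ranked candidate partitions for an alignment."""
    if aln.n < 3:
        raise ValueError("need at least 3 records")
    out = {}
    for model in models:
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        dm = pairwise_distances(aln, model)
        out[model] = asap_partition(
            dm, n_perm=n_perm, seed=derive_seed(seed, f"asap-{model}"),
            reference_threshold=reference_threshold,
        )
    return out


def candidates_to_json(result: dict[str, list[PartitionCandidate]], path) -> None:
    payload = {m: [c.to_dict() for c in cands] for m, cands in result.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


class AsapPartitioner(BaseEstimator):
    """Estimator interface to barcode-gap partitioning.

    ``fit`` accepts an :class:`~delimpy.seqdata.Alignment` or a
    :class:`~delimpy.seqdata.DistanceMatrix`.  With an alignment, one
    candidate list is produced per substitution model; the overall best
    candidate (lowest asap-score, K80 preferred on ties) provides
    ``labels_``.

    Attributes
    ----------
    candidates_ : dict model -> ranked list of PartitionCandidate
    best_model_ : str
    best_ : PartitionCandidate
    labels_ : ndarray of group ids in ``ids_`` order
    """

    def __init__(self, models=("p", "JC69", "K80"), n_perm: int = DEFAULT_N_PERM,
                 reference_threshold: float = DEFAULT_REFERENCE_THRESHOLD,
                 random_state: int = 0):
        self.models = models
        self.n_perm = n_perm
        self.reference_threshold = reference_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, DistanceMatrix):
            self.candidates_ = {
                X.model: asap_partition(
                    X, n_perm=self.n_perm, seed=self.random_state,
                    reference_threshold=self.reference_threshold,
                )
            }
            self.ids_ = list(X.labels)
        elif isinstance(X, Alignment):
            self.candidates_ = asap_delimit(
                X, models=self.models, n_perm=self.n_perm,
                seed=self.random_state,
                reference_threshold=self.reference_threshold,
            )
            self.ids_ = list(X.ids)
        else:
            raise TypeError("X must be an Alignment or a DistanceMatrix")
        # prefer K80 on score ties, then the declared model order
        pref = {m: i for i, m in enumerate(["K80", "JC69", "p"])}
        self.best_model_ = min(
            self.candidates_,
            key=lambda m: (self.candidates_[m][0].asap_score, pref.get(m, 99)),
        )
        self.best_ = self.candidates_[self.best_model_][0]
        self.labels_ = self.best_.labels(self.ids_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
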