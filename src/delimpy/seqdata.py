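"""Aligned sequence data: FASTA I/O, haplotype collapsing and genetic distances.

The unit of analysis is a single-locus alignment (here, concatenated plastid
regions, which are inherited as one linkage block).  Two dataset variants are
supported: the "haplotypes" dataset, in which identical sequences are collapsed
to unique haplotypes, and the "populations" dataset, in which haplotypes are
replicated roughly in proportion to their frequency in natural populations.

Pairwise distances are offered under three substitution models:

* ``p``    -- raw proportion of differing sites,
* ``JC69`` -- Jukes-Cantor correction  d = -(3/4) ln(1 - 4p/3),
* ``K80``  -- Kimura two-parameter correction
              d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q),
              with P and Q the transition and transversion proportions.

Sites where either sequence carries a gap or an ``N`` are dropped pair by pair
before counting (pairwise deletion).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, ParseError, SaturationError

ALPHABET = set("ACGTN-")
MODELS = ("p", "JC69", "K80")

# nucleotide byte codes; 255 marks N or gap (excluded pairwise)
_CODE = np.full(256, 254, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 255
_CODE[ord("-")] = 255

# purines (A=0, G=2); a substitution within {A,G} or within {C,T} is a transition
_IS_PURINE = np.array([True, False, True, False])


@dataclass
class Alignment:
    """An ordered, equal-length nucleotide alignment over {A,C,G,T,N,-}."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if not self.ids:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i, c in Counter(self.ids).items() if c > 1]
            raise AlignmentError(f"duplicate record ids: {dup}")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        for rid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"record {rid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - ALPHABET
            if bad:
                col = next(i for i, c in enumerate(s) if c in bad)
                raise ParseError(
                    f"illegal character {s[col]!r} in record {rid!r} at column {col}"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix; 255 marks N/gap."""
        arr = np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)
        return _CODE[arr]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, s in zip(self.ids, self.seqs):
                fh.write(f">{rid}\n{s}\n")


def read_alignment(path) -> Alignment:
    """Read a FASTA alignment, case-normalizing and preserving input order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


@dataclass
class Haplotype:
    hap_id: str
    sequence: str
    members: list[str]
    populations: Counter = field(default_factory=Counter)

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    """Unique sequences with multiplicities and population membership."""

    haplotypes: list[Haplotype]

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    def __getitem__(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    def to_alignment(self) -> Alignment:
        return Alignment(
            [h.hap_id for h in self.haplotypes],
            [h.sequence for h in self.haplotypes],
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hap_id\tcount\tmembers\tpopulations\n")
            for h in self.haplotypes:
                pops = ",".join(f"{p}:{c}" for p, c in sorted(h.populations.items()))
                fh.write(f"{h.hap_id}\t{h.count}\t{','.join(h.members)}\t{pops}\n")


def _matches_with_n(a: str, b: str) -> bool:
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def collapse_haplotypes(
    aln: Alignment,
    ambiguity_policy: str = "strict",
    populations: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse identical sequences to unique haplotypes.

    Under ``strict``, only exact string equality merges records; under
    ``n_wildcard`` a record whose only mismatches against a haplotype's
    representative fall on ``N`` positions merges into it (first match wins).
    Haplotypes are ordered by descending count, ties by first occurrence,
    and named ``h1, h2, ...`` in that order.
    """
    if ambiguity_policy not in ("strict", "n_wildcard"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    groups: list[Haplotype] = []
    index: dict[str, Haplotype] = {}
    for rid, seq in zip(aln.ids, aln.seqs):
        hit = None
        if ambiguity_policy == "strict":
            hit = index.get(seq)
        else:
            for h in groups:
                if _matches_with_n(seq, h.sequence):
                    hit = h
                    break
        if hit is None:
            hit = Haplotype(hap_id="", sequence=seq, members=[])
            groups.append(hit)
            if ambiguity_policy == "strict":
                index[seq] = hit
        hit.members.append(rid)
        if populations is not None and rid in populations:
            hit.populations[populations[rid]] += 1
    order = sorted(range(len(groups)), key=lambda i: (-groups[i].count, i))
    out = [groups[i] for i in order]
    for k, h in enumerate(out, 1):
        h.hap_id = f"h{k}"
    return HaplotypeTable(out)


def build_population_dataset(
    ht: HaplotypeTable, representation: Mapping[str, int] | Iterable[tuple[str, int]]
) -> Alignment:
    """Expand haplotypes into a "populations" dataset alignment.

    ``representation`` maps hap_id -> copy number (>= 1).  Replicated records
    are suffixed ``_1 .. _k``; a haplotype found in only one population is
    conventionally represented once.
    """
    rep = dict(representation)
    known = {h.hap_id for h in ht.haplotypes}
    unknown = set(rep) - known
    if unknown:
        raise KeyError(f"unknown haplotype ids: {sorted(unknown)}")
    ids, seqs = [], []
    for h in ht.haplotypes:
        copies = rep.get(h.hap_id, 0)
        if copies < 0:
            raise ValueError(f"negative copy number for {h.hap_id}")
        for k in range(1, copies + 1):
            ids.append(f"{h.hap_id}_{k}")
            seqs.append(h.sequence)
    return Alignment(ids, seqs)


@dataclass
class PairCounts:
    """Site counts for one sequence pair after pairwise deletion."""

    L_eff: int
    diff: int
    transitions: int
    transversions: int

    @property
    def p(self) -> float:
        return self.diff / self.L_eff

    @property
    def P(self) -> float:
        return self.transitions / self.L_eff

    @property
    def Q(self) -> float:
        return self.transversions / self.L_eff


def pair_counts(a: np.ndarray, b: np.ndarray) -> PairCounts:
    """Count comparable, differing, transition and transversion sites."""
    ok = (a < 4) & (b < 4)
    aa, bb = a[ok], b[ok]
    neq = aa != bb
    ts = int(np.sum(neq & (_IS_PURINE[aa] == _IS_PURINE[bb])))
    diff = int(np.sum(neq))
    return PairCounts(int(ok.sum()), diff, ts, diff - ts)


def jc69_distance(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"JC69 undefined for p = {p:.4f} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k80_distance(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K80 undefined for P = {P:.4f}, Q = {Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix under a named substitution model."""

    labels: list[str]
    D: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("non-finite distances")
        if np.any(self.D < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("matrix not symmetric")
        np.fill_diagonal(self.D, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.D):
                fh.write(lab + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.D):
                fh.write(f"{lab:<10s} " + " ".join(f"{x:.8f}" for x in row) + "\n")


def pairwise_distances(aln: Alignment, model: str = "K80") -> DistanceMatrix:
    """All pairwise distances under ``p``, ``JC69`` or ``K80``.

    Columns with a gap or ``N`` in either member of a pair are excluded for
    that pair only.  A pair left with no comparable sites, or whose observed
    proportions exceed the model's domain, raises an error naming the pair.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if aln.n < 2:
        raise AlignmentError("need at least 2 records for distances")
    enc = aln.encoded()
    n = aln.n
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pc = pair_counts(enc[i], enc[j])
            if pc.L_eff == 0:
                raise AlignmentError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            try:
                if model == "p":
                    d = pc.p
                elif model == "JC69":
                    d = jc69_distance(pc.p)
                else:
                    d = k80_distance(pc.P, pc.Q)
            except SaturationError as e:
                raise SaturationError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}): {e}"
                ) from None
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.ids), D, model)
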