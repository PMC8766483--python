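"""Exact canonical k-mer sharing between genomes.

Profiles are exact sets of canonical k-mers (the lexicographic minimum of a
window and its reverse complement), default k = 25.  Pairwise sharing is the
plain set intersection — equivalent to a MinHash sketch large enough to be
lossless, without the approximation.  A binary "shares >= 1 k-mer" network
over genome pairs can then be compared with a binary "shares >= 1 host"
network from an interaction matrix via plug-in mutual information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .matrix_io import InteractionMatrix

__all__ = [
    "KmerProfile",
    "kmer_profile",
    "profiles_from_fasta",
    "pairwise_sharing",
    "host_sharing_vector",
    "binary_mutual_information",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerProfile:
    """The set of canonical k-mers of one genome."""

    genome_id: str
    k: int
    kmers: frozenset[str] = field(repr=False)

    def __len__(self) -> int:
        return len(self.kmers)


def kmer_profile(genome_id: str, sequence: str, k: int = 25) -> KmerProfile:
    """Canonical k-mer set of a sequence.

    Windows containing any symbol outside {A, C, G, T} (after uppercasing)
    are skipped; a sequence shorter than k yields an empty profile.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = str(sequence).upper()
    valid = np.frombuffer(seq.encode(), dtype=np.uint8)
    ok = (valid == ord("A")) | (valid == ord("C")) | (valid == ord("G")) | (valid == ord("T"))
    kmers = set()
    for i in range(len(seq) - k + 1):
        if ok[i : i + k].all():
            kmers.add(canonical(seq[i : i + k]))
    return KmerProfile(genome_id, k, frozenset(kmers))


def profiles_from_fasta(path: str | Path, k: int = 25) -> list[KmerProfile]:
    """One profile per record of a multi-FASTA; record id = genome id."""
    profiles = [
        kmer_profile(rec.id, str(rec.seq), k=k) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not profiles:
        raise ValueError(f"no FASTA records in {path}")
    return profiles


def mash_distance(jaccard: float, k: int) -> float:
    """-(1/k) ln(2J / (1+J)); 0 iff J = 1, +inf when J = 0."""
    if jaccard == 0:
        return math.inf
    return -math.log(2 * jaccard / (1 + jaccard)) / k


def pairwise_sharing(profiles: list[KmerProfile]) -> pd.DataFrame:
    """Shared-k-mer table over all unordered genome pairs.

    Columns: genome_a, genome_b, shared_count, jaccard, mash_distance,
    binary_share.  Pair order follows ``itertools.combinations`` over the
    input order, matching :func:`host_sharing_vector`.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"profiles built with mixed k: {sorted(ks)}")
    k = ks.pop()
    rows = []
    for a, b in combinations(profiles, 2):
        shared = len(a.kmers & b.kmers)
        union = len(a.kmers | b.kmers)
        j = shared / union if union else 0.0
        rows.append(
            {
                "genome_a": a.genome_id,
                "genome_b": b.genome_id,
                "shared_count": shared,
                "jaccard": j,
                "mash_distance": mash_distance(j, k),
                "binary_share": shared >= 1,
            }
        )
    return pd.DataFrame(rows)


def host_sharing_vector(m: InteractionMatrix) -> pd.DataFrame:
    """Binary per-phage-pair vector: 1 iff the pair kills >= 1 common host.

    Pair ordering is ``itertools.combinations`` over the matrix's phage
    column order, aligning with :func:`pairwise_sharing` run on profiles in
    the same order.
    """
    A = np.asarray(m.cells)
    overlap = A.T @ A  # phage x phage co-kill counts
    rows = [
        {
            "genome_a": m.phage_ids[i],
            "genome_b": m.phage_ids[j],
            "shares_host": bool(overlap[i, j] >= 1),
        }
        for i, j in combinations(range(m.n_phages), 2)
    ]
    return pd.DataFrame(rows)


def binary_mutual_information(a, b) -> float:
    """Plug-in mutual information (bits) between two binary vectors.

    Empirical 2x2 joint frequencies, log2, with 0 * log 0 = 0; bounded by
    min of the marginal entropies, hence by 1 bit.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("inputs must be equal-length nonempty vectors")
    n = len(a)
    mi = 0.0
    for va in (0, 1):
        pa = np.mean(a == va)
        for vb in (0, 1):
            pb = np.mean(b == vb)
            pab = np.mean((a == va) & (b == vb))
            if pab > 0:
                mi += pab * math.log2(pab / (pa * pb))
    return float(max(mi, 0.0))
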