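"""Read simulation and k-mer pseudo-mapping for cross-recruitment analysis.

Quantifies how easily reads simulated from one phage genome are falsely
"detected" against a related reference when mapping requires only a single
matching 31-mer (the pseudo-alignment criterion).  Detection follows the
standard viral-metagenome thresholds: genome coverage >= 0.1, observed to
expected coverage ratio >= 0.3, and >= 10 mapped reads.

The simulator is deliberately simple: uniform fragment placement, normal
outer distance, substitution errors only, constant base quality.  Coverage
of the reference is taken as the union of the reference-located occurrences
of the matched 31-mers — pseudo-alignment yields no base-level alignment,
so matched-k-mer intervals stand in for aligned bases.  Expected coverage
uses the Lander-Waterman form 1 - exp(-mapped_bases / reference_length).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sequence_sharing import canonical, reverse_complement

__all__ = [
    "ReadSimConfig",
    "DetectionCriteria",
    "MappingResult",
    "ReadPair",
    "KmerReferenceIndex",
    "simulate_reads",
    "write_fastq",
    "build_reference_index",
    "pseudo_map",
    "detect",
    "false_positive_rates",
]

PSEUDO_K = 31  # pseudo-alignment seed length


@dataclass(frozen=True)
class ReadSimConfig:
    """Paired-end simulation parameters.

    ``insert_mean``/``insert_sd`` describe the outer distance of the pair in
    bases; ``error_rate`` is the per-base substitution probability.
    """

    n_reads: int = 100_000
    read_length: int = 250
    error_rate: float = 0.001
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < PSEUDO_K:
            raise ValueError(f"read_length must be >= {PSEUDO_K} for mappability")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass(frozen=True)
class DetectionCriteria:
    min_coverage_fraction: float = 0.1
    min_obs_exp_ratio: float = 0.3
    min_mapped_reads: int = 10

    def __post_init__(self) -> None:
        if min(self.min_coverage_fraction, self.min_obs_exp_ratio, self.min_mapped_reads) < 0:
            raise ValueError("all detection thresholds must be >= 0")


@dataclass(frozen=True)
class ReadPair:
    name: str
    read1: str
    read2: str


@dataclass(frozen=True)
class MappingResult:
    source_genome: str
    reference_genome: str
    mapped_reads: int
    covered_fraction: float
    expected_coverage_fraction: float
    obs_exp_ratio: float
    detected: bool


@dataclass(frozen=True)
class KmerReferenceIndex:
    """Canonical 31-mers of a reference with their start positions.

    ``positions`` maps each canonical k-mer to ``(start, forward)`` tuples:
    the 0-based start of the occurrence and whether the reference's forward
    strand spells the canonical form there.
    """

    genome_id: str
    k: int
    length: int
    positions: dict[str, tuple[tuple[int, bool], ...]] = field(repr=False)

    @property
    def kmers(self) -> frozenset[str]:
        return frozenset(self.positions)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _add_errors(read: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate == 0:
        return read
    hit = np.nonzero(rng.random(len(read)) < error_rate)[0]
    for i in hit:
        choices = _BASES[_BASES != read[i]]
        read[i] = choices[rng.integers(3)]
    return read


def simulate_reads(genome_id: str, genome: str, config: ReadSimConfig) -> list[ReadPair]:
    """Simulate paired-end reads from one genome.

    Per pair: the outer distance is drawn Normal(insert_mean, insert_sd)
    truncated to [2 * read_length, genome length], the fragment start is
    uniform, read 1 is the fragment prefix and read 2 the reverse complement
    of the fragment suffix; each base substitutes with ``error_rate`` to a
    uniformly chosen different base.  Deterministic given ``config.seed``.
    """
    seq = str(genome).upper()
    L = len(seq)
    if L <= config.insert_mean:
        raise ValueError(
            f"genome {genome_id!r} ({L} bp) shorter than insert_mean {config.insert_mean}"
        )
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rng = np.random.default_rng(config.seed)
    lo, hi = 2 * config.read_length, L
    pairs = []
    for i in range(config.n_reads):
        frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        frag = min(max(frag, lo), hi)
        start = int(rng.integers(L - frag + 1))
        r1 = _add_errors(arr[start : start + config.read_length].copy(), config.error_rate, rng)
        tail = arr[start + frag - config.read_length : start + frag].copy()
        r2 = _add_errors(tail, config.error_rate, rng)
        pairs.append(
            ReadPair(
                name=f"{genome_id}_{i}",
                read1=r1.tobytes().decode(),
                read2=reverse_complement(r2.tobytes().decode()),
            )
        )
    return pairs


def write_fastq(pairs: list[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_1.fastq`` / ``<prefix>_2.fastq`` with constant quality."""
    prefix = Path(prefix)
    paths = (prefix.parent / f"{prefix.name}_1.fastq", prefix.parent / f"{prefix.name}_2.fastq")
    for path, mate in zip(paths, ("read1", "read2")):
        with open(path, "w") as fh:
            for pair in pairs:
                seq = getattr(pair, mate)
                fh.write(f"@{pair.name}/{mate[-1]}\n{seq}\n+\n{'I' * len(seq)}\n")
    return paths


def build_reference_index(genome_id: str, sequence: str, k: int = PSEUDO_K) -> KmerReferenceIndex:
    """Positional canonical k-mer index of a reference genome."""
    seq = str(sequence).upper()
    positions: dict[str, list[tuple[int, bool]]] = {}
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if set(window) <= {"A", "C", "G", "T"}:
            c = canonical(window)
            positions.setdefault(c, []).append((i, window == c))
    return KmerReferenceIndex(
        genome_id, k, len(seq), {kmer: tuple(v) for kmer, v in positions.items()}
    )


def _read_spans(read: str, index: KmerReferenceIndex) -> list[tuple[int, int]]:
    """Reference spans claimed by a read via its matched k-mers.

    Each matched k-mer anchors the read on the reference: the full read
    length is projected around the match, on the strand implied by the
    read-window and reference-window orientations, and clipped to the
    reference.  Empty list means the read does not map.
    """
    k = index.k
    rl = len(read)
    spans = []
    for i in range(rl - k + 1):
        window = read[i : i + k]
        c = canonical(window)
        hits = index.positions.get(c)
        if not hits:
            continue
        read_forward = window == c
        for pos, ref_forward in hits:
            if read_forward == ref_forward:
                start = pos - i
            else:
                start = pos + k + i - rl
            spans.append((max(start, 0), min(start + rl, index.length)))
    return spans


def pseudo_map(
    pairs: list[ReadPair],
    index: KmerReferenceIndex,
    source_genome: str,
    criteria: DetectionCriteria | None = None,
) -> MappingResult:
    """Map read pairs to a reference by the single-31-mer criterion.

    A read maps iff at least one of its canonical 31-mers occurs in the
    reference; both mates are counted individually.  Reference coverage is
    the union of the full read spans projected onto the reference around
    each matched 31-mer (clipped at the ends) — a single matching 31-mer
    therefore claims about a read length of coverage, which is why longer
    reads inflate false-positive coverage.
    """
    if index.k != PSEUDO_K:
        raise ValueError(f"reference index must use k = {PSEUDO_K}, got {index.k}")
    criteria = criteria or DetectionCriteria()
    covered = np.zeros(index.length, dtype=bool)
    mapped_reads = 0
    read_length = 0
    for pair in pairs:
        for read in (pair.read1, pair.read2):
            read_length = max(read_length, len(read))
            spans = _read_spans(read, index)
            if spans:
                mapped_reads += 1
                for a, b in spans:
                    covered[a:b] = True
    covered_fraction = float(covered.mean()) if index.length else 0.0
    expected = 1.0 - float(np.exp(-mapped_reads * read_length / index.length))
    ratio = covered_fraction / expected if expected > 0 else 0.0
    result = MappingResult(
        source_genome=source_genome,
        reference_genome=index.genome_id,
        mapped_reads=mapped_reads,
        covered_fraction=covered_fraction,
        expected_coverage_fraction=expected,
        obs_exp_ratio=ratio,
        detected=False,
    )
    return replace(result, detected=detect(result, criteria))


def false_positive_rates(
    read_lengths: tuple[int, ...] = (100, 250),
    n_replicates: int = 10,
    n_reads: int = 200,
    shared_length: int = 100,
    source_length: int = 8000,
    reference_length: int = 1500,
    error_rate: float = 0.001,
    seed: int = 0,
) -> dict[int, float]:
    """Cross-recruitment false-positive rate per read length.

    Each replicate builds a source genome and an unrelated reference that
    share one identical ``shared_length`` bp segment, simulates reads from
    the source, pseudo-maps them to the reference, and applies the default
    detection criteria.  Returns the fraction of replicates in which the
    non-source reference was (falsely) called present, keyed by read
    length.  Longer reads claim more collateral coverage per matched
    31-mer, so the rate grows with read length.
    """
    rates = {}
    for rl in read_lengths:
        hits = 0
        for rep in range(n_replicates):
            rng = np.random.default_rng((seed, rep))
            bases = np.array(list("ACGT"))

            def rand_seq(n):
                return "".join(rng.choice(bases, size=n))

            segment = rand_seq(shared_length)
            half_src = (source_length - shared_length) // 2
            source = rand_seq(half_src) + segment + rand_seq(half_src)
            half_ref = (reference_length - shared_length) // 2
            reference = rand_seq(half_ref) + segment + rand_seq(half_ref)
            cfg = ReadSimConfig(
                n_reads=n_reads, read_length=rl, error_rate=error_rate, seed=int(rng.integers(2**31))
            )
            res = pseudo_map(
                simulate_reads("source", source, cfg),
                build_reference_index("reference", reference),
                "source",
            )
            hits += res.detected
        rates[rl] = hits / n_replicates
    return rates


def detect(result: MappingResult, criteria: DetectionCriteria | None = None) -> bool:
    """Apply the presence thresholds to a mapping result."""
    c = criteria or DetectionCriteria()
    return (
        result.covered_fraction >= c.min_coverage_fraction
        and result.obs_exp_ratio >= c.min_obs_exp_ratio
        and result.mapped_reads >= c.min_mapped_reads
    )
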