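"""Seeded generators for synthetic interaction matrices, taxonomies, and genomes.

Every pipeline stage gets a self-contained, reproducible fixture:

* :func:`generate_matrix` — sparse binary bipartite matrices with planted
  module blocks, an optional strictly nested block, and exclusive
  one-to-one singleton pairs, returned with the ground-truth partition.
* :func:`generate_genomes` — genomes organized in a two-level taxonomy
  (species nested in genera), built from per-species templates, with
  planted horizontal-transfer segments and optional "no-flow" pools of
  genera guaranteed to share zero k-mers across pools.
* :func:`generate_host_range_groups` — interaction matrices whose phage
  columns follow a two-level taxonomy, species sharing a template kill
  vector with per-member bit-flip noise.

All generators are pure functions of their config plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import InteractionMatrix
from .network_structure import ModulePartition, barber_qb, interaction_ratio_qr
from .sequence_sharing import kmer_profile

__all__ = [
    "MatrixGenConfig",
    "GenomeGenConfig",
    "HostRangeGenConfig",
    "generate_matrix",
    "generate_genomes",
    "generate_host_range_groups",
]

_MORPHOTYPE_CYCLE = ("siphovirus", "podovirus", "myovirus", "non-tailed")


@dataclass(frozen=True)
class MatrixGenConfig:
    """Planted-structure interaction matrix parameters.

    ``n_hosts`` x ``n_phages`` cells are divided into ``n_modules``
    near-equal diagonal blocks filled at ``within_fill`` (off-block at
    ``between_fill``); ``n_singletons`` exclusive one-to-one pairs and an
    optional square strictly nested block add fresh rows/columns.
    """

    n_hosts: int = 40
    n_phages: int = 40
    n_modules: int = 4
    within_fill: float = 0.9
    between_fill: float = 0.01
    n_singletons: int = 0
    nested_block: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.between_fill <= self.within_fill <= 1:
            raise ValueError("need 0 <= between_fill <= within_fill <= 1")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.n_hosts < self.n_modules or self.n_phages < self.n_modules:
            raise ValueError("each planted module needs >= 1 host and >= 1 phage")
        if self.nested_block is not None:
            r, c = self.nested_block
            if r != c or r < 2:
                raise ValueError(
                    "nested_block must be square with side >= 2 (strict triangle)"
                )


def _block_sizes(total: int, blocks: int) -> list[int]:
    base, extra = divmod(total, blocks)
    return [base + (1 if i < extra else 0) for i in range(blocks)]


def generate_matrix(config: MatrixGenConfig) -> tuple[InteractionMatrix, ModulePartition]:
    """Generate a matrix with planted modules; returns it with ground truth.

    Module blocks are laid out contiguously, then rows and columns are
    shuffled (seeded).  Singleton pairs and the nested block occupy fresh
    exclusive rows/columns and carry their own ground-truth module labels
    (the nested block is one module).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nested = cfg.nested_block or (0, 0)
    H = cfg.n_hosts + cfg.n_singletons + nested[0]
    P = cfg.n_phages + cfg.n_singletons + nested[1]
    cells = np.zeros((H, P), dtype=np.int8)
    host_labels = np.empty(H, dtype=int)
    phage_labels = np.empty(P, dtype=int)

    hsizes = _block_sizes(cfg.n_hosts, cfg.n_modules)
    psizes = _block_sizes(cfg.n_phages, cfg.n_modules)
    core = cells[: cfg.n_hosts, : cfg.n_phages]
    core[:] = rng.random(core.shape) < cfg.between_fill
    h0 = p0 = 0
    for b, (hs, ps) in enumerate(zip(hsizes, psizes)):
        core[h0 : h0 + hs, p0 : p0 + ps] = rng.random((hs, ps)) < cfg.within_fill
        host_labels[h0 : h0 + hs] = b
        phage_labels[p0 : p0 + ps] = b
        h0 += hs
        p0 += ps

    label = cfg.n_modules
    r, c = nested
    if r:
        # strict triangle: row i of the block kills columns 0..r-i-1, so row
        # and column degrees both decrease strictly and stand-alone NODF = 1
        for i in range(r):
            cells[cfg.n_hosts + i, cfg.n_phages : cfg.n_phages + r - i] = 1
        host_labels[cfg.n_hosts : cfg.n_hosts + r] = label
        phage_labels[cfg.n_phages : cfg.n_phages + c] = label
        label += 1
    for s in range(cfg.n_singletons):
        i, j = cfg.n_hosts + r + s, cfg.n_phages + c + s
        cells[i, j] = 1
        host_labels[i] = label
        phage_labels[j] = label
        label += 1

    hperm = rng.permutation(H)
    pperm = rng.permutation(P)
    cells = cells[hperm][:, pperm]
    host_labels = host_labels[hperm]
    phage_labels = phage_labels[pperm]
    hosts = tuple(f"H{i:04d}" for i in range(H))
    phages = tuple(f"P{j:04d}" for j in range(P))
    m = InteractionMatrix(hosts, phages, cells)
    part = ModulePartition(
        host_assignment=dict(zip(hosts, map(int, host_labels))),
        phage_assignment=dict(zip(phages, map(int, phage_labels))),
        n_modules=label,
        Qb=float("nan"),
        Qr=float("nan"),
    )
    if m.n_interactions > 0:
        part = ModulePartition(
            part.host_assignment,
            part.phage_assignment,
            part.n_modules,
            barber_qb(m, part),
            interaction_ratio_qr(m, part),
        )
    return m, part


@dataclass(frozen=True)
class GenomeGenConfig:
    """Template-based genome generation parameters.

    ``taxonomy`` maps genus -> species -> member count.  Each species gets
    one random template of ``genome_length`` bases; members copy a seeded
    ``species_identity`` fraction of template positions and draw the rest
    uniformly from ACGT.  ``planted_transfers`` copies verbatim segments
    from a member of the donor group (species or genus label) into a member
    of the recipient group.  Genera in different ``no_flow_pools`` are
    regenerated until they share zero canonical ``k``-mers across pools.
    """

    taxonomy: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"G1": {"S1": 3, "S2": 2}, "G2": {"S3": 3}}
    )
    genome_length: int = 10_000
    species_identity: float = 0.98
    planted_transfers: tuple[tuple[str, str, int, int], ...] = ()
    no_flow_pools: tuple[tuple[str, ...], ...] = ()
    k: int = 25
    seed: int = 0
    morphotypes: dict[str, str] = field(default_factory=dict)
    life_histories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.species_identity <= 1:
            raise ValueError("species_identity must be in [0, 1]")
        for donor, recipient, length, count in self.planted_transfers:
            if length < self.k:
                raise ValueError(
                    f"transfer segment {length} shorter than k = {self.k}"
                )
        pooled = [g for pool in self.no_flow_pools for g in pool]
        if len(pooled) != len(set(pooled)):
            raise ValueError("a genus appears in more than one no-flow pool")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(4, size=length)]


def _genus_of(cfg: GenomeGenConfig, group: str) -> list[str]:
    """Members (genome ids) of a species- or genus-level group label."""
    out = []
    for genus, species_map in cfg.taxonomy.items():
        for species, count in species_map.items():
            if group in (genus, species):
                out.extend(f"{species}_m{i}" for i in range(count))
    if not out:
        raise ValueError(f"unknown group {group!r} in planted transfer")
    return out


def generate_genomes(
    config: GenomeGenConfig, max_retries: int = 20
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate genomes and their annotation table.

    Returns ``(records, annotations)`` where records are ``(genome_id,
    sequence)`` in taxonomy order and annotations carry species, genus,
    morphotype and life-history labels.  Cross-pool zero k-mer sharing is
    enforced by rejection (regenerate with a fresh subseed, bounded by
    ``max_retries``).
    """
    cfg = config
    genus_of = {
        sp: genus for genus, species_map in cfg.taxonomy.items() for sp in species_map
    }
    pool_of = {g: i for i, pool in enumerate(cfg.no_flow_pools) for g in pool}
    for donor, recipient, _, _ in cfg.planted_transfers:
        gd = genus_of.get(donor, donor)
        gr = genus_of.get(recipient, recipient)
        if pool_of.get(gd) != pool_of.get(gr):
            raise ValueError(
                f"planted transfer {donor}->{recipient} crosses no-flow pools"
            )

    for attempt in range(max_retries):
        rng = np.random.default_rng((cfg.seed, attempt))
        genomes: dict[str, np.ndarray] = {}
        for genus, species_map in cfg.taxonomy.items():
            for species, count in species_map.items():
                template = _random_seq(rng, cfg.genome_length)
                n_copy = int(round(cfg.species_identity * cfg.genome_length))
                for i in range(count):
                    member = _random_seq(rng, cfg.genome_length)
                    keep = rng.choice(cfg.genome_length, size=n_copy, replace=False)
                    member[keep] = template[keep]
                    genomes[f"{species}_m{i}"] = member
        for donor, recipient, length, count in cfg.planted_transfers:
            donors = _genus_of(cfg, donor)
            recipients = _genus_of(cfg, recipient)
            for _ in range(count):
                src = genomes[donors[rng.integers(len(donors))]]
                dst = genomes[recipients[rng.integers(len(recipients))]]
                start = int(rng.integers(len(src) - length + 1))
                at = int(rng.integers(len(dst) - length + 1))
                dst[at : at + length] = src[start : start + length]

        if _no_flow_ok(cfg, genomes, genus_of, pool_of):
            break
    else:
        raise RuntimeError(
            f"could not satisfy no-flow pools after {max_retries} regenerations"
        )

    records = [(gid, seq.tobytes().decode()) for gid, seq in genomes.items()]
    morpho_cycle = {
        genus: cfg.morphotypes.get(genus, _MORPHOTYPE_CYCLE[i % len(_MORPHOTYPE_CYCLE)])
        for i, genus in enumerate(cfg.taxonomy)
    }
    annotations = pd.DataFrame(
        {
            "phage_id": [gid for gid, _ in records],
            "species_group": [gid.rsplit("_m", 1)[0] for gid, _ in records],
        }
    )
    annotations["genus_group"] = annotations["species_group"].map(genus_of)
    annotations["morphotype"] = annotations["genus_group"].map(morpho_cycle)
    annotations["life_history"] = annotations["genus_group"].map(
        lambda g: cfg.life_histories.get(g, "unknown")
    )
    return records, annotations


def _no_flow_ok(cfg, genomes, genus_of, pool_of) -> bool:
    if not cfg.no_flow_pools:
        return True
    pool_kmers: dict[int, set[str]] = {}
    for gid, seq in genomes.items():
        genus = genus_of[gid.rsplit("_m", 1)[0]]
        if genus not in pool_of:
            continue
        pool_kmers.setdefault(pool_of[genus], set()).update(
            kmer_profile(gid, seq.tobytes().decode(), k=cfg.k).kmers
        )
    pools = list(pool_kmers.values())
    return all(
        not (pools[i] & pools[j])
        for i in range(len(pools))
        for j in range(i + 1, len(pools))
    )


@dataclass(frozen=True)
class HostRangeGenConfig:
    """Two-level taxonomy host-range matrix parameters.

    Each species draws a template of ``kills_per_species`` hosts; species in
    the same genus share ``genus_overlap`` of their template hosts (a genus
    core), the rest being species-exclusive.  Members flip each template bit
    with probability ``noise`` and are redrawn (bounded) if left with zero
    kills.
    """

    taxonomy: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"G1": {"S1": 4, "S2": 3}, "G2": {"S3": 4, "S4": 3}}
    )
    n_hosts: int = 40
    kills_per_species: int = 5
    genus_overlap: float = 0.0
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must be in [0, 1]")
        if not 0 <= self.genus_overlap <= 1:
            raise ValueError("genus_overlap must be in [0, 1]")
        if self.n_hosts < 2 and self.noise > 0:
            raise ValueError("noisy profiles on a < 2 host universe are degenerate")


def generate_host_range_groups(
    config: HostRangeGenConfig, max_retries: int = 100
) -> tuple[InteractionMatrix, pd.DataFrame]:
    """Generate an interaction matrix with species-structured phage columns."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_core = int(round(cfg.genus_overlap * cfg.kills_per_species))
    n_unique = cfg.kills_per_species - n_core
    needed = sum(
        n_core + n_unique * len(species_map) for species_map in cfg.taxonomy.values()
    )
    if needed > cfg.n_hosts:
        raise ValueError(
            f"taxonomy needs {needed} template hosts but only {cfg.n_hosts} exist"
        )
    free = list(rng.permutation(cfg.n_hosts))
    templates: dict[str, np.ndarray] = {}
    genus_of: dict[str, str] = {}
    for genus, species_map in cfg.taxonomy.items():
        core = [free.pop() for _ in range(n_core)]
        for species in species_map:
            genus_of[species] = genus
            hosts = core + [free.pop() for _ in range(n_unique)]
            t = np.zeros(cfg.n_hosts, dtype=np.int8)
            t[hosts] = 1
            templates[species] = t

    phage_ids = []
    columns = []
    for genus, species_map in cfg.taxonomy.items():
        for species, count in species_map.items():
            for i in range(count):
                for _ in range(max_retries):
                    x = templates[species].copy()
                    flips = rng.random(cfg.n_hosts) < cfg.noise
                    x[flips] = 1 - x[flips]
                    if x.sum() >= 1:
                        break
                else:
                    raise RuntimeError("member resampling failed to yield >= 1 kill")
                phage_ids.append(f"{species}_m{i}")
                columns.append(x)
    cells = np.stack(columns, axis=1)
    hosts = tuple(f"H{i:04d}" for i in range(cfg.n_hosts))
    m = InteractionMatrix(hosts, tuple(phage_ids), cells)
    morpho_cycle = {
        genus: _MORPHOTYPE_CYCLE[i % len(_MORPHOTYPE_CYCLE)]
        for i, genus in enumerate(cfg.taxonomy)
    }
    annotations = pd.DataFrame(
        {
            "phage_id": phage_ids,
            "species_group": [p.rsplit("_m", 1)[0] for p in phage_ids],
        }
    )
    annotations["genus_group"] = annotations["species_group"].map(genus_of)
    annotations["morphotype"] = annotations["genus_group"].map(morpho_cycle)
    annotations["life_history"] = "unknown"
    return m, annotations
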