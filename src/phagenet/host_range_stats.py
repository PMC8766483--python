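"""Host-range concordance and group-comparison statistics.

The central quantity is the scaled host range divergence D_h of a group of
phages: each phage's binary kill vector over the m assayed hosts is
normalized to a probability distribution p_i = x_i / sum(x_i), and

    D_h = gJSD(p_1, ..., p_n) / log2(n)

where gJSD is the generalized Jensen-Shannon divergence in bits (entropy of
the mean distribution minus mean of the entropies).  D_h = 0 means all host
ranges coincide; D_h = 1 means they are pairwise disjoint.  Concordance is
1 - D_h.

The module also carries the accompanying comparisons: Welch's t-test between
species- and genus-level concordances, per-morphotype kill-breadth summaries
with pairwise Student's t-tests, a two-sample Kolmogorov-Smirnov test for
life-history strategy, the r/m recombination-to-mutation composition with a
one-sample Wilcoxon test against 1, and Spearman correlation between
concordance and r/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import InteractionMatrix, validate_annotations

__all__ = [
    "HostRangeProfile",
    "ConcordanceResult",
    "RMRecord",
    "host_range_profiles",
    "scaled_divergence",
    "group_concordance",
    "compare_levels",
    "morphotype_kill_stats",
    "life_history_ks",
    "rm_value",
    "rm_group_test",
    "concordance_rm_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HostRangeProfile:
    """One phage's kill vector and its probability-normalized form."""

    phage_id: str
    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if not np.all((x == 0) | (x == 1)):
            raise ValueError(f"kill vector of {self.phage_id!r} is not binary")
        x.setflags(write=False)
        object.__setattr__(self, "x", x)

    @property
    def n_kills(self) -> int:
        return int(self.x.sum())

    @property
    def p(self) -> np.ndarray:
        if self.n_kills == 0:
            raise ValueError(f"phage {self.phage_id!r} kills no host; p undefined")
        return self.x / self.x.sum()


@dataclass(frozen=True)
class ConcordanceResult:
    group_id: str
    level: str  # "species" | "genus"
    mode: str  # "all_members" | "single_representative"
    n: int
    D_h: float
    concordance: float


@dataclass(frozen=True)
class SimpleTestResult:
    """Degenerate-case stand-in mirroring scipy's (statistic, pvalue) shape."""

    statistic: float
    pvalue: float


@dataclass(frozen=True)
class RMRecord:
    """r/m = (R/theta) * delta * nu: relative contribution of homologous
    recombination versus mutation to sequence divergence."""

    group_id: str
    R_over_theta: float
    delta: float
    nu: float
    r_over_m: float


def host_range_profiles(m: InteractionMatrix) -> dict[str, HostRangeProfile]:
    """Per-phage profiles over the matrix's host axis, in column order."""
    cells = np.asarray(m.cells)
    return {
        p: HostRangeProfile(p, cells[:, j]) for j, p in enumerate(m.phage_ids)
    }


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def scaled_divergence(profiles: list[HostRangeProfile]) -> float:
    """Scaled host range divergence D_h of >= 2 profiles, in [0, 1]."""
    if len(profiles) < 2:
        raise ValueError("D_h needs at least 2 profiles")
    lengths = {len(pr.x) for pr in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles span different host sets")
    for pr in profiles:
        if pr.n_kills == 0:
            raise ValueError(f"phage {pr.phage_id!r} kills no host; excluded from D_h")
    P = np.stack([pr.p for pr in profiles])
    mixture = P.mean(axis=0)
    gjsd = _entropy_bits(mixture) - float(np.mean([_entropy_bits(row) for row in P]))
    d = gjsd / np.log2(len(profiles))
    return float(min(max(d, 0.0), 1.0))  # clip fp noise at the boundaries


def group_concordance(
    m: InteractionMatrix,
    annotations: pd.DataFrame,
    level: str = "species",
    mode: str = "all_members",
    seed: int = 0,
) -> list[ConcordanceResult]:
    """Concordance (1 - D_h) per species or genus group.

    ``mode="single_representative"`` draws one phage per species within each
    genus (uniformly, seeded) before computing D_h — the guard against
    intra-species blooms inflating genus-level concordance.  Groups with
    fewer than 2 usable members are skipped with a log record.  Phages with
    zero kills are excluded before normalization.
    """
    if level not in ("species", "genus"):
        raise ValueError(f"level must be 'species' or 'genus', got {level!r}")
    if mode not in ("all_members", "single_representative"):
        raise ValueError(f"unknown mode {mode!r}")
    if level == "species" and mode == "single_representative":
        raise ValueError("single_representative mode applies at the genus level")
    validate_annotations(annotations)
    ann = annotations.set_index("phage_id")
    missing = [p for p in m.phage_ids if p not in ann.index]
    if missing:
        raise ValueError(f"matrix phages missing from annotations: {missing}")

    profiles = host_range_profiles(m)
    usable = {p: pr for p, pr in profiles.items() if pr.n_kills >= 1}
    dropped = sorted(set(profiles) - set(usable))
    if dropped:
        logger.info("excluding %d zero-kill phages: %s", len(dropped), dropped)

    group_col = "species_group" if level == "species" else "genus_group"
    rng = np.random.default_rng(seed)
    results = []
    groups: dict[str, list[str]] = {}
    for p in m.phage_ids:  # matrix column order keeps the draw deterministic
        if p in usable:
            groups.setdefault(str(ann.at[p, group_col]), []).append(p)
    for gid, members in groups.items():
        if mode == "single_representative":
            by_species: dict[str, list[str]] = {}
            for p in members:
                by_species.setdefault(str(ann.at[p, "species_group"]), []).append(p)
            members = [sp_members[rng.integers(len(sp_members))] for sp_members in by_species.values()]
        if len(members) < 2:
            logger.info("skipping %s %r: %d usable member(s)", level, gid, len(members))
            continue
        d = scaled_divergence([usable[p] for p in members])
        results.append(
            ConcordanceResult(
                group_id=gid, level=level, mode=mode, n=len(members), D_h=d, concordance=1.0 - d
            )
        )
    return results


def compare_levels(species_concordances, genus_concordances):
    """Two-sided Welch's t-test between species- and genus-level concordances."""
    a = np.asarray(species_concordances, dtype=float)
    b = np.asarray(genus_concordances, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        # zero variance in both samples: t is 0/0; identical means -> p = 1
        equal = a.mean() == b.mean()
        return SimpleTestResult(0.0 if equal else np.inf, 1.0 if equal else 0.0)
    return stats.ttest_ind(a, b, equal_var=False)


def morphotype_kill_stats(
    m: InteractionMatrix, annotations: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kill-breadth summary per morphotype plus pairwise Student's t-tests.

    Returns ``(summary, tests)``: per-morphotype n / mean / sd (ddof=1) of
    strains killed, and two-sided equal-variance t-tests for every pair of
    morphotypes with >= 2 phages each.
    """
    validate_annotations(annotations)
    ann = annotations.set_index("phage_id")
    missing = [p for p in m.phage_ids if p not in ann.index]
    if missing:
        raise ValueError(f"matrix phages missing from annotations: {missing}")
    kills = np.asarray(m.cells).sum(axis=0)
    frame = pd.DataFrame(
        {
            "phage_id": m.phage_ids,
            "morphotype": [ann.at[p, "morphotype"] for p in m.phage_ids],
            "strains_killed": kills,
        }
    )
    summary = (
        frame.groupby("morphotype")["strains_killed"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    testable = summary.loc[summary["n"] >= 2, "morphotype"].tolist()
    rows = []
    for i, a in enumerate(testable):
        for b in testable[i + 1 :]:
            res = stats.ttest_ind(
                frame.loc[frame["morphotype"] == a, "strains_killed"],
                frame.loc[frame["morphotype"] == b, "strains_killed"],
                equal_var=True,
            )
            rows.append({"group_a": a, "group_b": b, "t": res.statistic, "p": res.pvalue})
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    # identical groups give nan from a zero pooled variance; report t=0, p=1
    tests[["t", "p"]] = tests[["t", "p"]].fillna({"t": 0.0, "p": 1.0})
    return summary, tests


def life_history_ks(kill_breadths_temperate, kill_breadths_virulent):
    """Two-sample two-sided Kolmogorov-Smirnov test of kill-breadth distributions."""
    a = np.asarray(kill_breadths_temperate, dtype=float)
    b = np.asarray(kill_breadths_virulent, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    return stats.ks_2samp(a, b, alternative="two-sided")


def rm_value(group_id: str, R_over_theta: float, delta: float, nu: float) -> RMRecord:
    """Compose r/m from the recombination-to-mutation rate ratio R/theta,
    the mean import length delta (bases) and the import nucleotide distance nu."""
    for name, v in (("R_over_theta", R_over_theta), ("delta", delta), ("nu", nu)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return RMRecord(group_id, R_over_theta, delta, nu, R_over_theta * delta * nu)


def rm_group_test(rm_values):
    """One-sample Wilcoxon signed-rank test of r/m values against 1.

    Two-sided, exact null distribution for n <= 25.  All values exactly 1
    carry no information and raise.
    """
    v = np.asarray(rm_values, dtype=float)
    diffs = v - 1.0
    if not np.any(diffs != 0):
        raise ValueError("all r/m values equal 1: no information against the null")
    method = "exact" if len(diffs) <= 25 else "auto"
    return stats.wilcoxon(diffs, alternative="two-sided", method=method)


def concordance_rm_correlation(concordances, rm_values):
    """Spearman rank correlation (average-rank ties) of concordance vs r/m,
    paired by group.  Constant input yields rho = nan (flagged by the caller)."""
    a = np.asarray(concordances, dtype=float)
    b = np.asarray(rm_values, dtype=float)
    if len(a) != len(b):
        raise ValueError("samples must be paired")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    return stats.spearmanr(a, b)
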