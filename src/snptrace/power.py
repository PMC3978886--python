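"""Discriminatory power of a SNP identity panel.

Model
-----
Each panel SNP *s* has allele frequency ``p_s`` and genotypes are drawn
under Hardy-Weinberg equilibrium (dosage ~ Binomial(2, p_s)),
independently across SNPs and across individuals.  Two independent
individuals then share a genotype at SNP *s* with probability

    m(p) = (p^2)^2 + (2 p q)^2 + (q^2)^2,   q = 1 - p,

which is minimised at m(1/2) = 3/8.  Whole profiles match with
probability ``P_match = prod_s m(p_s)`` and a cohort of *n* individuals
contains ``E[C] = n (n-1)/2 * P_match`` expected *collisions* (matching
unordered pairs; a profile shared by k samples contributes k(k-1)/2).

The Monte-Carlo engine simulates whole cohorts and counts collisions
per replicate dataset, reproducing the analytic expectation and giving
the across-replicate spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import PanelSNP, Profile

__all__ = [
    "AFVector",
    "PowerEstimate",
    "per_snp_match_prob",
    "profile_match_prob",
    "expected_collisions",
    "mismatch_moments",
    "simulate_profiles",
    "simulate_collisions",
    "size_curve",
    "dropout_analysis",
    "panel_afs",
]


@dataclass(frozen=True)
class AFVector:
    """Ordered allele frequencies, one per panel SNP."""

    freqs: tuple[float, ...]
    population: str = ""

    def __post_init__(self) -> None:
        for p in self.freqs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"allele frequency out of [0,1]: {p}")

    def __len__(self) -> int:
        return len(self.freqs)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


@dataclass
class PowerEstimate:
    """Analytic and simulated collision statistics for one panel/AF set."""

    population: str
    per_snp_match: np.ndarray
    p_match: float
    n: int
    expected_collisions: float
    sim_mean: float | None = None
    sim_sd: float | None = None
    sim_frac_any: float | None = None
    replicates: int = 0
    extras: dict = field(default_factory=dict)


def _as_af_array(afs: AFVector | Sequence[float] | np.ndarray) -> np.ndarray:
    arr = afs.array if isinstance(afs, AFVector) else np.asarray(afs, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("allele-frequency vector must be 1-D and non-empty")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("allele frequencies must lie in [0,1]")
    return arr


def panel_afs(panel: Sequence[PanelSNP], population: str) -> AFVector:
    """AFVector for one population column of a panel.

    ``population="perfect"`` gives the hypothetical ideal panel with
    every frequency 0.5.
    """
    if population == "perfect":
        return AFVector(tuple(0.5 for _ in panel), "perfect")
    try:
        freqs = tuple(s.afs[population] for s in panel)
    except KeyError as exc:
        raise KeyError(
            f"population {population!r} not annotated on every panel SNP"
        ) from exc
    return AFVector(freqs, population)


def per_snp_match_prob(p: float | np.ndarray) -> float | np.ndarray:
    """P(two independent HWE genotypes identical) at allele frequency p."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"allele frequency out of [0,1]: {p}")
    q = 1.0 - arr
    m = (arr**2) ** 2 + (2 * arr * q) ** 2 + (q**2) ** 2
    return float(m) if np.isscalar(p) or arr.ndim == 0 else m


def profile_match_prob(afs: AFVector | Sequence[float]) -> float:
    """P(two independent individuals share the entire profile)."""
    return float(np.prod(per_snp_match_prob(_as_af_array(afs))))


def expected_collisions(afs: AFVector | Sequence[float], n: int) -> float:
    """Expected matching unordered pairs in a cohort of n individuals."""
    if n < 2:
        raise ValueError(f"cohort size must be >= 2, got {n}")
    return n * (n - 1) / 2 * profile_match_prob(afs)


def mismatch_moments(afs: AFVector | Sequence[float]) -> tuple[float, float]:
    """Mean and variance of the pairwise allelic mismatch count.

    The per-SNP allelic difference d = |G1 - G2| between two independent
    HWE genotypes takes values 0, 1, 2 with

        P(d=0) = m(p),  P(d=2) = 2 p^2 q^2,  P(d=1) = 1 - P(0) - P(2),

    and the panel total is the sum of independent per-SNP terms.
    """
    p = _as_af_array(afs)
    q = 1.0 - p
    p0 = per_snp_match_prob(p)
    p2 = 2 * (p**2) * (q**2)
    p1 = 1.0 - p0 - p2
    mean = p1 + 2 * p2
    var = p1 + 4 * p2 - mean**2
    return float(np.sum(mean)), float(np.sum(var))


def _draw_dosages(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n HWE genotype rows over the SNPs of p, as an int8 matrix.

    Inverse-CDF categorical draw over genotype probabilities
    (q^2, 2pq, p^2): distributionally identical to Binomial(2, p) but a
    single uniform per genotype.
    """
    q = 1.0 - p
    c0 = q * q          # P(dosage = 0)
    c1 = c0 + 2 * p * q  # P(dosage <= 1)
    u = rng.random((n, p.size))
    return (u >= c0).view(np.int8) + (u >= c1).view(np.int8)


def simulate_profiles(
    afs: AFVector | Sequence[float],
    n: int,
    seed: int,
    sample_prefix: str = "S",
) -> list[Profile]:
    """Simulate n independent HWE profiles (dosage ~ Binomial(2, p_s))."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = _as_af_array(afs)
    d = _draw_dosages(p, n, np.random.default_rng(seed))
    width = len(str(n))
    return [Profile(f"{sample_prefix}{i+1:0{width}d}", d[i]) for i in range(n)]


def _collision_count(dosages: np.ndarray) -> int:
    """Matching unordered pairs among the rows of a dosage matrix."""
    n_snps = dosages.shape[1]
    if n_snps > 39:  # 3^40 overflows int64; fall back to row hashing
        codes = np.array(
            [hash(row.tobytes()) for row in np.ascontiguousarray(dosages)]
        )
    else:
        powers = 3 ** np.arange(n_snps, dtype=np.int64)
        codes = dosages.astype(np.int64) @ powers
    codes.sort(kind="stable")
    boundaries = np.flatnonzero(np.diff(codes) != 0)
    counts = np.diff(np.concatenate(([0], boundaries + 1, [codes.size])))
    return int((counts * (counts - 1) // 2).sum())


def simulate_collisions(
    afs: AFVector | Sequence[float],
    n: int,
    replicates: int,
    seed: int,
) -> tuple[float, float, float]:
    """Monte-Carlo collision statistics across replicate cohorts.

    Each replicate simulates a fresh cohort of ``n`` HWE profiles and
    counts its collisions.  Returns ``(mean, sd, frac_any)``: the mean
    and SD of per-dataset collision counts across replicates and the
    fraction of datasets containing at least one collision.

    Each replicate uses an RNG stream derived from ``(seed, replicate
    index)``, so results for early replicates are unchanged when
    ``replicates`` grows.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    p = _as_af_array(afs)
    counts = np.empty(replicates, dtype=np.int64)
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        counts[rep] = _collision_count(_draw_dosages(p, n, rng))
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if replicates > 1 else 0.0
    return mean, sd, float((counts > 0).mean())


def estimate_power(
    afs: AFVector,
    n: int,
    replicates: int = 0,
    seed: int = 0,
) -> PowerEstimate:
    """Analytic (and optionally simulated) power summary for one AF set."""
    p = _as_af_array(afs)
    est = PowerEstimate(
        population=afs.population if isinstance(afs, AFVector) else "",
        per_snp_match=per_snp_match_prob(p),
        p_match=profile_match_prob(p),
        n=n,
        expected_collisions=expected_collisions(p, n),
    )
    if replicates:
        est.sim_mean, est.sim_sd, est.sim_frac_any = simulate_collisions(
            p, n, replicates, seed
        )
        est.replicates = replicates
    return est


def size_curve(
    afs: AFVector | Sequence[float],
    sizes: Sequence[int],
    replicates: int = 0,
    seed: int = 0,
) -> list[dict]:
    """Expected (and optionally simulated) collisions per cohort size.

    ``sizes`` must be ascending; the analytic curve is monotone
    non-decreasing since E[C] scales as n(n-1)/2.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    out = []
    for n in sizes:
        row = {"n": int(n), "expected_collisions": expected_collisions(afs, n)}
        if replicates:
            mean, sd, frac = simulate_collisions(afs, n, replicates, seed)
            row.update(sim_mean=mean, sim_sd=sd, sim_frac_any=frac)
        out.append(row)
    return out


def cohort_size_for_one_collision(afs: AFVector | Sequence[float]) -> float:
    """Cohort size at which one collision is expected (E[C] = 1).

    Solves n(n-1)/2 * P_match = 1 for n.
    """
    pm = profile_match_prob(afs)
    return 0.5 * (1.0 + math.sqrt(1.0 + 8.0 / pm))


def dropout_analysis(afs: AFVector | Sequence[float], n: int = 10_000) -> dict:
    """Impact of total single-SNP dropout on discriminatory power.

    If SNP *s* yields no data, its factor m(p_s) leaves P_match, so the
    expected collision count rises by fold 1/m(p_s).  Since
    m(p) >= 3/8, no single SNP dropout can cost more than a 8/3-fold
    (< 3-fold) loss of discriminatory power.
    """
    p = _as_af_array(afs)
    if p.size < 2:
        raise ValueError("dropout analysis needs a panel of >= 2 SNPs")
    folds = 1.0 / per_snp_match_prob(p)
    base = expected_collisions(p, n)
    return {
        "per_snp_fold": folds,
        "max_fold": float(folds.max()),
        "argmax_snp": int(folds.argmax()),
        "baseline_expected_collisions": base,
        "worst_case_expected_collisions": float(base * folds.max()),
    }
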