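"""Synthetic cohorts, VCFs and design fixtures.

Everything downstream of panel design is testable without external
data: this module simulates a genotyping batch (truth profiles, a
sequencing-derived set with planted sample swaps, and an orthogonal
replicate set with independent noise), writes profiles as VCF, and
builds annotated candidate sets with a planted, known filter outcome.

The cohort scenario mirrors a routine QC workflow: a batch of samples
is exome sequenced while an orthogonal genotyping replicate plate is
made directly from the primary plate, so a downstream swap in one
pipeline shows up as a reciprocal discrepancy between the two
genotype sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import MISSING, PanelSNP, Profile
from .panel_design import PRIMARY_CRITERIA, CandidateVariant, FilterReport
from .power import AFVector, panel_afs, simulate_profiles

__all__ = ["ScenarioSpec", "generate_cohort", "write_vcf", "generate_design_fixture"]


@dataclass
class ScenarioSpec:
    """Plan for one synthetic genotyping batch.

    Planted events are ground truth, recorded in the ledger returned by
    :func:`generate_cohort`:

    swaps
        (i, j) index pairs whose profiles are exchanged in the
        sequencing set (a physical reciprocal transposition).
    duplicates
        (i, new_id): an extra sequencing sample that duplicates truth
        sample i under another identifier.
    missing_rate / error_rate
        Per-call rates of dropout and of symmetric genotyping error
        (dosage perturbed by +/-1, clipped to [0, 2]) applied to the
        orthogonal set.
    """

    n: int = 48
    population: str = "perfect"
    afs: AFVector | None = None
    swaps: Sequence[tuple[int, int]] = ()
    duplicates: Sequence[tuple[int, str]] = ()
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0
    sample_prefix: str = "S"

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for rate, name in ((self.missing_rate, "missing_rate"), (self.error_rate, "error_rate")):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        touched: set[int] = set()
        for i, j in self.swaps:
            if i == j:
                raise ValueError(f"swap ({i},{j}) is a no-op")
            for idx in (i, j):
                if not 0 <= idx < self.n:
                    raise ValueError(f"swap index {idx} out of range [0,{self.n})")
                if idx in touched:
                    raise ValueError(f"sample index {idx} planted in two swaps")
                touched.add(idx)
        for i, _ in self.duplicates:
            if not 0 <= i < self.n:
                raise ValueError(f"duplicate source index {i} out of range")


def _apply_noise(
    calls: np.ndarray, missing_rate: float, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    out = calls.copy()
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        delta = rng.choice((-1, 1), size=out.shape)
        perturbed = np.clip(out + delta, 0, 2).astype(np.int8)
        out = np.where(err & (out != MISSING), perturbed, out)
    if missing_rate > 0:
        out = np.where(rng.random(out.shape) < missing_rate, MISSING, out)
    return out.astype(np.int8)


def generate_cohort(
    spec: ScenarioSpec, panel: Sequence[PanelSNP]
) -> tuple[list[Profile], list[Profile], list[Profile], dict]:
    """Simulate a batch: truth, sequencing set and orthogonal set.

    Truth profiles are HWE draws from the scenario's AF source.  The
    sequencing set is the truth with planted swaps applied (and planted
    duplicates appended); the orthogonal set is the truth with
    independent missingness/error noise.  The returned ledger records
    every planted event for downstream verification.
    """
    spec.validate()
    afs = spec.afs if spec.afs is not None else panel_afs(panel, spec.population)
    if len(afs) != len(panel):
        raise ValueError("AF vector length does not match panel size")
    truth = simulate_profiles(afs, spec.n, spec.seed, spec.sample_prefix)
    ids = [p.sample_id for p in truth]

    seq_calls = {p.sample_id: p.calls.copy() for p in truth}
    for i, j in spec.swaps:
        seq_calls[ids[i]], seq_calls[ids[j]] = seq_calls[ids[j]], seq_calls[ids[i]]
    sequencing = [Profile(s, seq_calls[s]) for s in ids]
    for i, new_id in spec.duplicates:
        if new_id in seq_calls:
            raise ValueError(f"duplicate id {new_id!r} already present")
        sequencing.append(Profile(new_id, truth[i].calls.copy()))

    rng = np.random.default_rng([spec.seed, 0x0_0F])
    orthogonal = [
        Profile(p.sample_id, _apply_noise(p.calls, spec.missing_rate, spec.error_rate, rng))
        for p in truth
    ]
    ledger = {
        "n": spec.n,
        "population": afs.population,
        "seed": spec.seed,
        "sample_ids": ids,
        "swaps": [(ids[i], ids[j]) for i, j in spec.swaps],
        "duplicates": [(ids[i], new_id) for i, new_id in spec.duplicates],
        "missing_rate": spec.missing_rate,
        "error_rate": spec.error_rate,
    }
    return truth, sequencing, orthogonal, ledger


def write_vcf(
    profiles: Sequence[Profile],
    panel: Sequence[PanelSNP],
    path,
    swap_orientation_at: Sequence[int] = (),
) -> None:
    """Write profiles as a multi-sample VCF v4.2 at the panel loci.

    REF/ALT default to allele_a/allele_b; indices in
    ``swap_orientation_at`` are written with REF/ALT reversed (and GTs
    complemented) to exercise downstream allele harmonization.
    Missing calls become ``./.``.  Records are sorted by chromosome
    label and position.
    """
    for p in profiles:
        if len(p) != len(panel):
            raise ValueError(f"{p.sample_id}: profile/panel length mismatch")
    swap = set(swap_orientation_at)
    order = sorted(range(len(panel)), key=lambda i: (_chrom_key(panel[i].chrom), panel[i].pos))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(panel[i].chrom for i in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(p.sample_id for p in profiles)
            + "\n"
        )
        for i in order:
            snp = panel[i]
            if i in swap:
                ref, alt = snp.allele_b, snp.allele_a
                dose = lambda d: d if d == MISSING else 2 - d
            else:
                ref, alt = snp.allele_a, snp.allele_b
                dose = lambda d: d
            gts = "\t".join(gt_map[dose(int(p.calls[i]))] for p in profiles)
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def _chrom_key(chrom: str):
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# panel-design fixture

_POPS = ("CEU", "CHB", "JPT", "YRI")


def _passing_candidate(rng: np.random.Generator, idx: int) -> CandidateVariant:
    """A candidate satisfying every primary criterion by construction."""
    pair = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")][int(rng.integers(4))]
    return CandidateVariant(
        chrom=str(int(rng.integers(1, 23))),
        pos=int(rng.integers(1, 10_000_000)),
        rsid=f"rsFIX{idx:04d}",
        alleles=pair,
        pop_afs={p: round(float(rng.uniform(0.25, 0.75)), 2) for p in _POPS},
        flank_gc=float(rng.uniform(0.41, 0.54)),
        homopolymer_len=int(rng.integers(1, 5)),
        in_repeat=False,
        nearby_variants=[(int(rng.integers(60, 500)), 0.3)],
        consequence="synonymous",
        omim_flag=False,
        exon_distance=int(rng.integers(10, 200)),
        similarity_score=float(rng.uniform(0, 100)),
        gene=f"GENE{idx}",
    )


_BREAKERS = {
    "biallelic_non_complementary": lambda c, rng: _set(c, alleles=("A", "T")),
    "outside_repeats": lambda c, rng: _set(c, in_repeat=True),
    "no_homopolymer": lambda c, rng: _set(c, homopolymer_len=int(rng.integers(5, 12))),
    "flank_gc_band": lambda c, rng: _set(
        c, flank_gc=float(rng.choice([rng.uniform(0.0, 0.39), rng.uniform(0.56, 1.0)]))
    ),
    "no_common_neighbor": lambda c, rng: _set(
        c, nearby_variants=[(int(rng.integers(0, 51)), float(rng.uniform(0.01, 0.5)))]
    ),
    "af_band_all_populations": lambda c, rng: _set(
        c,
        pop_afs={**c.pop_afs, str(rng.choice(_POPS)): float(rng.choice([0.05, 0.9]))},
    ),
    "synonymous": lambda c, rng: _set(c, consequence="nonsynonymous"),
    "no_omim_record": lambda c, rng: _set(c, omim_flag=True),
}


def _set(cand: CandidateVariant, **kw) -> CandidateVariant:
    for k, v in kw.items():
        setattr(cand, k, v)
    return cand


def generate_design_fixture(
    seed: int,
    n_passing: int = 6,
    n_single_fail: int = 8,
    n_multi_fail: int = 4,
) -> tuple[list[CandidateVariant], FilterReport]:
    """Candidates with planted primary-criterion failures + the expected
    audit report.

    The expected :class:`FilterReport` is derived from the generation
    plan (which failures were planted where), not by running the
    cascade, so it can serve as an independent oracle for
    :func:`~snptrace.panel_design.apply_primary_filters`.
    """
    rng = np.random.default_rng(seed)
    names = [name for name, _, _ in PRIMARY_CRITERIA]
    candidates: list[CandidateVariant] = []
    planned_fail: list[set[str]] = []

    for i in range(n_passing):
        candidates.append(_passing_candidate(rng, len(candidates)))
        planned_fail.append(set())
    for i in range(n_single_fail):
        crit = names[i % len(names)]
        cand = _BREAKERS[crit](_passing_candidate(rng, len(candidates)), rng)
        candidates.append(cand)
        planned_fail.append({crit})
    for _ in range(n_multi_fail):
        picked = set(
            rng.choice(names, size=int(rng.integers(2, 4)), replace=False).tolist()
        )
        cand = _passing_candidate(rng, len(candidates))
        for crit in picked:
            cand = _BREAKERS[crit](cand, rng)
        candidates.append(cand)
        planned_fail.append(picked)

    # expected report straight from the plan
    import pandas as pd

    outcomes = pd.DataFrame(
        {name: [name not in fails for fails in planned_fail] for name in names},
        index=[c.rsid for c in candidates],
    )
    expected = FilterReport(outcomes=outcomes)
    n = len(candidates)
    class_of = {name: cls for name, cls, _ in PRIMARY_CRITERIA}
    for name in names:
        n_pass = int(outcomes[name].sum())
        expected.criteria.append((name, class_of[name], n, n_pass, n - n_pass))
    return candidates, expected
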