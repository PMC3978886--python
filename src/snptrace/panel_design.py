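"""Candidate SNP identification and panel selection.

A sample-identity panel for exome sequencing must consist of SNPs that
(i) every common capture kit actually sequences, (ii) both sequencing
and orthogonal assays genotype reliably, (iii) are common in all target
populations, and (iv) carry no phenotypic information.  This module
implements that selection as an auditable filter cascade over
pre-annotated candidate variants, plus the final prioritisation of
survivors by closeness of their allele frequencies to 0.5.

Primary criteria (defaults):

1. biallelic substitution, excluding complementary (A/T, G/C) pairs;
2. technically amenable: outside large-scale repeats, no homopolymer
   run of >= 5 bp at the site, flanking GC in [40%, 55%], no other
   variant with AF >= 0.01 within 50 bp;
3. allele frequency in [0.2, 0.8] in all target populations;
4. synonymous consequence and no disease-gene (OMIM) record.

Secondary criteria: >= 10 bp from exon boundaries; no off-target
alignment score above 100; pairwise linkage disequilibrium below
threshold among selected SNPs.

Every criterion is counted independently over the full input (a
variant failing several criteria is tallied under each), so the report
reproduces a per-criterion breakdown as well as the surviving set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import COMPLEMENTARY_PAIRS, VALID_BASES, PanelSNP, SnptraceError

__all__ = [
    "Region",
    "CandidateVariant",
    "FilterConfig",
    "FilterReport",
    "intersect_regions",
    "merge_regions",
    "read_bed",
    "total_length",
    "apply_primary_filters",
    "apply_secondary_filters",
    "prioritize",
]


class AnnotationIncompleteError(SnptraceError):
    """A candidate is missing an annotation a criterion requires."""


class PanelShortfallError(SnptraceError):
    """Fewer candidates than requested survive the selection constraints."""


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(start >= end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CandidateVariant:
    """A fully annotated variant flowing through the design cascade.

    Annotations are produced upstream (population AF tables, flanking
    sequence analysis, repeat masks, alignment scores); the cascade
    consumes them and never touches raw sequence.
    """

    chrom: str
    pos: int  # 1-based
    rsid: str
    alleles: tuple[str, str]
    pop_afs: Mapping[str, float] = field(default_factory=dict)
    flank_gc: float | None = None
    homopolymer_len: int | None = None
    in_repeat: bool | None = None
    nearby_variants: Sequence[tuple[int, float]] = ()  # (distance bp, AF)
    consequence: str | None = None  # synonymous | nonsynonymous | other
    omim_flag: bool | None = None
    exon_distance: int | None = None
    similarity_score: float | None = None
    ld_partners: Mapping[str, float] = field(default_factory=dict)  # rsid -> r2
    gene: str = ""


@dataclass
class FilterConfig:
    """Thresholds of the cascade; defaults are the published design."""

    homopolymer_max: int = 4          # fail at runs of >= 5 bp
    gc_range: tuple[float, float] = (0.40, 0.55)
    neighbor_window: int = 50         # bp
    neighbor_af: float = 0.01
    af_range: tuple[float, float] = (0.2, 0.8)
    populations: tuple[str, ...] = ("CEU", "CHB", "JPT", "YRI")
    required_consequence: str = "synonymous"
    min_exon_distance: int = 10       # bp
    max_similarity_score: float = 100.0
    ld_r2_max: float = 0.1
    ld_fallback_distance: int = 1_000_000  # bp, same-chromosome proximity rule

    @classmethod
    def from_mapping(cls, overrides: Mapping) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown filter config keys: {sorted(bad)}")
        cfg = cls(**overrides)
        # YAML gives lists where tuples are expected
        cfg.gc_range = tuple(cfg.gc_range)  # type: ignore[assignment]
        cfg.af_range = tuple(cfg.af_range)  # type: ignore[assignment]
        cfg.populations = tuple(cfg.populations)  # type: ignore[assignment]
        return cfg


@dataclass
class FilterReport:
    """Per-criterion audit of one cascade stage.

    ``criteria`` rows are (name, class, n_in, n_pass, n_fail) with
    n_in the full stage input; ``outcomes`` is the per-variant boolean
    table (rsid x criterion).
    """

    criteria: list[tuple[str, str, int, int, int]] = field(default_factory=list)
    outcomes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def survivors_mask(self) -> np.ndarray:
        return self.outcomes.all(axis=1).to_numpy()

    def class_summary(self) -> pd.DataFrame:
        """Counts aggregated into criterion classes (variants failing
        any criterion of a class count once per class)."""
        df = self.to_frame()
        rows = []
        for cls_name, grp in df.groupby("class", sort=False):
            cols = grp["criterion"].tolist()
            ok = self.outcomes[cols].all(axis=1)
            rows.append(
                {
                    "class": cls_name,
                    "n_in": len(self.outcomes),
                    "n_pass": int(ok.sum()),
                    "n_fail": int((~ok).sum()),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.criteria,
            columns=["criterion", "class", "n_in", "n_pass", "n_fail"],
        )

    def to_json_dict(self) -> dict:
        return {
            "criteria": self.to_frame().to_dict(orient="records"),
            "classes": self.class_summary().to_dict(orient="records"),
            "n_in": len(self.outcomes),
            "n_survivors": int(self.survivors_mask.sum()),
        }


# ---------------------------------------------------------------------------
# interval handling

def merge_regions(regions: Sequence[Region]) -> list[Region]:
    """Merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[Region] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for r in ivs[1:]:
            if r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                out.append(Region(chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        out.append(Region(chrom, cur_s, cur_e))
    return out


def _intersect_two(a: list[Region], b: list[Region]) -> list[Region]:
    """Intersect two merged, sorted interval lists (sweep per chromosome)."""
    out: list[Region] = []
    a_by: dict[str, list[Region]] = {}
    b_by: dict[str, list[Region]] = {}
    for r in a:
        a_by.setdefault(r.chrom, []).append(r)
    for r in b:
        b_by.setdefault(r.chrom, []).append(r)
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(Region(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def intersect_regions(region_sets: Sequence[Sequence[Region]]) -> list[Region]:
    """Maximal intervals present in every input set.

    Each input set is merged first, so overlapping intervals within a
    set are allowed.  The result is merged, sorted and disjoint; its
    total length is ``total_length(result)``.
    """
    if not region_sets:
        raise ValueError("need at least one region set")
    current = merge_regions(list(region_sets[0]))
    for other in region_sets[1:]:
        current = _intersect_two(current, merge_regions(list(other)))
        if not current:
            return []
    return current


def total_length(regions: Sequence[Region]) -> int:
    return sum(len(r) for r in regions)


def read_bed(path) -> list[Region]:
    """Read a BED file (0-based half-open) into Regions."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {lineno}: fewer than 3 BED columns")
            try:
                region = Region(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            out.append(region)
    return out


# ---------------------------------------------------------------------------
# filter cascade

def _require(cand: CandidateVariant, attr: str):
    val = getattr(cand, attr)
    if val is None:
        raise AnnotationIncompleteError(
            f"{cand.rsid}: required annotation {attr!r} is missing"
        )
    return val


def _crit_biallelic(cand: CandidateVariant, cfg: FilterConfig) -> bool:
    a, b = cand.alleles
    if a not in VALID_BASES or b not in VALID_BASES or a == b:
        return False
    return frozenset((a, b)) not in COMPLEMENTARY_PAIRS


def _crit_repeat(cand, cfg):
    return not _require(cand, "in_repeat")


def _crit_homopolymer(cand, cfg):
    return _require(cand, "homopolymer_len") <= cfg.homopolymer_max


def _crit_gc(cand, cfg):
    lo, hi = cfg.gc_range
    return lo <= _require(cand, "flank_gc") <= hi


def _crit_neighbors(cand, cfg):
    return not any(
        dist <= cfg.neighbor_window and af >= cfg.neighbor_af
        for dist, af in cand.nearby_variants
    )


def _crit_af_band(cand, cfg):
    lo, hi = cfg.af_range
    for pop in cfg.populations:
        if pop not in cand.pop_afs:
            raise AnnotationIncompleteError(
                f"{cand.rsid}: required annotation 'pop_afs[{pop}]' is missing"
            )
        if not lo <= cand.pop_afs[pop] <= hi:
            return False
    return True


def _crit_consequence(cand, cfg):
    return _require(cand, "consequence") == cfg.required_consequence


def _crit_omim(cand, cfg):
    return not _require(cand, "omim_flag")


PRIMARY_CRITERIA: list[tuple[str, str, Callable]] = [
    ("biallelic_non_complementary", "substitution", _crit_biallelic),
    ("outside_repeats", "technical", _crit_repeat),
    ("no_homopolymer", "technical", _crit_homopolymer),
    ("flank_gc_band", "technical", _crit_gc),
    ("no_common_neighbor", "technical", _crit_neighbors),
    ("af_band_all_populations", "allele_frequency", _crit_af_band),
    ("synonymous", "functional_neutrality", _crit_consequence),
    ("no_omim_record", "functional_neutrality", _crit_omim),
]


def _crit_exon_distance(cand, cfg):
    return _require(cand, "exon_distance") >= cfg.min_exon_distance


def _crit_similarity(cand, cfg):
    return _require(cand, "similarity_score") <= cfg.max_similarity_score


SECONDARY_CRITERIA: list[tuple[str, str, Callable]] = [
    ("exon_boundary_distance", "secondary", _crit_exon_distance),
    ("no_offtarget_similarity", "secondary", _crit_similarity),
]


def _run_criteria(
    candidates: Sequence[CandidateVariant],
    criteria: list[tuple[str, str, Callable]],
    cfg: FilterConfig,
) -> FilterReport:
    outcomes = pd.DataFrame(
        {
            name: [bool(fn(c, cfg)) for c in candidates]
            for name, _, fn in criteria
        },
        index=[c.rsid for c in candidates],
    )
    report = FilterReport(outcomes=outcomes)
    n = len(candidates)
    for name, cls_name, _ in criteria:
        n_pass = int(outcomes[name].sum())
        report.criteria.append((name, cls_name, n, n_pass, n - n_pass))
    return report


def apply_primary_filters(
    candidates: Sequence[CandidateVariant],
    config: FilterConfig | Mapping | None = None,
) -> tuple[list[CandidateVariant], FilterReport]:
    """Apply the primary selection criteria; audit every criterion.

    Each criterion is evaluated on the complete input so the report's
    per-criterion counts are independent of application order; the
    survivors are the variants passing all criteria.
    """
    cfg = _as_config(config)
    report = _run_criteria(candidates, PRIMARY_CRITERIA, cfg)
    survivors = [c for c, ok in zip(candidates, report.survivors_mask) if ok]
    return survivors, report


def _ld_prune(
    candidates: Sequence[CandidateVariant], cfg: FilterConfig
) -> list[bool]:
    """Greedy mutual-independence scan in input order.

    A candidate is kept unless it is in LD (r^2 >= threshold) with an
    already-kept candidate; with no LD annotation for a pair, nearby
    same-chromosome candidates (within the fallback distance) are
    treated as potentially linked.
    """
    kept: list[CandidateVariant] = []
    flags = []
    for cand in candidates:
        ok = True
        for prev in kept:
            r2 = cand.ld_partners.get(prev.rsid, prev.ld_partners.get(cand.rsid))
            if r2 is not None:
                if r2 >= cfg.ld_r2_max:
                    ok = False
                    break
            elif (
                cand.chrom == prev.chrom
                and abs(cand.pos - prev.pos) <= cfg.ld_fallback_distance
            ):
                ok = False
                break
        if ok:
            kept.append(cand)
        flags.append(ok)
    return flags


def apply_secondary_filters(
    candidates: Sequence[CandidateVariant],
    config: FilterConfig | Mapping | None = None,
) -> tuple[list[CandidateVariant], FilterReport]:
    """Apply the optimisation criteria: exon-boundary distance,
    off-target similarity, and mutual linkage-disequilibrium pruning."""
    cfg = _as_config(config)
    report = _run_criteria(candidates, SECONDARY_CRITERIA, cfg)
    # LD is pairwise, evaluated greedily over candidates passing the
    # per-variant criteria (order = input order).
    pre_ok = report.survivors_mask
    pre_survivors = [c for c, ok in zip(candidates, pre_ok) if ok]
    ld_flags_sub = _ld_prune(pre_survivors, cfg)
    ld_col = []
    it = iter(ld_flags_sub)
    for ok in pre_ok:
        ld_col.append(bool(next(it)) if ok else True)  # only judged if reached
    report.outcomes["ld_independent"] = ld_col
    n = len(candidates)
    n_pass = int(sum(ld_col))
    report.criteria.append(("ld_independent", "secondary", n, n_pass, n - n_pass))
    survivors = [c for c, ok in zip(candidates, report.survivors_mask) if ok]
    return survivors, report


def _as_config(config) -> FilterConfig:
    if config is None:
        return FilterConfig()
    if isinstance(config, FilterConfig):
        return config
    return FilterConfig.from_mapping(dict(config))


# ---------------------------------------------------------------------------
# prioritisation

def af_balance_score(cand: CandidateVariant, populations: Sequence[str]) -> float:
    """Sum over populations of |AF - 0.5|; lower = more discriminatory.

    Invariant under p <-> 1-p per population.
    """
    try:
        return float(sum(abs(cand.pop_afs[p] - 0.5) for p in populations))
    except KeyError as exc:
        raise AnnotationIncompleteError(
            f"{cand.rsid}: missing AF for population {exc.args[0]!r}"
        ) from exc


def prioritize(
    candidates: Sequence[CandidateVariant],
    k: int,
    max_per_chrom: int | None = None,
    config: FilterConfig | Mapping | None = None,
) -> list[PanelSNP]:
    """Select the k most discriminatory candidates as a panel.

    Candidates are ranked by :func:`af_balance_score` ascending (ties
    broken by rsid, so builds are deterministic) and picked greedily,
    honouring the per-chromosome cap and mutual LD independence.

    Raises
    ------
    PanelShortfallError
        If the constraints leave fewer than k eligible candidates.
    """
    cfg = _as_config(config)
    if k > len(candidates):
        raise PanelShortfallError(
            f"requested panel of {k} from {len(candidates)} candidates"
        )
    ranked = sorted(
        candidates,
        key=lambda c: (af_balance_score(c, cfg.populations), c.rsid),
    )
    chosen: list[CandidateVariant] = []
    per_chrom: dict[str, int] = {}
    for cand in ranked:
        if len(chosen) == k:
            break
        if max_per_chrom is not None and per_chrom.get(cand.chrom, 0) >= max_per_chrom:
            continue
        if not _ld_prune(chosen + [cand], cfg)[-1]:
            continue
        chosen.append(cand)
        per_chrom[cand.chrom] = per_chrom.get(cand.chrom, 0) + 1
    if len(chosen) < k:
        raise PanelShortfallError(
            f"only {len(chosen)} of the requested {k} SNPs satisfy the "
            "chromosome and linkage constraints"
        )
    return [
        PanelSNP(
            chrom=c.chrom,
            pos=c.pos,
            rsid=c.rsid,
            gene=c.gene,
            allele_a=c.alleles[0],
            allele_b=c.alleles[1],
            afs=dict(c.pop_afs),
        )
        for c in chosen
    ]
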