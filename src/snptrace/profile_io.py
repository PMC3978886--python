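"""Panel and profile input/output.

Loads the packaged 24-SNP identity panel (or a user panel in the same
TSV layout), extracts :class:`~snptrace.core.Profile` objects from VCF
files and from orthogonal genotype tables (e.g. KASP assay exports),
and reads/writes profile tables.

File formats
------------
Panel TSV
    Header ``chrom pos rsid gene allele_a allele_b af_CEU af_CHB
    af_JPT af_YRI``; ``#`` lines are comments.  Positions 1-based.
Genotype table TSV
    Header ``sample_id rsid call``; a call is an unordered allele pair
    such as ``AG`` or ``AA``, or ``--``/``NA``/``.`` for missing.
Profile table TSV
    Samples x rsids matrix of dosages, ``.`` for missing.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import (
    MISSING,
    AlignmentError,
    IncompatibleAlleleError,
    PanelIntegrityError,
    PanelSNP,
    Profile,
    encode_dosage,
    harmonize_site,
)

logger = logging.getLogger(__name__)

_PANEL_COLUMNS = ["chrom", "pos", "rsid", "gene", "allele_a", "allele_b"]
_MISSING_CALLS = {"--", "-", "NA", "N/A", ".", "..", "./.", "", "00", "0"}


def default_panel_path() -> Path:
    """Path of the packaged 24-SNP identity panel."""
    return Path(str(resources.files("snptrace").joinpath("data/panel24.tsv")))


def load_panel(path: str | Path | None = None) -> list[PanelSNP]:
    """Load a panel TSV; with no argument, the packaged 24-SNP panel.

    Enforces panel invariants at load time: valid non-complementary
    biallelic substitutions, AFs in [0, 1], unique rsids.
    """
    path = default_panel_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing_cols = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelIntegrityError(f"{path}: missing columns {missing_cols}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    panel: list[PanelSNP] = []
    for row in df.itertuples(index=False):
        afs = {c[3:]: float(getattr(row, c)) for c in af_cols}
        panel.append(
            PanelSNP(
                chrom=str(row.chrom),
                pos=int(row.pos),
                rsid=str(row.rsid),
                gene=str(row.gene),
                allele_a=str(row.allele_a),
                allele_b=str(row.allele_b),
                afs=afs,
            )
        )
    rsids = [s.rsid for s in panel]
    if len(set(rsids)) != len(rsids):
        dupes = sorted({r for r in rsids if rsids.count(r) > 1})
        raise PanelIntegrityError(f"{path}: duplicate rsids {dupes}")
    return panel


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def extract_from_vcf(
    vcf_path: str | Path,
    panel: Sequence[PanelSNP],
    absent_site_policy: str = "missing",
) -> list[Profile]:
    """Extract one Profile per VCF sample at the panel loci.

    Sites found in the VCF are orientation-harmonized against the panel
    (REF/ALT may list the alleles in either order).  Loci absent from
    the VCF are handled per ``absent_site_policy``:

    ``"missing"`` (default)
        Call is MISSING — appropriate for per-sample exome VCFs, which
        usually omit hom-ref sites.
    ``"assume_ref"``
        Dosage 0 in panel orientation — for all-sites VCFs.

    Half-calls, non-diploid GTs and allele-incompatible sites become
    MISSING with a logged warning.
    """
    if absent_site_policy not in ("missing", "assume_ref"):
        raise ValueError(f"unknown absent_site_policy {absent_site_policy!r}")
    vcf_path = str(vcf_path)
    vcf = pysam.VariantFile(vcf_path)
    samples = list(vcf.header.samples)
    if not samples:
        raise ValueError(f"{vcf_path}: VCF has no sample columns")
    loci = {(_norm_chrom(s.chrom), s.pos): i for i, s in enumerate(panel)}
    fill = 0 if absent_site_policy == "assume_ref" else MISSING
    dosages = np.full((len(samples), len(panel)), fill, dtype=np.int8)
    seen = np.zeros(len(panel), dtype=bool)

    for rec in vcf:
        key = (_norm_chrom(rec.chrom), rec.pos)
        idx = loci.get(key)
        if idx is None:
            continue
        snp = panel[idx]
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            logger.warning(
                "%s: site %s:%d is not a biallelic SNV; calls set to missing",
                vcf_path, rec.chrom, rec.pos,
            )
            dosages[:, idx] = MISSING
            seen[idx] = True
            continue
        try:
            orientation = harmonize_site(rec.ref, alts[0], snp)
        except Exception:
            logger.warning(
                "%s: alleles %s/%s at %s incompatible with panel %s/%s; "
                "calls set to missing",
                vcf_path, rec.ref, alts[0], snp.rsid,
                snp.allele_a, snp.allele_b,
            )
            dosages[:, idx] = MISSING
            seen[idx] = True
            continue
        for si, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                dosages[si, idx] = MISSING
                continue
            if any(a not in (0, 1) for a in gt):
                logger.warning(
                    "%s: sample %s GT %s at %s not biallelic diploid; missing",
                    vcf_path, sample, gt, snp.rsid,
                )
                dosages[si, idx] = MISSING
                continue
            raw = int(sum(gt))
            dosages[si, idx] = 2 - raw if orientation == "swapped" else raw
        seen[idx] = True
    vcf.close()

    for i, snp in enumerate(panel):
        n_called = int((dosages[:, i] != MISSING).sum())
        logger.info(
            "panel locus %s: %s in VCF, call rate %d/%d",
            snp.rsid, "present" if seen[i] else "absent", n_called, len(samples),
        )
    return [Profile(s, dosages[i]) for i, s in enumerate(samples)]


def read_genotype_table(path: str | Path, panel: Sequence[PanelSNP]) -> list[Profile]:
    """Read an orthogonal genotype table into panel-aligned Profiles.

    Rows are ``sample_id  rsid  call``; every rsid must be in the
    panel and each (sample, rsid) may appear once.  Loci without a row
    for a sample are MISSING.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    required = {"sample_id", "rsid", "call"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    index = {s.rsid: i for i, s in enumerate(panel)}
    samples: dict[str, np.ndarray] = {}
    seen: set[tuple[str, str]] = set()
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        rsid = row.rsid
        if rsid not in index:
            raise IncompatibleAlleleError(
                f"{path} line {rownum}: unknown rsid {rsid!r} (not in panel)"
            )
        if (row.sample_id, rsid) in seen:
            raise ValueError(
                f"{path} line {rownum}: duplicate call for "
                f"({row.sample_id}, {rsid})"
            )
        seen.add((row.sample_id, rsid))
        calls = samples.setdefault(
            row.sample_id, np.full(len(panel), MISSING, dtype=np.int8)
        )
        call = row.call.strip().upper()
        if call in _MISSING_CALLS:
            continue
        try:
            calls[index[rsid]] = encode_dosage(call, panel[index[rsid]])
        except IncompatibleAlleleError as exc:
            raise IncompatibleAlleleError(f"{path} line {rownum}: {exc}") from exc
    return [Profile(s, c) for s, c in samples.items()]


def write_genotype_table(
    profiles: Iterable[Profile], panel: Sequence[PanelSNP], path: str | Path
) -> None:
    """Write Profiles as a ``sample_id rsid call`` allele-pair table."""
    rows = []
    for p in profiles:
        if len(p) != len(panel):
            raise AlignmentError(f"{p.sample_id}: profile/panel length mismatch")
        for snp, d in zip(panel, p.calls):
            if d == MISSING:
                call = "--"
            else:
                call = snp.allele_a * (2 - int(d)) + snp.allele_b * int(d)
            rows.append((p.sample_id, snp.rsid, call))
    pd.DataFrame(rows, columns=["sample_id", "rsid", "call"]).to_csv(
        path, sep="\t", index=False
    )


def write_profile_table(
    profiles: Iterable[Profile], panel: Sequence[PanelSNP], path: str | Path
) -> None:
    """Write a samples x rsids dosage matrix TSV (``.`` for missing)."""
    profiles = list(profiles)
    data = {
        "sample_id": [p.sample_id for p in profiles],
    }
    for i, snp in enumerate(panel):
        col = [int(p.calls[i]) for p in profiles]
        data[snp.rsid] = ["." if d == MISSING else str(d) for d in col]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_profile_table(path: str | Path, panel: Sequence[PanelSNP]) -> list[Profile]:
    """Read a samples x rsids dosage matrix TSV back into Profiles."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [s.rsid for s in panel if s.rsid not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing panel columns {missing}")
    out = []
    for _, row in df.iterrows():
        calls = np.array(
            [
                MISSING if row[s.rsid] == "." else int(row[s.rsid])
                for s in panel
            ],
            dtype=np.int8,
        )
        out.append(Profile(row["sample_id"], calls))
    return out
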