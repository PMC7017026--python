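"""Readers and writers for the formats the pipeline touches.

Coordinate conventions
----------------------
Variant positions and segment coordinates are 1-based inclusive everywhere
inside the package (VCF convention).  Interval *tracks* and all BED output are
0-based half-open (BED convention).  The conversion happens only at the format
boundary, in :func:`write_bed` / :func:`read_bed`.

Only biallelic SNPs (single-base REF and ALT) enter the pipeline; indels and
multi-allelic records are dropped on read with a logged count.  Multi-sample
VCFs are rejected: the analysis is defined for a single congenic individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantCall",
    "GenomicSegment",
    "StrainPanel",
    "VcfFormatError",
    "CALL_COLUMNS",
    "GENOTYPES",
    "calls_to_frame",
    "frame_to_calls",
    "empty_calls",
    "read_vcf",
    "write_vcf",
    "write_bed",
    "read_bed",
    "read_strain_panel",
    "write_strain_panel",
]

log = logging.getLogger(__name__)

#: canonical column order of a call frame
CALL_COLUMNS = (
    "chromosome",
    "position",
    "ref",
    "alt",
    "genotype",
    "mapping_quality",
    "status_pass",
)

GENOTYPES = ("het", "hom_ref", "hom_alt", "missing")

_BASES = frozenset("ACGT")

#: cyvcf2 gt_types codes -> zygosity labels
_GT_CODE = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}

_GT_FIELD = {"het": "0/1", "hom_ref": "0/0", "hom_alt": "1/1", "missing": "./."}

#: FILTER string used for calls that failed the caller's internal status check
STATUS_FAIL_FILTER = "StatusFail"


class VcfFormatError(ValueError):
    """Raised for VCF content the pipeline does not support."""


@dataclass(frozen=True)
class VariantCall:
    """One called SNP site.

    ``mapping_quality`` is the per-site quality score carried in INFO/MQ; a
    missing score is represented as NaN (the call is retained on read but will
    not survive a quality filter).  ``status_pass`` is True iff FILTER is PASS.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    genotype: str
    mapping_quality: float
    status_pass: bool

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _BASES:
                raise ValueError(f"{name} allele {allele!r} is not a DNA string")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.genotype == "het" and self.ref == self.alt:
            raise ValueError("heterozygous call requires ref != alt")
        if not np.isnan(self.mapping_quality) and self.mapping_quality < 0:
            raise ValueError("mapping_quality must be non-negative")


def empty_calls() -> pd.DataFrame:
    """An empty call frame with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "chromosome": pd.Series(dtype=str),
            "position": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "genotype": pd.Series(dtype=str),
            "mapping_quality": pd.Series(dtype=float),
            "status_pass": pd.Series(dtype=bool),
        }
    )


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Pack :class:`VariantCall` records into the canonical call frame."""
    records = list(calls)
    if not records:
        return empty_calls()
    return pd.DataFrame([c.__dict__ for c in records], columns=list(CALL_COLUMNS))


def frame_to_calls(frame: pd.DataFrame) -> list[VariantCall]:
    """Unpack a call frame into validated :class:`VariantCall` records."""
    return [
        VariantCall(
            chromosome=str(r.chromosome),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            genotype=str(r.genotype),
            mapping_quality=float(r.mapping_quality),
            status_pass=bool(r.status_pass),
        )
        for r in frame.itertuples(index=False)
    ]


def read_vcf(path: str | Path, region: str | None = None) -> pd.DataFrame:
    """Read a single-sample VCF into a call frame.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped).
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (requires an
        index for compressed files; plain-text files are scanned).

    Returns
    -------
    pandas.DataFrame
        Columns :data:`CALL_COLUMNS`; one row per biallelic SNP record.

    Raises
    ------
    VcfFormatError
        If the file carries more than one sample.
    """
    vcf = VCF(str(path))
    try:
        if len(vcf.samples) != 1:
            raise VcfFormatError(
                f"{path}: expected exactly one sample, found {len(vcf.samples)} "
                f"({vcf.samples}); multi-sample VCFs are unsupported"
            )
        rows: list[tuple] = []
        n_non_snp = 0
        n_missing_mq = 0
        iterator = vcf(region) if region else vcf
        for rec in iterator:
            if len(rec.REF) != 1 or len(rec.ALT) != 1 or len(rec.ALT[0]) != 1:
                n_non_snp += 1
                continue
            if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
                n_non_snp += 1
                continue
            mq = rec.INFO.get("MQ")
            if mq is None:
                n_missing_mq += 1
                mq = np.nan
            rows.append(
                (
                    rec.CHROM,
                    rec.POS,
                    rec.REF,
                    rec.ALT[0],
                    _GT_CODE.get(int(rec.gt_types[0]), "missing"),
                    float(mq),
                    rec.FILTER is None,  # cyvcf2: None <=> PASS
                )
            )
    finally:
        vcf.close()
    if n_non_snp:
        log.info("%s: dropped %d non-SNP record(s)", path, n_non_snp)
    if n_missing_mq:
        log.warning(
            "%s: %d record(s) lack INFO/MQ; retained with mapping_quality=NaN",
            path,
            n_missing_mq,
        )
    if not rows:
        return empty_calls()
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="Per-site mapping quality score">
##FILTER=<ID={fail},Description="Failed the variant caller's internal status check">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    calls: pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    sample: str = "sample1",
) -> None:
    """Write a call frame as a minimal single-sample VCF v4.2.

    Records are sorted by (chromosome, position); chromosome order follows
    ``contig_lengths`` when given, else first appearance.  Mapping quality is
    written to INFO/MQ (integral values without a decimal point, so that
    write/read round-trips are exact for integer scores).
    """
    if contig_lengths is not None:
        order = {c: i for i, c in enumerate(contig_lengths)}
    else:
        order = {c: i for i, c in enumerate(dict.fromkeys(calls["chromosome"]))}
    frame = calls.sort_values(
        by=["chromosome", "position"],
        key=lambda s: s.map(order) if s.name == "chromosome" else s,
        kind="mergesort",
    )
    lines = [_VCF_HEADER.format(fail=STATUS_FAIL_FILTER)]
    if contig_lengths:
        for contig, length in contig_lengths.items():
            lines.append(f"##contig=<ID={contig},length={int(length)}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
    )
    for r in frame.itertuples(index=False):
        mq = r.mapping_quality
        if np.isnan(mq):
            info = "."
        elif float(mq).is_integer():
            info = f"MQ={int(mq)}"
        else:
            info = f"MQ={mq:g}"
        filt = "PASS" if r.status_pass else STATUS_FAIL_FILTER
        lines.append(
            f"{r.chromosome}\t{int(r.position)}\t.\t{r.ref}\t{r.alt}\t.\t"
            f"{filt}\t{info}\tGT\t{_GT_FIELD[r.genotype]}\n"
        )
    Path(path).write_text("".join(lines))


SEGMENT_CLASSIFICATIONS = ("introgressed", "artifact_candidate")


@dataclass(frozen=True)
class GenomicSegment:
    """A contiguous interval called as introgressed, or flagged as artifact.

    Coordinates are 1-based inclusive; a single-SNP artifact candidate may be
    degenerate (``start == end``).
    """

    chromosome: str
    start: int
    end: int
    n_supporting_snps: int
    classification: str = "introgressed"
    mean_mapping_quality: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid segment interval [{self.start}, {self.end}]"
            )
        if self.n_supporting_snps < 1:
            raise ValueError("segment needs at least one supporting SNP")
        if self.classification not in SEGMENT_CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")

    @property
    def length(self) -> int:
        """Interval length in bp (inclusive of both ends)."""
        return self.end - self.start + 1

    def annotated(self, **changes) -> "GenomicSegment":
        return replace(self, **changes)


def write_bed(segments: Sequence[GenomicSegment], path: str | Path) -> None:
    """Write segments as BED (0-based half-open), name column = classification.

    Columns: chrom, start, end, name, score (supporting SNP count).  Output is
    deterministically ordered by (chromosome, start).
    """
    ordered = sorted(segments, key=lambda s: (s.chromosome, s.start, s.end))
    with open(path, "w") as fh:
        for s in ordered:
            fh.write(
                f"{s.chromosome}\t{s.start - 1}\t{s.end}\t"
                f"{s.classification}\t{s.n_supporting_snps}\n"
            )


def read_bed(path: str | Path) -> list[GenomicSegment]:
    """Read a BED file written by :func:`write_bed` back into segments.

    Three-column BED is accepted: the name defaults to ``introgressed`` and
    the score to 1.
    """
    segments: list[GenomicSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: not a BED line: {line!r}")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "introgressed"
            score = int(parts[4]) if len(parts) > 4 else 1
            segments.append(
                GenomicSegment(
                    chromosome=chrom,
                    start=start0 + 1,
                    end=end,
                    n_supporting_snps=score,
                    classification=name,
                )
            )
    return segments


_PANEL_SITE_COLUMNS = ("chromosome", "position", "ref", "alt")


@dataclass
class StrainPanel:
    """Strain x site presence/absence matrix of alternate alleles.

    ``alleles[i, j]`` is True iff strain ``strains[i]`` carries the alternate
    allele of site ``j`` (row ``j`` of ``sites``).
    """

    strains: list[str]
    sites: pd.DataFrame  # columns: chromosome, position, ref, alt
    alleles: np.ndarray  # bool, shape (n_strains, n_sites)

    def __post_init__(self) -> None:
        self.strains = list(self.strains)
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain labels in panel")
        missing = [c for c in _PANEL_SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"panel site table lacks columns {missing}")
        self.sites = self.sites.reset_index(drop=True)
        self.alleles = np.asarray(self.alleles, dtype=bool)
        if self.alleles.shape != (len(self.strains), len(self.sites)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.strains)} strains x {len(self.sites)} sites"
            )
        dup = self.sites.duplicated(subset=["chromosome", "position"])
        if dup.any():
            first = self.sites[dup].iloc[0]
            raise ValueError(
                f"duplicate panel site {first['chromosome']}:{first['position']}"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict[tuple[str, int], int]:
        """Map (chromosome, position) -> column index of the allele matrix."""
        return {
            (str(c), int(p)): j
            for j, (c, p) in enumerate(
                zip(self.sites["chromosome"], self.sites["position"])
            )
        }

    def carried_by_any(self) -> np.ndarray:
        """Per-site boolean: at least one strain carries the alt allele."""
        if self.n_strains == 0:
            return np.zeros(self.n_sites, dtype=bool)
        return self.alleles.any(axis=0)


def write_strain_panel(panel: StrainPanel, path: str | Path) -> None:
    """Write a panel as a tab-delimited table (one row per site, 0/1 per strain)."""
    out = panel.sites.loc[:, list(_PANEL_SITE_COLUMNS)].copy()
    for i, strain in enumerate(panel.strains):
        out[strain] = panel.alleles[i].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_strain_panel(path: str | Path) -> StrainPanel:
    """Read a tab-delimited strain x site table written by :func:`write_strain_panel`.

    Raises
    ------
    ValueError
        For ragged rows, duplicate (chromosome, position) sites, or allele
        entries other than 0/1.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in _PANEL_SITE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: panel table lacks columns {missing}")
    strains = [c for c in table.columns if c not in _PANEL_SITE_COLUMNS]
    allele_block = table.loc[:, strains]
    if allele_block.isna().any().any() or table.loc[:, list(_PANEL_SITE_COLUMNS)].isna().any().any():
        raise ValueError(f"{path}: ragged or incomplete rows in panel table")
    values = allele_block.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: allele entries must be 0 or 1")
    return StrainPanel(
        strains=strains,
        sites=table.loc[:, list(_PANEL_SITE_COLUMNS)],
        alleles=values.T.astype(bool),
    )
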