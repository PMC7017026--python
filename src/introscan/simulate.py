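"""Synthetic congenic genomes, strain panels, cohorts and qPCR tables.

The generator emulates the inputs of the discovery pipeline with a fully
known ground truth, so that every downstream operation can be tested as a
planted-truth recovery problem:

* a congenic variant call set — reference-homozygous everywhere except a
  planted introgressed mosaic of heterozygous blocks on one chromosome, plus
  small scattered artifact clusters (sequencing error / drift) with degraded
  quality scores;
* a 36-strain genotype panel in which introgressed alleles are shared with
  other strains at strain-specific rates, except inside a planted
  private-site region carried by no strain;
* phenotype cohorts with genotype-dependent sex-reversal probabilities and
  categorical gonad scores;
* qPCR Ct replicates with a planted fold change between groups.

All randomness flows from a single integer seed through named sub-streams,
so each output is reproducible independently of the others.

Interval convention: planted truth intervals (blocks, gaps, regions) are
0-based half-open ``(start_bp, end_bp)``; a 1-based variant position ``p``
lies inside iff ``start_bp < p <= end_bp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CALL_COLUMNS, StrainPanel, empty_calls

__all__ = [
    "HET",
    "HOM_REF",
    "QualityModel",
    "IntrogressionTruth",
    "SimulationConfig",
    "CohortConfig",
    "QpcrConfig",
    "GONAD_CATEGORIES",
    "DEFAULT_STRAINS",
    "default_sharing_profile",
    "default_introgression_truth",
    "generate_congenic_callset",
    "generate_strain_panel",
    "generate_cohort",
    "generate_qpcr",
]

HET = "heterozygous"
HOM_REF = "reference_homozygous"

_BASES = np.array(["A", "C", "G", "T"])

# named sub-streams hanging off the single config seed
_STREAMS = {
    "het_sites": 1,
    "artifacts": 2,
    "alleles": 3,
    "panel": 4,
    "cohort": 5,
    "qpcr": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# configuration / truth types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualityModel:
    """Two-component per-site quality model.

    Calls of introgression origin draw their mapping quality from a high
    component, artifact calls from a lower-shifted one, so that a quality
    filter at the default threshold (score 200) is meaningful: essentially
    all true sites survive it while most artifact sites do not.  Scores are
    clipped to ``[mq_min, mq_max]`` and rounded to integers.
    """

    true_mq_mean: float = 700.0
    true_mq_sd: float = 120.0
    artifact_mq_mean: float = 150.0
    artifact_mq_sd: float = 80.0
    mq_min: float = 0.0
    mq_max: float = 1000.0
    true_pass_prob: float = 0.98
    artifact_pass_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("true_pass_prob", "artifact_pass_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.true_mq_sd < 0 or self.artifact_mq_sd < 0:
            raise ValueError("quality-score standard deviations must be >= 0")
        if self.mq_min > self.mq_max:
            raise ValueError("mq_min must not exceed mq_max")


@dataclass(frozen=True)
class IntrogressionTruth:
    """Planted introgression: a mosaic of het / hom-ref blocks on one chromosome.

    ``blocks`` must be sorted, non-overlapping and contiguous in intent (gaps
    between blocks are simply background, i.e. reference-homozygous);
    ``devoid_gaps`` are intervals *inside heterozygous blocks* that carry zero
    variants; ``private_site_region`` is the interval in which panel-private
    sites are concentrated (no panel strain carries those alleles).
    """

    chromosome: str
    blocks: tuple[tuple[int, int, str], ...]
    devoid_gaps: tuple[tuple[int, int], ...] = ()
    private_site_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("truth needs at least one block")
        prev_end = -1
        for start, end, state in self.blocks:
            if state not in (HET, HOM_REF):
                raise ValueError(f"unknown block state {state!r}")
            if not 0 <= start < end:
                raise ValueError(f"invalid block interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = end
        het = self.het_blocks()
        for gs, ge in self.devoid_gaps:
            if gs >= ge:
                raise ValueError(f"invalid devoid gap ({gs}, {ge})")
            if not any(bs <= gs and ge <= be for bs, be in het):
                raise ValueError(
                    f"devoid gap ({gs}, {ge}) not inside a heterozygous block"
                )
        if self.private_site_region is not None:
            ps, pe = self.private_site_region
            if ps >= pe:
                raise ValueError("invalid private_site_region")

    def het_blocks(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, state in self.blocks if state == HET]

    def het_intervals(self) -> list[tuple[int, int]]:
        """Heterozygous blocks with devoid gaps subtracted."""
        out: list[tuple[int, int]] = []
        for bs, be in self.het_blocks():
            cut = [(gs, ge) for gs, ge in sorted(self.devoid_gaps) if gs >= bs and ge <= be]
            pos = bs
            for gs, ge in cut:
                if gs > pos:
                    out.append((pos, gs))
                pos = ge
            if pos < be:
                out.append((pos, be))
        return out

    @property
    def region_start(self) -> int:
        return self.blocks[0][0]

    @property
    def region_end(self) -> int:
        return self.blocks[-1][1]

    @property
    def region_length(self) -> int:
        """Planted region length: last end minus first start."""
        return self.region_end - self.region_start


# mm10 chromosome sizes for the simulated subset of the genome
_DEFAULT_CHROM_LENGTHS = {
    "1": 195_471_971,
    "4": 156_508_116,
    "13": 120_421_639,
}

#: the 36 inbred and wild-derived strains of the comparison panel
DEFAULT_STRAINS = (
    "129P2/OlaHsd", "129S1/SvImJ", "129S5SvEvBrd", "A/J", "AKR/J",
    "BALB/cJ", "BTBR T+ Itpr3tf/J", "BUB/BnJ", "C3H/HeH", "C3H/HeJ",
    "C57BL/10J", "C57BL/6NJ", "C57BR/cdJ", "C57L/J", "C58/J",
    "CAST/EiJ", "CBA/J", "DBA/1J", "DBA/2J", "FVB/NJ",
    "I/LnJ", "KK/HiJ", "LEWES/EiJ", "LP/J", "MOLF/EiJ",
    "NOD/ShiLtJ", "NZB/B1NJ", "NZO/HlLtJ", "NZW/LacJ", "PWK/PhJ",
    "RF/J", "SEA/GnJ", "SPRET/EiJ", "ST/bJ", "WSB/EiJ", "ZALENDE/EiJ",
)

_WILD_DERIVED = frozenset(
    {"CAST/EiJ", "PWK/PhJ", "SPRET/EiJ", "MOLF/EiJ", "WSB/EiJ",
     "LEWES/EiJ", "ZALENDE/EiJ"}
)


def default_sharing_profile(strains: Sequence[str] = DEFAULT_STRAINS) -> dict[str, float]:
    """Per-strain probability that an introgressed allele is carried.

    BALB/cJ is given the highest sharing rate and C57BL/6NJ the lowest
    (classical-strain haplotypes are widely shared; the two B6 substrains are
    outliers in a region divergent from the reference); wild-derived strains
    share at a reduced rate.  Remaining classical strains get rates spread
    deterministically over 0.35-0.65.
    """
    profile: dict[str, float] = {}
    for i, strain in enumerate(strains):
        if strain == "BALB/cJ":
            profile[strain] = 0.85
        elif strain == "C57BL/6NJ":
            profile[strain] = 0.02
        elif strain in _WILD_DERIVED:
            profile[strain] = 0.15
        else:
            profile[strain] = 0.35 + 0.30 * (i % 7) / 6.0
    return profile


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the congenic call-set / panel generator.

    ``het_site_rate`` is the density of heterozygous non-reference calls
    inside heterozygous blocks, in sites per Mb.  ``artifact_cluster_rate``
    is the expected number of artifact clusters per simulated genome; each
    cluster carries ``artifact_cluster_size`` (uniform inclusive bounds)
    sites within a tight span of ``artifact_cluster_span`` bp.
    """

    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_LENGTHS)
    )
    het_site_rate: float = 1000.0  # sites per Mb inside het blocks
    artifact_cluster_rate: float = 20.0  # clusters per genome
    artifact_cluster_size: tuple[int, int] = (1, 5)
    artifact_cluster_span: int = 500  # bp
    quality: QualityModel = field(default_factory=QualityModel)
    panel_strains: tuple[str, ...] = DEFAULT_STRAINS
    sharing_profile: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.het_site_rate < 0 or self.artifact_cluster_rate < 0:
            raise ValueError("rates must be >= 0")
        lo, hi = self.artifact_cluster_size
        if not 1 <= lo <= hi:
            raise ValueError("artifact_cluster_size bounds must satisfy 1 <= lo <= hi")
        if self.artifact_cluster_span < 1:
            raise ValueError("artifact_cluster_span must be >= 1")
        for c, length in self.chromosome_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {c} has non-positive length")
        if self.sharing_profile is not None:
            extra = set(self.sharing_profile) - set(self.panel_strains)
            if extra:
                raise ValueError(f"unknown strain label(s) in sharing_profile: {sorted(extra)}")
            for strain, p in self.sharing_profile.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"sharing probability for {strain} not in [0, 1]")

    def resolved_sharing_profile(self) -> dict[str, float]:
        if self.sharing_profile is None:
            return default_sharing_profile(self.panel_strains)
        profile = dict(self.sharing_profile)
        missing = set(self.panel_strains) - set(profile)
        if missing:
            raise ValueError(
                f"sharing_profile lacks strain(s): {sorted(missing)}"
            )
        return profile


def default_introgression_truth() -> IntrogressionTruth:
    """The default planted introgression used throughout tests and the demo.

    A ~37.5 Mb mosaic on chromosome 13 spanning 38.2-75.7 Mb: four
    heterozygous blocks interleaved with three short reference-homozygous
    blocks (the signature of successive backcross recombination), one 4.5 Mb
    variant-devoid gap centered on 51.8 Mb inside the second heterozygous
    block, and panel-private sites concentrated in 60-70 Mb.
    """
    mb = 1_000_000
    return IntrogressionTruth(
        chromosome="13",
        blocks=(
            (int(38.2 * mb), int(44.0 * mb), HET),
            (int(44.0 * mb), int(45.5 * mb), HOM_REF),
            (int(45.5 * mb), int(58.0 * mb), HET),
            (int(58.0 * mb), int(59.5 * mb), HOM_REF),
            (int(59.5 * mb), int(70.5 * mb), HET),
            (int(70.5 * mb), int(71.5 * mb), HOM_REF),
            (int(71.5 * mb), int(75.7 * mb), HET),
        ),
        devoid_gaps=((int(49.55 * mb), int(54.05 * mb)),),
        private_site_region=(60 * mb, 70 * mb),
    )


# ---------------------------------------------------------------------------
# call-set generator
# ---------------------------------------------------------------------------


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Random REF plus a distinct ALT base for n sites."""
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def generate_congenic_callset(
    config: SimulationConfig,
    truth: IntrogressionTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the SNP call set of one congenic individual.

    Heterozygous calls are emitted at homogeneous-Poisson positions inside
    the heterozygous truth blocks (never inside devoid gaps); artifact
    clusters are placed uniformly elsewhere in the genome (outside
    heterozygous blocks).  Every call carries a mapping quality and a
    status-pass flag drawn from the two-component quality model.

    Returns
    -------
    (calls, truth_record)
        ``calls``: canonical call frame (see :mod:`introscan.io`).
        ``truth_record``: one row per emitted call with columns
        ``chromosome, position, origin`` (``introgression`` | ``artifact``)
        and ``in_private_region``.

    Raises
    ------
    ValueError
        If the truth chromosome is absent from the configured genome or a
        block exceeds the chromosome bounds.
    """
    if truth is None:
        truth = default_introgression_truth()
    lengths = dict(config.chromosome_lengths)
    if truth.chromosome not in lengths:
        raise ValueError(
            f"truth chromosome {truth.chromosome!r} not in configured genome "
            f"{sorted(lengths)}"
        )
    chrom_len = lengths[truth.chromosome]
    if truth.region_end > chrom_len:
        raise ValueError(
            f"truth blocks end at {truth.region_end} bp, beyond chromosome "
            f"{truth.chromosome} length {chrom_len}"
        )

    q = config.quality

    # --- introgressed heterozygous sites: Poisson per het interval ----------
    rng_het = _rng(config.seed, "het_sites")
    pos_parts: list[np.ndarray] = []
    for start, end in truth.het_intervals():
        n = rng_het.poisson(config.het_site_rate * (end - start) / 1e6)
        if n:
            pos_parts.append(rng_het.integers(start + 1, end + 1, n, dtype=np.int64))
    het_pos = (
        np.unique(np.concatenate(pos_parts)) if pos_parts else np.empty(0, np.int64)
    )
    n_het = len(het_pos)

    # --- artifact clusters: uniform over the genome, outside het blocks -----
    rng_art = _rng(config.seed, "artifacts")
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    n_clusters = rng_art.poisson(config.artifact_cluster_rate)
    het_blocks = truth.het_blocks()
    art_chrom: list[str] = []
    art_pos_parts: list[np.ndarray] = []
    lo, hi = config.artifact_cluster_size
    span = config.artifact_cluster_span
    for _ in range(n_clusters):
        for _attempt in range(1000):
            c = chroms[rng_art.choice(len(chroms), p=weights)]
            center = int(rng_art.integers(1, lengths[c] + 1))
            if c == truth.chromosome and any(
                bs < center + span and center - span <= be for bs, be in het_blocks
            ):
                continue  # would touch a heterozygous block: redraw
            break
        size = int(rng_art.integers(lo, hi + 1))
        offsets = rng_art.choice(span, size=min(size, span), replace=False)
        positions = np.clip(center + offsets, 1, lengths[c]).astype(np.int64)
        positions = np.unique(positions)
        art_pos_parts.append(positions)
        art_chrom.extend([c] * len(positions))
    art_pos = (
        np.concatenate(art_pos_parts) if art_pos_parts else np.empty(0, np.int64)
    )
    n_art = len(art_pos)

    # --- assemble -----------------------------------------------------------
    rng_alleles = _rng(config.seed, "alleles")
    chromosome = np.concatenate(
        [np.repeat(truth.chromosome, n_het), np.array(art_chrom, dtype=object)]
    )
    position = np.concatenate([het_pos, art_pos])
    origin = np.concatenate(
        [np.repeat("introgression", n_het), np.repeat("artifact", n_art)]
    )
    mq = np.concatenate(
        [
            rng_alleles.normal(q.true_mq_mean, q.true_mq_sd, n_het),
            rng_alleles.normal(q.artifact_mq_mean, q.artifact_mq_sd, n_art),
        ]
    )
    mq = np.clip(np.round(mq), q.mq_min, q.mq_max)
    status = np.concatenate(
        [
            rng_alleles.random(n_het) < q.true_pass_prob,
            rng_alleles.random(n_art) < q.artifact_pass_prob,
        ]
    )
    ref, alt = _draw_alleles(rng_alleles, n_het + n_art)

    frame = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": position,
            "ref": ref,
            "alt": alt,
            "genotype": "het",
            "mapping_quality": mq,
            "status_pass": status,
            "origin": origin,
        }
    )
    # drop position collisions across origins (conservation: one origin per call)
    frame = frame.drop_duplicates(subset=["chromosome", "position"], keep="first")
    order = {c: i for i, c in enumerate(chroms)}
    frame = frame.sort_values(
        by=["chromosome", "position"],
        key=lambda s: s.map(order) if s.name == "chromosome" else s,
        kind="mergesort",
    ).reset_index(drop=True)

    in_private = np.zeros(len(frame), dtype=bool)
    if truth.private_site_region is not None:
        ps, pe = truth.private_site_region
        in_private = (
            (frame["chromosome"] == truth.chromosome)
            & (frame["position"] > ps)
            & (frame["position"] <= pe)
        ).to_numpy()

    calls = frame.loc[:, list(CALL_COLUMNS)].copy()
    truth_record = pd.DataFrame(
        {
            "chromosome": frame["chromosome"],
            "position": frame["position"],
            "origin": frame["origin"],
            "in_private_region": in_private,
        }
    )
    return calls, truth_record


# ---------------------------------------------------------------------------
# strain panel generator
# ---------------------------------------------------------------------------


def generate_strain_panel(
    config: SimulationConfig,
    calls: pd.DataFrame,
    truth_record: pd.DataFrame,
) -> tuple[StrainPanel, pd.DataFrame]:
    """Simulate the strain x site allele panel for the introgressed sites.

    Each introgression-origin site is carried by each panel strain with that
    strain's sharing probability, except sites inside the planted private
    region, which no strain carries.

    Returns
    -------
    (panel, site_truth)
        ``site_truth`` has one row per panel site with the *realized* label:
        ``private`` iff no strain carries the alt allele (guaranteed inside
        the planted private region, possible by chance elsewhere).
    """
    profile = config.resolved_sharing_profile()
    strains = list(config.panel_strains)

    merged = calls.merge(
        truth_record, on=["chromosome", "position"], how="left", validate="1:1"
    )
    sites = merged[merged["origin"] == "introgression"].reset_index(drop=True)
    n_sites = len(sites)

    rng = _rng(config.seed, "panel")
    alleles = np.zeros((len(strains), n_sites), dtype=bool)
    shareable = ~sites["in_private_region"].to_numpy()
    for i, strain in enumerate(strains):
        alleles[i] = shareable & (rng.random(n_sites) < profile[strain])

    panel = StrainPanel(
        strains=strains,
        sites=sites.loc[:, ["chromosome", "position", "ref", "alt"]],
        alleles=alleles,
    )
    carried = panel.carried_by_any()
    site_truth = pd.DataFrame(
        {
            "chromosome": sites["chromosome"],
            "position": sites["position"],
            "label": np.where(carried, "shared", "private"),
            "in_private_region": sites["in_private_region"],
        }
    )
    return panel, site_truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

GONAD_CATEGORIES = ("O", "Ot", "ot", "oT", "T")

_DEFAULT_GONAD_PROBS = {
    # XY individuals of a sex-reversing congenic colony: region carriers are
    # shifted toward testicular tissue; full testes are not observed.
    "+/+": {"O": 0.55, "Ot": 0.30, "ot": 0.12, "oT": 0.03, "T": 0.0},
    "var/+": {"O": 0.10, "Ot": 0.20, "ot": 0.40, "oT": 0.30, "T": 0.0},
}


@dataclass(frozen=True)
class CohortConfig:
    """Phenotype-cohort generator parameters.

    Defaults emulate an XY sex-reversal colony in which ~72.5% of
    non-carriers develop as phenotypic females while carriers of the
    protective region mostly develop as males.
    """

    n_per_genotype: Mapping[str, int] = field(
        default_factory=lambda: {"+/+": 150, "var/+": 150}
    )
    p_female: Mapping[str, float] = field(
        default_factory=lambda: {"+/+": 0.725, "var/+": 0.30}
    )
    gonad_category_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in _DEFAULT_GONAD_PROBS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_genotype.items():
            if n < 0:
                raise ValueError(f"negative count for genotype {g!r}")
            if g not in self.p_female:
                raise ValueError(f"p_female missing genotype {g!r}")
            if g not in self.gonad_category_probs:
                raise ValueError(f"gonad_category_probs missing genotype {g!r}")
        for g, p in self.p_female.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_female[{g!r}] not in [0, 1]")
        for g, probs in self.gonad_category_probs.items():
            unknown = set(probs) - set(GONAD_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown gonad categories {sorted(unknown)}")
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"gonad category probabilities for {g!r} sum to {total}, not 1"
                )


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a phenotype cohort table.

    Returns a frame with columns ``animal_id, genotype, phenotypic_sex,
    gonad_category`` — Bernoulli sex draws and categorical gonad scores per
    animal, reproducible under the config seed.
    """
    rng = _rng(config.seed, "cohort")
    rows = []
    counter = 0
    for genotype, n in config.n_per_genotype.items():
        p_f = config.p_female[genotype]
        probs = config.gonad_category_probs[genotype]
        pvec = np.array([probs.get(c, 0.0) for c in GONAD_CATEGORIES])
        sexes = np.where(rng.random(n) < p_f, "female", "male")
        cats = rng.choice(len(GONAD_CATEGORIES), size=n, p=pvec)
        for s, c in zip(sexes, cats):
            counter += 1
            rows.append((f"a{counter:05d}", genotype, s, GONAD_CATEGORIES[c]))
    return pd.DataFrame(
        rows, columns=["animal_id", "genotype", "phenotypic_sex", "gonad_category"]
    )


# ---------------------------------------------------------------------------
# qPCR generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrConfig:
    """qPCR Ct-table generator parameters.

    The *last* group in ``groups`` is the calibrator; every other group
    expresses the target at ``true_fold_change`` times the calibrator level.
    Per replicate, the reference-gene Ct is Gaussian around
    ``reference_gene_ct_mean`` and the target Ct is the reference mean plus
    ``target_offset_ct`` minus log2(relative expression), both with cycle
    noise of ``ct_noise_sd``.
    """

    groups: tuple[str, ...] = ("var/+", "+/+")
    n_replicates: int = 5
    true_fold_change: float = 0.5
    ct_noise_sd: float = 0.2
    reference_gene_ct_mean: float = 20.0
    target_offset_ct: float = 2.0
    target_gene: str = "Rspo1"
    reference_gene: str = "Hprt1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups (one is the calibrator)")
        if self.true_fold_change <= 0:
            raise ValueError("true_fold_change must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    @property
    def calibrator_group(self) -> str:
        return self.groups[-1]


def generate_qpcr(config: QpcrConfig) -> pd.DataFrame:
    """Draw a long-format Ct table.

    Returns a frame with columns ``sample_id, group, gene, ct`` carrying one
    target-gene and one reference-gene measurement per replicate.
    """
    rng = _rng(config.seed, "qpcr")
    rows = []
    counter = 0
    for group in config.groups:
        expr = 1.0 if group == config.calibrator_group else config.true_fold_change
        for _ in range(config.n_replicates):
            counter += 1
            sid = f"s{counter:04d}"
            ct_ref = rng.normal(config.reference_gene_ct_mean, config.ct_noise_sd)
            ct_tgt = rng.normal(
                config.reference_gene_ct_mean
                + config.target_offset_ct
                - math.log2(expr),
                config.ct_noise_sd,
            )
            rows.append((sid, group, config.reference_gene, ct_ref))
            rows.append((sid, group, config.target_gene, ct_tgt))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
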