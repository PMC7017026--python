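"""Strain-panel comparison: private/shared SNP classification, strain
similarity ranking, private-SNP geography, and marker-based region genotyping.

A segment SNP is *shared* if at least one panel strain carries its alternate
allele, and *private* otherwise — private variants have no known donor among
the catalogued strains.  Sites absent from the panel's site list count as
carried by no strain (mirroring classification against an incomplete
catalogue) and are logged so users can audit the decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import StrainPanel
from .scan import ScanParams, WindowDensityTrack, window_density

__all__ = [
    "ProvenanceReport",
    "REGION_GENOTYPES",
    "classify_private",
    "strain_similarity",
    "windowed_private_density",
    "densest_span",
    "compare_to_panel",
    "genotype_region",
    "default_marker_table",
]

log = logging.getLogger(__name__)


def classify_private(sites: pd.DataFrame, panel: StrainPanel) -> pd.DataFrame:
    """Label each site ``private`` or ``shared`` against the panel.

    Parameters
    ----------
    sites
        Frame with at least ``chromosome`` and ``position`` columns (e.g. the
        heterozygous calls inside a called segment).
    panel
        Strain x site allele panel.

    Returns
    -------
    pandas.DataFrame
        ``sites`` plus columns ``label`` (private/shared) and ``shared_with``
        (comma-joined strain labels carrying the alt allele; empty for
        private sites).
    """
    if panel.n_strains == 0:
        log.warning("empty strain panel: every site classified private")
    index = panel.site_index()
    carried = panel.carried_by_any()
    alleles = panel.alleles
    strains = np.array(panel.strains, dtype=object)

    labels: list[str] = []
    shared_with: list[str] = []
    n_absent = 0
    for chrom, pos in zip(sites["chromosome"], sites["position"]):
        j = index.get((str(chrom), int(pos)))
        if j is None:
            n_absent += 1
            labels.append("private")
            shared_with.append("")
        elif carried[j]:
            labels.append("shared")
            shared_with.append(",".join(strains[alleles[:, j]]))
        else:
            labels.append("private")
            shared_with.append("")
    if n_absent:
        log.info(
            "%d site(s) absent from the panel catalogue; counted as carried "
            "by no strain (private)",
            n_absent,
        )
    out = sites.copy()
    out["label"] = labels
    out["shared_with"] = shared_with
    return out


def strain_similarity(sites: pd.DataFrame, panel: StrainPanel) -> pd.DataFrame:
    """Per-strain fraction of sites whose alternate allele the strain carries.

    Returns a frame with columns ``strain, fraction, rank`` sorted by
    descending fraction; ties broken deterministically by strain label.

    Raises
    ------
    ValueError
        If ``sites`` is empty.
    """
    if len(sites) == 0:
        raise ValueError("strain similarity needs at least one site")
    index = panel.site_index()
    cols = [
        index[(str(c), int(p))]
        for c, p in zip(sites["chromosome"], sites["position"])
        if (str(c), int(p)) in index
    ]
    n = len(sites)
    if cols:
        counts = panel.alleles[:, cols].sum(axis=1)
    else:
        counts = np.zeros(panel.n_strains, dtype=int)
    out = pd.DataFrame(
        {"strain": panel.strains, "fraction": counts / n}
    ).sort_values(
        by=["fraction", "strain"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def windowed_private_density(
    labeled_sites: pd.DataFrame,
    chromosome_length: int,
    params: ScanParams | None = None,
) -> WindowDensityTrack:
    """Windowed density split into private and shared counts.

    ``labeled_sites`` must carry a ``label`` column (from
    :func:`classify_private`) and lie on a single chromosome.
    """
    chroms = labeled_sites["chromosome"].unique()
    if len(chroms) > 1:
        raise ValueError(f"sites span multiple chromosomes: {sorted(map(str, chroms))}")
    chromosome = str(chroms[0]) if len(chroms) else ""
    return window_density(
        labeled_sites,
        chromosome,
        chromosome_length,
        params,
        labels=labeled_sites["label"].to_numpy() if len(labeled_sites) else [],
    )


def densest_span(
    track: WindowDensityTrack,
    span_bp: int = 10_000_000,
    which: str = "private",
) -> tuple[int, int]:
    """Start (0-based bp) and count of the span maximizing the windowed count.

    The span covers ``span_bp // window_size`` consecutive windows and slides
    in 1-window steps; ties resolve to the smallest start.

    Returns
    -------
    (start_bp, count)
    """
    counts = {
        "private": track.private_counts,
        "shared": track.shared_counts,
        "total": track.counts,
    }[which]
    if counts is None:
        raise ValueError(f"track carries no {which!r} counts")
    k = max(1, span_bp // track.window_size)
    k = min(k, len(counts))
    sums = np.convolve(counts, np.ones(k, dtype=np.int64), mode="valid")
    i = int(np.argmax(sums))  # first maximum: smallest start wins ties
    return i * track.window_size, int(sums[i])


@dataclass
class ProvenanceReport:
    """Private/shared classification of a segment against a strain panel."""

    sites: pd.DataFrame        # labeled sites (classify_private output)
    similarity: pd.DataFrame   # strain, fraction, rank
    track: WindowDensityTrack | None = None

    @property
    def n_private(self) -> int:
        return int((self.sites["label"] == "private").sum())

    @property
    def n_shared(self) -> int:
        return int((self.sites["label"] == "shared").sum())

    @property
    def top_strain(self) -> str:
        return str(self.similarity.iloc[0]["strain"])

    def summary(self) -> str:
        lines = [
            "Strain-panel comparison",
            "=======================",
            f"sites:           {len(self.sites)}",
            f"  private:       {self.n_private}",
            f"  shared:        {self.n_shared}",
            "",
            "top strains by similarity:",
        ]
        for r in self.similarity.head(5).itertuples(index=False):
            lines.append(f"  {r.rank:>2}. {r.strain:<20} {r.fraction:.3f}")
        if self.track is not None and self.track.private_counts is not None:
            start, count = densest_span(self.track)
            lines.append("")
            lines.append(
                f"densest 10-Mb private span: starts {start / 1e6:.0f} Mb "
                f"({count} private SNPs)"
            )
        return "\n".join(lines)


def compare_to_panel(
    sites: pd.DataFrame,
    panel: StrainPanel,
    chromosome_length: int | None = None,
    params: ScanParams | None = None,
) -> ProvenanceReport:
    """Classify sites, rank strains, and (optionally) build the density split."""
    labeled = classify_private(sites, panel)
    similarity = strain_similarity(sites, panel)
    track = None
    if chromosome_length is not None:
        track = windowed_private_density(labeled, chromosome_length, params)
    return ProvenanceReport(sites=labeled, similarity=similarity, track=track)


# ---------------------------------------------------------------------------
# marker-based region genotyping
# ---------------------------------------------------------------------------

REGION_GENOTYPES = ("+/+", "var/+", "var/var", "discordant")

_CALL_TO_GENOTYPE = {
    "hom_ref": "+/+",
    "het": "var/+",
    "hom_alt": "var/var",
}


def default_marker_table() -> pd.DataFrame:
    """Nine diagnostic marker SNPs spread across the default region.

    Positions span 39-75 Mb of chromosome 13 at 4.5 Mb intervals.
    """
    mb = 1_000_000
    positions = [int((39.0 + 4.5 * i) * mb) for i in range(9)]
    return pd.DataFrame(
        {
            "marker": [f"m{i + 1:02d}" for i in range(9)],
            "chromosome": "13",
            "position": positions,
        }
    )


def genotype_region(
    marker_calls: Mapping[str, str] | pd.DataFrame,
    markers: Sequence[str] | pd.DataFrame | None = None,
) -> str:
    """Derive the region genotype from per-marker SNP calls.

    All informative markers heterozygous -> ``var/+``; all homozygous
    alternate -> ``var/var``; all homozygous reference -> ``+/+``.  Any
    mixture is reported as ``discordant`` (a possible recombinant) and is
    deliberately never resolved by majority.

    Parameters
    ----------
    marker_calls
        Mapping marker id -> genotype (``het``/``hom_ref``/``hom_alt``/
        ``missing``), or a frame with ``marker`` and ``genotype`` columns.
    markers
        Known marker ids (sequence or a frame with a ``marker`` column);
        calls at unknown ids raise.  Defaults to the nine markers of
        :func:`default_marker_table`.

    Raises
    ------
    ValueError
        For an unknown marker id, no marker calls, or all-missing calls.
    """
    if isinstance(marker_calls, pd.DataFrame):
        calls = dict(zip(marker_calls["marker"], marker_calls["genotype"]))
    else:
        calls = dict(marker_calls)
    if not calls:
        raise ValueError("need at least one marker call")
    if markers is None:
        known = set(default_marker_table()["marker"])
    elif isinstance(markers, pd.DataFrame):
        known = set(markers["marker"])
    else:
        known = set(markers)
    unknown = set(calls) - known
    if unknown:
        raise ValueError(f"unknown marker id(s): {sorted(unknown)}")
    observed = {g for g in calls.values() if g != "missing"}
    if not observed:
        raise ValueError("all marker calls missing; cannot genotype")
    bad = observed - set(_CALL_TO_GENOTYPE)
    if bad:
        raise ValueError(f"unknown marker genotype(s): {sorted(bad)}")
    if len(observed) == 1:
        return _CALL_TO_GENOTYPE[observed.pop()]
    return "discordant"
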