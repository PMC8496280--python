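"""Trans-eQTL hotspot (trans-band) detection and GO enrichment.

A trans-band is a locus where many trans-eQTLs of the same SNP
distribution pattern co-locate.  Detection is stratified by SDP and
proceeds by greedy peak extraction: among the markers of an SDP on a
chromosome, take the marker harboring the most not-yet-assigned
trans-eQTL peaks (of that SDP) within a 1-Mbp window to both sides;
if that count strictly exceeds the minimum (100 by default) it founds a
band and claims the eQTLs in its window, and the search repeats on the
remainder.  Greedy extraction lets two hotspots of the same SDP closer
than two window widths remain separate bands — a configuration that
occurs in practice — while absorbing satellite candidates that merely
overlap a hotspot's window.  Band borders are peak +/- window, clipped
at the chromosome ends; two overlapping same-SDP bands share the
midpoint between their peaks as a boundary, which keeps band membership
a partition.  Member genes are tested for GO-term over-representation
with the upper-tail hypergeometric test against the expressed-gene
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .stats import hypergeom_upper_tail


@dataclass
class TransBand:
    """One trans-eQTL hotspot: SDP, location, borders, and member genes."""

    sdp: str
    chromosome: str
    peak: int
    left: int
    right: int
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.left <= self.peak <= self.right):
            raise ValueError("band borders must satisfy left <= peak <= right")

    @property
    def count(self) -> int:
        return len(self.genes)


def detect_trans_bands(
    records: pd.DataFrame,
    genos: GenotypeMatrix,
    min_count: int = 100,
    window: int = 1_000_000,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[TransBand]:
    """Detect trans-bands from significant trans-eQTL records.

    ``records`` needs ``chromosome``, ``position``, ``sdp`` and ``type``
    columns (only ``type == "trans"`` rows are used); the gene id is the
    index.  Counting and banding are per SDP; a candidate marker must
    harbor strictly more than ``min_count`` trans-eQTLs within
    ``window`` bp to both sides.
    """
    bands: list[TransBand] = []
    if len(records) == 0:
        return bands
    trans = records[records["type"] == "trans"]
    if len(trans) == 0:
        return bands
    marker_meta = genos.marker_frame()
    for sdp in sorted(trans["sdp"].unique()):
        sub = trans[trans["sdp"] == sdp]
        sdp_markers = marker_meta[marker_meta["sdp"] == sdp]
        for chrom in sorted(sub["chromosome"].unique()):
            peaks = np.sort(sub.loc[sub["chromosome"] == chrom, "position"].to_numpy())
            cand = sdp_markers[sdp_markers["chromosome"] == chrom].sort_values("position")
            if len(cand) == 0 or len(peaks) <= min_count:
                continue
            pos = cand["position"].to_numpy()
            L = (chrom_lengths or {}).get(chrom)
            chrom_bands: list[TransBand] = []
            unassigned = np.ones(len(peaks), dtype=bool)
            while True:
                avail = peaks[unassigned]
                counts = np.searchsorted(avail, pos + window, side="right") - np.searchsorted(
                    avail, pos - window, side="left"
                )
                best = int(np.argmax(counts))  # ties: lowest position (sorted order)
                if counts[best] <= min_count:
                    break
                peak = int(pos[best])
                unassigned &= np.abs(peaks - peak) > window
                left = max(0, peak - window)
                right = peak + window if L is None else min(peak + window, L)
                chrom_bands.append(TransBand(sdp, chrom, peak, left, right))
            # trim overlapping same-SDP bands at the midpoint between peaks
            chrom_bands.sort(key=lambda b: b.peak)
            for a, b in zip(chrom_bands, chrom_bands[1:]):
                if a.right >= b.left:
                    mid = (a.peak + b.peak) / 2.0
                    a.right = int(np.floor(mid))
                    b.left = int(np.floor(mid)) + 1
            for band in chrom_bands:
                members = sub[
                    (sub["chromosome"] == chrom)
                    & (sub["position"] >= band.left)
                    & (sub["position"] <= band.right)
                ]
                band.genes = list(members.index)
            bands.extend(chrom_bands)
    bands.sort(key=lambda b: (b.chromosome, b.peak, b.sdp))
    return bands


def bands_frame(bands: Sequence[TransBand]) -> pd.DataFrame:
    """Band summary with positions also in Mbp (2 decimals), report style."""
    return pd.DataFrame(
        {
            "sdp": [b.sdp for b in bands],
            "chromosome": [b.chromosome for b in bands],
            "peak_bp": [b.peak for b in bands],
            "left_bp": [b.left for b in bands],
            "right_bp": [b.right for b in bands],
            "peak_mbp": [round(b.peak / 1e6, 2) for b in bands],
            "left_mbp": [round(b.left / 1e6, 2) for b in bands],
            "right_mbp": [round(b.right / 1e6, 2) for b in bands],
            "n_eqtls": [b.count for b in bands],
        },
        index=pd.Index([f"TB{i + 1}" for i in range(len(bands))], name="band"),
    )


def go_enrichment(
    test_genes: set[str],
    go_map: dict[str, set[str]],
    background: set[str],
    p_threshold: float = 1e-5,
    min_set: int = 3,
    all_rows: bool = False,
) -> pd.DataFrame:
    """Hypergeometric GO-term over-representation of a gene set.

    The population is the background restricted to genes with any GO
    annotation; draws are the annotated test genes.  A term is reported
    when its upper-tail p is below ``p_threshold`` and its background
    gene count m is strictly greater than ``min_set``.  With
    ``all_rows`` every tested term is returned with a ``significant``
    flag.
    """
    if not background:
        raise ValueError("background gene set is empty")
    if not test_genes <= background:
        raise ValueError("test genes must be a subset of the background")
    annotated = set().union(*go_map.values()) if go_map else set()
    universe = background & annotated
    test = test_genes & universe
    N, n = len(universe), len(test)
    rows = []
    for term in sorted(go_map):
        members = go_map[term] & universe
        m = len(members)
        if m == 0:
            continue
        k = len(members & test)
        p = hypergeom_upper_tail(k, N, m, n)
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": m,
                "test_size": n,
                "background_size": N,
                "p_value": p,
                "significant": (p < p_threshold) and (m > min_set),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "test_size", "background_size", "p_value", "significant"],
    ).set_index("term")
    if not all_rows:
        df = df[df["significant"]].drop(columns="significant")
    return df.sort_values("p_value")
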